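"""Per-individual genotype calls at catalog variant positions.

Calls are made from per-column base depths (reads supporting each base at a
variant column, aggregated over the individual's stacks in the locus):

* top base below ``min_allele_depth``            -> missing (low_depth)
* no stack at the locus                          -> missing (no_stack)
* second base passing depth and minor/major >=
  ``min_minor_ratio``                            -> heterozygous
* otherwise                                      -> homozygous for the major
  base, with an allele_imbalance note whenever a minor base was observed
* three credible bases                           -> missing (repetitive)

No quality model is used: the library carries constant qualities.  The
default thresholds (depth >= 2, minor/major >= 0.1) are sized for the
20-60x tag depths this design targets: each allele of a heterozygote is
sampled Poisson(depth/2), so demanding three minor reads or a 0.25 ratio
discards 1-2% of true heterozygotes at 20x, while sequencing-error minor
alleles (expected ~0.17% of column depth per base at a 0.5% error rate)
essentially never reach two reads at a tenth of the major depth.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stacks import CatalogLocus

MISSING = "./."

REASON_NO_STACK = "no_stack"
REASON_LOW_DEPTH = "low_depth"
REASON_REPETITIVE = "repetitive"
NOTE_IMBALANCE = "allele_imbalance"

_ROW_TO_BASE = "ACGT"


def format_call(b1: str, b2: str) -> str:
    """Unordered diploid call, e.g. ('C','A') -> 'A/C'."""
    return "/".join(sorted((b1, b2)))


def is_het(call: str) -> bool:
    if call == MISSING:
        return False
    a, b = call.split("/")
    return a != b


def call_column(
    col_counts: np.ndarray,
    min_allele_depth: int = 2,
    min_minor_ratio: float = 0.1,
) -> tuple[str, str | None]:
    """Call one individual at one column from its 4-vector of base depths.

    Returns (call, note) where call is 'A/C'-style or './.' and note is a
    missing reason or imbalance annotation (None when clean).
    """
    order = np.argsort(col_counts, kind="stable")[::-1]
    c1, c2, c3 = (int(col_counts[order[i]]) for i in range(3))
    if c1 < min_allele_depth:
        return MISSING, REASON_LOW_DEPTH
    b1 = _ROW_TO_BASE[int(order[0])]
    if c2 >= min_allele_depth and c2 / c1 >= min_minor_ratio:
        if c3 >= min_allele_depth and c3 / c1 >= min_minor_ratio:
            return MISSING, REASON_REPETITIVE
        b2 = _ROW_TO_BASE[int(order[1])]
        return format_call(b1, b2), None
    note = NOTE_IMBALANCE if c2 > 0 else None
    return format_call(b1, b1), note


def call_genotypes(
    catalog: list[CatalogLocus],
    individuals: list[str],
    min_allele_depth: int = 2,
    min_minor_ratio: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Genotype matrix over all (locus, variant position) rows.

    Returns (matrix, notes): the matrix is indexed by (locus_id, position)
    with one column per individual and './.' for missing; notes records the
    reason/annotation for every missing or imbalanced cell.  Repetitive loci
    are excluded from the matrix entirely.
    """
    if not 0 <= min_minor_ratio <= 1:
        raise ValueError("min_minor_ratio must lie in [0, 1]")
    if min_allele_depth < 1:
        raise ValueError("min_allele_depth must be >= 1")

    rows = []
    index = []
    note_rows = []
    for locus in catalog:
        if locus.repetitive or not locus.variant_positions:
            continue
        per_ind = {ind: locus.individual_column_counts(ind) for ind in individuals}
        for pos in locus.variant_positions:
            col = pos - 1
            calls = {}
            for ind in individuals:
                cc = per_ind[ind]
                if cc is None:
                    calls[ind] = MISSING
                    note_rows.append((locus.locus_id, pos, ind, REASON_NO_STACK))
                    continue
                call, note = call_column(cc[:, col], min_allele_depth, min_minor_ratio)
                calls[ind] = call
                if note is not None:
                    note_rows.append((locus.locus_id, pos, ind, note))
            rows.append(calls)
            index.append((locus.locus_id, pos))

    matrix = pd.DataFrame(
        rows,
        index=pd.MultiIndex.from_tuples(index, names=["locus_id", "position"])
        if index
        else pd.MultiIndex.from_arrays([[], []], names=["locus_id", "position"]),
        columns=individuals,
        dtype=object,
    )
    notes = pd.DataFrame(
        note_rows, columns=["locus_id", "position", "individual_id", "note"]
    )
    return matrix, notes


def write_genotype_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t")


def read_genotype_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=["locus_id", "position"], dtype=str)
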