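"""Per-individual and per-group sequencing summary accounting.

Reproduces the standard RADseq run-summary table for a fixed 82-bp read
length: total RAD sequence = reads x 82 bp; total tag sequence = tags x 82
bp; coverage depth = reads / tags; sequence coverage = total RAD sequence /
genome size.  All printed ratios are rounded half-up to one decimal (two for
GC percent), and group averages are arithmetic means of the per-individual
derived values — a mean of ratios, not a ratio of sums, which is what such
tables print.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .simulate import TAG_LENGTH

#: haploid genome size used for sequence-coverage columns unless overridden;
#: flow-cytometry estimate for pistachio, the reference organism of the
#: bundled summary dataset
DEFAULT_GENOME_SIZE = 660_000_000


def round_half_up(value: float | Decimal, decimals: int = 0) -> float:
    """Decimal round-half-up (0.05 -> 0.1), matching printed-table rounding."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(str(value)).quantize(q, rounding=ROUND_HALF_UP))


def _ratio(num: int | float, den: int | float, decimals: int) -> float:
    return float(
        (Decimal(str(num)) / Decimal(str(den))).quantize(
            Decimal(1).scaleb(-decimals), rounding=ROUND_HALF_UP
        )
    )


@dataclass
class SummaryRow:
    individual_id: str
    read_number: int
    total_rad_sequence: int  # bp = reads x 82
    n_rad_tags: int
    total_tag_sequence: int  # bp = tags x 82
    coverage_depth: float | None  # reads / tags, 1 decimal
    sequence_coverage: float  # total RAD sequence / genome size, 1 decimal
    gc_rate: float | None  # percent, 2 decimals
    total_snp: int | None
    het_snp_rate: float | None  # percent, 1 decimal
    genome_size: int = DEFAULT_GENOME_SIZE  # carried for exact aggregation


def summarize_individual(
    individual_id: str,
    read_number: int,
    n_rad_tags: int,
    genome_size: int = DEFAULT_GENOME_SIZE,
    gc_rate: float | None = None,
    gc_count: int | None = None,
    base_count: int | None = None,
    total_snp: int | None = None,
    het_snp_rate: float | None = None,
) -> SummaryRow:
    """Derive all computed columns from raw counts.

    GC may be given directly (percent) or as (gc_count, base_count) tallies
    over all read bases.  With zero tags the coverage depth is undefined and
    reported as missing rather than raising.
    """
    if read_number < 0 or n_rad_tags < 0:
        raise ValueError("counts must be non-negative")
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    if gc_rate is None and gc_count is not None and base_count:
        gc_rate = _ratio(100 * gc_count, base_count, 2)
    return SummaryRow(
        individual_id=individual_id,
        read_number=read_number,
        total_rad_sequence=read_number * TAG_LENGTH,
        n_rad_tags=n_rad_tags,
        total_tag_sequence=n_rad_tags * TAG_LENGTH,
        coverage_depth=_ratio(read_number, n_rad_tags, 1) if n_rad_tags else None,
        sequence_coverage=_ratio(read_number * TAG_LENGTH, genome_size, 1),
        gc_rate=gc_rate,
        total_snp=total_snp,
        het_snp_rate=het_snp_rate,
        genome_size=genome_size,
    )


def bp_per_snp(total_tag_sequence: int, total_snp: int) -> int | None:
    """SNP density as base pairs of tag sequence per SNP (nearest integer)."""
    if total_snp < 0:
        raise ValueError("total_snp must be non-negative")
    if total_snp == 0:
        return None
    return int(_ratio(total_tag_sequence, total_snp, 0))


_SUM_COLS = [
    "read_number",
    "total_rad_sequence",
    "n_rad_tags",
    "total_tag_sequence",
    "coverage_depth",
    "sequence_coverage",
    "total_snp",
]
_MEAN_DECIMALS = {
    "read_number": 0,
    "total_rad_sequence": 0,
    "n_rad_tags": 0,
    "total_tag_sequence": 0,
    "coverage_depth": 1,
    "sequence_coverage": 1,
    "gc_rate": 2,
    "total_snp": 0,
    "het_snp_rate": 1,
}


def _rows_frame(rows: list[SummaryRow], groups: list[str]) -> pd.DataFrame:
    df = pd.DataFrame([vars(r) for r in rows])
    df.insert(1, "group", groups)
    return df


def _exact_ratios(df: pd.DataFrame, col: str) -> list[Decimal]:
    """Unrounded per-row values for the ratio columns, recomputed from raw
    counts: printed tables aggregate the exact ratios and round once."""
    out = []
    for r in df.itertuples(index=False):
        if col == "coverage_depth":
            if r.n_rad_tags:
                out.append(Decimal(int(r.read_number)) / Decimal(int(r.n_rad_tags)))
        else:  # sequence_coverage
            out.append(
                Decimal(int(r.total_rad_sequence)) / Decimal(int(r.genome_size))
            )
    return out


def _agg(df: pd.DataFrame, label: str, kind: str) -> dict:
    out: dict = {"individual_id": label, "group": ""}
    for col in _MEAN_DECIMALS:
        if col in ("coverage_depth", "sequence_coverage"):
            exact = _exact_ratios(df, col)
            if not exact:
                out[col] = None
                continue
            total = sum(exact, Decimal("0"))
            dec = _MEAN_DECIMALS[col]
            q = Decimal(1).scaleb(-dec)
            if kind == "sum":
                out[col] = float(total.quantize(q, rounding=ROUND_HALF_UP))
            else:
                out[col] = float(
                    (total / len(exact)).quantize(q, rounding=ROUND_HALF_UP)
                )
            continue
        vals = df[col].dropna()
        if vals.empty:
            out[col] = None
            continue
        if kind == "sum":
            if col in _SUM_COLS:
                total = Decimal("0")
                for v in vals:
                    total += Decimal(str(v))
                out[col] = float(total)
            else:
                out[col] = None
        else:
            total = Decimal("0")
            for v in vals:
                total += Decimal(str(v))
            mean = total / len(vals)
            dec = _MEAN_DECIMALS[col]
            out[col] = float(mean.quantize(Decimal(1).scaleb(-dec), rounding=ROUND_HALF_UP))
    return out


def summarize_group(rows: list[SummaryRow], groups: list[str]) -> pd.DataFrame:
    """Assemble the full summary table with Subtotal/Subaverage per group
    and Total/Average over all rows.

    Subtotals are column sums; for the ratio columns both subtotals and
    averages aggregate the exact (unrounded) per-individual ratios and round
    once at the end, which is how printed tables behave.  Averages of all
    other columns are arithmetic means of the per-individual values, rounded
    half-up to the printed precision of each column.
    """
    if len(rows) != len(groups):
        raise ValueError("one group label per row required")
    if not rows:
        raise ValueError("no rows to summarize")
    df = _rows_frame(rows, groups)

    records: list[dict] = []
    for g in pd.unique(df["group"]):
        sub = df[df["group"] == g]
        records.extend(sub.to_dict("records"))
        records.append(_agg(sub, f"Subtotal ({g})", "sum"))
        records.append(_agg(sub, f"Subaverage ({g})", "mean"))
    records.append(_agg(df, "Total", "sum"))
    records.append(_agg(df, "Average", "mean"))
    return pd.DataFrame(records)[["individual_id", "group", *list(_MEAN_DECIMALS)]]
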