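"""Scoring a pipeline run against the simulator's truth tables.

These helpers close the loop on synthetic data: they map de novo catalog
loci back to the simulated cut sites, compare called genotypes with planted
ones, check that planted sex-linked SNPs surfaced as candidates of the right
heterogamety, and Monte-Carlo the autosomal false-positive rate of the
perfect-cosegregation screen against its closed form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype import MISSING, format_call
from .samples import FEMALE, MALE
from .screen import SexMarkerCandidate, screen_sex_association
from .simulate import SEX_LINKED, SimGenome
from .stacks import CatalogLocus, _encode


def map_loci_to_sites(
    catalog: list[CatalogLocus], genome: SimGenome, max_mismatch: int = 4
) -> dict[str, int]:
    """locus_id -> simulated cut site, by nearest reference tag sequence.

    A slightly wider radius than the clustering one absorbs consensus drift
    from planted variants; ambiguous loci (no site within radius) are left
    unmapped.
    """
    sites = genome.usable_sites
    if not sites or not catalog:
        return {}
    ref_mat = _encode([genome.tag_sequence(s) for s in sites])
    out: dict[str, int] = {}
    for locus in catalog:
        row = _encode([locus.reference_consensus])[0]
        dist = (ref_mat != row).sum(axis=1)
        j = int(dist.argmin())
        if int(dist[j]) <= max_mismatch:
            out[locus.locus_id] = sites[j]
    return out


@dataclass
class ConcordanceReport:
    n_cells: int  # truth variant x individual cells
    n_match: int
    n_mismatch: int
    n_missing: int  # called './.'
    n_absent_rows: int  # truth variants with no row in the matrix

    @property
    def concordance(self) -> float:
        """Fraction of all truth cells called identically to the truth;
        missing cells count as discordant."""
        return self.n_match / self.n_cells if self.n_cells else float("nan")


def genotype_concordance(
    matrix: pd.DataFrame,
    truth: pd.DataFrame,
    locus_site_map: dict[str, int],
    individuals: list[str],
) -> ConcordanceReport:
    """Compare the called matrix against the simulator truth table.

    A truth variant with no row in the matrix carries the implied call
    hom(reference) for every individual — the absence of a variant row is
    the pipeline's way of calling a position invariant, and is correct
    whenever the variant is monomorphic in the sampled family.
    """
    site_to_locus = {s: l for l, s in locus_site_map.items()}
    n_cells = n_match = n_mismatch = n_missing = n_absent = 0
    for t in truth.itertuples(index=False):
        locus = site_to_locus.get(t.site)
        key = (locus, t.tag_position) if locus else None
        present = key is not None and key in matrix.index
        row = matrix.loc[key] if present else None
        if not present:
            n_absent += 1
        implied = f"{t.ref}/{t.ref}"
        for ind in individuals:
            n_cells += 1
            call = row[ind] if present else implied
            expected = getattr(t, ind)
            if call == MISSING:
                n_missing += 1
            elif call == expected:
                n_match += 1
            else:
                n_mismatch += 1
    return ConcordanceReport(n_cells, n_match, n_mismatch, n_missing, n_absent)


def sex_marker_recovery(
    candidates: list[SexMarkerCandidate],
    truth: pd.DataFrame,
    locus_site_map: dict[str, int],
    expected_heterogametic_sex: str = FEMALE,
) -> tuple[float, int, int]:
    """(recovered fraction, n recovered, n planted) of sex-linked variants.

    A planted variant counts as recovered when some candidate maps to its
    site at its tag position with the expected heterogametic sex.
    """
    site_to_locus = {s: l for l, s in locus_site_map.items()}
    planted = truth[truth["linkage"] == SEX_LINKED]
    found = {
        (c.locus_id, c.position)
        for c in candidates
        if c.heterogametic_sex == expected_heterogametic_sex
    }
    n_rec = 0
    for t in planted.itertuples(index=False):
        locus = site_to_locus.get(t.site)
        if locus and (locus, t.tag_position) in found:
            n_rec += 1
    n = len(planted)
    return (n_rec / n if n else float("nan")), n_rec, n


def cosegregation_monte_carlo(
    n_loci: int,
    n_female: int,
    n_male: int,
    seed: int | None = None,
    max_missing: int = 0,
) -> float:
    """Observed fraction of informative autosomal loci passing the screen.

    Simulates ``n_loci`` mother-het/father-hom loci (each progeny het with
    probability 1/2 independently of sex) and runs the real
    perfect-cosegregation screen over the progeny.  With the closed form
    ``2 * (1/2)^(n_female + n_male)`` this is the false-positive calibration
    of the screen.
    """
    rng = np.random.default_rng(seed)
    females = [f"F{i:02d}" for i in range(1, n_female + 1)]
    males = [f"M{i:02d}" for i in range(1, n_male + 1)]
    progeny = females + males
    het, hom = format_call("A", "C"), format_call("C", "C")
    draws = rng.random((n_loci, len(progeny))) < 0.5
    data = np.where(draws, het, hom)
    matrix = pd.DataFrame(
        data,
        index=pd.MultiIndex.from_tuples(
            [(f"L{i + 1:05d}", 1) for i in range(n_loci)],
            names=["locus_id", "position"],
        ),
        columns=progeny,
    )
    sexes = {i: FEMALE for i in females} | {i: MALE for i in males}
    hits = screen_sex_association(matrix, sexes, max_missing=max_missing)
    return len(hits) / n_loci
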