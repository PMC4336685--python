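"""Sex-cosegregation screen and heterogamety inference.

The core logic of marker discovery in a dioecious full-sib family: keep only
loci polymorphic between the parents, then demand a *perfect* split — every
female one identical heterozygous genotype and every male one identical
homozygous genotype whose base belongs to the het pair (or the mirror image).
Candidates where females are the heterozygous sex imply female heterogamety
(ZW); all-male-het candidates imply XY.

The screen is an exact-match filter, not a statistical test; the closed-form
probability that an informative autosomal locus passes by chance,
``2 * (1/2)^(n_female + n_male)`` progeny-wise, is reported alongside for
context on the expected false-positive load.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd

from .genotype import MISSING, is_het
from .samples import FEMALE, MALE
from .stacks import CatalogLocus

#: standard one-letter ambiguity codes for unordered base pairs
IUPAC_CODES = {
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("GC"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
}
AMBIGUITY_TO_PAIR = {code: pair for pair, code in IUPAC_CODES.items()}

_COMPLEMENT = str.maketrans("ACGTRYSWKM", "TGCAYRSWMK")


def iupac_code(b1: str, b2: str) -> str:
    """Ambiguity letter for an unordered heterozygous base pair."""
    if b1 == b2:
        raise ValueError("heterozygote bases must differ")
    try:
        return IUPAC_CODES[frozenset((b1, b2))]
    except KeyError:
        raise ValueError(f"not a base pair: {b1!r}/{b2!r}") from None


def snp_positions(bracketed: str) -> list[int]:
    """1-based tag positions of the SNPs in a bracketed marker sequence.

    Marker sequences print the SNP as a bracketed ambiguity letter inside the
    82-nt tag, e.g. ``AATTC...ATG(Y)GGA...``; the coordinate of each SNP is
    its position in the unbracketed sequence, counting from the leading A.
    """
    positions = []
    plain_len = 0
    for token in re.finditer(r"\(([A-Z])\)|([A-Z])", bracketed):
        plain_len += 1
        if token.group(1):
            positions.append(plain_len)
    return positions


def bracket_sequence(tag: str, position: int, code: str) -> str:
    """Insert a bracketed ambiguity code at a 1-based tag position."""
    if not 1 <= position <= len(tag):
        raise ValueError("position outside tag")
    return f"{tag[:position - 1]}({code}){tag[position:]}"


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SexMarkerCandidate:
    """A (locus, position) whose genotypes split perfectly by sex."""

    locus_id: str
    position: int
    het_bases: tuple[str, str]  # unordered, sorted
    hom_base: str
    heterogametic_sex: str  # 'female' (ZW-type) or 'male' (XY-type)
    iupac: str
    name: str = ""
    flanking: str | None = None

    def __post_init__(self) -> None:
        if self.hom_base not in self.het_bases:
            raise ValueError("homozygous base must be one of the het pair")
        if self.iupac != IUPAC_CODES[frozenset(self.het_bases)]:
            raise ValueError("iupac code inconsistent with het pair")

    @property
    def extension_strand_iupac(self) -> str:
        """Ambiguity code as read on the reverse strand (assays extending
        from the reverse primer report this orientation)."""
        return self.iupac.translate(_COMPLEMENT)


@dataclass
class SexSystemCall:
    system: str  # 'ZW' | 'XY' | 'undetermined'
    n_female_het_loci: int
    n_male_het_loci: int


def filter_parent_polymorphic(
    matrix: pd.DataFrame, mother_id: str, father_id: str
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Keep rows where both parents are called and their genotypes differ."""
    for pid in (mother_id, father_id):
        if pid not in matrix.columns:
            raise ValueError(f"parent {pid!r} not in genotype matrix")
    mom, dad = matrix[mother_id], matrix[father_id]
    called = (mom != MISSING) & (dad != MISSING)
    keep = called & (mom != dad)
    stats = {
        "input": len(matrix),
        "kept": int(keep.sum()),
        "dropped_parent_missing": int((~called).sum()),
        "dropped_monomorphic": int((called & ~keep).sum()),
    }
    return matrix.loc[keep], stats


def _uniform_pattern(calls: list[str]) -> str | None:
    """The shared genotype if all calls are identical and called, else None."""
    if not calls:
        return None
    first = calls[0]
    if first == MISSING:
        return None
    return first if all(c == first for c in calls) else None


def screen_sex_association(
    matrix: pd.DataFrame,
    sexes: dict[str, str],
    max_missing: int = 0,
    catalog: list[CatalogLocus] | None = None,
    name_prefix: str = "SIM",
) -> list[SexMarkerCandidate]:
    """Find (locus, position) rows that co-segregate perfectly with sex.

    Only individuals present in ``sexes`` are screened, so the caller decides
    whether parents take part in the pattern (they do in the standard cross
    screen: the heterogametic parent must itself be heterozygous).  Rows with
    more than ``max_missing`` missing calls among screened individuals are
    skipped.
    """
    females = [i for i, s in sexes.items() if s == FEMALE]
    males = [i for i, s in sexes.items() if s == MALE]
    unknown = set(sexes) - set(matrix.columns)
    if unknown:
        raise ValueError(f"individuals missing from matrix: {sorted(unknown)}")
    by_locus = {l.locus_id: l for l in catalog} if catalog else {}

    candidates: list[SexMarkerCandidate] = []
    for (locus_id, position), row in matrix.iterrows():
        screened = [row[i] for i in females + males]
        if sum(c == MISSING for c in screened) > max_missing:
            continue
        f_calls = [row[i] for i in females if row[i] != MISSING]
        m_calls = [row[i] for i in males if row[i] != MISSING]
        f_pat, m_pat = _uniform_pattern(f_calls), _uniform_pattern(m_calls)
        if f_pat is None or m_pat is None:
            continue

        het_sex = None
        if is_het(f_pat) and not is_het(m_pat):
            het_pat, hom_pat, het_sex = f_pat, m_pat, FEMALE
        elif is_het(m_pat) and not is_het(f_pat):
            het_pat, hom_pat, het_sex = m_pat, f_pat, MALE
        if het_sex is None:
            continue
        b1, b2 = het_pat.split("/")
        hom = hom_pat.split("/")[0]
        if hom not in (b1, b2):
            continue

        code = iupac_code(b1, b2)
        flanking = None
        locus = by_locus.get(locus_id)
        if locus is not None:
            flanking = bracket_sequence(locus.reference_consensus, position, code)
        candidates.append(
            SexMarkerCandidate(
                locus_id=locus_id,
                position=position,
                het_bases=(b1, b2),
                hom_base=hom,
                heterogametic_sex=het_sex,
                iupac=code,
                name=f"SNP-{name_prefix}-{locus_id.lstrip('L').lstrip('0') or '0'}-{code}{position}",
                flanking=flanking,
            )
        )
    return candidates


def infer_sex_system(candidates: list[SexMarkerCandidate]) -> SexSystemCall:
    """ZW iff all candidates are female-heterogametic (and there is at least
    one); XY for the mirror; undetermined otherwise."""
    n_f = sum(c.heterogametic_sex == FEMALE for c in candidates)
    n_m = sum(c.heterogametic_sex == MALE for c in candidates)
    if n_f >= 1 and n_m == 0:
        system = "ZW"
    elif n_m >= 1 and n_f == 0:
        system = "XY"
    else:
        system = "undetermined"
    return SexSystemCall(system=system, n_female_het_loci=n_f, n_male_het_loci=n_m)


def chance_cosegregation_probability(n_female: int, n_male: int) -> float:
    """Probability that an informative autosomal locus (one parent het, the
    other hom) splits perfectly by sex among the progeny: each progeny is het
    with probability 1/2 independently, and either sex may end up the
    all-het one."""
    if n_female < 1 or n_male < 1:
        raise ValueError("need at least one progeny of each sex")
    return 2.0 * 0.5 ** (n_female + n_male)


def score_validation_panel(
    candidates: list[SexMarkerCandidate], panel: pd.DataFrame
) -> pd.DataFrame:
    """Score markers on an independent genotype panel with known sexes.

    ``panel`` has one row per individual, a ``sex`` column and one
    ``locus_id:position`` genotype column per marker ('A/C'-style or './.').
    Prediction rule: heterozygous call -> the marker's heterogametic sex,
    homozygous -> the other sex.  A marker is validated at 100% accuracy
    over its called individuals; missing calls are tallied separately.
    """
    if panel.empty:
        raise ValueError("empty validation panel")
    if "sex" not in panel.columns:
        raise ValueError("panel needs a 'sex' column")

    out = []
    for cand in candidates:
        key = f"{cand.locus_id}:{cand.position}"
        if key not in panel.columns:
            continue
        other = MALE if cand.heterogametic_sex == FEMALE else FEMALE
        correct = wrong = missing = 0
        for _, r in panel.iterrows():
            call = r[key]
            if call == MISSING or pd.isna(call):
                missing += 1
                continue
            predicted = cand.heterogametic_sex if is_het(call) else other
            if predicted == r["sex"]:
                correct += 1
            else:
                wrong += 1
        called = correct + wrong
        accuracy = correct / called if called else float("nan")
        out.append(
            {
                "marker": cand.name or key,
                "locus_id": cand.locus_id,
                "position": cand.position,
                "n_correct": correct,
                "n_wrong": wrong,
                "n_missing": missing,
                "accuracy": accuracy,
                "validated": called > 0 and wrong == 0,
            }
        )
    return pd.DataFrame(out)


def candidates_to_frame(candidates: list[SexMarkerCandidate]) -> pd.DataFrame:
    """Candidate table in the shape of a published marker list: name, SNP
    position, IUPAC genotypes per sex, bracketed flanking sequence, and the
    reverse-strand code for extension-based assays."""
    rows = []
    for c in candidates:
        rows.append(
            {
                "marker": c.name,
                "locus_id": c.locus_id,
                "position": c.position,
                "heterogametic_sex": c.heterogametic_sex,
                "het_genotype": f"{c.iupac} ({c.het_bases[0]}{c.het_bases[1]})",
                "hom_genotype": c.hom_base,
                "iupac": c.iupac,
                "extension_strand_iupac": c.extension_strand_iupac,
                "flanking_sequence": c.flanking or "",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "marker", "locus_id", "position", "heterogametic_sex",
            "het_genotype", "hom_genotype", "iupac",
            "extension_strand_iupac", "flanking_sequence",
        ],
    )
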