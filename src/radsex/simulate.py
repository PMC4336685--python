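"""Synthetic EcoRI RAD library for a single full-sib cross in a ZW (or XY) species.

The generator emulates the data a reduced-representation experiment produces
when hunting sex-linked markers in a dioecious species:

* a random genome with a controlled number of planted EcoRI recognition sites
  (``G/AATTC``) and a designated non-recombining sex-determining region;
* a female(ZW) x male(ZZ) cross — two parents plus F1 progeny of both sexes —
  in which planted sex-linked SNPs ride on the W haplotype (so every ZW
  individual is heterozygous and every ZZ individual homozygous reference)
  while autosomal SNPs segregate Mendelianly from drawn parental genotypes;
* 90-nt single-end reads of the form ``MID + AATTC + 77 nt`` taken downstream
  of each cut site, with Poisson depth per haplotype and a uniform per-base
  substitution error.

Every run is fully determined by its seed, and each run emits a truth table
(per-variant, per-individual genotypes) against which the whole discovery
pipeline can be scored.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np

from .samples import (
    FEMALE,
    MALE,
    ROLE_FATHER,
    ROLE_MOTHER,
    ROLE_PROGENY,
    Individual,
    validate_mids,
)

ECORI_SITE = "GAATTC"
#: the cut leaves AATTC at the 5' end of the downstream fragment; the leading
#: G stays on the upstream fragment, so tags never include it
AFTER_CUT = "AATTC"
TAG_LENGTH = 82
MID_LENGTH = 8
READ_LENGTH = MID_LENGTH + TAG_LENGTH
#: nt of haplotype sequence past the residual AATTC in every tag
TAIL_LENGTH = TAG_LENGTH - len(AFTER_CUT)

QUALITY_CHAR = "?"  # constant Q30; the pipeline never reads qualities

BASES = "ACGT"
_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
_OTHER = {b: [c for c in BASES if c != b] for b in BASES}

SEX_LINKED = "sex_linked"
AUTOSOMAL = "autosomal"

# parental genotype configurations for autosomal variants, with draw weights.
# The pseudo-testcross configurations (one parent heterozygous) dominate
# because they are the informative ones; a slice of monomorphic and
# both-heterozygous loci exercises the parent-polymorphism filter.
MOTHER_HET = "mother_het"
FATHER_HET = "father_het"
BOTH_HET = "both_het"
HOM_REF = "hom_ref"
_AUTOSOMAL_CONFIGS = [MOTHER_HET, FATHER_HET, BOTH_HET, HOM_REF]
_AUTOSOMAL_WEIGHTS = [0.4, 0.4, 0.1, 0.1]


class SimulationError(RuntimeError):
    """Raised when requested simulation parameters cannot be satisfied."""


# ---------------------------------------------------------------------------
# genome


@dataclass
class SimGenome:
    """Random genome with planted EcoRI sites and a sex-determining region."""

    length: int
    sequence: str
    ecoRI_sites: list[int]
    sex_region: tuple[int, int]
    seed: int | None = None

    @property
    def usable_sites(self) -> list[int]:
        """Sites far enough from the 3' end to yield a full 82-nt tag."""
        return [s for s in self.ecoRI_sites if s + 1 + TAG_LENGTH <= self.length]

    def tag_window(self, site: int) -> tuple[int, int]:
        """Half-open genome interval covered by the tag of ``site``."""
        return site + 1, site + 1 + TAG_LENGTH

    def tag_sequence(self, site: int) -> str:
        lo, hi = self.tag_window(site)
        return self.sequence[lo:hi]

    def sites_inside_region(self) -> list[int]:
        lo, hi = self.sex_region
        return [s for s in self.usable_sites if lo <= s and s + 1 + TAG_LENGTH <= hi]

    def sites_outside_region(self) -> list[int]:
        lo, hi = self.sex_region
        return [
            s
            for s in self.usable_sites
            if s + 1 + TAG_LENGTH <= lo or s >= hi
        ]


def _occurrences(sequence: str, motif: str) -> list[int]:
    hits, start = [], sequence.find(motif)
    while start != -1:
        hits.append(start)
        start = sequence.find(motif, start + 1)
    return hits


def simulate_genome(
    length: int,
    n_ecoRI_target: int,
    sex_region_fraction: float,
    seed: int | None = None,
    min_loci: int = 1,
    site_spacing: int = 100,
) -> SimGenome:
    """Generate a genome whose EcoRI sites are planted, not left to chance.

    Sites are placed on a spaced grid (so tag windows never overlap) with
    ``round(n_ecoRI_target * sex_region_fraction)`` of them fully inside the
    sex-determining region; accidental ``GAATTC`` occurrences elsewhere are
    scrubbed so the realised site count equals the plan.
    """
    if length < 10_000:
        raise ValueError("genome length must be >= 10,000 nt")
    if not 0 < sex_region_fraction < 0.5:
        raise ValueError("sex_region_fraction must lie in (0, 0.5)")
    if n_ecoRI_target <= 0:
        raise SimulationError("a genome without restriction sites yields no RAD tags")

    rng = np.random.default_rng(seed)
    arr = _BASE_BYTES[rng.integers(0, 4, size=length)]

    region_len = int(round(sex_region_fraction * length))
    region_start = int(rng.integers(0, length - region_len + 1))
    region = (region_start, region_start + region_len)

    n_inside = int(round(n_ecoRI_target * sex_region_fraction))
    n_inside = max(n_inside, min_loci)
    n_outside = n_ecoRI_target - n_inside
    if n_outside < min_loci:
        raise SimulationError(
            f"target of {n_ecoRI_target} sites leaves fewer than {min_loci} "
            "outside the sex region"
        )

    window = 1 + TAG_LENGTH  # site motif start .. tag end
    inside_slots = np.arange(region[0], region[1] - window - 5, site_spacing)
    left = np.arange(0, max(region[0] - window - 5, 0), site_spacing)
    right = np.arange(region[1], max(length - window - 5, region[1]), site_spacing)
    outside_slots = np.concatenate([left, right])
    if len(inside_slots) < n_inside or len(outside_slots) < n_outside:
        raise SimulationError(
            "unsatisfiable site placement: genome too short/dense for "
            f"{n_ecoRI_target} sites at spacing {site_spacing}"
        )

    sites = sorted(
        int(s)
        for s in np.concatenate(
            [
                rng.choice(inside_slots, size=n_inside, replace=False),
                rng.choice(outside_slots, size=n_outside, replace=False),
            ]
        )
    )

    motif = np.frombuffer(ECORI_SITE.encode(), dtype=np.uint8)
    for s in sites:
        arr[s:s + 6] = motif

    # scrub accidental GAATTC occurrences so site count is exactly as planned
    planted = set(sites)
    protected = [(s, s + 6) for s in sites]
    for _ in range(200):
        seq = arr.tobytes().decode()
        extra = [o for o in _occurrences(seq, ECORI_SITE) if o not in planted]
        if not extra:
            break
        for occ in extra:
            for idx in range(occ, occ + 6):
                if not any(lo <= idx < hi for lo, hi in protected):
                    current = chr(arr[idx])
                    arr[idx] = ord(_OTHER[current][int(rng.integers(0, 3))])
                    break
    else:  # pragma: no cover - would need pathological density
        raise SimulationError("could not scrub accidental EcoRI sites")

    genome = SimGenome(
        length=length,
        sequence=arr.tobytes().decode(),
        ecoRI_sites=sites,
        sex_region=region,
        seed=seed,
    )
    if len(genome.sites_inside_region()) < min_loci or len(
        genome.sites_outside_region()
    ) < min_loci:
        raise SimulationError("fewer than min_loci usable sites in/outside sex region")
    return genome


# ---------------------------------------------------------------------------
# variants


@dataclass(frozen=True)
class PlantedVariant:
    """A biallelic substitution planted on one RAD tag.

    ``tag_position`` is 1-based within the 82-nt tag (position 1 = the leading
    A of AATTC), so ``genome_offset = site + tag_position``.
    """

    variant_id: str
    genome_offset: int
    site: int
    tag_position: int
    ref_base: str
    alt_base: str
    linkage: str  # sex_linked | autosomal
    parental_config: str | None = None  # autosomal only

    def __post_init__(self) -> None:
        if self.ref_base == self.alt_base:
            raise ValueError("ref and alt must differ")
        if self.genome_offset != self.site + self.tag_position:
            raise ValueError("offset inconsistent with site/tag_position")


def plant_variants(
    genome: SimGenome,
    n_sex_linked: int,
    n_autosomal: int,
    seed: int | None = None,
    max_per_tag: int = 2,
    min_tag_position: int = 6,
) -> list[PlantedVariant]:
    """Choose variant positions on tags: sex-linked inside the sex region,
    autosomal outside, at most ``max_per_tag`` per tag, never touching the
    residual AATTC (positions 1-5)."""
    rng = np.random.default_rng(seed)
    placements: list[tuple[int, int]] = []  # (site, tag_position)

    def _alloc(sites: list[int], n: int, label: str) -> list[tuple[int, int]]:
        if n == 0:
            return []
        capacity = len(sites) * max_per_tag
        if n > capacity:
            raise SimulationError(
                f"cannot place {n} {label} variants on {len(sites)} tags "
                f"(max {max_per_tag} per tag)"
            )
        order = [int(s) for s in rng.permutation(sites)]
        used: dict[int, set[int]] = defaultdict(set)
        out: list[tuple[int, int]] = []
        for _round in range(max_per_tag):
            for s in order:
                if len(out) == n:
                    return out
                for _ in range(50):
                    pos = int(rng.integers(min_tag_position, TAG_LENGTH + 1))
                    if pos not in used[s]:
                        used[s].add(pos)
                        out.append((s, pos))
                        break
        return out

    placements += _alloc(genome.sites_inside_region(), n_sex_linked, SEX_LINKED)
    n_sex_placed = len(placements)
    placements += _alloc(genome.sites_outside_region(), n_autosomal, AUTOSOMAL)

    variants: list[PlantedVariant] = []
    for k, (site, pos) in enumerate(placements):
        offset = site + pos
        ref = genome.sequence[offset]
        alts = list(_OTHER[ref])
        rng.shuffle(alts)
        alt = None
        for cand in alts:
            lo = max(offset - 5, 0)
            window = (
                genome.sequence[lo:offset] + cand + genome.sequence[offset + 1:offset + 6]
            )
            if ECORI_SITE not in window:
                alt = cand
                break
        if alt is None:  # pragma: no cover - all three alts making a site is absurd
            continue
        linkage = SEX_LINKED if k < n_sex_placed else AUTOSOMAL
        config = None
        if linkage == AUTOSOMAL:
            config = str(rng.choice(_AUTOSOMAL_CONFIGS, p=_AUTOSOMAL_WEIGHTS))
        variants.append(
            PlantedVariant(
                variant_id="",  # assigned after sorting
                genome_offset=offset,
                site=site,
                tag_position=pos,
                ref_base=ref,
                alt_base=alt,
                linkage=linkage,
                parental_config=config,
            )
        )
    variants.sort(key=lambda v: v.genome_offset)
    return [
        PlantedVariant(
            variant_id=f"V{i + 1:04d}",
            genome_offset=v.genome_offset,
            site=v.site,
            tag_position=v.tag_position,
            ref_base=v.ref_base,
            alt_base=v.alt_base,
            linkage=v.linkage,
            parental_config=v.parental_config,
        )
        for i, v in enumerate(variants)
    ]


# ---------------------------------------------------------------------------
# cross


@dataclass
class SimPedigree:
    mother: Individual
    father: Individual
    progeny: list[Individual]
    karyotypes: dict[str, str]

    @property
    def individuals(self) -> list[Individual]:
        return [self.mother, self.father, *self.progeny]


@dataclass
class CrossResult:
    pedigree: SimPedigree
    #: individual_id -> (maternal haplotype, paternal haplotype); each
    #: haplotype maps genome_offset -> carried base at every planted variant
    haplotypes: dict[str, tuple[dict[int, str], dict[int, str]]]
    truth: "pd.DataFrame"
    sex_system: str = "ZW"


def simulate_cross(
    genome: SimGenome,
    variants: list[PlantedVariant],
    n_female: int,
    n_male: int,
    seed: int | None = None,
    sex_system: str = "ZW",
    balanced: bool = True,
) -> CrossResult:
    """Draw parental phased genotypes and Mendelian F1 progeny.

    Under ZW the mother is the heterogametic parent and every planted
    sex-linked alt allele rides her W haplotype, so ZW individuals (mother and
    all female progeny) are heterozygous and ZZ individuals homozygous
    reference at those offsets; under XY the rule mirrors onto the father's Y.
    """
    import pandas as pd

    if n_female < 1 or n_male < 1:
        raise ValueError("need at least one progeny of each sex")
    if sex_system not in ("ZW", "XY"):
        raise ValueError("sex_system must be 'ZW' or 'XY'")
    for v in variants:
        if not 0 <= v.genome_offset < genome.length:
            raise ValueError(f"variant {v.variant_id} offset outside genome")

    rng = np.random.default_rng(seed)

    mother = Individual("mother", FEMALE, ROLE_MOTHER)
    father = Individual("father", MALE, ROLE_FATHER)
    if balanced:
        sexes = [FEMALE] * n_female + [MALE] * n_male
    else:
        draws = rng.random(n_female + n_male) < 0.5
        sexes = [FEMALE if d else MALE for d in draws]
    fi = mi = 0
    progeny = []
    for s in sexes:
        if s == FEMALE:
            fi += 1
            progeny.append(Individual(f"F{fi:02d}", FEMALE, ROLE_PROGENY))
        else:
            mi += 1
            progeny.append(Individual(f"M{mi:02d}", MALE, ROLE_PROGENY))

    if sex_system == "ZW":
        karyo = {"mother": "ZW", "father": "ZZ"}
        karyo.update({p.individual_id: "ZW" if p.sex == FEMALE else "ZZ" for p in progeny})
    else:
        karyo = {"mother": "XX", "father": "XY"}
        karyo.update({p.individual_id: "XX" if p.sex == FEMALE else "XY" for p in progeny})
    assert "WW" not in karyo.values(), "a ZW x ZZ cross cannot yield WW"

    pedigree = SimPedigree(mother, father, progeny, karyo)

    # phased parental haplotypes: slot 0/1 per parent; for the heterogametic
    # parent, slot 0 is the sex-limited chromosome (W under ZW, Y under XY)
    mother_haps: tuple[dict[int, str], dict[int, str]] = ({}, {})
    father_haps: tuple[dict[int, str], dict[int, str]] = ({}, {})
    for v in variants:
        o = v.genome_offset
        if v.linkage == SEX_LINKED:
            if sex_system == "ZW":
                mother_haps[0][o], mother_haps[1][o] = v.alt_base, v.ref_base
                father_haps[0][o] = father_haps[1][o] = v.ref_base
            else:
                father_haps[0][o], father_haps[1][o] = v.alt_base, v.ref_base
                mother_haps[0][o] = mother_haps[1][o] = v.ref_base
        else:
            m_alt = v.parental_config in (MOTHER_HET, BOTH_HET)
            f_alt = v.parental_config in (FATHER_HET, BOTH_HET)
            for haps, has_alt in ((mother_haps, m_alt), (father_haps, f_alt)):
                if has_alt:
                    slot = int(rng.integers(0, 2))
                    haps[slot][o] = v.alt_base
                    haps[1 - slot][o] = v.ref_base
                else:
                    haps[0][o] = haps[1][o] = v.ref_base

    haplotypes: dict[str, tuple[dict[int, str], dict[int, str]]] = {
        "mother": mother_haps,
        "father": father_haps,
    }
    for p in progeny:
        mat: dict[int, str] = {}
        pat: dict[int, str] = {}
        for v in variants:
            o = v.genome_offset
            if v.linkage == SEX_LINKED:
                if sex_system == "ZW":
                    # females inherit the W, males the mother's Z
                    mat[o] = mother_haps[0][o] if p.sex == FEMALE else mother_haps[1][o]
                    pat[o] = v.ref_base
                else:
                    mat[o] = v.ref_base
                    pat[o] = father_haps[0][o] if p.sex == MALE else father_haps[1][o]
            else:
                mat[o] = mother_haps[int(rng.integers(0, 2))][o]
                pat[o] = father_haps[int(rng.integers(0, 2))][o]
        haplotypes[p.individual_id] = (mat, pat)

    rows = []
    ind_ids = [i.individual_id for i in pedigree.individuals]
    het_karyo = "ZW" if sex_system == "ZW" else "XY"
    for v in variants:
        o = v.genome_offset
        row = {
            "variant_id": v.variant_id,
            "genome_offset": o,
            "site": v.site,
            "tag_position": v.tag_position,
            "linkage": v.linkage,
            "ref": v.ref_base,
            "alt": v.alt_base,
            "parental_config": v.parental_config or "",
        }
        for iid in ind_ids:
            a, b = haplotypes[iid][0][o], haplotypes[iid][1][o]
            row[iid] = "/".join(sorted((a, b)))
            if v.linkage == SEX_LINKED:
                expect_het = karyo[iid] == het_karyo
                assert (a != b) == expect_het, (
                    f"sex-linked carrier rule violated for {iid} at {v.variant_id}"
                )
        rows.append(row)
    truth = pd.DataFrame(
        rows,
        columns=[
            "variant_id", "genome_offset", "site", "tag_position",
            "linkage", "ref", "alt", "parental_config", *ind_ids,
        ],
    )
    return CrossResult(pedigree, haplotypes, truth, sex_system)


# ---------------------------------------------------------------------------
# reads


@dataclass
class ReadSimParams:
    mean_depth_per_tag: float = 20.0
    error_rate: float = 0.0
    read_length: int = READ_LENGTH
    mid_length: int = MID_LENGTH
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.read_length != self.mid_length + TAG_LENGTH:
            raise ValueError(
                f"read_length must equal MID length + {TAG_LENGTH}"
            )
        if not 0.0 <= self.error_rate <= 0.05:
            raise ValueError("error_rate must lie in [0, 0.05]")
        if self.mean_depth_per_tag < 0:
            raise ValueError("mean_depth_per_tag must be >= 0")


def generate_mids(n: int, seed: int | None = None, min_distance: int = 3) -> list[str]:
    """Random 8-nt barcodes with pairwise Hamming distance >= min_distance."""
    rng = np.random.default_rng(seed)
    out: list[str] = []
    for _ in range(20_000):
        if len(out) == n:
            return out
        cand = "".join(BASES[i] for i in rng.integers(0, 4, size=MID_LENGTH))
        if all(sum(a != b for a, b in zip(cand, m)) >= min_distance for m in out):
            out.append(cand)
    raise SimulationError(f"could not generate {n} spaced barcodes")


def simulate_reads(
    genome: SimGenome,
    cross: CrossResult,
    params: ReadSimParams,
    mids: dict[str, str],
    fastq_path,
) -> dict:
    """Write the multiplexed FASTQ and return its manifest.

    One tag per usable cut site per haplotype, plus-strand only; depth is
    Poisson(mean_depth_per_tag / 2) per haplotype so the two alleles of a
    heterozygote are sampled independently.
    """
    individuals = cross.pedigree.individuals
    sheet = [
        Individual(i.individual_id, i.sex, i.role, mids[i.individual_id])
        for i in individuals
    ]
    validate_mids(sheet)

    rng = np.random.default_rng(params.seed)
    usable = genome.usable_sites
    skipped = [s for s in genome.ecoRI_sites if s not in set(usable)]

    # per-site variant offsets for fast tag editing
    by_site: dict[int, list[int]] = defaultdict(list)
    all_offsets = set()
    for _, haps in cross.haplotypes.items():
        all_offsets.update(haps[0])
        break
    for o in sorted(all_offsets):
        for s in usable:
            lo, hi = genome.tag_window(s)
            if lo <= o < hi:
                by_site[s].append(o)

    per_individual = {}
    total = 0
    lam = params.mean_depth_per_tag / 2.0
    err = params.error_rate
    with open(fastq_path, "w") as fh:
        for ind in individuals:
            mid = mids[ind.individual_id]
            haps = cross.haplotypes[ind.individual_id]
            n_reads = 0
            for s in usable:
                lo, _hi = genome.tag_window(s)
                ref_tag = genome.tag_sequence(s)
                for hap_idx in (0, 1):
                    tag = ref_tag
                    offs = by_site.get(s, ())
                    if offs:
                        chars = list(ref_tag)
                        for o in offs:
                            chars[o - lo] = haps[hap_idx][o]
                        tag = "".join(chars)
                    template = mid + tag
                    depth = int(rng.poisson(lam))
                    for r in range(depth):
                        read = template
                        if err > 0.0:
                            hits = np.flatnonzero(rng.random(params.read_length) < err)
                            if hits.size:
                                chars = list(read)
                                for idx in hits:
                                    chars[idx] = _OTHER[chars[idx]][
                                        int(rng.integers(0, 3))
                                    ]
                                read = "".join(chars)
                        fh.write(
                            f"@{ind.individual_id}|site{s}|hap{hap_idx}|{r}\n"
                            f"{read}\n+\n{QUALITY_CHAR * params.read_length}\n"
                        )
                        n_reads += 1
            per_individual[ind.individual_id] = n_reads
            total += n_reads

    return {
        "mean_depth_per_tag": params.mean_depth_per_tag,
        "error_rate": params.error_rate,
        "read_length": params.read_length,
        "mid_length": params.mid_length,
        "seed": params.seed,
        "sex_system": cross.sex_system,
        "n_sites": len(usable),
        "skipped_sites": skipped,
        "mids": dict(mids),
        "reads_per_individual": per_individual,
        "total_reads": total,
    }


def write_truth_table(truth, path) -> None:
    truth.to_csv(path, sep="\t", index=False)
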