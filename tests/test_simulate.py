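"""Synthetic-library generator: genome, cross, and read-level contracts."""

import pytest

from radsex import (
    PlantedVariant,
    ReadSimParams,
    generate_mids,
    plant_variants,
    simulate_cross,
    simulate_genome,
    simulate_reads,
)
from radsex.simulate import (
    AFTER_CUT,
    AUTOSOMAL,
    ECORI_SITE,
    MOTHER_HET,
    SEX_LINKED,
    SimulationError,
)


def _count_motif(seq, motif):
    n, start = 0, seq.find(motif)
    while start != -1:
        n += 1
        start = seq.find(motif, start + 1)
    return n


class TestGenome:
    def test_site_counts_and_placement(self):
        g = simulate_genome(100_000, 50, 0.2, seed=1)
        # every listed offset is an exact motif occurrence
        for s in g.ecoRI_sites:
            assert g.sequence[s:s + 6] == ECORI_SITE
        # direct string scan agrees with the site list (no accidental sites)
        assert _count_motif(g.sequence, ECORI_SITE) == len(g.ecoRI_sites)
        assert 40 <= len(g.ecoRI_sites) <= 60
        assert len(g.sites_inside_region()) >= 8
        lo, hi = g.sex_region
        assert 0 <= lo < hi <= g.length

    def test_same_seed_is_byte_identical(self):
        a = simulate_genome(50_000, 30, 0.25, seed=9)
        b = simulate_genome(50_000, 30, 0.25, seed=9)
        assert a.sequence == b.sequence
        assert a.ecoRI_sites == b.ecoRI_sites
        assert a.sex_region == b.sex_region

    def test_zero_sites_rejected(self):
        with pytest.raises(SimulationError):
            simulate_genome(10_000, 0, 0.2, seed=0)

    def test_unsatisfiable_density_rejected(self):
        with pytest.raises(SimulationError):
            simulate_genome(10_000, 500, 0.2, seed=0)

    @pytest.mark.parametrize("length,frac", [(5_000, 0.2), (100_000, 0.6)])
    def test_precondition_validation(self, length, frac):
        with pytest.raises(ValueError):
            simulate_genome(length, 20, frac, seed=0)


class TestVariants:
    def test_partitioned_by_region(self):
        g = simulate_genome(100_000, 60, 0.2, seed=4)
        variants = plant_variants(g, 4, 30, seed=5)
        lo, hi = g.sex_region
        for v in variants:
            assert v.ref_base != v.alt_base
            assert g.sequence[v.genome_offset] == v.ref_base
            # the substitution must not destroy the residual AATTC
            assert v.tag_position >= 6
            if v.linkage == SEX_LINKED:
                assert lo <= v.genome_offset < hi
            else:
                assert not lo <= v.genome_offset < hi
        assert sum(v.linkage == SEX_LINKED for v in variants) == 4
        assert sum(v.linkage == AUTOSOMAL for v in variants) == 30
        # at most two variants share a tag
        from collections import Counter
        per_site = Counter(v.site for v in variants)
        assert max(per_site.values()) <= 2

    def test_overplanting_rejected(self):
        g = simulate_genome(30_000, 10, 0.25, seed=4)
        with pytest.raises(SimulationError):
            plant_variants(g, 1000, 0, seed=0)


class TestCross:
    def _setup(self, n_sex=1, n_auto=5, seed=11):
        g = simulate_genome(60_000, 40, 0.25, seed=seed)
        v = plant_variants(g, n_sex, n_auto, seed=seed + 1)
        return g, v

    def test_sex_linked_truth_pattern(self):
        g, v = self._setup()
        cross = simulate_cross(g, v, 8, 8, seed=3)
        truth = cross.truth
        row = truth[truth.linkage == SEX_LINKED].iloc[0]
        ind_cols = [i.individual_id for i in cross.pedigree.individuals]
        hets = [c for c in ind_cols if len(set(row[c].split("/"))) == 2]
        homs = [c for c in ind_cols if len(set(row[c].split("/"))) == 1]
        # mother + 8 F1 females heterozygous; father + 8 F1 males homozygous
        assert len(hets) == 9 and len(homs) == 9
        assert "mother" in hets and "father" in homs
        assert all(c.startswith("F") or c == "mother" for c in hets)

    def test_no_ww_karyotype_and_balanced_counts(self):
        g, v = self._setup()
        cross = simulate_cross(g, v, 5, 3, seed=2)
        assert "WW" not in cross.pedigree.karyotypes.values()
        sexes = [p.sex for p in cross.pedigree.progeny]
        assert sexes.count("female") == 5 and sexes.count("male") == 3

    def test_xy_mirror(self):
        g, v = self._setup()
        cross = simulate_cross(g, v, 4, 4, seed=2, sex_system="XY")
        row = cross.truth[cross.truth.linkage == SEX_LINKED].iloc[0]
        ind_cols = [i.individual_id for i in cross.pedigree.individuals]
        hets = {c for c in ind_cols if len(set(row[c].split("/"))) == 2}
        assert hets == {"father", "M01", "M02", "M03", "M04"}

    def test_no_sex_linked_variants(self):
        g, v = self._setup(n_sex=0)
        cross = simulate_cross(g, v, 2, 2, seed=2)
        assert (cross.truth.linkage == SEX_LINKED).sum() == 0

    def test_variant_offset_outside_genome_rejected(self):
        g, v = self._setup()
        bad = PlantedVariant("VBAD", g.length + 7, g.length, 7, "A", "C", AUTOSOMAL,
                             MOTHER_HET)
        with pytest.raises(ValueError):
            simulate_cross(g, v + [bad], 2, 2, seed=2)

    def test_mother_het_segregates_one_to_one(self):
        """An informative (mother het, father hom) autosomal variant gives
        heterozygous progeny at rate 1/2 — binomial check over 1,200 draws."""
        g = simulate_genome(60_000, 40, 0.25, seed=21)
        v = [x for x in plant_variants(g, 0, 40, seed=22)
             if x.parental_config == MOTHER_HET][:2]
        assert v, "expected at least one informative autosomal variant"
        cross = simulate_cross(g, v, 600, 600, seed=23)
        row = cross.truth.iloc[0]
        prog = [p.individual_id for p in cross.pedigree.progeny]
        n_het = sum(len(set(row[c].split("/"))) == 2 for c in prog)
        p_hat = n_het / len(prog)
        se = (0.5 * 0.5 / len(prog)) ** 0.5
        assert abs(p_hat - 0.5) <= 3 * se


class TestReads:
    def _library(self, error_rate=0.0, depth=20.0, seed=31, n_female=1, n_male=1):
        g = simulate_genome(20_000, 10, 0.2, seed=seed)
        v = plant_variants(g, 1, 3, seed=seed + 1)
        cross = simulate_cross(g, v, n_female, n_male, seed=seed + 2)
        inds = cross.pedigree.individuals
        mids = dict(zip([i.individual_id for i in inds],
                        generate_mids(len(inds), seed=seed + 3)))
        params = ReadSimParams(mean_depth_per_tag=depth, error_rate=error_rate,
                               seed=seed + 4)
        return g, cross, params, mids

    def test_read_structure_and_conservation(self, tmp_path):
        g, cross, params, mids = self._library()
        fq = tmp_path / "r.fastq"
        manifest = simulate_reads(g, cross, params, mids, fq)
        lines = fq.read_text().splitlines()
        assert len(lines) == 4 * manifest["total_reads"]
        mid_set = set(mids.values())
        for seq in lines[1::4]:
            assert len(seq) == 90
            assert seq[:8] in mid_set
            # error_rate=0: barcode removal leaves an AATTC-led 82-nt tag
            assert seq[8:13] == AFTER_CUT
        assert sum(manifest["reads_per_individual"].values()) == manifest["total_reads"]

    def test_same_seed_same_bytes(self, tmp_path):
        g, cross, params, mids = self._library()
        a, b = tmp_path / "a.fastq", tmp_path / "b.fastq"
        simulate_reads(g, cross, params, mids, a)
        simulate_reads(g, cross, params, mids, b)
        assert a.read_bytes() == b.read_bytes()

    def test_zero_depth_is_empty_but_valid(self, tmp_path):
        g, cross, params, mids = self._library(depth=0.0)
        fq = tmp_path / "empty.fastq"
        manifest = simulate_reads(g, cross, params, mids, fq)
        assert manifest["total_reads"] == 0
        assert fq.read_text() == ""

    def test_error_rate_realised(self, tmp_path):
        """Observed per-base mismatch fraction against the true haplotype
        templates is within 3 s.e. of the configured substitution rate."""
        rate = 0.01
        g, cross, p0, mids = self._library(error_rate=rate, depth=30.0)
        fq = tmp_path / "n.fastq"
        simulate_reads(g, cross, p0, mids, fq)
        lines = fq.read_text().splitlines()
        mism = total = 0
        for header, seq in zip(lines[0::4], lines[1::4]):
            ind, site, hap, _ = header[1:].split("|")
            site = int(site.removeprefix("site"))
            hap_idx = int(hap.removeprefix("hap"))
            lo, hi = g.tag_window(site)
            chars = list(g.tag_sequence(site))
            for off, base in cross.haplotypes[ind][hap_idx].items():
                if lo <= off < hi:
                    chars[off - lo] = base
            template = mids[ind] + "".join(chars)
            mism += sum(x != y for x, y in zip(seq, template))
            total += 90
        se = (rate * (1 - rate) / total) ** 0.5
        assert abs(mism / total - rate) <= 3 * se

    def test_bad_mids_rejected(self, tmp_path):
        g, cross, params, _ = self._library()
        ids = [i.individual_id for i in cross.pedigree.individuals]
        near = {iid: m for iid, m in zip(ids, ["AAAAAAAA", "AAAAAAAT",
                                               "CCCCCCCC", "GGGGGGGG"])}
        with pytest.raises(ValueError):
            simulate_reads(g, cross, params, near, tmp_path / "x.fastq")


def test_generate_mids_are_spaced():
    mids = generate_mids(24, seed=7)
    assert len(set(mids)) == 24
    for i, a in enumerate(mids):
        for b in mids[i + 1:]:
            assert sum(x != y for x, y in zip(a, b)) >= 3


def test_read_params_validation():
    with pytest.raises(ValueError):
        ReadSimParams(error_rate=0.2)
    with pytest.raises(ValueError):
        ReadSimParams(read_length=80)
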