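"""Parent filter, perfect sex-cosegregation screen, heterogamety inference."""

import itertools

import numpy as np
import pandas as pd
import pytest

from radsex import (
    chance_cosegregation_probability,
    cosegregation_monte_carlo,
    filter_parent_polymorphic,
    infer_sex_system,
    iupac_code,
    score_validation_panel,
    screen_sex_association,
    snp_positions,
)
from radsex.datasets import PISTACHIO_MARKER_SEQUENCES, PISTACHIO_VALIDATED_LOCI
from radsex.genotype import MISSING, is_het
from radsex.screen import (
    AMBIGUITY_TO_PAIR,
    SexMarkerCandidate,
    bracket_sequence,
    reverse_complement,
)


def _matrix(rows: dict, individuals: list[str]) -> pd.DataFrame:
    idx = pd.MultiIndex.from_tuples(list(rows), names=["locus_id", "position"])
    return pd.DataFrame(list(rows.values()), index=idx, columns=individuals)


class TestIupac:
    @pytest.mark.parametrize("pair,code", [
        (("C", "A"), "M"), (("T", "A"), "W"), (("G", "T"), "K"),
        (("A", "G"), "R"), (("C", "T"), "Y"), (("G", "C"), "S"),
    ])
    def test_standard_codes(self, pair, code):
        assert iupac_code(*pair) == code
        assert iupac_code(pair[1], pair[0]) == code  # unordered

    def test_all_pairs_roundtrip(self):
        for b1, b2 in itertools.combinations("ACGT", 2):
            code = iupac_code(b1, b2)
            assert AMBIGUITY_TO_PAIR[code] == frozenset((b1, b2))

    def test_identical_bases_rejected(self):
        with pytest.raises(ValueError):
            iupac_code("A", "A")


class TestCoordinates:
    def test_published_marker_positions(self):
        """The bracketed marker sequences carry their SNPs at the positions
        encoded in the marker names (1-based from the leading A of AATTC)."""
        expected = {
            "SNP-PIS-1319": [28, 77],
            "SNP-PIS-29689": [33, 71],
            "SNP-PIS-112277": [10, 61],
            "SNP-PIS-120693": [19, 57],
            "SNP-PIS-127343": [27],
            "SNP-PIS-133396": [46, 47],
            "SNP-PIS-135862": [40, 41],
            "SNP-PIS-136404": [23],
            "SNP-PIS-167992": [36],
            "SNP-PIS-174431": [56],
            "SNP-PIS-176863": [57],
        }
        for marker, seq in PISTACHIO_MARKER_SEQUENCES.items():
            assert snp_positions(seq) == expected[marker]
            plain = seq.replace("(", "").replace(")", "")
            assert len(plain) == 82
            assert plain.startswith("AATTC")

    def test_bracket_roundtrip(self):
        tag = "AATTC" + "A" * 77
        bracketed = bracket_sequence(tag, 28, "Y")
        assert snp_positions(bracketed) == [28]
        assert bracketed.replace("(Y)", "A") == tag


class TestParentFilter:
    INDS = ["mother", "father", "F01", "M01"]

    def test_informative_kept_monomorphic_dropped(self):
        m = _matrix(
            {
                ("L1", 5): ["A/G", "G/G", "A/G", "G/G"],   # informative
                ("L2", 9): ["A/A", "A/A", "A/A", "A/A"],   # monomorphic
                ("L3", 2): [MISSING, "C/C", "C/C", "C/C"],  # parent missing
            },
            self.INDS,
        )
        reduced, stats = filter_parent_polymorphic(m, "mother", "father")
        assert list(reduced.index) == [("L1", 5)]
        assert stats == {
            "input": 3, "kept": 1,
            "dropped_parent_missing": 1, "dropped_monomorphic": 1,
        }

    def test_unknown_parent_rejected(self):
        m = _matrix({("L1", 5): ["A/G", "G/G", "A/G", "G/G"]}, self.INDS)
        with pytest.raises(ValueError):
            filter_parent_polymorphic(m, "nobody", "father")


class TestScreen:
    def _family(self, n=9):
        females = [f"F{i}" for i in range(n)]
        males = [f"M{i}" for i in range(n)]
        sexes = {f: "female" for f in females} | {m: "male" for m in males}
        return females, males, sexes

    def test_perfect_female_het_pattern(self):
        females, males, sexes = self._family()
        m = _matrix({("L1", 28): ["C/T"] * 9 + ["T/T"] * 9}, females + males)
        (cand,) = screen_sex_association(m, sexes)
        assert cand.heterogametic_sex == "female"
        assert cand.iupac == "Y"
        assert cand.het_bases == ("C", "T") and cand.hom_base == "T"
        assert cand.extension_strand_iupac == "R"

    def test_single_discordant_male_disqualifies(self):
        females, males, sexes = self._family()
        calls = ["C/T"] * 9 + ["T/T"] * 8 + ["C/T"]
        m = _matrix({("L1", 28): calls}, females + males)
        assert screen_sex_association(m, sexes) == []

    def test_mirror_male_het_pattern(self):
        females, males, sexes = self._family()
        m = _matrix({("L1", 10): ["A/A"] * 9 + ["A/G"] * 9}, females + males)
        (cand,) = screen_sex_association(m, sexes)
        assert cand.heterogametic_sex == "male"

    def test_hom_base_outside_het_pair_disqualifies(self):
        females, males, sexes = self._family(3)
        m = _matrix({("L1", 7): ["C/T"] * 3 + ["G/G"] * 3},
                    [*sexes][:3] + [*sexes][3:])
        assert screen_sex_association(m, sexes) == []

    def test_max_missing_respected(self):
        females, males, sexes = self._family(3)
        calls = ["C/T", "C/T", MISSING, "T/T", "T/T", "T/T"]
        m = _matrix({("L1", 7): calls}, females + males)
        assert screen_sex_association(m, sexes, max_missing=0) == []
        (cand,) = screen_sex_association(m, sexes, max_missing=1)
        assert cand.heterogametic_sex == "female"

    def test_matches_bruteforce_row_enumeration(self):
        """On random matrices the screen equals an independent brute-force
        scan for the perfect-split definition."""
        rng = np.random.default_rng(99)
        females, males, sexes = self._family(4)
        inds = females + males
        genos = ["A/A", "C/C", "A/C", MISSING]
        for rep in range(30):
            rows = {
                (f"L{k}", 1): [genos[i] for i in rng.integers(0, 4, len(inds))]
                for k in range(40)
            }
            m = _matrix(rows, inds)
            got = {(c.locus_id, c.position, c.heterogametic_sex)
                   for c in screen_sex_association(m, sexes)}
            assert got == _bruteforce_screen(m, sexes)


def _bruteforce_screen(matrix, sexes, max_missing=0):
    out = set()
    for key, row in matrix.iterrows():
        calls = {i: row[i] for i in sexes}
        if sum(c == MISSING for c in calls.values()) > max_missing:
            continue
        f = {c for i, c in calls.items() if sexes[i] == "female" and c != MISSING}
        m = {c for i, c in calls.items() if sexes[i] == "male" and c != MISSING}
        if len(f) != 1 or len(m) != 1:
            continue
        fc, mc = next(iter(f)), next(iter(m))
        if is_het(fc) and not is_het(mc) and mc.split("/")[0] in fc.split("/"):
            out.add((key[0], key[1], "female"))
        elif is_het(mc) and not is_het(fc) and fc.split("/")[0] in mc.split("/"):
            out.add((key[0], key[1], "male"))
    return out


class TestSystemInference:
    def _cand(self, het_sex, k):
        return SexMarkerCandidate(f"L{k}", 1, ("A", "G"), "A", het_sex, "R")

    def test_all_female_het_is_zw(self):
        call = infer_sex_system([self._cand("female", k) for k in range(8)])
        assert call.system == "ZW"
        assert call.n_female_het_loci == 8 and call.n_male_het_loci == 0

    def test_all_male_het_is_xy(self):
        assert infer_sex_system(
            [self._cand("male", k) for k in range(3)]
        ).system == "XY"

    def test_mixed_or_empty_is_undetermined(self):
        mixed = [self._cand("female", 0), self._cand("female", 1),
                 self._cand("male", 2), self._cand("male", 3)]
        assert infer_sex_system(mixed).system == "undetermined"
        assert infer_sex_system([]).system == "undetermined"


class TestChanceCosegregation:
    def test_closed_forms(self):
        assert chance_cosegregation_probability(8, 8) == 3.0517578125e-05
        assert chance_cosegregation_probability(1, 1) == 0.5

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            chance_cosegregation_probability(0, 8)

    def test_monte_carlo_matches_closed_form(self):
        """Observed false-positive fraction among informative autosomal loci
        is within 3 s.e. of 2*(1/2)^8 for a 4F+4M family."""
        p = chance_cosegregation_probability(4, 4)
        n = 3000
        obs = cosegregation_monte_carlo(n, 4, 4, seed=2015)
        se = (p * (1 - p) / n) ** 0.5
        assert abs(obs - p) <= 3 * se


class TestValidationPanel:
    def _panel(self, cand, n_female=83, n_male=83, flip_one_male=False):
        key = f"{cand.locus_id}:{cand.position}"
        het = "/".join(sorted(cand.het_bases))
        hom = f"{cand.hom_base}/{cand.hom_base}"
        rows = [{"sex": "female", key: het} for _ in range(n_female)]
        rows += [{"sex": "male", key: hom} for _ in range(n_male)]
        if flip_one_male:
            rows[-1][key] = het
        return pd.DataFrame(rows)

    def _cand(self):
        return SexMarkerCandidate("L7", 28, ("C", "T"), "T", "female", "Y",
                                  name="SNP-X-7-Y28")

    def test_perfect_panel_validates(self):
        cand = self._cand()
        report = score_validation_panel([cand], self._panel(cand))
        row = report.iloc[0]
        assert row.accuracy == 1.0 and bool(row.validated)
        assert row.n_correct == 166

    def test_one_het_male_fails_validation(self):
        cand = self._cand()
        report = score_validation_panel(
            [cand], self._panel(cand, flip_one_male=True)
        )
        row = report.iloc[0]
        assert row.accuracy < 1.0 and not row.validated

    def test_missing_calls_counted_separately(self):
        cand = self._cand()
        panel = self._panel(cand)
        panel.loc[0, f"{cand.locus_id}:{cand.position}"] = MISSING
        row = score_validation_panel([cand], panel).iloc[0]
        assert row.n_missing == 1 and row.n_correct == 165

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            score_validation_panel([self._cand()], pd.DataFrame())

    def test_published_patterns_are_consistent(self):
        """Every published validated locus has a male base drawn from the
        female het pair, on the tag strand."""
        for marker, pos, pair, male in PISTACHIO_VALIDATED_LOCI.values():
            assert male in pair
            code = iupac_code(*pair)
            seq = PISTACHIO_MARKER_SEQUENCES[marker]
            plain = seq.replace("(", "").replace(")", "")
            assert plain[pos - 1] == code


def test_reverse_complement_of_codes():
    assert reverse_complement("AATTC") == "GAATT"
    assert reverse_complement("R") == "Y"
    assert reverse_complement("S") == "S"
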