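"""MID collapse, natural-abundance correction and diagnostic ratios."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tracefate import (IsotopomerDist, MID, Metabolite, collapse_to_mid,
                       diagnostics, forward_convolve, fractional_labeling,
                       labeled_synthesis, natural_abundance_correct)
from tracefate.errors import InputError
from tracefate.mid_analysis import LabelTimeCourse, correction_matrix

FUM = Metabolite("FUM", 4, symmetric=True)
SH7P = Metabolite("SH7P", 7)


def random_mid(met, rng):
    return MID(met, rng.dirichlet(np.ones(met.n_carbons + 1)))


class TestCollapse:
    def test_unlabeled_collapses_to_m0(self):
        mid = collapse_to_mid(IsotopomerDist.unlabeled(FUM))
        assert mid.fractions[0] == pytest.approx(1.0)

    @given(st.integers(0, 2 ** 31 - 1))
    def test_matches_popcount_binning(self, seed):
        rng = np.random.default_rng(seed)
        d = IsotopomerDist(SH7P, rng.dirichlet(np.ones(128)))
        mid = collapse_to_mid(d).fractions
        expected = np.zeros(8)
        for p, w in enumerate(d.weights):
            expected[bin(p).count("1")] += w
        np.testing.assert_allclose(mid, expected, atol=1e-12)
        assert mid.sum() == pytest.approx(1.0, abs=1e-9)

    def test_linearity(self, rng):
        d1 = IsotopomerDist(FUM, rng.dirichlet(np.ones(16)))
        d2 = IsotopomerDist(FUM, rng.dirichlet(np.ones(16)))
        mix = IsotopomerDist(FUM, 0.3 * d1.weights + 0.7 * d2.weights)
        np.testing.assert_allclose(
            collapse_to_mid(mix).fractions,
            0.3 * collapse_to_mid(d1).fractions
            + 0.7 * collapse_to_mid(d2).fractions,
            atol=1e-12,
        )


class TestNaturalAbundance:
    def test_zero_p13_is_identity(self, rng):
        m = random_mid(FUM, rng)
        np.testing.assert_array_equal(
            natural_abundance_correct(m, p13=0.0).fractions, m.fractions)

    @given(st.integers(0, 2 ** 31 - 1))
    def test_convolve_then_correct_round_trips(self, seed):
        rng = np.random.default_rng(seed)
        tracer = random_mid(SH7P, rng)
        observed = forward_convolve(tracer, 0.0107)
        recovered = natural_abundance_correct(observed, p13=0.0107)
        np.testing.assert_allclose(recovered.fractions, tracer.fractions,
                                   atol=1e-9)

    def test_pure_m0_correction_raises_m0(self):
        observed = MID(FUM, [1.0, 0, 0, 0, 0])
        corrected = natural_abundance_correct(observed, p13=0.02)
        assert corrected.fractions[0] >= observed.fractions[0]

    def test_correction_matrix_is_lower_triangular_substochastic(self):
        C = correction_matrix(5, 0.0107)
        assert np.allclose(C, np.tril(C))
        assert np.all(C.sum(axis=0) <= 1.0 + 1e-12)

    def test_out_of_range_p13_rejected(self, rng):
        with pytest.raises(InputError):
            natural_abundance_correct(random_mid(FUM, rng), p13=0.2)


class TestFractionalLabeling:
    @pytest.mark.parametrize("m0,expected", [(1.0, 0.0), (0.4, 0.6), (0.0, 1.0)])
    def test_definition(self, m0, expected):
        rest = (1.0 - m0) / 4
        m = MID(FUM, [m0, rest, rest, rest, rest])
        assert fractional_labeling(m) == pytest.approx(expected)

    def test_consistent_with_isotopomer_popcount(self, rng):
        d = IsotopomerDist(FUM, rng.dirichlet(np.ones(16)))
        assert fractional_labeling(collapse_to_mid(d)) == pytest.approx(
            1.0 - d.weights[0])


class TestLabeledSynthesis:
    def _tc(self):
        rows = [
            ("G3P", 0, 2.0, np.array([1.0, 0, 0, 0])),
            ("G3P", 1, 2.0, np.array([0.75, 0.05, 0.05, 0.15])),
        ]
        return LabelTimeCourse.from_records(rows)

    def test_unlabeled_start_gives_zero(self):
        assert labeled_synthesis(self._tc(), "G3P", 0) == pytest.approx(0.0)

    def test_fraction_times_pool(self):
        assert labeled_synthesis(self._tc(), "G3P", 1) == pytest.approx(0.5)

    def test_missing_point_raises(self):
        with pytest.raises(InputError):
            labeled_synthesis(self._tc(), "G3P", 7)


class TestDiagnostics:
    PANEL = {"G6P": 1.0, "F6P": 1.0, "DHAP": 1.0, "3PGA": 1.0, "2PGA": 1.0,
             "PEP": 1.0, "PYR": 1.0, "6PGA": 1.0, "Ru5P": 1.0, "R5P": 1.0,
             "SH7P": 1.0}

    def test_equal_pools_give_unit_ratios(self):
        d = diagnostics(self.PANEL)
        assert d["G6P/F6P"] == pytest.approx(1.0)
        assert d["G6P/6PGA"] == pytest.approx(1.0)
        assert d["(6PGA+Ru5P)/(R5P+SH7P)"] == pytest.approx(1.0)
        assert d["3PGA/glycolytic_sum"] == pytest.approx(1 / 7)

    def test_simple_ratio_arithmetic(self):
        d = diagnostics({"G6P": 2.0, "6PGA": 1.0})
        assert d["G6P/6PGA"] == pytest.approx(2.0)

    def test_steady_ppp_entry_ratio_near_one(self):
        d = diagnostics({"6PGA": 0.3, "Ru5P": 0.3})
        assert d["6PGA/Ru5P"] == pytest.approx(1.0)

    def test_scale_invariance(self):
        base = diagnostics(self.PANEL)
        scaled = diagnostics({k: 17.3 * v for k, v in self.PANEL.items()})
        for key in base:
            assert scaled[key] == pytest.approx(base[key])

    def test_missing_metabolites_yield_absent_ratios(self):
        d = diagnostics({"G6P": 1.0})
        assert "G6P/F6P" not in d

    def test_zero_denominator_yields_nan_not_error(self):
        d = diagnostics({"G6P": 1.0, "F6P": 0.0})
        assert np.isnan(d["G6P/F6P"])

    def test_synonyms_accepted(self):
        d = diagnostics({"glucose-6-phosphate": 3.0,
                         "fructose-6-phosphate": 1.5})
        assert d["G6P/F6P"] == pytest.approx(2.0)


class TestTimeCourseIO:
    def test_csv_round_trip(self, tmp_path):
        rows = [("FUM", t, 1.5, np.array([0.7, 0.1, 0.1, 0.05, 0.05]))
                for t in range(3)]
        tc = LabelTimeCourse.from_records(rows)
        path = tmp_path / "tc.csv"
        tc.to_csv(path)
        back = LabelTimeCourse.from_csv(path)
        assert back.frame.equals(tc.frame) or np.allclose(
            back.frame.select_dtypes(float).to_numpy(),
            tc.frame.select_dtypes(float).to_numpy(), equal_nan=True)
        np.testing.assert_allclose(back.mid("FUM", 2).fractions,
                                   tc.mid("FUM", 2).fractions)

    def test_non_increasing_turns_rejected(self):
        import pandas as pd
        df = LabelTimeCourse.from_records(
            [("FUM", 0, 1.0, np.array([1.0, 0, 0, 0, 0]))]).frame
        bad = pd.concat([df, df])
        LabelTimeCourse(bad)  # duplicate single turn is fine (one point)
        with pytest.raises(InputError):
            LabelTimeCourse(df.drop(columns=["pool_nmol"]))
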