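"""Differential delta scoring, selectivity classification and marker-strain
concordance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sdhscreen.differential import (
    GrowthSummary,
    Thresholds,
    classify,
    delta_scores,
    marker_concordance,
    score_table,
)

THR = Thresholds(delta_s=0.3, delta_r=0.3, delta_l=0.5)


def summ(S=1.0, R=0.3, L=3.0, converged=True):
    return GrowthSummary(saturation=S, max_rate=R, lag_h=L, converged=converged)


class TestDeltaScores:
    def test_no_effect_gives_zero_deltas(self):
        sc = delta_scores(summ(), summ(), summ(), summ())
        assert (sc.delta_s, sc.delta_r, sc.delta_l) == (0.0, 0.0, 0.0)

    def test_symmetric_effect_cancels(self):
        """A drug halving saturation in both strains is not differential."""
        sc = delta_scores(summ(), summ(S=0.5), summ(), summ(S=0.5))
        assert sc.delta_s == pytest.approx(0.0)

    def test_mutant_selective_saturation_effect(self):
        sc = delta_scores(summ(), summ(S=0.9), summ(), summ(S=0.2))
        assert sc.delta_s == pytest.approx(0.7)
        assert sc.delta_r == pytest.approx(0.0)
        assert sc.delta_l == pytest.approx(0.0)

    def test_lag_sign_convention_mutant_more_inhibited_positive(self):
        """Drug doubling the mutant lag only -> positive delta_L."""
        sc = delta_scores(summ(), summ(), summ(), summ(L=6.0))
        assert sc.delta_l == pytest.approx(1.0)

    def test_zero_control_lag_uses_floor(self):
        sc = delta_scores(summ(L=0.0), summ(L=0.5), summ(L=0.0), summ(L=0.5))
        assert np.isfinite(sc.delta_l)
        assert sc.delta_l == pytest.approx(0.0)

    def test_nonconverged_input_raises(self):
        with pytest.raises(ValueError):
            delta_scores(summ(), summ(converged=False), summ(), summ())

    @given(
        s_rd=st.floats(0.05, 1.0), s_md=st.floats(0.05, 1.0),
        r_rd=st.floats(0.05, 1.0), r_md=st.floats(0.05, 1.0),
        l_rd=st.floats(1.0, 4.0), l_md=st.floats(1.0, 4.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_antisymmetry_under_strain_swap(self, s_rd, s_md, r_rd, r_md, l_rd, l_md):
        ref_c, mut_c = summ(), summ()
        ref_d = summ(S=s_rd, R=r_rd, L=l_rd)
        mut_d = summ(S=s_md, R=r_md, L=l_md)
        fwd = delta_scores(ref_c, ref_d, mut_c, mut_d)
        rev = delta_scores(mut_c, mut_d, ref_c, ref_d)
        assert fwd.delta_s == pytest.approx(-rev.delta_s, abs=1e-12)
        assert fwd.delta_r == pytest.approx(-rev.delta_r, abs=1e-12)
        assert fwd.delta_l == pytest.approx(-rev.delta_l, abs=1e-12)

    @given(scale=st.floats(0.1, 50.0))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance_of_saturation_delta(self, scale):
        base = delta_scores(summ(S=1.0), summ(S=0.9), summ(S=1.2), summ(S=0.3))
        scaled = delta_scores(summ(S=scale), summ(S=0.9 * scale),
                              summ(S=1.2 * scale), summ(S=0.3 * scale))
        assert scaled.delta_s == pytest.approx(base.delta_s, rel=1e-9)


class TestClassify:
    def test_all_zero_is_nonselective(self):
        sc = delta_scores(summ(), summ(), summ(), summ())
        assert classify(sc, THR) == "nonselective"

    def test_threshold_is_strict(self):
        sc = delta_scores(summ(S=1.0), summ(S=0.7), summ(S=1.0), summ(S=0.4))
        assert sc.delta_s == pytest.approx(0.3)
        assert classify(sc, THR) == "nonselective"  # exact tie goes to nonselective

    def test_directions(self):
        mut = delta_scores(summ(), summ(S=0.9), summ(), summ(S=0.2))
        ref = delta_scores(summ(), summ(S=0.2), summ(), summ(S=0.9))
        assert classify(mut, THR) == "mutant_selective"
        assert classify(ref, THR) == "reference_selective"

    def test_nan_is_indeterminate(self):
        from sdhscreen.differential import DifferentialScore

        sc = DifferentialScore("c", 50.0, np.nan, 0.0, 0.0)
        assert classify(sc, THR) == "indeterminate"


class TestScoreTable:
    @staticmethod
    def _fits_frame():
        rows = []
        for strain, mult in (("wt", 0.9), ("sdh2", 0.2)):
            rows.append(dict(strain=strain, compound_id="", conc_um=0.0, drug_present=False,
                             saturation=1.0, max_rate=0.3, lag_h=3.0, converged=True))
            for cid, m in (("A", mult), ("B", 1.0)):
                rows.append(dict(strain=strain, compound_id=cid, conc_um=50.0,
                                 drug_present=True, saturation=m, max_rate=0.3,
                                 lag_h=3.0, converged=True))
        return pd.DataFrame(rows)

    def test_per_compound_calls(self):
        scores = score_table(self._fits_frame(), mutant="sdh2", reference="wt", thresholds=THR)
        by_id = scores.set_index("compound_id")["call"]
        assert by_id["A"] == "mutant_selective"
        assert by_id["B"] == "nonselective"
        assert scores.set_index("compound_id")["any_selective"]["A"]

    def test_incomplete_quadruple_raises(self):
        fits = self._fits_frame()
        fits = fits[fits["strain"] == "wt"]
        with pytest.raises(ValueError):
            score_table(fits, mutant="sdh2", reference="wt", thresholds=THR)


class TestMarkerConcordance:
    @staticmethod
    def _strain_fits(ratio_s=0.5, strain="wt"):
        return pd.DataFrame([
            dict(strain=strain, compound_id="", conc_um=0.0, drug_present=False,
                 saturation=1.0, max_rate=0.3, lag_h=3.0, converged=True),
            dict(strain=strain, compound_id="A", conc_um=50.0, drug_present=True,
                 saturation=ratio_s, max_rate=0.3, lag_h=3.0, converged=True),
        ])

    def test_identical_fits_concordant(self):
        ok, report = marker_concordance(self._strain_fits(), self._strain_fits(strain="nhp6a"))
        assert ok and report["concordant"].all()

    def test_marker_sensitized_flags_discordant(self):
        """Three-fold difference in drug effect between the reference-like
        strains indicates a selection-marker artifact."""
        ok, report = marker_concordance(
            self._strain_fits(ratio_s=0.6),
            self._strain_fits(ratio_s=0.2, strain="nhp6a"),
        )
        assert not ok
        assert not report.loc[0, "concordant"]

    def test_empty_comparison_is_error(self):
        a = self._strain_fits()
        b = self._strain_fits(strain="nhp6a")
        b["conc_um"] = b["conc_um"].replace(50.0, 25.0)  # no matched condition
        with pytest.raises(ValueError):
            marker_concordance(a, b)
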