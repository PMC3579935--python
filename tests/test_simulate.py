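"""Synthetic-data generator: ground-truth construction, reproducibility,
plate layout and enzyme progress-curve properties."""

import numpy as np
import pytest

import sdhscreen as s
from sdhscreen.simulate import BLANK_COLS, NEG_CONTROL_COLS, PLATE_ROWS


class TestGrowthCurveGeneration:
    def test_mutant_on_nonfermentable_media_is_flat(self):
        """Respiration-deficient strain on glycerol only: no growth above baseline."""
        cv = s.gen_growth_curve(s.sdh2_null(), cfg=s.SimConfig(noise_sd=0.0, media_mix=0.0))
        assert cv.true_phases == ()
        assert np.allclose(cv.od, 0.05)
        assert cv.true_total_saturation == pytest.approx(0.05)

    def test_wt_interphase_plateau_equals_baseline_plus_phase1(self, wt_curve_clean):
        cv = wt_curve_clean
        p1, p2 = cv.true_phases
        # evaluate in the diauxic pause, after phase 1 is done, before phase 2 starts
        t_mid = (p1.inflection_h + 4 / p1.shape_rate + p2.lag_h) / 2
        od_mid = np.interp(t_mid, cv.times_h, cv.od)
        assert od_mid == pytest.approx(0.05 + p1.saturation, abs=0.02)

    def test_media_mix_one_suppresses_respiratory_phase(self):
        cv = s.gen_growth_curve(s.wild_type(), cfg=s.SimConfig(noise_sd=0.0, media_mix=1.0))
        assert len(cv.true_phases) == 1

    def test_noise_free_curves_nondecreasing(self, wt_curve_clean, sdh2_curve_clean):
        for cv in (wt_curve_clean, sdh2_curve_clean):
            assert (np.diff(cv.od) >= -1e-12).all()

    def test_zero_dose_identity(self):
        """Drug at zero concentration reproduces the no-drug curve bit-for-bit."""
        drug = s.DrugEffectModel("x", {"wt": s.DrugEffect(ec50_um=1.0, sat_mult=0.1)})
        cfg = s.SimConfig(seed=42)
        a = s.gen_growth_curve(s.wild_type(), drug=None, cfg=cfg)
        b = s.gen_growth_curve(s.wild_type(), drug=drug, conc_um=0.0, cfg=cfg)
        assert np.array_equal(a.od, b.od)
        assert a.true_phases == b.true_phases

    def test_seed_reproducibility_bit_exact(self):
        cfg = s.SimConfig(seed=7)
        a = s.gen_growth_curve(s.wild_type(), cfg=cfg)
        b = s.gen_growth_curve(s.wild_type(), cfg=cfg)
        assert np.array_equal(a.od, b.od)

    def test_drug_transforms_truth_via_hill(self):
        eff = s.DrugEffect(ec50_um=10.0, hill=1.0, sat_mult=0.5, rate_mult=0.8, lag_add_h=4.0)
        drug = s.DrugEffectModel("x", {"sdh2": eff})
        cv = s.gen_growth_curve(s.sdh2_null(), drug=drug, conc_um=10.0,
                                cfg=s.SimConfig(noise_sd=0.0, media_mix=1.0))
        base = s.sdh2_null().phase1
        # at c == ec50 occupancy is exactly 1/2
        assert cv.true_phases[0].saturation == pytest.approx(base.saturation * 0.75)
        assert cv.true_phases[0].max_rate == pytest.approx(base.max_rate * 0.9)
        assert cv.true_phases[0].lag_h == pytest.approx(base.lag_h + 2.0)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            s.gen_growth_curve(s.wild_type(), conc_um=-1.0)

    def test_bad_config_rejected(self):
        with pytest.raises(ValueError):
            s.SimConfig(duration_h=0.0)
        with pytest.raises(ValueError):
            s.SimConfig(media_mix=1.5)

    def test_sampling_interval_respected(self, wt_curve_clean):
        dt = np.diff(wt_curve_clean.times_h)
        assert np.allclose(dt, 0.1)


class TestScreenPlate:
    def test_layout_roles(self):
        reads, plate_map, truth = s.gen_screen_plate(n_compounds=320, cfg=s.SimConfig(seed=1))
        for c in NEG_CONTROL_COLS:
            wells = plate_map[plate_map["well"].str.fullmatch(f"[A-P]{c}")]
            assert (wells["role"] == "neg_control").all()
        for c in BLANK_COLS:
            wells = plate_map[plate_map["well"].str.fullmatch(f"[A-P]{c}")]
            assert (wells["role"] == "blank").all()
        assert (plate_map["role"] == "compound").sum() == 320
        assert len(truth) == 320

    def test_two_read_times(self):
        reads, _, _ = s.gen_screen_plate(n_compounds=10, cfg=s.SimConfig(seed=1))
        assert set(reads["time_min"]) == {960.0, 2880.0}

    def test_hit_count_is_rounded_binomial_design(self):
        _, _, truth = s.gen_screen_plate(n_compounds=320, hit_fraction=0.05,
                                         cfg=s.SimConfig(seed=3))
        assert truth["is_inhibitor"].sum() == 16

    def test_overflow_needs_multiplate(self):
        with pytest.raises(ValueError):
            s.gen_screen_plate(n_compounds=321)
        reads, plate_map, truth = s.gen_screen_plate(
            n_compounds=400, cfg=s.SimConfig(seed=1), allow_multiplate=True
        )
        assert plate_map["plate_id"].nunique() == 2
        assert len(truth) == 400

    def test_control_plate_alternating_rows(self):
        _, cmap = s.gen_control_plate(s.SimConfig(seed=1))
        roles = ["neg_control", "pos_control", "blank"]
        for i, row in enumerate(PLATE_ROWS):
            sub = cmap[cmap["well"].str.startswith(row) & cmap["well"].str[1:].str.isdigit()]
            assert set(sub["role"]) == {roles[i % 3]}


class TestEnzymeAssay:
    def test_zero_dose_slope_matches_uninhibited_rate(self):
        recs = s.gen_enzyme_assay(5.0, replicates=1, cfg=s.SimConfig(noise_sd=0.0))
        rec0 = [r for r in recs if r.conc_um == 0][0]
        slope0 = (rec0.a340[1] - rec0.a340[0]) / 2.0
        assert -slope0 == pytest.approx(rec0.true_v0, rel=0.05)

    def test_half_maximal_at_true_ic50(self):
        recs = s.gen_enzyme_assay(
            10.0, dilution=s.serial_dilution(10.0, 2.0, 4), replicates=1,
            cfg=s.SimConfig(noise_sd=0.0),
        )
        by_conc = {r.conc_um: r for r in recs}
        assert by_conc[10.0].true_v0 == pytest.approx(0.5 * by_conc[0.0].true_v0)

    def test_assay_design_counts(self):
        """8-point 5-fold series from 62.5 µM with 4 replicates -> 32 inhibitor curves."""
        recs = s.gen_enzyme_assay(1.3, replicates=4, cfg=s.SimConfig(seed=1),
                                  include_zero=False)
        assert len(recs) == 32
        assert len({r.conc_um for r in recs}) == 8
        assert all(len(r.times_min) == 11 for r in recs)
        assert all(r.times_min[-1] == 20.0 for r in recs)

    def test_progress_curves_decrease(self):
        recs = s.gen_enzyme_assay(5.0, replicates=1, cfg=s.SimConfig(noise_sd=0.0))
        for r in recs:
            assert (np.diff(r.a340) < 0).all()

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            s.gen_enzyme_assay(-1.0)
        with pytest.raises(ValueError):
            s.gen_enzyme_assay(5.0, replicates=0)
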