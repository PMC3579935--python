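"""Plate-level screening analytics: percent inhibition, z-factor, hit calling,
and acoustic-dispensing mass balance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sdhscreen as s
from sdhscreen.plates import (
    DispenseProtocol,
    QCError,
    call_hits,
    dispense_concentration,
    percent_inhibition,
    plate_qc,
    summarize_plate,
    z_factor,
)


class TestPercentInhibition:
    @pytest.mark.parametrize(
        "test,control,blank,expected",
        [
            (1.0, 1.0, 0.1, 0.0),      # uninhibited well sits at 0%
            (0.1, 1.0, 0.1, 100.0),    # complete inhibition sits at 100%
            (0.55, 1.0, 0.1, 50.0),    # 100*(1 - 0.45/0.9)
            (0.05, 1.0, 0.1, 105.556), # below-blank values pass through
            (1.9, 1.0, 0.1, -100.0),   # growth stimulation goes negative
        ],
    )
    def test_fixed_points(self, test, control, blank, expected):
        assert percent_inhibition(test, control, blank) == pytest.approx(expected, abs=1e-3)

    def test_failed_plate_raises(self):
        with pytest.raises(QCError):
            percent_inhibition(0.5, 0.1, 0.1)
        with pytest.raises(QCError):
            percent_inhibition(0.5, 0.05, 0.1)

    @given(
        test=st.floats(0.0, 3.0),
        scale=st.floats(0.1, 10.0),
        offset=st.floats(-0.5, 0.5),
    )
    @settings(max_examples=100, deadline=None)
    def test_affine_invariance(self, test, scale, offset):
        """Rescaling all absorbances by a common positive affine map leaves PI unchanged."""
        base = percent_inhibition(test, 1.0, 0.1)
        mapped = percent_inhibition(
            scale * test + offset, scale * 1.0 + offset, scale * 0.1 + offset
        )
        assert mapped == pytest.approx(base, abs=1e-6, rel=1e-6)


class TestZFactor:
    def test_perfect_separation_is_one(self):
        assert z_factor([100.0, 100.0, 100.0], [0.0, 0.0, 0.0]) == 1.0

    def test_hand_computed_example(self):
        # sample sd of both control lists is exactly 10 -> 1 - 3*20/100
        assert z_factor([90, 100, 110], [-10, 0, 10]) == pytest.approx(0.4)

    def test_overlapping_controls_negative(self):
        z = z_factor([60, 30, 90], [0, 40, -40])
        assert z < 0

    def test_label_swap_invariance_and_bound(self):
        rng = np.random.default_rng(0)
        pos = rng.normal(95, 4, 12)
        neg = rng.normal(3, 4, 12)
        assert z_factor(pos, neg) == pytest.approx(z_factor(neg, pos))
        assert z_factor(pos, neg) <= 1.0

    def test_equal_means_is_qc_failure(self):
        with pytest.raises(QCError):
            z_factor([50, 50], [50, 50])

    def test_needs_replicates(self):
        with pytest.raises(QCError):
            z_factor([100.0], [0.0, 1.0])


@pytest.fixture(scope="module")
def null_screen():
    reads, plate_map, truth = s.gen_screen_plate(
        n_compounds=320, hit_fraction=0.0, cfg=s.SimConfig(seed=11)
    )
    return summarize_plate(reads, plate_map), truth


class TestSummarizeAndHits:

    def test_null_screen_centred_at_zero(self, null_screen):
        pi, _ = null_screen
        comp = pi[pi["role"] == "compound"]
        assert abs(comp["percent_inhibition"].mean()) < 1.0
        # noise-set spread: a few percent at most
        assert comp["percent_inhibition"].std() < 5.0

    def test_zero_threshold_calls_half_of_null_wells(self, null_screen):
        pi, _ = null_screen
        hits = call_hits(pi, threshold=0.0, read_time_h=48.0)
        frac = len(hits) / 320
        assert 0.4 < frac < 0.6

    def test_positive_threshold_on_null_calls_nothing(self, null_screen):
        pi, _ = null_screen
        assert call_hits(pi, threshold=50.0, read_time_h=48.0).empty

    def test_strong_hits_recover_truth_table(self):
        reads, plate_map, truth = s.gen_screen_plate(
            n_compounds=320, hit_fraction=0.05, cfg=s.SimConfig(seed=5)
        )
        assert truth["is_inhibitor"].sum() == 16
        pi = summarize_plate(reads, plate_map)
        hits = call_hits(pi, threshold=50.0, read_time_h=48.0)
        assert set(hits["compound_id"]) == set(truth.loc[truth["is_inhibitor"], "compound_id"])
        # deterministic ordering: PI descending then compound id
        pis = hits["percent_inhibition"].to_numpy()
        assert (np.diff(pis) <= 1e-12).all()

    def test_all_wells_at_control_mean_give_zero_pi(self):
        rows, mrows = [], []
        for i, well in enumerate(["A1", "A24", "B2", "B23", "C5", "C6"]):
            role = ("neg_control" if well in ("A1", "A24")
                    else "blank" if well in ("B2", "B23") else "compound")
            value = {"neg_control": 0.9, "blank": 0.1, "compound": 0.9}[role]
            rows.append({"plate_id": "P1", "well": well, "time_min": 960.0,
                         "channel": "od600", "value": value})
            mrows.append({"plate_id": "P1", "well": well, "role": role,
                          "compound_id": f"C{i}" if role == "compound" else "",
                          "conc_um": 10.0, "strain": "sdh2"})
        pi = summarize_plate(pd.DataFrame(rows), pd.DataFrame(mrows))
        assert pi.loc[pi["role"] == "compound", "percent_inhibition"].abs().max() < 1e-9

    def test_missing_controls_raise(self):
        reads = pd.DataFrame([{"plate_id": "P1", "well": "C3", "time_min": 960.0,
                               "channel": "od600", "value": 0.5}])
        plate_map = pd.DataFrame([{"plate_id": "P1", "well": "C3", "role": "compound",
                                   "compound_id": "C1", "conc_um": 10.0, "strain": "sdh2"}])
        with pytest.raises(QCError):
            summarize_plate(reads, plate_map)

    def test_duplicate_wells_raise(self):
        reads = pd.DataFrame([
            {"plate_id": "P1", "well": "A1", "time_min": 960.0, "channel": "od600", "value": 0.5},
            {"plate_id": "P1", "well": "A1", "time_min": 960.0, "channel": "od600", "value": 0.6},
        ])
        plate_map = pd.DataFrame([{"plate_id": "P1", "well": "A1", "role": "neg_control",
                                   "compound_id": "", "conc_um": 0.0, "strain": "sdh2"}])
        with pytest.raises(ValueError):
            summarize_plate(reads, plate_map)

    def test_control_plate_z_factor_screenable(self):
        """Alternating-row control plate yields z > 0.5 at both read times."""
        reads, cmap = s.gen_control_plate(s.SimConfig(seed=7))
        qc = plate_qc(summarize_plate(reads, cmap))
        assert set(qc["read_time_h"]) == {16.0, 48.0}
        assert (qc["z_factor"] > 0.5).all()
        assert (qc["z_factor"] <= 1.0).all()


class TestDispense:
    def test_screening_protocol_stage_concentrations(self):
        p = DispenseProtocol()
        after = dispense_concentration(p, "after_dispense")
        assert after.nominal_conc_um == pytest.approx(50.0)
        topup = dispense_concentration(p, "after_topup")
        assert topup.nominal_conc_um == pytest.approx(12.5)
        assert topup.nominal_solvent_pct == pytest.approx(0.125)
        final = dispense_concentration(p, "final_assay")
        assert final.nominal_conc_um == pytest.approx(10.0)
        assert final.nominal_solvent_pct == pytest.approx(0.1)
        # full accounting differs only by the 50 nL droplet volume
        assert final.conc_um == pytest.approx(10.0, rel=2e-3)

    def test_zero_droplets_zero_everywhere(self):
        p = DispenseProtocol(n_droplets=0)
        for stage in ("after_dispense", "after_topup", "final_assay"):
            assert dispense_concentration(p, stage).conc_um == 0.0

    def test_unknown_stage(self):
        with pytest.raises(ValueError):
            dispense_concentration(DispenseProtocol(), "mid_topup")

    @given(
        stock=st.floats(0.5, 50.0),
        droplet=st.floats(1.0, 10.0),
        n=st.integers(1, 50),
    )
    @settings(max_examples=50, deadline=None)
    def test_mass_conservation_across_stages(self, stock, droplet, n):
        """conc x volume is the same at every stage (compound amount conserved)."""
        p = DispenseProtocol(stock_conc_mm=stock, droplet_vol_nl=droplet, n_droplets=n)
        amounts = [
            dispense_concentration(p, stage).conc_um
            * dispense_concentration(p, stage).total_vol_ul
            for stage in ("after_dispense", "after_topup", "final_assay")
        ]
        assert np.ptp(amounts) < 1e-9 * max(amounts)
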