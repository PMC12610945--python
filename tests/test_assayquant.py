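"""Tabular assays: ΔΔCt, telomere T/S, replicate averaging, wound closure."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import agescore as ag
from agescore import assayquant as aq


def _ct_table(rows):
    return pd.DataFrame(rows, columns=["sample_id", "condition", "gene", "ct"])


class TestDdct:
    def test_control_against_itself_is_fold_one(self):
        table = _ct_table(
            [("s1", "ctrl", "TP53", 25.0), ("s1", "ctrl", "GAPDH", 18.0),
             ("s2", "ctrl", "TP53", 25.0), ("s2", "ctrl", "GAPDH", 18.0)]
        )
        out = aq.ddct_relative_expression(table, "GAPDH", "ctrl")
        assert out.fold_change.tolist() == pytest.approx([1.0, 1.0])

    def test_known_ddct_gives_fold_two(self):
        table = _ct_table(
            [("c1", "ctrl", "TP53", 25.0), ("c1", "ctrl", "GAPDH", 18.0),
             ("c2", "ctrl", "TP53", 25.0), ("c2", "ctrl", "GAPDH", 18.0),
             ("t1", "aged", "TP53", 24.0), ("t1", "aged", "GAPDH", 18.0)]
        )
        out = aq.ddct_relative_expression(table, "GAPDH", "ctrl")
        aged = out[out.condition == "aged"]
        assert aged.ddct.iloc[0] == pytest.approx(-1.0)
        assert aged.fold_change.iloc[0] == pytest.approx(2.0)

    def test_technical_replicates_averaged_first(self):
        table = pd.DataFrame(
            {"sample_id": ["s1"] * 4, "condition": ["ctrl"] * 4,
             "gene": ["TP53", "TP53", "GAPDH", "GAPDH"],
             "ct": [24.0, 26.0, 17.0, 19.0], "tech_rep": [1, 2, 1, 2]}
        )
        out = aq.ddct_relative_expression(table, "GAPDH", "ctrl")
        assert out.delta_ct.iloc[0] == pytest.approx(25.0 - 18.0)

    def test_generator_planted_shift_recovered(self):
        design = ag.StudyDesign(wells_per_arm=4, seed=11)
        eff = [ag.MarkerEffectSpec("tgt", "ct_shift", 0.0, -2.0, dispersion=0.05)]
        bundle = ag.generate_study(design, eff)
        out = aq.ddct_relative_expression(
            bundle.qpcr, "GAPDH", "-DOX", group_within=["timepoint_days"]
        )
        means = out.groupby("condition").fold_change.mean()
        assert means["+DOX"] == pytest.approx(4.0, rel=0.15)
        assert means["-DOX"] == pytest.approx(1.0, rel=0.05)

    def test_missing_reference_names_sample(self):
        table = _ct_table(
            [("s1", "ctrl", "TP53", 25.0), ("s1", "ctrl", "GAPDH", 18.0),
             ("s2", "ctrl", "TP53", 25.0)]
        )
        with pytest.raises(ValueError, match="s2"):
            aq.ddct_relative_expression(table, "GAPDH", "ctrl")


def _standard(t0=14.0, s0=22.0):
    conc = 100.0 / 2.0 ** np.arange(8)
    return pd.DataFrame(
        {"concentration": conc, "t_ct": t0 - np.log2(conc), "s_ct": s0 - np.log2(conc)}
    )


def _runs(sample, t_cts, s_cts):
    return pd.DataFrame(
        {"sample_id": sample, "replicate": range(1, len(t_cts) + 1),
         "t_ct": t_cts, "s_ct": s_cts}
    )


class TestTelomere:
    def test_equal_quantities_give_tlr_one(self):
        runs = _runs("s1", [10.0, 10.1, 9.9], [18.0, 18.1, 17.9])
        out = aq.telomere_ts_ratio(runs, _standard())
        assert out.tlr.iloc[0] == pytest.approx(1.0, rel=0.01)
        assert out.qc_pass.iloc[0]

    def test_doubled_telomere_signal(self):
        # one cycle earlier on T = 2x telomere quantity
        runs = _runs("s1", [9.0, 9.0, 9.0], [18.0, 18.0, 18.0])
        out = aq.telomere_ts_ratio(runs, _standard())
        assert out.tlr.iloc[0] == pytest.approx(2.0, rel=0.01)

    def test_outlier_replicate_fails_cv_qc(self):
        runs = _runs("s1", [10.0, 10.0, 6.0], [18.0, 18.0, 18.0])
        out = aq.telomere_ts_ratio(runs, _standard())
        assert not out.qc_pass.iloc[0]
        assert "CV" in out.qc_reason.iloc[0]

    def test_fewer_than_three_replicates_fails_qc(self):
        runs = _runs("s1", [10.0, 10.0], [18.0, 18.0])
        out = aq.telomere_ts_ratio(runs, _standard())
        assert not out.qc_pass.iloc[0]
        assert "replicates" in out.qc_reason.iloc[0]

    def test_non_monotone_standard_rejected(self):
        std = _standard()
        std.loc[3, "t_ct"] = std.loc[0, "t_ct"] - 5.0
        with pytest.raises(ValueError, match="monotone"):
            aq.telomere_ts_ratio(_runs("s1", [10] * 3, [18] * 3), std)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(shift=st.floats(-2.0, 2.0))
    def test_common_scale_factor_invariance(self, shift):
        """Scaling both signals by a common factor (a Ct shift on both
        channels) leaves the T/S ratio unchanged."""
        base = aq.telomere_ts_ratio(
            _runs("s1", [10.0, 10.2, 9.8], [18.0, 18.2, 17.8]), _standard()
        )
        shifted = aq.telomere_ts_ratio(
            _runs("s1", [10.0 + shift, 10.2 + shift, 9.8 + shift],
                  [18.0 + shift, 18.2 + shift, 17.8 + shift]),
            _standard(),
        )
        assert shifted.tlr.iloc[0] == pytest.approx(base.tlr.iloc[0], rel=1e-9)

    def test_generator_planted_ratio_recovered(self):
        design = ag.StudyDesign(wells_per_arm=4, seed=11)
        eff = [ag.MarkerEffectSpec("telomere", "ts_shift", 1.0, 2.0, dispersion=0.02)]
        bundle = ag.generate_study(design, eff)
        out = aq.telomere_ts_ratio(bundle.telomere_runs, bundle.telomere_standard)
        meta = bundle.telomere_runs[["sample_id", "condition"]].drop_duplicates()
        means = out.merge(meta).groupby("condition").tlr.mean()
        assert means["+DOX"] == pytest.approx(2.0, rel=0.1)
        assert means["-DOX"] == pytest.approx(1.0, rel=0.1)


class TestReplicateAveraging:
    def test_duplicates_averaged(self):
        table = pd.DataFrame(
            {"sample_id": ["s1", "s1"], "analyte": ["il6", "il6"], "value": [4.0, 6.0]}
        )
        out = aq.average_technical_replicates(table, ["sample_id", "analyte"])
        assert out.value.tolist() == [5.0]

    def test_single_replicate_passes_through(self):
        table = pd.DataFrame({"sample_id": ["s1"], "analyte": ["il6"], "value": [3.0]})
        out = aq.average_technical_replicates(table, ["sample_id", "analyte"])
        assert out.value.tolist() == [3.0]

    def test_biological_n_not_inflated(self):
        design = ag.StudyDesign(wells_per_arm=3, seed=1)
        eff = [ag.MarkerEffectSpec("il6", "secretion_level", 15.0, 60.0)]
        bundle = ag.generate_study(design, eff)
        out = aq.average_technical_replicates(
            bundle.elisa, ["sample_id", "condition", "timepoint_days", "analyte"]
        )
        n = out.groupby(["condition", "timepoint_days"]).sample_id.nunique()
        assert (n == 3).all()  # wells, not technical replicates


class TestWoundClosure:
    def test_identical_masks_zero_percent(self):
        m = np.ones((20, 40), dtype=bool)
        assert aq.wound_closure(m, m) == pytest.approx(0.0)

    def test_empty_last_mask_full_closure(self):
        m = np.ones((20, 40), dtype=bool)
        assert aq.wound_closure(m, np.zeros_like(m)) == pytest.approx(100.0)

    def test_empty_first_mask_is_error(self):
        m = np.zeros((20, 40), dtype=bool)
        with pytest.raises(ValueError, match="no wound"):
            aq.wound_closure(m, m)

    def test_monotone_decreasing_in_final_area(self):
        first = np.zeros((20, 60), dtype=bool)
        first[:, 10:50] = True
        closures = []
        for width in (40, 30, 20, 10, 0):
            last = np.zeros_like(first)
            last[:, 10 : 10 + width] = True
            closures.append(aq.wound_closure(first, last))
        assert closures == sorted(closures)
        assert all(c <= 100.0 for c in closures)

    def test_generator_planted_closure_recovered(self):
        design = ag.StudyDesign(wells_per_arm=3, seed=4)
        eff = [ag.MarkerEffectSpec("mig", "gap_closure_rate", 60.0, 30.0,
                                   dispersion=1.0)]
        bundle = ag.generate_study(design, eff)
        for wound in bundle.wounds:
            got = aq.wound_closure(wound.gap_mask_first, wound.gap_mask_last)
            assert got == pytest.approx(wound.planted_closure_percent, abs=2.0)

    def test_threshold_entry_point(self):
        img = np.full((30, 80), 50.0)
        img[:, 30:50] = 5.0  # cell-free gap
        mask = aq.wound_mask_from_image(img)
        assert mask.sum() == 30 * 20
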