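import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rimpet import (
    ActivityThreshold,
    LabelMap,
    PipelineConfig,
    Volume3D,
    active_fraction,
    calibrate_threshold,
    classify_activity,
    classify_rbrl,
    classify_rim_level,
    default_threshold,
    phenotype_lesions,
    summarize_patient,
    write_report,
)
from rimpet.errors import CalibrationError, NumericDomainError, UndefinedFractionError
from rimpet.phenotype import HIGH, LOW


class TestThreshold:
    def test_calibration_is_mean_plus_one_sd(self):
        thr = calibrate_threshold([1.0, 1.4])
        assert thr.control_mean == pytest.approx(1.2)
        assert thr.control_sd == pytest.approx(0.2828, abs=1e-4)
        assert thr.value == pytest.approx(1.4828, abs=1e-4)
        assert thr.source == "calibrated"

    def test_degenerate_sample_gives_mean(self):
        assert calibrate_threshold([1.0, 1.0, 1.0]).value == pytest.approx(1.0)

    def test_single_value_raises(self):
        with pytest.raises(CalibrationError):
            calibrate_threshold([1.0])

    def test_shipped_default_without_control_data(self):
        thr = default_threshold()
        assert thr.value == 1.3624
        assert thr.source == "configured"


class TestActiveFraction:
    thr = ActivityThreshold(1.3624)

    def test_uniform_low_region_is_zero_percent(self):
        dvr = Volume3D(np.full((4, 4, 4), 1.0))
        assert active_fraction(dvr, np.ones((4, 4, 4), bool), self.thr) == 0.0

    def test_half_active_region_is_fifty_percent(self):
        data = np.full((4, 4, 4), 1.2)
        data[:2] = 1.5
        dvr = Volume3D(data)
        assert active_fraction(dvr, np.ones((4, 4, 4), bool), self.thr) == 50.0

    def test_voxel_exactly_at_threshold_counts_inactive(self):
        dvr = Volume3D(np.full((2, 2, 2), 1.3624))
        assert active_fraction(dvr, np.ones((2, 2, 2), bool), self.thr) == 0.0

    def test_empty_region_raises(self):
        dvr = Volume3D(np.ones((2, 2, 2)))
        with pytest.raises(UndefinedFractionError):
            active_fraction(dvr, np.zeros((2, 2, 2), bool), self.thr)


class TestActivityRules:
    @pytest.mark.parametrize(
        "core,rim,expected",
        [
            (0, 0, "inactive"),
            (10, 25, "rim_active"),  # 25 >= 2*10
            (10, 19, "overall_active"),  # under the doubling requirement
            (3, 9, "rim_active"),  # 9 >= 3+5
            (3, 7, "overall_active"),  # 7 < 3+5
            (30, 80, "overall_active"),
            (0, 4, "overall_active"),  # not inactive; fails both rim rules
            (0, 5, "rim_active"),
            (5, 10, "rim_active"),  # band edges inclusive
            (20, 40, "rim_active"),
            (20.1, 100, "overall_active"),  # just above the core band
        ],
    )
    def test_rule_examples(self, core, rim, expected):
        assert classify_activity(core, rim) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(NumericDomainError):
            classify_activity(-1, 0)
        with pytest.raises(NumericDomainError):
            classify_activity(0, 101)

    def test_rules_exhaustive_and_exclusive_on_grid(self):
        """Independently evaluated predicates assign exactly one class at
        every point of a 0.1-step grid over [0, 100]^2."""
        core, rim = np.meshgrid(
            np.arange(0, 100.05, 0.1), np.arange(0, 100.05, 0.1), indexing="ij"
        )
        inactive = (core == 0) & (rim == 0)
        rim_act = ((core >= 5) & (core <= 20) & (rim >= 2 * core)) | (
            (core < 5) & (rim >= core + 5)
        )
        n_classes = (
            inactive.astype(int)
            + (rim_act & ~inactive).astype(int)
            + (~inactive & ~rim_act).astype(int)
        )
        assert (n_classes == 1).all()
        # and the implementation agrees with the predicates on a subsample
        idx = np.random.default_rng(0).integers(0, core.shape[0], size=(300, 2))
        for i, j in idx:
            got = classify_activity(core[i, j], rim[i, j])
            want = (
                "inactive"
                if inactive[i, j]
                else "rim_active" if rim_act[i, j] else "overall_active"
            )
            assert got == want

    @given(
        core=st.floats(0, 100, allow_nan=False),
        rim=st.floats(0, 100, allow_nan=False),
    )
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_every_input_gets_exactly_one_class(self, core, rim):
        assert classify_activity(core, rim) in ("inactive", "rim_active", "overall_active")


class TestRimLevels:
    thr = ActivityThreshold(1.3624)

    def test_mean_above_threshold_is_high(self):
        dvr = Volume3D(np.full((3, 3, 3), 1.5))
        assert classify_rim_level(dvr, np.ones((3, 3, 3), bool), self.thr) == HIGH

    def test_mean_exactly_at_threshold_is_low(self):
        dvr = Volume3D(np.full((3, 3, 3), 1.3624))
        assert classify_rim_level(dvr, np.ones((3, 3, 3), bool), self.thr) == LOW

    def test_mean_below_threshold_is_low(self):
        dvr = Volume3D(np.full((3, 3, 3), 1.2))
        assert classify_rim_level(dvr, np.ones((3, 3, 3), bool), self.thr) == LOW

    def test_empty_shell_is_low_with_warning(self, caplog):
        import logging

        dvr = Volume3D(np.ones((2, 2, 2)))
        with caplog.at_level(logging.WARNING, logger="rimpet"):
            assert classify_rim_level(dvr, np.zeros((2, 2, 2), bool), self.thr) == LOW
        assert any("empty shell" in m for m in caplog.messages)

    @pytest.mark.parametrize(
        "inner,outer,expected",
        [(HIGH, HIGH, True), (HIGH, LOW, False), (LOW, HIGH, False), (LOW, LOW, False)],
    )
    def test_rbrl_requires_high_high(self, inner, outer, expected):
        assert classify_rbrl(inner, outer) is expected


def _sphere_phantom(core_dvr, inner_dvr, outer_dvr):
    from rimpet.synthetic import PhantomLesion, PhantomSpec, generate_phantom

    spec = PhantomSpec(
        shape=(21, 21, 21),
        lesions=[PhantomLesion((10.5, 10.5, 10.5), 4.0, core_dvr, inner_dvr, outer_dvr)],
    )
    return generate_phantom(spec)


class TestPhenotypePipeline:
    def test_rim_active_rbrl_phantom(self):
        """Core below / both shells above threshold: rim-active and rBRL."""
        dvr, labels, _ = _sphere_phantom(1.2, 1.6, 1.6)
        (rec,) = phenotype_lesions(dvr, labels)
        assert rec.activity_class == "rim_active"
        assert rec.is_rbrl is True
        assert rec.rim_inner_label == HIGH and rec.rim_outer_label == HIGH
        assert rec.core_active_pct == 0.0

    def test_cold_phantom_all_inactive(self):
        dvr, labels, _ = _sphere_phantom(1.0, 1.0, 1.0)
        (rec,) = phenotype_lesions(dvr, labels)
        assert rec.activity_class == "inactive"
        assert rec.is_rbrl is False

    def test_subthreshold_volume_gives_empty_report(self):
        from rimpet.synthetic import PhantomLesion, PhantomSpec, generate_phantom

        spec = PhantomSpec(
            shape=(15, 15, 15),
            lesions=[PhantomLesion((7.5, 7.5, 7.5), 2.0, 1.6, 1.6, 1.6)],  # ~33 mm^3
        )
        dvr, labels, _ = generate_phantom(spec)
        assert phenotype_lesions(dvr, labels) == []

    def test_raising_threshold_never_activates_inactive_lesion(self):
        dvr, labels, _ = _sphere_phantom(1.2, 1.2, 1.2)
        for value in (1.3624, 1.5, 2.0, 5.0):
            (rec,) = phenotype_lesions(
                dvr, labels, threshold=ActivityThreshold(value)
            )
            assert rec.activity_class == "inactive"

    def test_report_is_byte_identical_across_runs(self, tmp_path):
        dvr, labels, _ = _sphere_phantom(1.6, 1.2, 1.6)
        paths = []
        for i in range(2):
            p = tmp_path / f"run{i}.csv"
            write_report(phenotype_lesions(dvr, labels), p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]


class TestPatientSummary:
    def _phen(self, rbrl, activity):
        from rimpet.phenotype import LesionPhenotype

        inner = HIGH if rbrl else LOW
        return LesionPhenotype(
            lesion_id=1,
            volume_mm3=100.0,
            core_active_pct=0.0,
            rim_inner_active_pct=0.0,
            rim_inner_mean_dvr=1.5,
            rim_outer_mean_dvr=1.5,
            rim_inner_label=inner,
            rim_outer_label=inner,
            activity_class=activity,
            is_rbrl=rbrl,
        )

    def test_counts_and_proportion(self):
        phens = [self._phen(True, "rim_active")] * 2 + [self._phen(False, "inactive")] * 8
        s = summarize_patient(phens, "p1")
        assert s.n_lesions == 10 and s.n_rbrl == 2
        assert s.prop_rbrl == pytest.approx(0.2)
        assert s.has_rbrl is True

    def test_empty_patient(self):
        s = summarize_patient([], "p0")
        assert s.n_lesions == 0 and s.prop_rbrl == 0.0 and not s.has_rbrl

    def test_all_rbrl_proportion_is_one(self):
        s = summarize_patient([self._phen(True, "rim_active")] * 4)
        assert s.prop_rbrl == 1.0
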