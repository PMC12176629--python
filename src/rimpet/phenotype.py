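"""Rule-based TSPO-PET lesion phenotyping.

Each white-matter lesion larger than the inclusion volume is classified on
two independent axes:

* an **activity class** (inactive / rim-active / overall-active) from the
  percentage of active voxels (DVR strictly above the threshold) in the
  lesion core and in the 0-2 mm perilesional shell;
* a **radiological broad-rim-lesion (rBRL) flag**: both the 0-2 mm and the
  2-4 mm shells have mean DVR above the threshold (a HIGH-HIGH pattern).

The two taxonomies overlap by design: an rBRL may carry any activity class.
Equality with the threshold counts as LOW/inactive everywhere (strict ">").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import (
    CalibrationError,
    NumericDomainError,
    UndefinedFractionError,
)
from .io import LabelMap, PipelineConfig, Volume3D, array_checksum, check_same_grid
from .rims import concentric_shells, filter_by_volume, lesion_volumes

log = logging.getLogger("rimpet")

HIGH = "HIGH"
LOW = "LOW"

INACTIVE = "inactive"
RIM_ACTIVE = "rim_active"
OVERALL_ACTIVE = "overall_active"
ACTIVITY_CLASSES = (INACTIVE, RIM_ACTIVE, OVERALL_ACTIVE)


@dataclass
class ActivityThreshold:
    """DVR level above which a voxel counts as aberrantly active.

    Calibrated as healthy-control white-matter mean + 1 sample s.d.; the
    shipped default (1.3624) lets the pipeline run without control data.
    """

    value: float
    source: str = "configured"
    control_mean: float | None = None
    control_sd: float | None = None

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError(f"threshold must be positive, got {self.value}")
        if self.source not in ("configured", "calibrated"):
            raise ValueError(f"unknown threshold source {self.source!r}")
        if self.source == "calibrated":
            if self.control_mean is None or self.control_sd is None:
                raise ValueError("calibrated threshold requires control mean and sd")
            if not np.isclose(self.value, self.control_mean + self.control_sd):
                raise ValueError("calibrated value must equal control_mean + control_sd")


def default_threshold(config: PipelineConfig | None = None) -> ActivityThreshold:
    cfg = config or PipelineConfig()
    return ActivityThreshold(cfg.dvr_threshold, source="configured")


def calibrate_threshold(control_wm_dvr) -> ActivityThreshold:
    """Mean + 1 s.d. (n-1 denominator) of healthy-control WM voxel DVRs."""
    values = np.asarray(list(control_wm_dvr), dtype=float).ravel()
    if values.size < 2:
        raise CalibrationError(f"need >= 2 control values, got {values.size}")
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    return ActivityThreshold(mean + sd, "calibrated", mean, sd)


def active_fraction(
    dvr: Volume3D, region: np.ndarray, thr: ActivityThreshold
) -> float:
    """Percentage of region voxels with DVR strictly above the threshold."""
    region = np.asarray(region) > 0
    n = int(region.sum())
    if n == 0:
        raise UndefinedFractionError("active fraction over an empty region")
    return 100.0 * float((dvr.data[region] > thr.value).sum()) / n


def classify_activity(core_pct: float, rim_pct: float) -> str:
    """Assign the activity class from core and 0-2 mm rim active percentages.

    * inactive: 0% active voxels in both core and rim;
    * rim-active: either 5-20% active core voxels with the rim at least
      twice the core percentage, or < 5% active core voxels with the rim at
      least 5 percentage points above the core;
    * overall-active: everything else.
    """
    for name, v in (("core_pct", core_pct), ("rim_pct", rim_pct)):
        if not (0.0 <= v <= 100.0):
            raise NumericDomainError(f"{name} must be in [0, 100], got {v}")
    if core_pct == 0.0 and rim_pct == 0.0:
        return INACTIVE
    if 5.0 <= core_pct <= 20.0 and rim_pct >= 2.0 * core_pct:
        return RIM_ACTIVE
    if core_pct < 5.0 and rim_pct >= core_pct + 5.0:
        return RIM_ACTIVE
    return OVERALL_ACTIVE


def classify_rim_level(
    dvr: Volume3D, shell: np.ndarray, thr: ActivityThreshold
) -> str:
    """HIGH iff the mean DVR over the shell strictly exceeds the threshold."""
    shell = np.asarray(shell) > 0
    if not shell.any():
        log.warning("classify_rim_level: empty shell (lesion at domain edge) -> LOW")
        return LOW
    return HIGH if float(dvr.data[shell].mean()) > thr.value else LOW


def classify_rbrl(inner_label: str, outer_label: str) -> bool:
    """rBRL iff both 2-mm shells are HIGH (the HIGH-HIGH pattern)."""
    for lab in (inner_label, outer_label):
        if lab not in (HIGH, LOW):
            raise ValueError(f"rim label must be HIGH or LOW, got {lab!r}")
    return inner_label == HIGH and outer_label == HIGH


@dataclass
class LesionPhenotype:
    """Per-lesion phenotyping record."""

    lesion_id: int
    volume_mm3: float
    core_active_pct: float
    rim_inner_active_pct: float
    rim_inner_mean_dvr: float
    rim_outer_mean_dvr: float
    rim_inner_label: str
    rim_outer_label: str
    activity_class: str
    is_rbrl: bool

    def __post_init__(self) -> None:
        for name in ("core_active_pct", "rim_inner_active_pct"):
            v = getattr(self, name)
            if not (0.0 <= v <= 100.0):
                raise ValueError(f"{name} out of [0, 100]: {v}")
        if self.activity_class not in ACTIVITY_CLASSES:
            raise ValueError(f"unknown activity class {self.activity_class!r}")
        if self.is_rbrl != (self.rim_inner_label == HIGH and self.rim_outer_label == HIGH):
            raise ValueError("is_rbrl inconsistent with rim labels")


@dataclass
class PatientPhenotypeSummary:
    """Per-patient roll-up of lesion phenotypes."""

    patient_id: str
    n_lesions: int
    n_rbrl: int
    prop_rbrl: float
    n_rim_active: int
    n_inactive: int
    n_overall_active: int
    has_rbrl: bool

    def __post_init__(self) -> None:
        if self.n_inactive + self.n_rim_active + self.n_overall_active != self.n_lesions:
            raise ValueError("activity-class counts must sum to n_lesions")


def phenotype_lesions(
    dvr: Volume3D,
    labels: LabelMap,
    domain: Volume3D | np.ndarray | None = None,
    config: PipelineConfig | None = None,
    threshold: ActivityThreshold | None = None,
) -> list[LesionPhenotype]:
    """Run the full per-lesion phenotyping pipeline.

    Applies the volume filter, builds concentric shells, computes active
    fractions (core and 0-2 mm shell), the activity class, HIGH/LOW labels
    of both shells, and the rBRL flag.  Deterministic given inputs.
    """
    cfg = config or PipelineConfig()
    thr = threshold or default_threshold(cfg)
    check_same_grid(dvr, labels, "phenotype_lesions")
    log.debug(
        "phenotype_lesions: config=%s dvr=%s labels=%s thr=%.4f",
        cfg.hash(), array_checksum(dvr.data), array_checksum(labels.labels), thr.value,
    )
    kept = filter_by_volume(labels, cfg.min_lesion_volume)
    vols = lesion_volumes(kept)
    out: list[LesionPhenotype] = []
    for lesion_id in kept.lesion_ids:
        shells = concentric_shells(kept, lesion_id, cfg.shell_step, cfg.shell_max, domain)
        core_pct = active_fraction(dvr, shells.core, thr)
        if shells.shell_inner.any():
            rim_pct = active_fraction(dvr, shells.shell_inner, thr)
            inner_mean = float(dvr.data[shells.shell_inner].mean())
        else:  # lesion fills the domain: no rim tissue at all
            rim_pct = 0.0
            inner_mean = float("nan")
        outer_mean = (
            float(dvr.data[shells.shell_outer].mean())
            if shells.shell_outer.any()
            else float("nan")
        )
        inner_label = classify_rim_level(dvr, shells.shell_inner, thr)
        outer_label = classify_rim_level(dvr, shells.shell_outer, thr)
        rec = LesionPhenotype(
            lesion_id=lesion_id,
            volume_mm3=vols[lesion_id],
            core_active_pct=core_pct,
            rim_inner_active_pct=rim_pct,
            rim_inner_mean_dvr=inner_mean,
            rim_outer_mean_dvr=outer_mean,
            rim_inner_label=inner_label,
            rim_outer_label=outer_label,
            activity_class=classify_activity(core_pct, rim_pct),
            is_rbrl=classify_rbrl(inner_label, outer_label),
        )
        log.debug("lesion %d: vol=%.1f core%%=%.1f rim%%=%.1f labels=%s/%s class=%s rbrl=%s",
                  lesion_id, rec.volume_mm3, core_pct, rim_pct,
                  inner_label, outer_label, rec.activity_class, rec.is_rbrl)
        out.append(rec)
    return out


def summarize_patient(
    phenotypes: list[LesionPhenotype], patient_id: str = ""
) -> PatientPhenotypeSummary:
    """Roll per-lesion phenotypes up to patient-level counts."""
    n = len(phenotypes)
    n_rbrl = sum(p.is_rbrl for p in phenotypes)
    return PatientPhenotypeSummary(
        patient_id=patient_id,
        n_lesions=n,
        n_rbrl=n_rbrl,
        prop_rbrl=(n_rbrl / n) if n else 0.0,
        n_rim_active=sum(p.activity_class == RIM_ACTIVE for p in phenotypes),
        n_inactive=sum(p.activity_class == INACTIVE for p in phenotypes),
        n_overall_active=sum(p.activity_class == OVERALL_ACTIVE for p in phenotypes),
        has_rbrl=n_rbrl >= 1,
    )
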