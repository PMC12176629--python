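"""Synthetic inputs with known ground truth for every pipeline stage.

Four generators cover the pipeline end to end:

* reference-tissue kinetics: a gamma-variate reference TAC and a
  simplified-reference-tissue-model (SRTM) forward simulation of target
  TACs with known BP_ND, so Logan DVR recovery can be checked against
  DVR = BP_ND + 1;
* 3D DVR phantoms: spherical/ellipsoidal lesions with configurable core
  and rim activity painted by *continuous* Euclidean distance from the
  lesion surface — an oracle geometry independent of the pipeline's voxel
  distance transform;
* 2D histology phantoms: circular lesions with annular myeloid rims of
  exact width plus Poisson cell point processes per compartment;
* cohorts: patients with rBRL status and EDSS trajectories in which rBRL
  shifts the odds of fast progression by a planted odds ratio.

Every generator is a pure function of its spec (including the seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .cohort import DAYS_PER_YEAR, EdssTimeline, PatientRecord
from .histology import Contour2D, SECTION_CLASSES, SectionImage2D
from .io import LabelMap, PipelineConfig, Volume3D
from .kinetics import TimeActivityCurve
from .phenotype import HIGH, LOW, PatientPhenotypeSummary

# ---------------------------------------------------------------------------
# Kinetics


def default_frame_schedule() -> tuple[np.ndarray, np.ndarray]:
    """A 60-min dynamic framing: 6x30s, 4x1min, 4x2min, 3x5min, 3x10min.

    Returns (frame mid-times, frame durations) in minutes; five frames have
    mid-times beyond the default 20-min linearisation start.
    """
    durations = np.array([0.5] * 6 + [1.0] * 4 + [2.0] * 4 + [5.0] * 3 + [10.0] * 3)
    ends = np.cumsum(durations)
    mids = ends - durations / 2.0
    return mids, durations


def gamma_variate(t, amplitude: float = 10.0, t_peak: float = 8.0, alpha: float = 2.0):
    """Gamma-variate bolus curve peaking at `t_peak` minutes.

    ``A * (t/tp)^alpha * exp(alpha * (1 - t/tp))`` — the conventional
    tracer-arrival shape; 0 at t = 0, single peak of height `amplitude`.
    """
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    r = t[pos] / t_peak
    out[pos] = amplitude * r**alpha * np.exp(alpha * (1.0 - r))
    return out


def simulate_reference_tac(times=None, amplitude: float = 10.0,
                           t_peak: float = 8.0, alpha: float = 2.0) -> TimeActivityCurve:
    """Reference-region TAC on a frame grid (gamma-variate shape)."""
    if times is None:
        times, _ = default_frame_schedule()
    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("frame grid must be strictly increasing")
    return TimeActivityCurve(times, gamma_variate(times, amplitude, t_peak, alpha))


@dataclass
class SrtmSpec:
    """SRTM forward-model parameters: target = f(reference; R1, k2, BP_ND)."""

    r1: float = 1.0
    k2: float = 0.1  # /min
    bp_nd: float = 0.5
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k2 <= 0:
            raise ValueError("k2 must be positive")
        if self.bp_nd < 0:
            raise ValueError("BP_ND must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def k2a(self) -> float:
        return self.k2 / (1.0 + self.bp_nd)

    @property
    def dvr(self) -> float:
        return 1.0 + self.bp_nd


def simulate_srtm_tac(ref: TimeActivityCurve, spec: SrtmSpec,
                      fine_dt: float = 0.01) -> TimeActivityCurve:
    """Forward-simulate a target TAC from the SRTM operational equation.

    ``C_T(t) = R1 C_ref(t) + (k2 - R1 k2a) [C_ref (x) exp(-k2a t)](t)``
    with ``k2a = k2 / (1 + BP_ND)``.  The convolution runs on a fine
    internal grid (`fine_dt` <= 0.1 min) with the reference linearly
    interpolated (0 at t = 0), then is sampled back at the frame times.
    """
    if fine_dt > 0.1:
        raise ValueError("fine_dt must be <= 0.1 min")
    t_end = float(ref.times[-1])
    tf = np.arange(0.0, t_end + fine_dt / 2, fine_dt)
    cref_f = np.interp(tf, np.concatenate([[0.0], ref.times]),
                       np.concatenate([[0.0], ref.activity]))
    k2a = spec.k2a
    # exact exponential-decay recursion with trapezoidal source term
    decay = np.exp(-k2a * fine_dt)
    conv = np.zeros_like(tf)
    for i in range(1, len(tf)):
        conv[i] = conv[i - 1] * decay + fine_dt * 0.5 * (cref_f[i] + cref_f[i - 1] * decay)
    ct_f = spec.r1 * cref_f + (spec.k2 - spec.r1 * k2a) * conv
    ct = np.interp(ref.times, tf, ct_f)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        ct = ct + rng.normal(0.0, spec.noise_sd, size=ct.shape)
    return TimeActivityCurve(ref.times, ct)


# ---------------------------------------------------------------------------
# 3D DVR phantoms


@dataclass
class PhantomLesion:
    """One painted lesion: centre/radii in mm plus core and rim DVR levels."""

    center_mm: tuple[float, float, float]
    radii_mm: tuple[float, float, float]
    core_dvr: float = 1.2
    inner_rim_dvr: float = 1.6
    outer_rim_dvr: float = 1.6

    def __post_init__(self) -> None:
        if isinstance(self.radii_mm, (int, float)):
            self.radii_mm = (float(self.radii_mm),) * 3
        self.radii_mm = tuple(float(r) for r in self.radii_mm)
        self.center_mm = tuple(float(c) for c in self.center_mm)
        if any(r <= 0 for r in self.radii_mm):
            raise ValueError("lesion radii must be positive")


@dataclass
class PhantomSpec:
    """A DVR phantom: grid geometry, background level, lesions, noise."""

    shape: tuple[int, int, int] = (32, 32, 32)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    background_dvr: float = 1.0
    lesions: list[PhantomLesion] = field(default_factory=list)
    noise_sd: float = 0.0
    rim_step_mm: float = 2.0
    rim_max_mm: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        extent = [n * s for n, s in zip(self.shape, self.spacing)]
        for les in self.lesions:
            for c, r, e in zip(les.center_mm, les.radii_mm, extent):
                if c - r < 0 or c + r > e:
                    raise ValueError(f"lesion at {les.center_mm} extends beyond the grid")


def _surface_distance_mm(spec: PhantomSpec, lesion: PhantomLesion) -> np.ndarray:
    """Signed continuous Euclidean distance (mm) of every voxel centre from
    the lesion surface: negative inside, positive outside.

    Spheres are handled in closed form; for true ellipsoids the exterior
    distance solves the point-to-ellipsoid projection by bisection.
    """
    grids = np.meshgrid(
        *[(np.arange(n) + 0.5) * s for n, s in zip(spec.shape, spec.spacing)],
        indexing="ij",
    )
    p = np.stack([g - c for g, c in zip(grids, lesion.center_mm)])
    a = np.array(lesion.radii_mm)
    if np.allclose(a, a[0]):  # sphere: exact signed distance
        return np.sqrt((p**2).sum(axis=0)) - a[0]
    level = ((p / a[:, None, None, None]) ** 2).sum(axis=0)
    inside = level <= 1.0
    # exterior: solve sum_i (a_i p_i / (a_i^2 + t))^2 = 1 for t >= 0
    flat = p.reshape(3, -1)
    out_idx = ~inside.ravel()
    q = flat[:, out_idx]
    lo = np.zeros(q.shape[1])
    hi = np.full(q.shape[1], a.max() * (np.sqrt((q**2).sum(axis=0)).max() + a.max()))
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        f = ((a[:, None] * q / (a[:, None] ** 2 + mid)) ** 2).sum(axis=0)
        lo = np.where(f > 1.0, mid, lo)
        hi = np.where(f > 1.0, hi, mid)
    t = 0.5 * (lo + hi)
    closest = (a[:, None] ** 2) * q / (a[:, None] ** 2 + t)
    d_out = np.sqrt(((q - closest) ** 2).sum(axis=0))
    dist = np.full(spec.shape, -1.0).ravel()  # interior depth is not needed
    dist[out_idx] = d_out
    return dist.reshape(spec.shape)


#: Forced activity class for pure 0/100 active-voxel fractions
#: (core active?, rim active?) -> class.
_FORCED_CLASS = {
    (False, False): "inactive",
    (False, True): "rim_active",
    (True, False): "overall_active",
    (True, True): "overall_active",
}


def generate_phantom(
    spec: PhantomSpec, threshold: float | None = None
) -> tuple[Volume3D, LabelMap, pd.DataFrame]:
    """Paint a DVR phantom and derive the analytically forced ground truth.

    Voxels are painted by continuous distance from each lesion surface:
    core inside, `inner_rim_dvr` in (0, rim_step] mm, `outer_rim_dvr` in
    (rim_step, rim_max] mm, background beyond.  The ground-truth table
    lists each lesion's forced HIGH/LOW labels, activity class and rBRL
    flag implied by the painted levels and the activity threshold; lesions
    whose painted bands overlap another lesion are flagged `overlap`.
    """
    thr = PipelineConfig().dvr_threshold if threshold is None else float(threshold)
    dvr = np.full(spec.shape, spec.background_dvr, dtype=float)
    labels = np.zeros(spec.shape, dtype=np.uint16)
    painted = np.zeros(spec.shape, dtype=bool)
    rows = []
    for lesion_id, les in enumerate(spec.lesions, start=1):
        d = _surface_distance_mm(spec, les)
        core = d <= 0
        band1 = (d > 0) & (d <= spec.rim_step_mm)
        band2 = (d > spec.rim_step_mm) & (d <= spec.rim_max_mm)
        overlap = bool((painted & (core | band1 | band2)).any())
        dvr[core] = les.core_dvr
        dvr[band1] = les.inner_rim_dvr
        dvr[band2] = les.outer_rim_dvr
        labels[core] = lesion_id
        painted |= core | band1 | band2
        inner_label = HIGH if les.inner_rim_dvr > thr else LOW
        outer_label = HIGH if les.outer_rim_dvr > thr else LOW
        core_active = les.core_dvr > thr
        rim_active = les.inner_rim_dvr > thr
        # The activity class is analytically forced unless the 2-mm line is
        # an inactive-to-active transition with an inactive core: there the
        # exact-0% rule depends on sub-voxel geometry and no class is forced.
        activity_forced = not (
            not core_active and not rim_active and les.outer_rim_dvr > thr
        )
        voxvol = float(np.prod(spec.spacing))
        rows.append(
            {
                "lesion_id": lesion_id,
                "volume_mm3": float(core.sum()) * voxvol,
                "rim_inner_label": inner_label,
                "rim_outer_label": outer_label,
                "activity_class": _FORCED_CLASS[(core_active, rim_active)],
                "activity_forced": activity_forced,
                "is_rbrl": inner_label == HIGH and outer_label == HIGH,
                "overlap": overlap,
            }
        )
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        dvr = dvr + rng.normal(0.0, spec.noise_sd, size=dvr.shape)
    return (
        Volume3D(dvr, spec.spacing),
        LabelMap(labels, spec.spacing),
        pd.DataFrame(rows),
    )


def random_phantom_spec(seed: int, dvr_levels=(1.2, 1.6)) -> PhantomSpec:
    """A single-lesion phantom with randomly drawn rim pattern.

    The lesion radius is drawn in [2.5, 5] mm (always above the 50 mm^3
    inclusion volume) and the core/rim DVR levels are drawn from
    `dvr_levels` = (LOW, HIGH), which straddle the default 1.3624 threshold
    with >= 0.15 margin so voxelisation cannot flip a forced label.
    """
    rng = np.random.default_rng(seed)
    low, high = dvr_levels
    radius = float(rng.uniform(2.5, 5.0))
    shape = (int(2 * (radius + 6)) + 1,) * 3
    center = tuple((n * 1.0) / 2 for n in shape)
    core_hi, inner_hi, outer_hi = (bool(b) for b in rng.integers(0, 2, size=3))
    if not core_hi and not inner_hi and outer_hi:
        # the only pattern whose activity class is not analytically forced
        # at voxel resolution (see generate_phantom); keep the LOW-HIGH rim
        # pattern but give it an active core so every label stays forced
        core_hi = True
    lesion = PhantomLesion(
        center_mm=center,
        radii_mm=radius,
        core_dvr=high if core_hi else low,
        inner_rim_dvr=high if inner_hi else low,
        outer_rim_dvr=high if outer_hi else low,
    )
    return PhantomSpec(shape=shape, spacing=(1.0, 1.0, 1.0), lesions=[lesion], seed=seed)


# ---------------------------------------------------------------------------
# 2D histology phantoms


def _circle_contour(radius: float, center=(0.0, 0.0), n_vertices: int = 360) -> Contour2D:
    theta = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
    pts = np.column_stack(
        [center[0] + radius * np.cos(theta), center[1] + radius * np.sin(theta)]
    )
    return Contour2D(pts)


def generate_histology_phantom(
    rim_width: float = 1500.0,
    lesion_radius: float = 4000.0,
    densities: dict | None = None,
    pixel_size: float = 20.0,
    margin: float = 2000.0,
    seed: int = 0,
) -> tuple[SectionImage2D, dict, np.ndarray, dict]:
    """A circular lesion with an annular myeloid rim of exact width.

    Parameters are in um.  The outer contour is the myeloid-rim outer edge
    (radius `lesion_radius`), the inner contour the myelin edge
    (radius `lesion_radius - rim_width`).  `densities` maps compartments
    ("center", "rim", "NAWM") to cell densities per mm^2; cells are
    homogeneous Poisson point processes.

    Returns (section image, contours dict, cell points (n, 2) um, ground truth).
    """
    if not (0.0 < rim_width < lesion_radius):
        raise ValueError("require 0 < rim_width < lesion_radius")
    densities = densities or {"center": 300.0, "rim": 1200.0, "NAWM": 400.0}
    rng = np.random.default_rng(seed)
    extent = 2 * (lesion_radius + margin)
    n_pix = int(np.ceil(extent / pixel_size))
    cx = cy = extent / 2.0
    yy, xx = np.meshgrid(
        (np.arange(n_pix) + 0.5) * pixel_size,
        (np.arange(n_pix) + 0.5) * pixel_size,
        indexing="ij",
    )
    r = np.hypot(xx - cx, yy - cy)
    r_inner = lesion_radius - rim_width
    labels = np.full((n_pix, n_pix), SECTION_CLASSES["NAWM"], dtype=np.uint8)
    labels[r <= lesion_radius] = SECTION_CLASSES["myeloid_rim"]
    labels[r <= r_inner] = SECTION_CLASSES["lesion_core"]
    section = SectionImage2D(labels, pixel_size)

    contours = {
        "outer": _circle_contour(lesion_radius, (cx, cy)),
        "inner": _circle_contour(r_inner, (cx, cy)),
    }

    um2_per_mm2 = 1e6
    areas = {
        "center": np.pi * r_inner**2 / um2_per_mm2,
        "rim": np.pi * (lesion_radius**2 - r_inner**2) / um2_per_mm2,
        "NAWM": (extent**2 - np.pi * lesion_radius**2) / um2_per_mm2,
    }
    points = []
    for comp, lam in densities.items():
        n = rng.poisson(lam * areas[comp])
        got = 0
        while got < n:  # rejection sampling within the compartment
            cand = rng.uniform(0.0, extent, size=(max(4 * (n - got), 16), 2))
            rc = np.hypot(cand[:, 0] - cx, cand[:, 1] - cy)
            if comp == "center":
                keep = rc <= r_inner
            elif comp == "rim":
                keep = (rc > r_inner) & (rc <= lesion_radius)
            else:
                keep = rc > lesion_radius
            sel = cand[keep][: n - got]
            points.append(sel)
            got += len(sel)
    pts = np.vstack(points) if points else np.empty((0, 2))
    truth = {
        "rim_width": rim_width,
        "lesion_radius": lesion_radius,
        "densities": dict(densities),
        "center_um": (cx, cy),
    }
    return section, contours, pts, truth


# ---------------------------------------------------------------------------
# Cohorts with a planted rBRL -> fast-progression effect


@dataclass
class CohortSpec:
    """A synthetic natural-history cohort.

    `prob_rbrl` is the fraction of patients carrying at least one rBRL
    (default 0.342, a realistic prevalence for a progressive-MS cohort);
    `odds_ratio_fast_given_rbrl` multiplies the odds of fast progression
    (reaching EDSS 4 within `horizon_years` of onset) for rBRL carriers
    relative to the baseline probability `prob_fast_baseline`.
    """

    n_patients: int = 100
    prob_rbrl: float = 0.342
    prob_rim_active_given_no_rbrl: float = 0.5
    prob_fast_baseline: float = 0.25
    odds_ratio_fast_given_rbrl: float = 5.0
    edss_noise: float = 0.5
    assessment_interval_months: float = 6.0
    horizon_years: float = 12.0
    followup_years: float = 16.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("prob_rbrl", "prob_rim_active_given_no_rbrl", "prob_fast_baseline"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.odds_ratio_fast_given_rbrl <= 0:
            raise ValueError("odds ratio must be positive")

    @property
    def prob_fast_rbrl(self) -> float:
        odds0 = self.prob_fast_baseline / (1.0 - self.prob_fast_baseline)
        odds1 = self.odds_ratio_fast_given_rbrl * odds0
        return odds1 / (1.0 + odds1)


def _half_step(x: float) -> float:
    return round(x * 2.0) / 2.0


def _make_phenotype(pid: str, category: str, rng) -> PatientPhenotypeSummary:
    n_lesions = int(rng.integers(3, 15))
    n_rbrl = int(rng.integers(1, 4)) if category == "rbrl" else 0
    n_rbrl = min(n_rbrl, n_lesions)
    if category == "rim_active":
        n_rim = int(rng.integers(1, n_lesions + 1))
    elif category == "neither":
        n_rim = 0
    else:
        n_rim = int(rng.integers(0, n_lesions + 1))
    n_inact = int(rng.integers(0, n_lesions - n_rim + 1))
    return PatientPhenotypeSummary(
        patient_id=pid,
        n_lesions=n_lesions,
        n_rbrl=n_rbrl,
        prop_rbrl=n_rbrl / n_lesions,
        n_rim_active=n_rim,
        n_inactive=n_inact,
        n_overall_active=n_lesions - n_rim - n_inact,
        has_rbrl=n_rbrl >= 1,
    )


def _edss_trajectory(kind: str, times_years: np.ndarray, rng,
                     horizon_years: float, noise: float) -> np.ndarray:
    """Monotone-plus-noise EDSS step curve consistent with the drawn status.

    fast: reaches EDSS >= 4 strictly within the horizon, then keeps rising;
    slow: stays below 2 throughout; intermediate: climbs slowly, ending
    between 2 and 3.5 without touching 4 inside the horizon.
    """
    t_end = times_years[-1]
    if kind == "fast":
        t_mile = rng.uniform(0.5 * horizon_years, 0.92 * horizon_years)
        base = 1.0 + 3.0 * np.minimum(times_years / t_mile, 1.0)
        base = base + 2.0 * np.maximum(times_years - t_mile, 0.0) / max(t_end - t_mile, 1.0)
    elif kind == "slow":
        base = 1.0 + 0.5 * times_years / t_end
    else:
        base = 1.0 + 2.2 * times_years / t_end
    jitter = rng.normal(0.0, noise * 0.3, size=base.shape)
    edss = np.maximum.accumulate(base + jitter)
    edss = np.array([_half_step(v) for v in edss])
    if kind == "fast":  # guarantee the milestone inside the horizon
        idx = np.searchsorted(times_years, t_mile)
        idx = min(idx, len(edss) - 1)
        edss[idx:] = np.maximum(edss[idx:], 4.0)
        pre = times_years < t_mile
        edss[pre] = np.minimum(edss[pre], 3.5)
    elif kind == "slow":
        edss = np.minimum(edss, 1.5)
    else:
        inside = times_years <= horizon_years
        edss[inside] = np.minimum(edss[inside], 3.5)
        edss = np.minimum(edss, 3.5)
        edss[-1] = max(edss[-1], 2.0)  # ends above the slow ceiling
    edss = np.maximum.accumulate(edss)
    return np.clip(edss, 1.0, 9.5)


def generate_cohort(spec: CohortSpec) -> list[PatientRecord]:
    """Draw a cohort with the planted rBRL -> fast-progression effect."""
    rng = np.random.default_rng(spec.seed)
    onset = date(2000, 1, 1)
    step_days = spec.assessment_interval_months * DAYS_PER_YEAR / 12.0
    n_visits = int(spec.followup_years * DAYS_PER_YEAR / step_days) + 1
    times_years = np.arange(n_visits) * step_days / DAYS_PER_YEAR
    records = []
    for i in range(spec.n_patients):
        pid = f"P{i:04d}"
        if rng.random() < spec.prob_rbrl:
            category = "rbrl"
            p_fast = spec.prob_fast_rbrl
        else:
            category = (
                "rim_active"
                if rng.random() < spec.prob_rim_active_given_no_rbrl
                else "neither"
            )
            p_fast = spec.prob_fast_baseline
        fast = rng.random() < p_fast
        kind = "fast" if fast else ("slow" if rng.random() < 0.5 else "intermediate")
        edss = _edss_trajectory(kind, times_years, rng, spec.horizon_years, spec.edss_noise)
        assessments = [
            (onset + timedelta(days=float(k * step_days)), float(e))
            for k, e in enumerate(edss)
        ]
        timeline = EdssTimeline(
            assessments=assessments,
            onset_date=onset,
            imaging_date=onset + timedelta(days=5 * DAYS_PER_YEAR),
        )
        records.append(
            PatientRecord(pid, timeline, _make_phenotype(pid, category, rng))
        )
    return records
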