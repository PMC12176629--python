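"""Reference-region Logan graphical analysis for DVR quantification.

The distribution volume ratio (DVR) of a reversibly bound tracer is
estimated from the late-time slope of

    int_0^t C_T dtau / C_T(t)  versus  int_0^t C_ref dtau / C_T(t)

where ``C_T`` is the target and ``C_ref`` the reference-region
time-activity curve.  The full operational equation adds a
``C_ref/(k2' C_T)`` term to the abscissa, where ``k2'`` is the reference
efflux rate; when ``k2'`` is unknown (the usual clinical situation) the
term is omitted, which biases the slope downward for slowly equilibrating
(high-binding) regions.  The slope over samples with ``t >= t_star`` is
reported as DVR.
Integrals are trapezoidal from t = 0 (activity taken as 0 at t = 0 when
the first sample is later), the standard graphical-analysis convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .errors import FitError, GridCompatibilityError, NumericDomainError
from .io import DynamicPET4D, LabelMap, Volume3D

log = logging.getLogger("rimpet")


@dataclass
class TimeActivityCurve:
    """Tracer activity sampled over the acquisition.

    times are minutes (strictly increasing, starting >= 0); activity is in
    any consistent concentration unit.
    """

    times: np.ndarray
    activity: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.activity = np.asarray(self.activity, dtype=float)
        if self.times.shape != self.activity.shape or self.times.ndim != 1:
            raise ValueError("times and activity must be equal-length 1D arrays")
        if len(self.times) and self.times[0] < 0:
            raise ValueError("times must start at or after 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.activity)):
            raise ValueError("activity must be finite")

    def __len__(self) -> int:
        return len(self.times)

    def scaled(self, k: float) -> "TimeActivityCurve":
        return TimeActivityCurve(self.times, k * self.activity)


@dataclass
class LoganFit:
    """Result of a Logan reference fit: slope (DVR), intercept, fit quality."""

    dvr: float
    intercept: float
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise FitError(f"Logan fit needs >= 3 points, got {self.n_points}")
        if not np.isfinite(self.dvr):
            raise FitError("Logan slope is not finite")


def _integral_from_zero(times: np.ndarray, activity: np.ndarray) -> np.ndarray:
    """Cumulative trapezoid of activity over time, anchored at (0, 0)."""
    if times[0] > 0:
        t = np.concatenate([[0.0], times])
        a = np.concatenate([[0.0], activity])
        return cumulative_trapezoid(a, t, initial=0.0)[1:]
    return cumulative_trapezoid(activity, times, initial=0.0)


def logan_reference_dvr(
    target: TimeActivityCurve,
    reference: TimeActivityCurve,
    t_star: float = 20.0,
    k2_ref: float | None = None,
) -> LoganFit:
    """Estimate DVR of `target` relative to `reference` by the Logan plot.

    Parameters
    ----------
    target, reference : TimeActivityCurve
        Must share the same time grid.
    t_star : float
        Start of the linear segment in minutes; only samples with
        ``t >= t_star`` enter the regression.
    k2_ref : float, optional
        Reference-region efflux rate k2' (/min).  When given, the
        ``C_ref/(k2' C_T)`` term of the operational equation is included,
        removing the high-binding underestimation bias; when None the term
        is omitted (no k2' is available for clinical data).

    Returns
    -------
    LoganFit
        Slope (DVR), intercept (minutes), R^2 and number of fitted points.
    """
    if len(target) != len(reference) or not np.allclose(target.times, reference.times):
        raise ValueError("target and reference must share the same time grid")
    sel = target.times >= t_star
    if int(sel.sum()) < 3:
        raise FitError(
            f"only {int(sel.sum())} samples at t >= {t_star} min; need >= 3"
        )
    ct_sel = target.activity[sel]
    if np.any(ct_sel <= 0):
        raise NumericDomainError(
            "target activity must be strictly positive for t >= t_star"
        )
    int_ct = _integral_from_zero(target.times, target.activity)[sel]
    int_cref = _integral_from_zero(reference.times, reference.activity)[sel]
    x = int_cref / ct_sel
    if k2_ref is not None:
        if k2_ref <= 0:
            raise NumericDomainError("k2_ref must be positive")
        x = x + reference.activity[sel] / (k2_ref * ct_sel)
    y = int_ct / ct_sel
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - np.sum(resid**2) / ss_tot)
    return LoganFit(float(slope), float(intercept), float(min(r2, 1.0)), int(sel.sum()))


def parametric_dvr_map(
    dyn: DynamicPET4D,
    reference: TimeActivityCurve,
    mask: LabelMap | Volume3D | np.ndarray,
    t_star: float = 20.0,
) -> Volume3D:
    """Voxelwise Logan DVR inside `mask`; NaN sentinel elsewhere.

    Voxels whose TAC is non-positive anywhere at ``t >= t_star`` get the
    NaN sentinel rather than aborting the map (air/CSF robustness).
    The regression is vectorised over voxels.
    """
    if isinstance(mask, LabelMap):
        from .io import check_same_grid

        check_same_grid(mask, dyn.spatial_grid(), "parametric_dvr_map")
        mask_arr = mask.as_binary()
    elif isinstance(mask, Volume3D):
        if mask.shape != dyn.frames.shape[:3] or not np.allclose(mask.spacing, dyn.spacing):
            raise GridCompatibilityError("mask grid does not match dynamic grid")
        mask_arr = mask.data > 0
    else:
        mask_arr = np.asarray(mask) > 0
        if mask_arr.shape != dyn.frames.shape[:3]:
            raise GridCompatibilityError("mask shape does not match dynamic grid")
    times = dyn.frame_mid_times
    if not np.allclose(times, reference.times):
        raise ValueError("dynamic frame mid-times must match the reference TAC grid")
    out = np.full(dyn.frames.shape[:3], np.nan, dtype=float)
    if not mask_arr.any():
        return Volume3D(out, dyn.spacing, dyn.origin)

    sel = times >= t_star
    if int(sel.sum()) < 3:
        raise FitError(f"only {int(sel.sum())} frames at t >= {t_star} min; need >= 3")
    tacs = dyn.frames[mask_arr]  # (n_voxels, n_frames)
    # integrals anchored at (0, 0)
    if times[0] > 0:
        t_full = np.concatenate([[0.0], times])
        tac_full = np.concatenate([np.zeros((tacs.shape[0], 1)), tacs], axis=1)
    else:
        t_full, tac_full = times, tacs
    int_ct = cumulative_trapezoid(tac_full, t_full, axis=1, initial=0.0)
    int_ct = int_ct[:, -int(sel.sum()):] if times[0] > 0 else int_ct[:, sel]
    int_cref = _integral_from_zero(times, reference.activity)[sel]

    ct_sel = tacs[:, sel]
    usable = np.all(ct_sel > 0, axis=1)
    x = np.where(ct_sel > 0, int_cref[None, :] / np.where(ct_sel > 0, ct_sel, 1.0), 0.0)
    y = np.where(ct_sel > 0, int_ct / np.where(ct_sel > 0, ct_sel, 1.0), 0.0)
    n = x.shape[1]
    sx, sy = x.sum(axis=1), y.sum(axis=1)
    sxx, sxy = (x * x).sum(axis=1), (x * y).sum(axis=1)
    denom = sxx - sx * sx / n
    good = usable & (np.abs(denom) > 1e-12)
    slope = np.full(tacs.shape[0], np.nan)
    slope[good] = (sxy[good] - sx[good] * sy[good] / n) / denom[good]
    out[mask_arr] = slope
    n_bad = int((~good).sum())
    if n_bad:
        log.debug("parametric_dvr_map: %d voxels set to sentinel (non-positive TAC)", n_bad)
    return Volume3D(out, dyn.spacing, dyn.origin)


def bp_to_dvr(bp_map: Volume3D) -> Volume3D:
    """Convert a binding-potential map to DVR via DVR = BP_ND + 1."""
    return bp_map.like(bp_map.data + 1.0)
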