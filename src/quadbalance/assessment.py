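"""Comparison metrics: force fits, tuning-curve metrics, dimensionality,
normalized control effort.

Horizontal and vertical force components are assessed separately because
vertical magnitudes are several times larger.  Horizontal-force direction
residuals are wrapped to (-180, 180] before squaring.  Dimensionality
uses the Kaiser criterion: the number of eigenvalues of the muscle
correlation matrix at or above 1.0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

log = logging.getLogger(__name__)


def cosine_tuning(directions_deg: np.ndarray, peak_deg: float,
                  halfwidth_deg: float, amplitude: float) -> np.ndarray:
    """Rectified-cosine tuning curve with a given full width at half max.

    The canonical directional-tuning model: activation peaks at
    ``peak_deg`` and falls to half maximum ``halfwidth_deg/2`` away.
    """
    k = 60.0 / (halfwidth_deg / 2.0)  # cos(k*delta) = 0.5 at delta = halfwidth/2
    delta = np.deg2rad(np.asarray(directions_deg, dtype=float) - peak_deg)
    return amplitude * np.clip(np.cos(np.minimum(np.abs(k * delta), np.pi)), 0.0, None)


def fit_cosine_peak(directions_deg: np.ndarray, values: np.ndarray) -> float:
    """Peak direction (deg) of a noisy tuning curve by template fitting.

    Fits peak, half-maximum width and amplitude of the rectified-cosine
    model in least squares, initialised at the argmax bin.
    """
    dirs = np.asarray(directions_deg, dtype=float)
    v = np.asarray(values, dtype=float)
    peak0 = float(dirs[np.argmax(v)])

    def resid(p):
        return cosine_tuning(dirs, p[0], p[1], p[2]) - v

    sol = least_squares(resid, [peak0, 105.0, max(float(v.max()), 1e-6)],
                        bounds=([peak0 - 60.0, 60.0, 0.0],
                                [peak0 + 60.0, 150.0, 10.0 * max(float(v.max()), 1e-6)]))
    return float(sol.x[0]) % 360.0


def wrap_angle_deg(a: np.ndarray) -> np.ndarray:
    """Wrap angles (deg) to (-180, 180]."""
    return -((-np.asarray(a, dtype=float) + 180.0) % 360.0 - 180.0)


def r_squared(observed: np.ndarray, predicted: np.ndarray,
              circular: bool = False) -> float:
    """Coefficient of determination 1 - SSres/SStot across directions.

    With ``circular=True`` residuals (and deviations from the circular-
    aware mean) are wrapped to (-180, 180] degrees.  A zero-variance
    observed series has no defined R^2 and returns NaN.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted series must align")
    if circular:
        resid = wrap_angle_deg(pred - obs)
        mean = np.degrees(np.arctan2(np.mean(np.sin(np.radians(obs))),
                                     np.mean(np.cos(np.radians(obs)))))
        dev = wrap_angle_deg(obs - mean)
    else:
        resid = pred - obs
        dev = obs - obs.mean()
    ss_tot = float(dev @ dev)
    if ss_tot == 0.0:
        return np.nan
    return 1.0 - float(resid @ resid) / ss_tot


@dataclass
class FitReport:
    """Per-condition force-component fits (R^2 across 12 directions)."""

    lh_hf_direction: float
    lh_hf_magnitude: float
    lh_vf_magnitude: float
    rf_vf_magnitude: float

    def as_dict(self) -> dict[str, float]:
        return {"LH_HF_dir": self.lh_hf_direction,
                "LH_HF_mag": self.lh_hf_magnitude,
                "LH_VF_mag": self.lh_vf_magnitude,
                "RF_VF_mag": self.rf_vf_magnitude}


def force_fit(predicted_forces: np.ndarray, observed_forces: np.ndarray) -> FitReport:
    """Component-wise fits of predicted vs observed limb forces.

    Both inputs have shape (n_directions, 4, 3) in LH, RH, LF, RF limb
    order.  Compares left-hindlimb horizontal-force direction (circular
    R^2) and magnitude, left-hindlimb vertical force and right-forelimb
    vertical force.
    """
    pred = np.asarray(predicted_forces, dtype=float)
    obs = np.asarray(observed_forces, dtype=float)
    if pred.shape != obs.shape or pred.ndim != 3 or pred.shape[1:] != (4, 3):
        raise ValueError("expected aligned (n_directions, 4, 3) force arrays")

    def hf_dir(f):
        return np.degrees(np.arctan2(f[:, 1], f[:, 0]))

    def hf_mag(f):
        return np.hypot(f[:, 0], f[:, 1])

    lh_p, lh_o = pred[:, 0], obs[:, 0]
    rf_p, rf_o = pred[:, 3], obs[:, 3]
    return FitReport(
        lh_hf_direction=r_squared(hf_dir(lh_o), hf_dir(lh_p), circular=True),
        lh_hf_magnitude=r_squared(hf_mag(lh_o), hf_mag(lh_p)),
        lh_vf_magnitude=r_squared(lh_o[:, 2], lh_p[:, 2]),
        rf_vf_magnitude=r_squared(rf_o[:, 2], rf_p[:, 2]),
    )


@dataclass
class TuningCurve:
    """One muscle's activation as a function of perturbation direction."""

    muscle: str
    directions_deg: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.directions_deg = np.asarray(self.directions_deg, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.directions_deg.shape != self.values.shape:
            raise ValueError("directions and values must align")
        if np.any(np.diff(self.directions_deg) <= 0):
            raise ValueError("directions must be strictly increasing")
        if np.any(self.values < -1e-12):
            raise ValueError("tuning values must be nonnegative")


def _tracked_peak(curve: TuningCurve, reference_peak_deg: float | None,
                  window_deg: float = 90.0) -> tuple[float, float]:
    """(direction, value) of the tracked peak.

    Without a reference this is the global maximum; with one, the maximum
    within ±window of the reference direction (dominant-lobe tracking for
    multimodal curves).
    """
    if reference_peak_deg is None:
        j = int(np.argmax(curve.values))
        return float(curve.directions_deg[j]), float(curve.values[j])
    sep = np.abs(wrap_angle_deg(curve.directions_deg - reference_peak_deg))
    mask = sep <= window_deg
    idx = np.flatnonzero(mask)
    j = idx[int(np.argmax(curve.values[idx]))]
    return float(curve.directions_deg[j]), float(curve.values[j])


@dataclass
class TuningPeakMetrics:
    """Scaling and shifting of one muscle's tuning peak across stances."""

    muscle: str
    peak_directions_deg: np.ndarray  # per stance
    peak_values: np.ndarray  # per stance, relative to preferred
    max_shift_deg: float
    excluded: bool = False


def tuning_peak_metrics(curves_by_stance: list[TuningCurve],
                        preferred_index: int = 0,
                        window_deg: float = 90.0) -> TuningPeakMetrics:
    """Track the preferred-configuration dominant peak across stances.

    Peak values are expressed relative to the preferred-configuration
    peak; the shift is the maximum circular difference of peak direction
    from the preferred configuration.  All-zero curves are excluded.
    """
    if len(curves_by_stance) < 2:
        raise ValueError("need curves from at least two stances")
    pref = curves_by_stance[preferred_index]
    if np.all(pref.values <= 1e-15):
        log.info("muscle %s excluded: all-zero preferred-stance curve", pref.muscle)
        return TuningPeakMetrics(muscle=pref.muscle,
                                 peak_directions_deg=np.full(len(curves_by_stance), np.nan),
                                 peak_values=np.full(len(curves_by_stance), np.nan),
                                 max_shift_deg=np.nan, excluded=True)
    ref_dir, ref_val = _tracked_peak(pref, None)
    dirs, vals = [], []
    for c in curves_by_stance:
        d, v = _tracked_peak(c, ref_dir, window_deg)
        dirs.append(d)
        vals.append(v / ref_val)
    dirs = np.array(dirs)
    shift = float(np.max(np.abs(wrap_angle_deg(dirs - ref_dir))))
    return TuningPeakMetrics(muscle=pref.muscle, peak_directions_deg=dirs,
                             peak_values=np.array(vals), max_shift_deg=shift)


def scaling_regression(peak_values: np.ndarray,
                       stance_codes: np.ndarray | None = None) -> float:
    """OLS slope of peak magnitude on ordinal stance code.

    Stances are coded 1 (longest) .. n (shortest); a positive slope means
    activation grows as stance shortens.  Requires at least 3 levels.
    """
    y = np.asarray(peak_values, dtype=float)
    if y.size < 3:
        raise ValueError("scaling regression requires at least 3 stance levels")
    x = np.arange(1, y.size + 1, dtype=float) if stance_codes is None \
        else np.asarray(stance_codes, dtype=float)
    x_c = x - x.mean()
    return float((x_c @ (y - y.mean())) / (x_c @ x_c))


def pca_dimensionality(activations: np.ndarray) -> int:
    """Kaiser-criterion dimensionality of a directions x muscles matrix.

    Zero-variance muscle columns are dropped (their correlation is
    undefined); the count of correlation-matrix eigenvalues >= 1.0 is
    returned.  Fewer than 2 usable columns yields 1 with a warning.
    """
    X = np.asarray(activations, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D directions x muscles matrix")
    keep = X.std(axis=0) > 1e-12
    X = X[:, keep]
    if X.shape[1] < 2:
        log.warning("pca_dimensionality: <2 non-constant columns; returning 1")
        return 1
    corr = np.corrcoef(X, rowvar=False)
    eig = np.linalg.eigvalsh(corr)
    return int(np.sum(eig >= 1.0))


@dataclass
class EffortReport:
    """Control effort per model, % of MMe in the preferred configuration."""

    baseline_effort: float
    percentages: dict[str, float] = field(default_factory=dict)
    solve_times_s: dict[str, float] = field(default_factory=dict)


def effort_report(efforts: dict[str, float],
                  baseline_key: str = "MMe_preferred",
                  solve_times: dict[str, float] | None = None) -> EffortReport:
    """Normalize summed efforts to 100% of the MMe preferred baseline."""
    if baseline_key not in efforts:
        raise ValueError(f"missing baseline effort {baseline_key!r}")
    base = efforts[baseline_key]
    if base <= 0:
        raise ValueError("baseline effort must be positive")
    pct = {k: 100.0 * v / base for k, v in efforts.items()}
    return EffortReport(baseline_effort=base, percentages=pct,
                        solve_times_s=dict(solve_times or {}))
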