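"""Threshold search, brightness prediction, sensitivity normalisation, and
experiment drivers.

The detection threshold theta_thresh is defined operationally: it is the
maximum pre-compression response produced by a "standard" electrode — one
with a 3 uA threshold for a 50 Hz cathodic-first train of 0.25 ms pulses
lasting 0.5 s — at its threshold current, using the normalisation
sensitivity of s = 0.43.  After calibration, finding any electrode's
threshold amounts to solving s * A * max_R2_unit >= theta_thresh for the
amplitude A.  Because the cascade is linear in amplitude before the
compressive output stage, the solve is exact; a conventional bisection
search over full simulations is also provided.

Electrodes differ in sensitivity only through the multiplicative scale s,
so threshold surfaces over (pulse width x frequency) for different
electrodes are the same shape up to 1/s — the model is separable — and s
can be recovered from measured thresholds by least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .electrodes import Electrode, current_field
from .percept import (fit_gaussian_size, quantify_ellipse,
                      render_spatial_field)
from .retinotopy import RetinoMap, STANDARD
from .sheet import CorticalSheet, SheetSpec, generate_maps, sheet_center_for_ecc
from .temporal import (PulseTrain, TemporalParams, compress, max_r2_unit,
                       simulate_temporal)

#: the standard-electrode defining train
STANDARD_TRAIN = PulseTrain(amplitude=3.0, pulse_width=0.25, frequency=50.0,
                            train_duration=0.5, polarity="cathodic-first")
#: sensitivity used for threshold normalisation
S_STANDARD = 0.43
#: search ceiling: 10 mA, a typical device safety bound
MAX_AMP_UA = 10_000.0


@dataclass
class ThresholdResult:
    electrode_id: str
    pulse_width: float
    frequency: float
    train_duration: float
    threshold: float | None      # uA; None if not reached below the ceiling
    tolerance: float
    s: float

    @property
    def found(self) -> bool:
        return self.threshold is not None


@dataclass
class CalibrationResult:
    s: dict[str, float]
    residuals: pd.DataFrame
    space: str


def calibrate_theta_thresh(params: TemporalParams | None = None) -> float:
    """Detection threshold on the pre-compression response scale.

    theta_thresh = s_standard * max_t R2 for the standard train at 3 uA.
    """
    params = params or TemporalParams()
    return S_STANDARD * STANDARD_TRAIN.amplitude * \
        max_r2_unit(STANDARD_TRAIN, params)


def find_threshold(train_template: PulseTrain, s: float,
                   params: TemporalParams | None = None,
                   theta_thresh: float | None = None,
                   spatial_factor: float = 1.0,
                   method: str = "linear", tol: float = 0.01,
                   electrode_id: str = "e", max_amp: float = MAX_AMP_UA,
                   ) -> ThresholdResult:
    """Amplitude at which the response first reaches theta_thresh.

    ``spatial_factor`` is the peak of the rendered spatial field per uA (1
    for purely temporal, single-location runs, where the spatial factor
    cancels).  ``method="linear"`` solves exactly using pre-compression
    linearity; ``method="bisect"`` runs a conventional bisection on full
    simulations to relative tolerance ``tol``, verifying the bracket.
    """
    params = params or TemporalParams()
    if theta_thresh is None:
        theta_thresh = params.theta_thresh
    if theta_thresh is None:
        theta_thresh = calibrate_theta_thresh(params)

    unit = s * spatial_factor * max_r2_unit(train_template, params)

    def done(th):
        return ThresholdResult(electrode_id, train_template.pulse_width,
                               train_template.frequency,
                               train_template.train_duration, th, tol, s)

    if unit <= 0:
        return done(None)
    exact = theta_thresh / unit
    if exact > max_amp:
        return done(None)
    if method == "linear":
        return done(exact)
    if method != "bisect":
        raise ValueError("method must be 'linear' or 'bisect'")

    def resp(a):
        r = simulate_temporal(replace(train_template, amplitude=a),
                              params).max_r2
        return s * spatial_factor * r

    lo, hi = 0.0, 1.0
    while resp(hi) < theta_thresh:
        hi *= 2.0
        if hi > max_amp:
            return done(None)
    while (hi - lo) > tol * hi:
        mid = 0.5 * (lo + hi)
        if resp(mid) >= theta_thresh:
            hi = mid
        else:
            lo = mid
    th = 0.5 * (lo + hi)
    # bracketing check
    assert resp(th * (1 + 2 * tol)) >= theta_thresh
    return done(th)


def predict_brightness(train: PulseTrain, s: float,
                       params: TemporalParams | None = None,
                       spatial_factor: float = 1.0) -> float:
    """Predicted brightness rating: max over time of the compressed response.

    Bounded in [0, s_out] (a 1-10 rating scale with the defaults).
    """
    params = params or TemporalParams()
    r2 = train.amplitude * spatial_factor * max_r2_unit(train, params)
    return float(compress(np.array(r2), s, params.p_div, params.s_out))


def fit_sensitivity(measured: pd.DataFrame,
                    params: TemporalParams | None = None,
                    theta_thresh: float | None = None,
                    space: str = "linear") -> CalibrationResult:
    """Recover per-electrode sensitivity s from measured thresholds.

    ``measured`` needs columns electrode, pulse_width, frequency,
    train_duration, threshold (uA, > 0).  Predicted thresholds scale as
    1/s, so linear-space least squares through the origin gives
    1/s = sum(T_pred * T_meas) / sum(T_pred^2) per electrode
    (``space="log"`` averages log ratios instead).
    """
    params = params or TemporalParams()
    if theta_thresh is None:
        theta_thresh = calibrate_theta_thresh(params)
    if (measured["threshold"] <= 0).any():
        raise ValueError("thresholds must be > 0")
    t_pred = np.array([
        theta_thresh / max_r2_unit(
            PulseTrain(amplitude=1.0, pulse_width=row.pulse_width,
                       frequency=row.frequency,
                       train_duration=row.train_duration), params)
        for row in measured.itertuples()])
    measured = measured.assign(t_pred_unit=t_pred)
    s_fit: dict[str, float] = {}
    rows = []
    for eid, grp in measured.groupby("electrode"):
        tp = grp["t_pred_unit"].to_numpy()
        tm = grp["threshold"].to_numpy()
        if space == "linear":
            inv_s = float(np.sum(tp * tm) / np.sum(tp ** 2))
            s_hat = 1.0 / inv_s
        elif space == "log":
            s_hat = float(np.exp(np.mean(np.log(tp) - np.log(tm))))
        else:
            raise ValueError("space must be 'linear' or 'log'")
        s_fit[str(eid)] = s_hat
        for tpv, tmv in zip(tp, tm):
            rows.append({"electrode": eid, "measured": tmv,
                         "predicted": tpv / s_hat,
                         "residual": tmv - tpv / s_hat})
    return CalibrationResult(s=s_fit, residuals=pd.DataFrame(rows),
                             space=space)


def run_strength_duration(s: float, pulse_widths=None, frequencies=None,
                          params: TemporalParams | None = None,
                          template: PulseTrain | None = None,
                          ) -> pd.DataFrame:
    """Threshold curves over a pulse-width grid and/or a frequency grid.

    The strength-duration (threshold vs pulse width) curve shape is set
    entirely by the fast integration stage and is identical across
    electrodes up to the 1/s scale.
    """
    params = params or TemporalParams()
    template = template or STANDARD_TRAIN
    theta = calibrate_theta_thresh(params)
    rows = []
    if pulse_widths is not None:
        for pw in pulse_widths:
            tr = replace(template, pulse_width=float(pw))
            res = find_threshold(tr, s, params, theta)
            rows.append({"variable": "pulse_width", "value": float(pw),
                         "threshold_uA": res.threshold,
                         "charge_uC_per_phase":
                             None if res.threshold is None
                             else res.threshold * pw * 1e-3})
    if frequencies is not None:
        for f in frequencies:
            tr = replace(template, frequency=float(f))
            res = find_threshold(tr, s, params, theta)
            rows.append({"variable": "frequency", "value": float(f),
                         "threshold_uA": res.threshold,
                         "charge_uC_per_phase":
                             None if res.threshold is None
                             else res.threshold * template.pulse_width * 1e-3})
    return pd.DataFrame(rows)


def _patch_for(ecc: float, rad_e: float, seed: int,
               rmap: RetinoMap = STANDARD,
               rf_preset: str = "keliris") -> CorticalSheet:
    size = max(6.0 * rad_e + 3.0, 4.0)
    # small electrodes need finer cortical sampling than the stimulated area
    spacing = 0.05 if rad_e < 0.5 else 0.1
    spec = SheetSpec(center=sheet_center_for_ecc(ecc, rmap),
                     extent=(size, size), spacing=spacing, seed=seed,
                     rf_preset=rf_preset, retinomap=rmap)
    return generate_maps(spec)


def simulate_phosphene(ecc: float, rad_e: float, amp_factor: float,
                       s: float = 0.57, seed: int = 0,
                       params: TemporalParams | None = None,
                       train: PulseTrain | None = None,
                       rmap: RetinoMap = STANDARD,
                       rf_preset: str = "keliris",
                       kind: str = "surface",
                       sheet: CorticalSheet | None = None) -> dict:
    """Render and quantify one phosphene at ``amp_factor`` times threshold.

    Returns a dict with the stimulus description, the threshold amplitude,
    and both size metrics (moment ellipse of the peak frame, and the
    threshold-free Gaussian-fit sigma).
    """
    params = params or TemporalParams()
    train = train or STANDARD_TRAIN
    if sheet is None:
        sheet = _patch_for(ecc, rad_e, seed, rmap, rf_preset)
    el = Electrode(id="e0", position=sheet_center_for_ecc(ecc, rmap),
                   rad_e=rad_e, kind=kind, s=s)
    cur_unit = current_field(el, sheet, 1.0)
    sl_min = float(sheet.sigma_rf[cur_unit > 0.01 * cur_unit.max()].min())
    spacing = max(0.02, sl_min / 8.0)
    x, y, field = render_spatial_field(sheet, cur_unit, spacing=spacing)
    r2max = max_r2_unit(train, params)
    theta = calibrate_theta_thresh(params)
    peak = field.max() * r2max * s
    thr = theta / peak if peak > 0 else None
    if thr is None:
        return {"ecc": ecc, "rad_e": rad_e, "amp_factor": amp_factor,
                "threshold_uA": None, "empty": True}
    amp = amp_factor * thr
    frame = compress(field * amp * r2max, s, params.p_div, params.s_out)
    stats = quantify_ellipse(frame, x, y, params.theta_draw)
    sigma = fit_gaussian_size(frame, x, y)
    return {"ecc": ecc, "rad_e": rad_e, "amp_factor": amp_factor,
            "amp_uA": amp, "threshold_uA": thr, "empty": stats.empty,
            "area_deg2": stats.area, "major_deg": stats.major,
            "minor_deg": stats.minor, "mean_diameter_deg": stats.mean_diameter,
            "gauss_sigma_deg": sigma}


def run_size_experiments(eccs, rad_es, amp_factors, s: float = 0.57,
                         seed: int = 0,
                         params: TemporalParams | None = None,
                         rf_preset: str = "keliris",
                         rmap: RetinoMap = STANDARD) -> pd.DataFrame:
    """Phosphene size tables over (eccentricity x electrode radius x drive).

    Drives are expressed as multiples of the per-configuration threshold.
    Empty phosphenes appear as sentinel rows (empty=True, NaN sizes).
    """
    rows = []
    for ecc in eccs:
        for rad_e in rad_es:
            sheet = _patch_for(float(ecc), float(rad_e), seed, rmap,
                               rf_preset)
            for af in amp_factors:
                rows.append(simulate_phosphene(
                    float(ecc), float(rad_e), float(af), s=s, seed=seed,
                    params=params, rf_preset=rf_preset, rmap=rmap,
                    sheet=sheet))
    return pd.DataFrame(rows)
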