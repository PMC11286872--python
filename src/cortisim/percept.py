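"""Receptive-field construction, percept rendering, and phosphene metrics.

Each cortical location carries a two-subunit receptive field: an ON and an
OFF anisotropic Gaussian (long axis sigma_rf, short axis sigma_rf/4, both
oriented at the location's preferred orientation), displaced by +/-
delta_onoff/2 along the short axis and each normalised to unit mass.  Only
the excitatory components are modeled.  The rendered percept is the
current-weighted linear sum of these profiles over the stimulated
population,

    R_sp(x) = sum_i I_i * eye_i * [w_onoff,i * ON_i - omega*(1-w_onoff,i) * OFF_i]

with omega = 0.8, so OFF subunits contribute *negative* (darker than
background) intensity; suprathreshold percepts stay net-bright.  Because
every stage before the compressive nonlinearity is linear, space and time
factor exactly: each movie frame is compress(R_sp * drive(t)), where
drive(t) is the slow temporal response per unit current.

Phosphenes are quantified two ways: a moment-based best-fit ellipse of the
|intensity| >= theta_draw binarisation (as when patients draw what they
see), and a threshold-free isotropic 2-D Gaussian fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .sheet import CorticalSheet
from .temporal import (PulseTrain, ResponseTrace, TemporalParams, compress,
                       simulate_temporal)

#: relative weight of OFF vs ON subunit contributions
OMEGA_OFF = 0.8


@dataclass
class RFProfile:
    """A single cell's two-subunit receptive field on a local grid."""

    center: complex            # deg
    theta: float               # rad
    sigma_long: float          # deg
    sigma_short: float         # deg
    delta: float               # deg, signed subunit separation
    w_onoff: float
    x: np.ndarray              # deg, grid columns
    y: np.ndarray              # deg, grid rows
    on: np.ndarray             # unit-mass ON field
    off: np.ndarray            # unit-mass OFF field

    @property
    def cell_class(self) -> str:
        """'simple' if the subunits are largely non-overlapping."""
        return "simple" if abs(self.delta) > self.sigma_long / 2 else "complex"

    def response_field(self) -> np.ndarray:
        return self.w_onoff * self.on - OMEGA_OFF * (1 - self.w_onoff) * self.off


@dataclass
class PerceptMovie:
    """Rendered percept frames on a visual-field grid.

    Intensities are signed brightness-rating units: positive = brighter than
    background, negative = darker.
    """

    x: np.ndarray              # deg
    y: np.ndarray              # deg
    frames: np.ndarray         # (nt, ny, nx)
    times: np.ndarray          # ms

    @property
    def spacing(self) -> float:
        return float(self.x[1] - self.x[0])

    @property
    def pixel_area(self) -> float:
        return self.spacing ** 2

    def peak_frame(self) -> np.ndarray:
        """Frame at the time of maximum absolute intensity."""
        i = int(np.argmax(np.max(np.abs(self.frames), axis=(1, 2))))
        return self.frames[i]


@dataclass
class EllipseStats:
    """Moment-based summary of a binarised phosphene."""

    empty: bool
    area: float                     # deg^2
    centroid: complex               # deg
    major: float                    # deg, full major diameter
    minor: float                    # deg
    orientation: float              # rad
    mean_diameter: float            # deg, (major + minor)/2

    @classmethod
    def sentinel(cls) -> "EllipseStats":
        return cls(empty=True, area=0.0, centroid=complex(np.nan, np.nan),
                   major=np.nan, minor=np.nan, orientation=np.nan,
                   mean_diameter=np.nan)


def _gauss2(x: np.ndarray, y: np.ndarray, center: complex, theta: float,
            sl: float, ss: float) -> np.ndarray:
    """Unit-mass anisotropic Gaussian on the grid (analytic normalisation)."""
    dx = x[None, :] - center.real
    dy = y[:, None] - center.imag
    ca, sa = math.cos(theta), math.sin(theta)
    u = dx * ca + dy * sa       # along long axis
    v = -dx * sa + dy * ca      # along short axis
    g = np.exp(-0.5 * ((u / sl) ** 2 + (v / ss) ** 2))
    return g / (2.0 * np.pi * sl * ss)


def build_rf(sheet: CorticalSheet, iy: int, ix: int,
             grid_halfwidth: float | None = None,
             spacing: float | None = None) -> RFProfile:
    """Construct the receptive field of one sheet location on a local grid."""
    if not sheet.valid[iy, ix]:
        raise ValueError("location maps outside the modeled hemifield")
    c = complex(sheet.z[iy, ix])
    theta = float(sheet.theta[iy, ix])
    sl = float(sheet.sigma_rf[iy, ix])
    ss = sl / 4.0
    delta = float(sheet.delta_onoff[iy, ix])
    if grid_halfwidth is None:
        grid_halfwidth = 4.0 * sl + abs(delta)
    if spacing is None:
        spacing = min(0.02, ss / 5.0)
    n = int(np.ceil(2 * grid_halfwidth / spacing)) + 1
    x = c.real + (np.arange(n) - (n - 1) / 2) * spacing
    y = c.imag + (np.arange(n) - (n - 1) / 2) * spacing
    # subunits displaced along the short axis
    off_dir = complex(-math.sin(theta), math.cos(theta))
    c_on = c + off_dir * (delta / 2.0)
    c_off = c - off_dir * (delta / 2.0)
    return RFProfile(center=c, theta=theta, sigma_long=sl, sigma_short=ss,
                     delta=delta, w_onoff=float(sheet.w_onoff[iy, ix]),
                     x=x, y=y,
                     on=_gauss2(x, y, c_on, theta, sl, ss),
                     off=_gauss2(x, y, c_off, theta, sl, ss))


def _eye_weights(sheet: CorticalSheet, eye_mode: str) -> np.ndarray:
    if eye_mode == "both":
        return np.ones_like(sheet.w_od)
    if eye_mode == "left":
        return sheet.w_od
    if eye_mode == "right":
        return 1.0 - sheet.w_od
    raise ValueError("eye_mode must be 'both', 'left' or 'right'")


def render_spatial_field(sheet: CorticalSheet, current: np.ndarray,
                         eye_mode: str = "both",
                         grid: tuple[np.ndarray, np.ndarray] | None = None,
                         spacing: float | None = None,
                         current_cutoff: float = 0.01,
                         ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pre-compression spatial percept field R_sp (per-uA response density).

    Sums current-weighted two-subunit RF profiles of every location whose
    current exceeds ``current_cutoff`` times the field maximum.  Returns
    (x, y, field).  The rendering grid covers the stimulated RFs to 3 sigma
    (plus subunit offsets); default spacing is min(0.02 deg, sigma_rf/5 of
    the smallest stimulated RF).
    """
    current = np.asarray(current, dtype=float)
    if current.shape != sheet.shape:
        raise ValueError("current field must be aligned with the sheet grid")
    cmax = current.max()
    active = (current > current_cutoff * cmax) & sheet.valid if cmax > 0 \
        else np.zeros_like(sheet.valid)
    if not np.any(active):
        if grid is None:
            x = y = np.linspace(-1, 1, 51)
        else:
            x, y = grid
        return x, y, np.zeros((y.size, x.size))

    zs = sheet.z[active]
    sls = sheet.sigma_rf[active]
    sss = sls / 4.0
    deltas = sheet.delta_onoff[active]
    thetas = sheet.theta[active]
    wons = sheet.w_onoff[active]
    eyew = _eye_weights(sheet, eye_mode)[active]
    amps = current[active]

    if grid is None:
        pad = 3.0 * sls + np.abs(deltas) / 2.0
        x0 = (zs.real - pad).min()
        x1 = (zs.real + pad).max()
        y0 = (zs.imag - pad).min()
        y1 = (zs.imag + pad).max()
        if spacing is None:
            spacing = min(0.02, sls.min() / 5.0)
        x = np.arange(x0, x1 + spacing, spacing)
        y = np.arange(y0, y1 + spacing, spacing)
    else:
        x, y = grid
        spacing = float(x[1] - x[0])
    if spacing > sls.min() / 4.0 + 1e-12:
        raise ValueError(
            f"grid spacing {spacing:.3g} deg too coarse for the smallest "
            f"stimulated RF (needs <= sigma_rf/4 = {sls.min() / 4:.3g})")

    field = np.zeros((y.size, x.size))
    for z0, sl, ss, dlt, th, won, ew, amp in zip(
            zs, sls, sss, deltas, thetas, wons, eyew, amps):
        off_dir = complex(-math.sin(th), math.cos(th))
        c_on = z0 + off_dir * (dlt / 2.0)
        c_off = z0 - off_dir * (dlt / 2.0)
        w = amp * ew
        field += w * won * _gauss2(x, y, c_on, th, sl, ss)
        field -= w * OMEGA_OFF * (1 - won) * _gauss2(x, y, c_off, th, sl, ss)
    return x, y, field


def unit_temporal_drive(train: PulseTrain, params: TemporalParams,
                        ) -> ResponseTrace:
    """Slow-stage response R2(t) of the train at unit (1 uA) amplitude."""
    from dataclasses import replace
    return simulate_temporal(replace(train, amplitude=1.0), params).r2


def render_percept(sheet: CorticalSheet, current: np.ndarray,
                   train: PulseTrain, params: TemporalParams,
                   eye_mode: str = "both", frame_dt: float = 25.0,
                   spacing: float | None = None) -> PerceptMovie:
    """Render the spatiotemporal percept movie for one stimulation pattern.

    Exploits exact spatiotemporal separability: one spatial field (including
    the current weighting, in uA) times one unit-amplitude temporal drive,
    compressed per frame.
    """
    x, y, field = render_spatial_field(sheet, current, eye_mode,
                                       spacing=spacing)
    drive = unit_temporal_drive(train, params)
    times = np.arange(0.0, drive.time[-1] + frame_dt, frame_dt)
    dvals = np.where(times <= drive.time[-1], drive.at(times), 0.0)
    pre = field[None, :, :] * dvals[:, None, None]
    frames = compress(pre, params.s_in, params.p_div, params.s_out)
    return PerceptMovie(x=x, y=y, frames=frames, times=times)


def render_sequence(sheet: CorticalSheet,
                    schedule: list[tuple[np.ndarray, PulseTrain, float]],
                    params: TemporalParams, eye_mode: str = "both",
                    frame_dt: float = 25.0,
                    spacing: float | None = None) -> PerceptMovie:
    """Render a multi-electrode schedule of (current_field, train, onset_s).

    Per-electrode spatiotemporal drives superpose *before* compression
    (the model has no electric-field or nonlinear neural interactions);
    overlapping and non-overlapping schedules are both allowed.
    """
    if not schedule:
        raise ValueError("schedule must contain at least one entry")
    # common grid covering all stimulated populations
    total = np.zeros(sheet.shape)
    for cur, _, _ in schedule:
        total = np.maximum(total, np.asarray(cur, dtype=float))
    x, y, _ = render_spatial_field(sheet, total, eye_mode, spacing=spacing)

    drives = []
    fields = []
    t_end = 0.0
    for cur, train, onset_s in schedule:
        _, _, f = render_spatial_field(sheet, cur, eye_mode, grid=(x, y))
        d = unit_temporal_drive(train, params)
        fields.append(f)
        drives.append((d, onset_s * 1000.0))
        t_end = max(t_end, onset_s * 1000.0 + d.time[-1])

    times = np.arange(0.0, t_end + frame_dt, frame_dt)
    pre = np.zeros((times.size, y.size, x.size))
    for f, (d, onset_ms) in zip(fields, drives):
        tv = times - onset_ms
        vals = np.where((tv >= 0) & (tv <= d.time[-1]), d.at(tv), 0.0)
        pre += f[None, :, :] * vals[:, None, None]
    frames = compress(pre, params.s_in, params.p_div, params.s_out)
    return PerceptMovie(x=x, y=y, frames=frames, times=times)


def quantify_ellipse(frame: np.ndarray, x: np.ndarray, y: np.ndarray,
                     theta_draw: float = 1.0) -> EllipseStats:
    """Moment-based ellipse of the binarised phosphene.

    Binarises at |intensity| >= theta_draw (dark regions count toward the
    drawn shape), computes raw and central image moments, and derives the
    equivalent-ellipse axes from the second central moments (a solid ellipse
    with semi-axis a has mu20/mu00 = a^2/4, so the full diameter is
    4*sqrt(eigenvalue)).  Returns an empty sentinel if nothing crosses the
    drawing threshold.
    """
    frame = np.asarray(frame, dtype=float)
    if not np.all(np.isfinite(frame)):
        raise ValueError("frame must be finite")
    binary = np.abs(frame) >= theta_draw
    m00 = binary.sum()
    if m00 == 0:
        return EllipseStats.sentinel()
    dx = float(x[1] - x[0])
    pix_area = dx * dx
    yy, xx = np.nonzero(binary)
    xs = x[xx]
    ys = y[yy]
    cx, cy = xs.mean(), ys.mean()
    mu20 = np.mean((xs - cx) ** 2)
    mu02 = np.mean((ys - cy) ** 2)
    mu11 = np.mean((xs - cx) * (ys - cy))
    cov = np.array([[mu20, mu11], [mu11, mu02]])
    evals = np.linalg.eigvalsh(cov)          # ascending
    evals = np.maximum(evals, 0.0)
    minor = 4.0 * math.sqrt(evals[0])
    major = 4.0 * math.sqrt(evals[1])
    orientation = 0.5 * math.atan2(2.0 * mu11, mu20 - mu02)
    return EllipseStats(empty=False, area=float(m00 * pix_area),
                        centroid=complex(cx, cy), major=major, minor=minor,
                        orientation=orientation,
                        mean_diameter=0.5 * (major + minor))


def fit_gaussian_size(frame: np.ndarray, x: np.ndarray, y: np.ndarray,
                      ) -> float:
    """Standard deviation (deg) of the best-fitting isotropic 2-D Gaussian.

    Threshold-free size metric; robust for irregular percepts from very
    small electrodes.  Returns NaN for frames with no mass.
    """
    frame = np.asarray(frame, dtype=float)
    mass = np.abs(frame)
    total = mass.sum()
    if total <= 0:
        return float("nan")
    xx, yy = np.meshgrid(x, y)
    cx = (mass * xx).sum() / total
    cy = (mass * yy).sum() / total
    var = ((mass * ((xx - cx) ** 2 + (yy - cy) ** 2)).sum() / total) / 2.0
    sigma0 = math.sqrt(max(var, 1e-8))
    amp0 = frame.max() if frame.max() > 0 else mass.max()

    fx = xx.ravel()
    fy = yy.ravel()
    fz = frame.ravel()

    def resid(p):
        a, x0, y0, lg_s = p
        s = math.exp(lg_s)
        return a * np.exp(-((fx - x0) ** 2 + (fy - y0) ** 2) / (2 * s * s)) - fz

    sol = least_squares(resid, x0=[amp0, cx, cy, math.log(sigma0)],
                        method="lm", max_nfev=200)
    return float(math.exp(sol.x[3]))
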