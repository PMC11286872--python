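"""Synthesis of V1 property maps on a flattened cortical patch.

Orientation-pinwheel, ocular-dominance (OD) and on/off-subunit maps are all
derived from a single seeded complex white-noise field, bandpass filtered
with an isotropic radial Gabor:

    F(r) = 1/(2*pi*sigma_F^2) * exp(-r^2 / (2*sigma_F^2)) * cos(omega * r)

* preferred orientation theta = half the angle of the filtered field
  (orientation is pi-periodic);
* ocular dominance w_od = normal CDF of the (z-scored) x-gradient of the
  real part — this yields OD stripes that tend to cross iso-orientation
  contours orthogonally, as in optical-imaging data;
* the same noise filtered at twice the radial frequency gives the on/off
  subunit maps: the (uniform) angle u of that field is transformed to an
  exponentially distributed signed subunit separation, and its x-gradient
  (through the normal CDF) gives the on/off balance w_onoff.

The radial frequency is parameterised by the mean OD column period in mm
(default 0.863).  Because the gradient step tilts the radial power peak
slightly above the filter's ring frequency, the ring frequency is solved
for analytically so that the *resulting OD maps* have the stated period
(see :func:`_omega_for_period`).  The filter envelope scale sigma_F
defaults to 0.5 mm.

Noise is drawn in the frequency domain in a ring-by-ring order so that
regenerating the sheet with the same seed at a finer grid spacing preserves
the large-scale structure (the shared low-frequency modes receive the same
draws).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr

from .retinotopy import RetinoMap, STANDARD, cortex_to_visual, visual_to_cortex

#: mean ocular-dominance column period, mm
DEFAULT_OD_PERIOD = 0.863
#: radial Gabor envelope scale, mm
DEFAULT_SIGMA_F = 0.5

#: receptive-field size presets: (slope deg/deg, intercept deg) of the long
#: axis vs eccentricity.  "keliris" is a single-study macaque estimate (the
#: smallest in the literature); "meta" is a representative meta-analytic
#: curve, larger at every eccentricity.
RF_PRESETS = {
    "keliris": (0.08, 0.16),
    "meta": (0.115, 0.25),
}


def rf_size(ecc, preset: str = "keliris"):
    """Receptive-field long-axis sigma (deg) at eccentricity ecc (deg).

    Linear in eccentricity: sigma_rf = b + m * ecc (default 0.16 + 0.08*ecc).
    The short axis is sigma_rf / 4.
    """
    ecc = np.asarray(ecc, dtype=float)
    if np.any(ecc < 0):
        raise ValueError("eccentricity must be >= 0")
    m, b = RF_PRESETS[preset] if isinstance(preset, str) else preset
    out = b + m * ecc
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class SheetSpec:
    """Specification of a gridded flattened-cortex patch.

    ``center`` is the cortical position (mm, complex) of the patch center;
    use :func:`sheet_center_for_ecc` to center a patch on the cortical image
    of a visual-field eccentricity.
    """

    center: complex = 0.0 + 0.0j
    extent: tuple[float, float] = (20.0, 20.0)   # mm (width, height)
    spacing: float = 0.1                          # mm
    od_period_mm: float = DEFAULT_OD_PERIOD
    sigma_F: float = DEFAULT_SIGMA_F
    seed: int = 0
    rf_preset: str = "keliris"
    retinomap: RetinoMap = field(default_factory=lambda: STANDARD)

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        if min(self.extent) < 6 * self.sigma_F:
            raise ValueError(
                "extent must cover at least 6*sigma_F for the filter support")
        if min(self.extent) < 3 * self.od_period_mm:
            raise ValueError("extent must cover several OD periods")


def sheet_center_for_ecc(ecc: float, rmap: RetinoMap = STANDARD) -> complex:
    """Cortical position of a visual-field point at (ecc, 0) deg."""
    return complex(visual_to_cortex(complex(ecc, 0.0), rmap))


@dataclass
class CorticalSheet:
    """Gridded cortical patch with per-location neuron properties.

    All 2-D arrays are indexed [iy, ix]; ``x`` and ``y`` are the cortical
    coordinates (mm) of the grid columns and rows.
    """

    x: np.ndarray                # mm, shape (nx,)
    y: np.ndarray                # mm, shape (ny,)
    theta: np.ndarray            # rad, orientation preference in (-pi/2, pi/2]
    w_od: np.ndarray             # ocular dominance in [0, 1]
    w_onoff: np.ndarray          # on/off balance in [0, 1]
    delta_onoff: np.ndarray      # deg, signed on/off subunit separation
    sigma_rf: np.ndarray         # deg, RF long axis
    z: np.ndarray                # deg, complex visual-field position
    valid: np.ndarray            # mask: True where the location maps into
                                 # the modeled hemifield
    spec: SheetSpec | None = None

    @property
    def w(self) -> np.ndarray:
        """Complex cortical coordinates of the grid (mm)."""
        return self.x[None, :] + 1j * self.y[:, None]

    @property
    def spacing(self) -> float:
        return float(self.x[1] - self.x[0])

    @property
    def shape(self) -> tuple[int, int]:
        return self.theta.shape

    def save(self, path) -> None:
        np.savez_compressed(
            path, x=self.x, y=self.y, theta=self.theta, w_od=self.w_od,
            w_onoff=self.w_onoff, delta_onoff=self.delta_onoff,
            sigma_rf=self.sigma_rf, z=self.z, valid=self.valid,
            seed=-1 if self.spec is None else self.spec.seed)

    @classmethod
    def load(cls, path) -> "CorticalSheet":
        d = np.load(path)
        return cls(x=d["x"], y=d["y"], theta=d["theta"], w_od=d["w_od"],
                   w_onoff=d["w_onoff"], delta_onoff=d["delta_onoff"],
                   sigma_rf=d["sigma_rf"], z=d["z"], valid=d["valid"])


def radial_gabor_filter(shape: tuple[int, int], spacing: float,
                        omega: float, sigma_F: float) -> np.ndarray:
    """Centered radial Gabor kernel sampled on a grid.

    F(r) = 1/(2*pi*sigma_F^2) * exp(-r^2/(2*sigma_F^2)) * cos(omega*r),
    with the kernel mean subtracted so the filter has zero DC gain (the raw
    Gabor has a small positive DC component).  ``omega`` is an angular
    frequency in rad/mm; the power spectrum peaks at radial frequency omega.
    """
    ny, nx = shape
    if min(nx, ny) * spacing < 6 * sigma_F:
        raise ValueError("kernel support must be at least 6*sigma_F")
    xs = (np.arange(nx) - nx // 2) * spacing
    ys = (np.arange(ny) - ny // 2) * spacing
    r = np.hypot(xs[None, :], ys[:, None])
    f = (1.0 / (2.0 * np.pi * sigma_F ** 2)
         * np.exp(-0.5 * (r / sigma_F) ** 2) * np.cos(omega * r))
    return f - f.mean()


from functools import lru_cache


@lru_cache(maxsize=32)
def _omega_for_period(period: float, sigma_F: float, spacing: float,
                      n: int) -> float:
    """Radial Gabor frequency that yields OD maps with the given period.

    The OD map is the x-gradient of the filtered field, which weights the
    filter's spectral ring by kx^2 and skews the radially averaged power
    peak above the ring frequency.  This solves for the omega whose
    *predicted* OD power peak (filter spectrum x discrete-gradient transfer,
    radially averaged with the same binning as the period estimator) sits at
    2*pi/period.  Purely analytic: no noise realisations involved.
    """
    def predicted(om: float) -> float:
        kern = radial_gabor_filter((n, n), spacing, om, sigma_F)
        khat = np.abs(np.fft.fft2(np.fft.ifftshift(kern))) ** 2
        k_ang = np.fft.fftfreq(n, d=spacing) * 2 * np.pi
        transfer = (np.sin(k_ang * spacing) / spacing) ** 2
        power = khat * transfer[None, :]
        kcyc = np.fft.fftfreq(n, d=spacing)
        kr = np.hypot(kcyc[None, :], kcyc[:, None]).ravel()
        df = 1.0 / (n * spacing)
        nbins = int(kr.max() / df) + 1
        idx = np.minimum((kr / df).astype(int), nbins - 1)
        sums = np.bincount(idx, weights=power.ravel(), minlength=nbins)
        counts = np.bincount(idx, minlength=nbins)
        radial = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
        i = 2 + int(np.argmax(radial[2:]))
        y0, y1, y2 = radial[i - 1], radial[i], radial[i + 1]
        denom = y0 - 2 * y1 + y2
        shift = float(np.clip(0.5 * (y0 - y2) / denom, -0.5, 0.5)) \
            if denom != 0 else 0.0
        return 1.0 / ((i + shift) * df)

    target = period
    lo, hi = 0.5 * 2 * np.pi / period, 1.2 * 2 * np.pi / period
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if predicted(mid) < target:   # period too short -> lower frequency
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def _noise_spectrum(n: int, seed: int) -> np.ndarray:
    """Complex Gaussian Fourier coefficients, drawn ring-by-ring.

    Modes are ordered by max(|jx|, |jy|) of their signed integer frequency
    index, so a finer grid over the same extent assigns identical draws to
    the shared low-frequency modes (refinement stability).
    """
    j = np.fft.fftfreq(n, d=1.0 / n).round().astype(int)
    jx, jy = np.meshgrid(j, j, indexing="xy")
    ring = np.maximum(np.abs(jx), np.abs(jy)).ravel()
    order = np.lexsort((jy.ravel(), jx.ravel(), ring))
    rng = np.random.default_rng(seed)
    draws = rng.standard_normal((n * n, 2))
    coef = np.empty(n * n, dtype=complex)
    coef[order] = draws[:, 0] + 1j * draws[:, 1]
    return coef.reshape(n, n)


def _filtered_noise(spec: SheetSpec, n: tuple[int, int],
                    omega: float) -> np.ndarray:
    """Complex white noise bandpass filtered at angular frequency omega."""
    ny, nx = n
    m = max(nx, ny)
    coef = _noise_spectrum(m, spec.seed)
    kernel = radial_gabor_filter((m, m), spec.spacing, omega, spec.sigma_F)
    khat = np.fft.fft2(np.fft.ifftshift(kernel))
    field_sq = np.fft.ifft2(coef * khat)
    return field_sq[:ny, :nx]


def generate_maps(spec: SheetSpec) -> CorticalSheet:
    """Generate all property maps for a cortical patch (deterministic in seed).

    theta comes from the angle of the filtered field (halved into the
    pi-periodic orientation range); w_od from the normal CDF of the z-scored
    x-gradient of its real part.  The on/off maps come from the same noise
    filtered at twice the radial frequency: the angle u (uniform on
    (-pi, pi]) maps to the signed separation

        delta_onoff = A_rf * sign(u) * (-log(|u|/pi)) / 2

    where A_rf = pi * sigma_rf * (sigma_rf/4) is the RF ellipse area, so
    |delta|/A_rf is exponential with rate 2 (small separations common,
    large ones rare).
    """
    # n * spacing == extent exactly, so the physical frequency lattice (and
    # hence the noise draws) is identical across grid refinements
    wx, wy = spec.extent
    nx = int(round(wx / spec.spacing))
    ny = int(round(wy / spec.spacing))
    x = spec.center.real + (np.arange(nx) - nx // 2) * spec.spacing
    y = spec.center.imag + (np.arange(ny) - ny // 2) * spec.spacing

    omega = _omega_for_period(spec.od_period_mm, spec.sigma_F, spec.spacing,
                              max(nx, ny))
    f1 = _filtered_noise(spec, (ny, nx), omega)
    f2 = _filtered_noise(spec, (ny, nx), 2.0 * omega)

    # orientation: angle is 2pi-periodic, orientation pi-periodic
    theta = np.angle(f1) / 2.0

    def _cdf_of_xgrad(fld: np.ndarray) -> np.ndarray:
        g = np.gradient(fld.real, spec.spacing, axis=1)
        return ndtr((g - g.mean()) / g.std())

    w_od = _cdf_of_xgrad(f1)
    w_onoff = _cdf_of_xgrad(f2)

    w = x[None, :] + 1j * y[:, None]
    z = np.asarray(cortex_to_visual(w, spec.retinomap))
    valid = z.real >= -1e-9
    ecc = np.abs(z)
    sigma_rf = rf_size(ecc, spec.rf_preset)

    u = np.angle(f2)
    area = np.pi * sigma_rf * (sigma_rf / 4.0)
    with np.errstate(divide="ignore"):
        mag = -np.log(np.abs(u) / np.pi)
    mag[~np.isfinite(mag)] = 0.0
    delta_onoff = area * np.sign(u) * mag / 2.0

    return CorticalSheet(x=x, y=y, theta=theta, w_od=w_od, w_onoff=w_onoff,
                         delta_onoff=delta_onoff, sigma_rf=sigma_rf, z=z,
                         valid=valid, spec=spec)


def estimate_column_period(w_od: np.ndarray, spacing: float) -> float:
    """Dominant spatial period (mm) of a column map.

    Peak of the radially averaged 2-D power spectrum (DC removed), refined
    by parabolic interpolation across the neighbouring frequency bins.
    Raises if the map has no spectral peak (flat map).
    """
    m = w_od - w_od.mean()
    if np.allclose(m, 0.0):
        raise ValueError("flat map: no spectral peak")
    ny, nx = m.shape
    power = np.abs(np.fft.fft2(m)) ** 2
    kx = np.fft.fftfreq(nx, d=spacing)
    ky = np.fft.fftfreq(ny, d=spacing)
    kr = np.hypot(kx[None, :], ky[:, None]).ravel()
    p = power.ravel()
    df = 1.0 / (max(nx, ny) * spacing)
    nbins = int(kr.max() / df) + 1
    idx = np.minimum((kr / df).astype(int), nbins - 1)
    sums = np.bincount(idx, weights=p, minlength=nbins)
    counts = np.bincount(idx, minlength=nbins)
    radial = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    # ignore the lowest bins (residual large-scale trend)
    lo = 2
    i = lo + int(np.argmax(radial[lo:]))
    if radial[i] <= 0:
        raise ValueError("flat map: no spectral peak")
    # parabolic refinement in frequency
    if 0 < i < nbins - 1:
        y0, y1, y2 = radial[i - 1], radial[i], radial[i + 1]
        denom = (y0 - 2 * y1 + y2)
        shift = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
        shift = float(np.clip(shift, -0.5, 0.5))
    else:
        shift = 0.0
    freq = (i + shift) * df
    return 1.0 / freq


def mean_column_period(seeds, extent=(24.0, 24.0), spacing=0.1,
                       **spec_kw) -> float:
    """Mean OD column period over several seeds (map statistics helper)."""
    periods = []
    for s in seeds:
        sheet = generate_maps(SheetSpec(extent=extent, spacing=spacing,
                                        seed=int(s), **spec_kw))
        periods.append(estimate_column_period(sheet.w_od, sheet.spacing))
    return float(np.mean(periods))
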