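"""Conformal log-polar map between visual field (deg) and flattened V1 (mm).

Visual space is represented by complex numbers z (real part = horizontal
eccentricity, imaginary = vertical position, in degrees); the flattened
cortical sheet by complex w (mm).  The forward map is the Schwartz
monopole approximation

    w = k * log(z + a)

with ``a`` (deg) controlling the fraction of cortex devoted to the fovea and
``k`` (mm) the overall cortical scale.  An anisotropy factor ``squish``
scales the cortical y (imaginary) dimension.  With the standard parameters
(a = 0.5, k = 15, squish = 1) the map is conformal, and the linear cortical
magnification along the horizontal meridian is k/(ecc + a) mm/deg.

One map instance covers one hemifield/hemisphere; the left visual field is
handled by mirroring the horizontal coordinate onto the right-hemifield map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class RetinoMap:
    k: float = 15.0        # mm, cortical scale
    a: float = 0.5         # deg, foveal offset
    squish: float = 1.0    # cortical-y anisotropy
    hemisphere: str = "left"   # cortical hemisphere (maps right visual field)

    def __post_init__(self) -> None:
        if self.k <= 0 or self.a <= 0 or self.squish <= 0:
            raise ValueError("k, a and squish must all be > 0")
        if self.hemisphere not in ("left", "right"):
            raise ValueError("hemisphere must be 'left' or 'right'")

    @property
    def fovea_w(self) -> complex:
        """Cortical image of the fovea (z = 0): k*log(a)."""
        return complex(self.k * np.log(self.a), 0.0)


#: standard template parameters
STANDARD = RetinoMap()
#: parameter set fit to a published 24-electrode surface-grid dataset
BEAUCHAMP2020 = RetinoMap(k=16.6, a=0.15, squish=0.63)

PRESETS = {"standard": STANDARD, "beauchamp2020": BEAUCHAMP2020}


def visual_to_cortex(z, rmap: RetinoMap = STANDARD):
    """Map visual-field points (deg, complex) to cortical points (mm, complex).

    Uses the principal branch of the complex log; the cortical y coordinate
    is multiplied by ``squish``.  z = -a is the singularity of the map.
    """
    z = np.asarray(z, dtype=complex)
    if np.any(np.isclose(z, -rmap.a)):
        raise ValueError("z = -a is the singularity of the log map")
    w = rmap.k * np.log(z + rmap.a)
    w = w.real + 1j * w.imag * rmap.squish
    if w.ndim == 0:
        return complex(w)
    return w


def cortex_to_visual(w, rmap: RetinoMap = STANDARD):
    """Exact inverse of :func:`visual_to_cortex`: z = exp(w'/k) - a."""
    w = np.asarray(w, dtype=complex)
    w = w.real + 1j * w.imag / rmap.squish
    z = np.exp(w / rmap.k) - rmap.a
    if z.ndim == 0:
        return complex(z)
    return z


def magnification(ecc, rmap: RetinoMap = STANDARD):
    """Linear cortical magnification k/(ecc + a) in mm/deg (ecc >= 0)."""
    ecc = np.asarray(ecc, dtype=float)
    if np.any(ecc < 0):
        raise ValueError("eccentricity must be >= 0")
    m = rmap.k / (ecc + rmap.a)
    return float(m) if m.ndim == 0 else m
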