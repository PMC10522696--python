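"""Stimulus colorimetry: CIE xyY to cone excitations and Weber cone contrasts.

Chromaticity/luminance coordinates are converted to tristimulus values
(X = xY/y, Z = (1-x-y)Y/y) and mapped to L, M, S cone excitations with the
Smith-Pokorny fundamentals (on Judd-modified tristimulus values, L+M
normalized to luminance). Cone contrast against the background is the Weber
ratio (eps_stim - eps_bg) / eps_bg.

Note the S-cone normalization of the reference display calibration below does
not follow the common Smith-Pokorny scaling (its S values are far smaller), so
S excitations computed from xyY are not comparable to the calibrated ones;
L and M are.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Smith-Pokorny cone fundamentals matrix (rows L, M, S; columns X, Y, Z).
SMITH_POKORNY = np.array([
    [0.15514, 0.54312, -0.03286],
    [-0.15514, 0.45684, 0.03286],
    [0.0, 0.0, 0.01608],
])

#: Display calibration of the search stimuli: red/green singleton circles
#: rendered isoluminant at 2.8 cd/m^2 on a gray background, with the cone
#: excitations measured for the ideal human observer.
DISPLAY_CALIBRATION = {
    "red": {"xyY": (0.648, 0.331, 2.8), "lms": (2.37, 0.43, 0.0014)},
    "green": {"xyY": (0.321, 0.598, 2.8), "lms": (1.74, 1.06, 0.0030)},
    "background": {"xyY": None, "lms": (1.86, 0.94, 0.023)},
}


@dataclass
class ConeSpec:
    """Cone description of one stimulus."""

    name: str
    xyY: tuple[float, float, float] | None
    excitations: tuple[float, float, float]
    contrasts: tuple[float, float, float] | None = None


def xyY_to_lms(x: float, y: float, Y: float,
               matrix: np.ndarray | None = None) -> np.ndarray:
    """Cone excitations (L, M, S) from CIE chromaticity and luminance."""
    if y <= 0:
        raise ValueError("chromaticity y must be positive")
    m = SMITH_POKORNY if matrix is None else np.asarray(matrix, dtype=float)
    X = x * Y / y
    Z = (1.0 - x - y) * Y / y
    return m @ np.array([X, Y, Z], dtype=float)


def cone_contrast(eps_stim, eps_bg) -> np.ndarray:
    """Weber cone contrast of a stimulus against the background."""
    stim = np.asarray(eps_stim, dtype=float)
    bg = np.asarray(eps_bg, dtype=float)
    if np.any(bg <= 0):
        raise ValueError("background excitations must be positive")
    return (stim - bg) / bg


def contrast_report(stimuli: dict | None = None, decimals: int = 2
                    ) -> dict[str, ConeSpec]:
    """Cone excitations and rounded Weber contrasts for a stimulus set.

    ``stimuli`` follows the :data:`DISPLAY_CALIBRATION` layout and must contain
    a ``background`` entry with measured excitations.
    """
    stimuli = stimuli or DISPLAY_CALIBRATION
    bg = np.asarray(stimuli["background"]["lms"], dtype=float)
    out = {}
    for name, spec in stimuli.items():
        lms = np.asarray(spec["lms"], dtype=float)
        contrasts = (None if name == "background" else
                     tuple(np.round(cone_contrast(lms, bg), decimals)))
        out[name] = ConeSpec(name=name, xyY=spec.get("xyY"),
                             excitations=tuple(lms), contrasts=contrasts)
    return out
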