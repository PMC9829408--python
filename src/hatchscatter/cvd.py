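"""Color-vision-deficiency simulation and palette separability audit.

Implements the standard physiologically based simulation of anomalous
trichromacy (Machado-family 3x3 transfer matrices applied in linear-light
RGB) for deuteranomaly (green-weak), protanomaly (red-weak) and tritanomaly
(blue-yellow), plus rod monochromacy as a luma projection.  Severity in
[0, 1] interpolates between normal vision (identity) and the full
dichromatic matrix; every matrix preserves the gray axis (rows sum to 1).

The audit operationalizes "CVD-friendly": simulate a palette under a
deficiency and measure the minimum pairwise CIEDE2000 distance of the
result.  Applied to a rendered figure, simulation touches only colors —
segment geometry is untouched, which is the redundant-coding guarantee.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from skimage.color import deltaE_ciede2000, rgb2lab

from .errors import ParameterError

__all__ = [
    "DEFICIENCIES",
    "CvdTransform",
    "simulate_cvd",
    "simulate_palette",
    "palette_separation",
    "simulate_figure",
]

# Machado, Oliveira & Fernandes dichromacy matrices (severity 1.0),
# applied in linear RGB; rows sum to 1 so grays are fixed points.
_FULL = {
    "protanomaly": np.array(
        [
            [0.152286, 1.052583, -0.204868],
            [0.114503, 0.786281, 0.099216],
            [-0.003882, -0.048116, 1.051998],
        ]
    ),
    "deuteranomaly": np.array(
        [
            [0.367322, 0.860646, -0.227968],
            [0.280085, 0.672501, 0.047413],
            [-0.011820, 0.042940, 0.968881],
        ]
    ),
    "tritanomaly": np.array(
        [
            [1.255528, -0.076749, -0.178779],
            [-0.078411, 0.930809, 0.147602],
            [0.004733, 0.691367, 0.303900],
        ]
    ),
    # Rec. 709 luma weights, replicated to all channels: grayscale vision
    "monochromacy": np.tile([0.2126, 0.7152, 0.0722], (3, 1)),
}

DEFICIENCIES = tuple(_FULL)


@dataclass(frozen=True)
class CvdTransform:
    """A deficiency at a given severity, as a linear-RGB transfer matrix."""

    deficiency: str
    severity: float = 1.0

    def __post_init__(self):
        if self.deficiency not in _FULL:
            raise ParameterError(
                f"unknown deficiency {self.deficiency!r}; valid: {DEFICIENCIES}"
            )
        if not (0.0 <= self.severity <= 1.0):
            raise ParameterError("severity must lie in [0, 1]")

    @property
    def matrix(self) -> np.ndarray:
        s = self.severity
        return (1.0 - s) * np.eye(3) + s * _FULL[self.deficiency]


def _hex_to_rgb01(color: str) -> np.ndarray:
    c = str(color).lstrip("#")
    if len(c) != 6:
        raise ParameterError(f"expected #RRGGBB color, got {color!r}")
    return np.array([int(c[k : k + 2], 16) for k in (0, 2, 4)], dtype=float) / 255.0


def _rgb01_to_hex(rgb: np.ndarray) -> str:
    v = np.clip(np.round(np.asarray(rgb) * 255.0), 0, 255).astype(int)
    return "#%02X%02X%02X" % tuple(v)


def _srgb_to_linear(c: np.ndarray) -> np.ndarray:
    return np.where(c <= 0.04045, c / 12.92, ((c + 0.055) / 1.055) ** 2.4)


def _linear_to_srgb(c: np.ndarray) -> np.ndarray:
    c = np.clip(c, 0.0, 1.0)
    return np.where(c <= 0.0031308, 12.92 * c, 1.055 * c ** (1 / 2.4) - 0.055)


def simulate_cvd(color: str, deficiency: str, severity: float = 1.0) -> str:
    """Simulate how a hex color appears under a color-vision deficiency.

    The color is decoded to linear light, multiplied by the
    severity-interpolated transfer matrix, clamped to gamut and re-encoded.
    Severity 0 returns the input unchanged.
    """
    t = CvdTransform(deficiency, severity)
    lin = _srgb_to_linear(_hex_to_rgb01(color))
    return _rgb01_to_hex(_linear_to_srgb(t.matrix @ lin))


def simulate_palette(colors, deficiency: str, severity: float = 1.0) -> list:
    return [simulate_cvd(c, deficiency, severity) for c in colors]


def palette_separation(
    colors, deficiency: str | None = None, severity: float = 1.0
) -> float:
    """Minimum pairwise CIEDE2000 distance of a palette under simulation.

    With ``deficiency=None`` the palette is measured as-is.  A duplicated
    color yields 0; larger values mean every pair stays distinguishable.
    """
    colors = list(colors)
    if len(colors) < 2:
        raise ParameterError("palette separation needs at least 2 colors")
    if deficiency is not None:
        colors = simulate_palette(colors, deficiency, severity)
    rgb = np.array([_hex_to_rgb01(c) for c in colors])
    lab = rgb2lab(rgb.reshape(1, -1, 3)).reshape(-1, 3)
    best = np.inf
    for a, b in combinations(range(len(colors)), 2):
        d = float(deltaE_ciede2000(lab[a], lab[b]))
        best = min(best, d)
    return best


def simulate_figure(fig, deficiency: str, severity: float = 1.0):
    """Recolor a rendered figure as a CVD observer would see it.

    Only colors change; every segment's endpoints, count and style geometry
    are preserved bit-identically — the pattern channel survives even total
    color collapse (monochromacy).
    """
    return fig.recolor(lambda c: simulate_cvd(c, deficiency, severity))
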