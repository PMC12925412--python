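"""Cone-catch images -> analysis channels (Lum, X, Y, Sat).

Luminance is the mean of the long- and mid-wave catches.  The colour channels
are receptor-noise-limited (RNL) opponent coordinates in just-noticeable-
difference units: X opposes long vs mid wave ("red-green"), Y opposes short
wave vs the long/mid pair ("blue-yellow"), and Sat is the Euclidean distance
of (X, Y) from the achromatic point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from mothwing.synthetic_wings import CATCH_FLOOR, ConeCatchImage

__all__ = [
    "RNLParams",
    "ChannelStack",
    "compute_luminance",
    "rnl_chromaticity",
    "saturation",
    "convert_channels",
    "channel_means",
]

CHANNEL_NAMES = ("Lum", "X", "Y", "Sat")


@dataclass(frozen=True)
class RNLParams:
    """Per-receptor Weber fractions (noise-to-signal ratios).

    A single value of 0.05 for every receptor is the default; one RNL unit
    then corresponds to roughly one just-noticeable difference.
    """

    weber: tuple[float, float, float] = (0.05, 0.05, 0.05)

    def __post_init__(self) -> None:
        if len(self.weber) != 3 or any(w <= 0 for w in self.weber):
            raise ValueError("Weber fractions must be three positive values")


@dataclass
class ChannelStack:
    """Per-specimen analysis channels sharing one mask and scale."""

    Lum: np.ndarray
    X: np.ndarray
    Y: np.ndarray
    Sat: np.ndarray
    mask: np.ndarray
    px_per_cm: float

    def __post_init__(self) -> None:
        shapes = {self.Lum.shape, self.X.shape, self.Y.shape, self.Sat.shape, self.mask.shape}
        if len(shapes) != 1:
            raise ValueError("all channel maps and the mask must share one shape")

    def channel(self, name: str) -> np.ndarray:
        return getattr(self, name)


def compute_luminance(img: ConeCatchImage) -> np.ndarray:
    """Lum = (q_L + q_M) / 2, the mean of the first two receptor catches."""
    q = np.asarray(img.q, dtype=float)
    if np.any(q[:2][:, img.mask] <= 0):
        raise ValueError("non-positive cone catch inside mask")
    return (q[0] + q[1]) / 2.0


def rnl_chromaticity(
    img: ConeCatchImage, params: RNLParams | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Log-linear trichromatic RNL opponent coordinates (X, Y).

    With f_i = ln(q_i) and Weber fractions (wL, wM, wS):

        X = (f_L - f_M) / sqrt(wL^2 + wM^2)
        Y = (f_S - (wM^2 f_L + wL^2 f_M) / (wL^2 + wM^2))
            * sqrt((wL^2 + wM^2) / (wL^2 wM^2 + wL^2 wS^2 + wM^2 wS^2))

    Catches are floored at ``CATCH_FLOOR`` before the log; masked catches
    must be positive.
    """
    params = params or RNLParams()
    q = np.asarray(img.q, dtype=float)
    if np.any(q[:, img.mask] <= 0):
        raise ValueError("non-positive cone catch inside mask")
    wL, wM, wS = params.weber
    f = np.log(np.maximum(q, CATCH_FLOOR))
    fL, fM, fS = f[0], f[1], f[2]
    a, b, c = wL * wL, wM * wM, wS * wS
    X = (fL - fM) / np.sqrt(a + b)
    Y = (fS - (b * fL + a * fM) / (a + b)) * np.sqrt((a + b) / (a * b + a * c + b * c))
    return X, Y


def saturation(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Sat = sqrt(X^2 + Y^2), pixelwise distance from the achromatic point."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape:
        raise ValueError(f"shape mismatch: {X.shape} vs {Y.shape}")
    return np.hypot(X, Y)


def convert_channels(img: ConeCatchImage, params: RNLParams | None = None) -> ChannelStack:
    """Full conversion of a cone-catch image to the four analysis channels."""
    Lum = compute_luminance(img)
    X, Y = rnl_chromaticity(img, params)
    return ChannelStack(
        Lum=Lum, X=X, Y=Y, Sat=saturation(X, Y), mask=img.mask.copy(), px_per_cm=img.px_per_cm
    )


def channel_means(stack: ChannelStack) -> dict[str, float]:
    """Arithmetic mean of each channel over masked pixels only."""
    if not stack.mask.any():
        raise ValueError("empty mask")
    m = stack.mask
    return {name: float(stack.channel(name)[m].mean()) for name in CHANNEL_NAMES}
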