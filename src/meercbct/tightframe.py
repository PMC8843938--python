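"""Undecimated piecewise-linear B-spline framelet transform (2-D, 9 bands).

The 1-D filter bank is the piecewise-linear framelet

    h0 = (1, 2, 1)/4,   h1 = sqrt(2)/4 * (1, 0, -1),   h2 = (-1, 2, -1)/4,

whose frequency responses satisfy the unitary extension principle
sum_k |H_k|^2 = 1.  Applied separably with periodic boundary handling and no
downsampling, the nine-band analysis operator W is a tight frame with frame
constant one: W^T W = I and ||W x|| = ||x|| exactly.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = ["TightFrameOperator"]

_H0 = np.array([1.0, 2.0, 1.0]) / 4.0
_H1 = np.array([1.0, 0.0, -1.0]) * (np.sqrt(2.0) / 4.0)
_H2 = np.array([-1.0, 2.0, -1.0]) / 4.0


class TightFrameOperator:
    """Single-level translation-invariant framelet analysis/synthesis.

    ``analyze`` maps an image (ny, nx) to coefficients (9, ny, nx);
    ``synthesize`` is the exact adjoint (and, by tightness, the inverse).
    """

    levels = 1
    filter_bank = "piecewise-linear B-spline framelet"

    def __init__(self):
        one_d = [_H0, _H1, _H2]
        self.kernels = [np.outer(a, b) for a in one_d for b in one_d]

    @property
    def n_bands(self) -> int:
        return len(self.kernels)

    def analyze(self, image: np.ndarray) -> np.ndarray:
        img = np.asarray(image, dtype=float)
        if img.ndim != 2:
            raise ValueError("expected a 2-D image")
        return np.stack(
            [ndimage.correlate(img, k, mode="wrap") for k in self.kernels]
        )

    def synthesize(self, coeffs: np.ndarray) -> np.ndarray:
        c = np.asarray(coeffs, dtype=float)
        if c.ndim != 3 or c.shape[0] != self.n_bands:
            raise ValueError(f"expected ({self.n_bands}, ny, nx) coefficients")
        out = np.zeros(c.shape[1:])
        for band, k in zip(c, self.kernels):
            out += ndimage.correlate(band, k[::-1, ::-1], mode="wrap")
        return out
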