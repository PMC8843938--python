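"""Fan-beam scan geometry, Siddon system matrix, and filtered back projection.

Conventions
-----------
All lengths are centimetres and attenuation coefficients are cm^-1, so line
integrals (sinogram values) are dimensionless.  The reconstruction slice is
the central axial plane of an axially uniform phantom; the detector is an
equiangular arc centred on the source.  Pixel (row, col) maps to world
coordinates ``x = (col - (nc-1)/2) * h`` and ``y = (row - (nr-1)/2) * h``
with the isocenter at the grid centre.  The source for view angle ``beta``
sits at ``SAD * (cos beta, sin beta)`` and ray ``k`` leaves the source at
angle ``beta + pi + gamma_k`` where ``gamma_k`` is the (signed, CCW
positive) fan angle of detector bin ``k``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

__all__ = [
    "ScanGeometry",
    "SystemMatrix",
    "build_system_matrix",
    "forward_project",
    "fbp_reconstruct",
    "AngularCoverageWarning",
]


class AngularCoverageWarning(UserWarning):
    """Raised (as a warning) when FBP input does not cover a full rotation."""


def _default_angles(n_views: int) -> np.ndarray:
    return np.arange(n_views) * (2.0 * np.pi / n_views)


@dataclass(frozen=True)
class ScanGeometry:
    """Circular fan-beam scan geometry (mm units).

    Parameters
    ----------
    source_to_isocenter, source_to_detector:
        Source-axis and source-detector distances in cm.
    n_views:
        Number of projection views over a full rotation.
    image_shape:
        ``(n_rows, n_cols)`` of the reconstruction grid.
    pixel_size:
        Pixel pitch in cm.
    n_detector_bins:
        Number of equiangular detector bins; defaults to ``2 * max(image_shape)``.
    detector_span:
        Total detector arc length (cm, at the detector); defaults to twice the
        grid diagonal, which comfortably covers the reconstruction circle.
    view_angles:
        Ascending gantry angles in radians; defaults to uniform over [0, 2pi).
    """

    source_to_isocenter: float = 100.0
    source_to_detector: float = 150.0
    n_views: int = 600
    image_shape: tuple[int, int] = (256, 256)
    pixel_size: float = 0.1  # 1 mm pixels (cm units)
    n_detector_bins: int | None = None
    detector_span: float | None = None
    view_angles: np.ndarray | None = None

    def __post_init__(self):
        if not (self.source_to_detector > self.source_to_isocenter > 0):
            raise ValueError(
                "require source_to_detector > source_to_isocenter > 0, got "
                f"{self.source_to_detector} and {self.source_to_isocenter}"
            )
        if self.pixel_size <= 0:
            raise ValueError(f"pixel size must be positive, got {self.pixel_size}")
        if self.n_views < 1:
            raise ValueError("need at least one view")
        nr, nc = self.image_shape
        if nr < 1 or nc < 1:
            raise ValueError(f"bad image_shape {self.image_shape}")
        if self.n_detector_bins is None:
            object.__setattr__(self, "n_detector_bins", 2 * max(nr, nc))
        if self.detector_span is None:
            diag = float(np.hypot(nr, nc)) * self.pixel_size
            object.__setattr__(self, "detector_span", 2.0 * diag)
        if self.view_angles is None:
            object.__setattr__(self, "view_angles", _default_angles(self.n_views))
        angles = np.asarray(self.view_angles, dtype=float)
        object.__setattr__(self, "view_angles", angles)
        if angles.shape != (self.n_views,):
            raise ValueError("view_angles length must equal n_views")
        if self.n_views > 1 and np.any(np.diff(angles) <= 0):
            raise ValueError("view_angles must be strictly increasing")

    # -- derived quantities ------------------------------------------------
    @property
    def n_pixels(self) -> int:
        return self.image_shape[0] * self.image_shape[1]

    @property
    def delta_gamma(self) -> float:
        """Fan-angle increment between detector bins (radians)."""
        return self.detector_bin_width / self.source_to_detector

    @property
    def detector_bin_width(self) -> float:
        """Arc length of one detector bin at the detector (cm)."""
        return self.detector_span / self.n_detector_bins

    @property
    def fan_angles(self) -> np.ndarray:
        """Signed fan angle of each detector bin centre (radians)."""
        k = np.arange(self.n_detector_bins)
        return (k - (self.n_detector_bins - 1) / 2.0) * self.delta_gamma

    def pixel_edges(self) -> tuple[np.ndarray, np.ndarray]:
        nr, nc = self.image_shape
        h = self.pixel_size
        x_edges = (np.arange(nc + 1) - nc / 2.0) * h
        y_edges = (np.arange(nr + 1) - nr / 2.0) * h
        return x_edges, y_edges

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        nr, nc = self.image_shape
        h = self.pixel_size
        x = (np.arange(nc) - (nc - 1) / 2.0) * h
        y = (np.arange(nr) - (nr - 1) / 2.0) * h
        return x, y


@dataclass
class SystemMatrix:
    """Sparse ray-tracing projector for a subset of views.

    ``matrix`` maps a flattened image (cm^-1) to line integrals
    (dimensionless); entries are exact ray-pixel intersection lengths in cm.
    """

    matrix: sparse.csr_matrix
    geometry: ScanGeometry
    views: np.ndarray
    n_detector_bins: int = field(init=False)

    def __post_init__(self):
        self.views = np.asarray(self.views, dtype=int)
        self.n_detector_bins = self.geometry.n_detector_bins

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    @property
    def angles(self) -> np.ndarray:
        return self.geometry.view_angles[self.views]

    def apply(self, image: np.ndarray) -> np.ndarray:
        """Forward project; returns a (n_views_subset, n_bins) block."""
        img = np.asarray(image, dtype=float)
        if img.shape != self.geometry.image_shape:
            raise ValueError(
                f"image shape {img.shape} does not match grid {self.geometry.image_shape}"
            )
        out = self.matrix @ img.ravel()
        return out.reshape(len(self.views), self.n_detector_bins)

    def adjoint_apply(self, sino_block: np.ndarray) -> np.ndarray:
        """Back project (unfiltered adjoint); returns an image."""
        s = np.asarray(sino_block, dtype=float)
        expect = (len(self.views), self.n_detector_bins)
        if s.shape != expect:
            raise ValueError(f"sinogram block shape {s.shape}, expected {expect}")
        img = self.matrix.T @ s.ravel()
        return img.reshape(self.geometry.image_shape)


def _siddon_one_view(geometry: ScanGeometry, beta: float):
    """Exact intersection lengths of all rays of one view with the pixel grid.

    Returns (ray_index, pixel_index, length_cm) arrays.
    """
    sad = geometry.source_to_isocenter
    sx, sy = sad * np.cos(beta), sad * np.sin(beta)
    theta = beta + np.pi + geometry.fan_angles
    dx, dy = np.cos(theta), np.sin(theta)
    x_edges, y_edges = geometry.pixel_edges()
    nb = geometry.n_detector_bins
    nr, nc = geometry.image_shape
    h = geometry.pixel_size

    def axis_crossings(s0, d, edges):
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (edges[None, :] - s0) / d[:, None]
        par = np.abs(d) < 1e-12
        if np.any(par):
            inside = (s0 >= edges[0]) & (s0 <= edges[-1])
            # parallel rays: planes impose no finite crossings
            t[par] = np.nan
            lo = np.where(par & inside, -np.inf, np.minimum(t[:, 0], t[:, -1]))
            hi = np.where(par & inside, np.inf, np.maximum(t[:, 0], t[:, -1]))
            lo = np.where(par & ~inside, np.inf, lo)
            hi = np.where(par & ~inside, -np.inf, hi)
        else:
            lo = np.minimum(t[:, 0], t[:, -1])
            hi = np.maximum(t[:, 0], t[:, -1])
        return t, lo, hi

    tx, lox, hix = axis_crossings(sx, dx, x_edges)
    ty, loy, hiy = axis_crossings(sy, dy, y_edges)
    t_enter = np.maximum(np.maximum(lox, loy), 0.0)
    t_exit = np.minimum(hix, hiy)
    hit = t_exit > t_enter + 1e-12

    t_all = np.concatenate(
        [tx, ty, t_enter[:, None], t_exit[:, None]], axis=1
    )
    t_all = np.where(np.isnan(t_all), t_enter[:, None], t_all)
    np.clip(t_all, t_enter[:, None], t_exit[:, None], out=t_all)
    t_all.sort(axis=1)
    seg = np.diff(t_all, axis=1)
    t_mid = 0.5 * (t_all[:, :-1] + t_all[:, 1:])
    xm = sx + t_mid * dx[:, None]
    ym = sy + t_mid * dy[:, None]
    ix = np.clip(np.floor((xm - x_edges[0]) / h).astype(np.int64), 0, nc - 1)
    iy = np.clip(np.floor((ym - y_edges[0]) / h).astype(np.int64), 0, nr - 1)
    keep = (seg > 1e-9) & hit[:, None]
    rows = np.broadcast_to(np.arange(nb)[:, None], seg.shape)[keep]
    cols = (iy * nc + ix)[keep]
    vals = seg[keep]
    return rows, cols, vals


def build_system_matrix(
    geometry: ScanGeometry, views: np.ndarray | None = None
) -> SystemMatrix:
    """Build the Siddon ray-tracing projection matrix for the given views.

    ``views`` is a sequence of view indices into ``geometry.view_angles``;
    ``None`` means all views.  Rows are ordered view-major in the order given,
    bins fastest, so restricting to a channel's views and stacking over
    channels reproduces exactly the rows of the full-scan matrix.
    """
    if views is None:
        views = np.arange(geometry.n_views)
    views = np.asarray(views, dtype=int)
    if views.size == 0:
        raise ValueError("empty view set")
    nb = geometry.n_detector_bins
    rows_all, cols_all, vals_all = [], [], []
    for j, v in enumerate(views):
        r, c, w = _siddon_one_view(geometry, float(geometry.view_angles[v]))
        rows_all.append(r + j * nb)
        cols_all.append(c)
        vals_all.append(w)
    mat = sparse.coo_matrix(
        (
            np.concatenate(vals_all),
            (np.concatenate(rows_all), np.concatenate(cols_all)),
        ),
        shape=(len(views) * nb, geometry.n_pixels),
    ).tocsr()
    return SystemMatrix(matrix=mat, geometry=geometry, views=views)


def forward_project(image: np.ndarray, system_matrix: SystemMatrix) -> np.ndarray:
    """Line integrals (view x bin block) of a single-channel image."""
    return system_matrix.apply(image)


def _ramp_kernel(nb: int, delta_gamma: float) -> np.ndarray:
    """Discrete equiangular fan-beam ramp kernel g(n * dgamma).

    The parallel-beam ramp kernel with the ``(n dg / sin(n dg))^2``
    equiangular correction folded in: 1/(8 dg^2) at n = 0, zero for even n,
    and -1 / (2 pi^2 sin^2(n dg)) for odd n.
    """
    n = np.arange(-(nb - 1), nb)
    g = np.zeros(n.shape)
    g[n == 0] = 1.0 / (8.0 * delta_gamma**2)
    odd = (n % 2) != 0
    g[odd] = -0.5 / (np.pi**2 * np.sin(n[odd] * delta_gamma) ** 2)
    return g


def _filter_projections(q: np.ndarray, delta_gamma: float, filter_name: str) -> np.ndarray:
    """Convolve cosine-weighted projections with the ramp kernel via FFT."""
    nv, nb = q.shape
    g = _ramp_kernel(nb, delta_gamma)
    size = int(2 ** np.ceil(np.log2(2 * nb)))  # zero-pad to next power of two
    G = np.fft.rfft(g, size)
    if filter_name == "hann":
        freq = np.arange(G.size) / G.size
        G = G * (0.5 + 0.5 * np.cos(np.pi * np.minimum(freq / 0.5, 1.0)))
    elif filter_name != "ramp":
        raise ValueError(f"unknown filter {filter_name!r}; use 'ramp' or 'hann'")
    Q = np.fft.irfft(np.fft.rfft(q, size) * G[None, :], size)[:, nb - 1 : 2 * nb - 1]
    return delta_gamma * Q


def fbp_reconstruct(
    sinogram: np.ndarray,
    geometry: ScanGeometry,
    views: np.ndarray | None = None,
    filter_name: str = "ramp",
) -> np.ndarray:
    """Equiangular fan-beam filtered back projection.

    ``sinogram`` is a (n_views_subset, n_bins) block of line integrals whose
    rows correspond to ``views`` (all views when ``None``).  Returns the
    attenuation image in cm^-1.  Emits :class:`AngularCoverageWarning` when
    the views do not cover a full rotation.
    """
    if views is None:
        views = np.arange(geometry.n_views)
    views = np.asarray(views, dtype=int)
    sino = np.asarray(sinogram, dtype=float)
    nb = geometry.n_detector_bins
    if sino.shape != (len(views), nb):
        raise ValueError(
            f"sinogram shape {sino.shape}, expected {(len(views), nb)}"
        )
    angles = geometry.view_angles[views]
    if len(angles) > 1:
        span = (angles[-1] - angles[0]) + np.mean(np.diff(angles))
        if span < 2.0 * np.pi - 0.05:
            warnings.warn(
                f"views cover only {span:.3f} rad (< 2 pi); FBP will be inaccurate",
                AngularCoverageWarning,
                stacklevel=2,
            )

    sad = geometry.source_to_isocenter
    gamma = geometry.fan_angles
    q = sino * (sad * np.cos(gamma))[None, :]
    Q = _filter_projections(q, geometry.delta_gamma, filter_name)

    xs, ys = geometry.pixel_centers()
    X, Y = np.meshgrid(xs, ys)
    recon = np.zeros(geometry.image_shape)
    if len(angles) > 1:
        dbeta = np.mean(np.diff(angles))
    else:
        dbeta = 2.0 * np.pi
    for i, beta in enumerate(angles):
        sx, sy = sad * np.cos(beta), sad * np.sin(beta)
        vx, vy = X - sx, Y - sy
        L2 = vx * vx + vy * vy
        cx, cy = -np.cos(beta), -np.sin(beta)  # central-ray direction
        along = vx * cx + vy * cy
        cross = cx * vy - cy * vx
        gamma_p = np.arctan2(cross, along)
        recon += np.interp(gamma_p, gamma, Q[i], left=0.0, right=0.0) / L2
    return recon * dbeta
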