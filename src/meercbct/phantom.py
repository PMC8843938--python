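"""Digital nine-insert iodine phantom.

A 20 cm water cylinder holds nine 3 cm inserts: one at the centre (pure
water) and eight evenly spaced with centres on a 7.5 cm circle, filled with
dilutions of a 175 mgI/ml iodine stock.  Concentrations are expressed as the
dilution fraction of the stock, so a 2.5% insert carries 4.375 mgI/ml.
The background of the digital phantom is water.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import ScanGeometry
from .spectral import WATER, Material, iodine_solution
from .dictionary import MaterialDictionary

__all__ = ["DigitalPhantom", "build_insert_phantom", "DEFAULT_CONCENTRATIONS"]

#: stock-dilution fractions of the eight peripheral inserts
DEFAULT_CONCENTRATIONS = (0.001, 0.005, 0.010, 0.015, 0.020, 0.030, 0.050, 0.10)

BODY_RADIUS_CM = 10.0
RING_RADIUS_CM = 7.5
INSERT_RADIUS_CM = 1.5


@dataclass
class DigitalPhantom:
    """Voxelized phantom: label map plus per-label material ground truth.

    Label 0 is air outside the body, 1 the water body, 2 the central water
    insert, and 3..10 the peripheral inserts in the order of
    ``concentrations``.
    """

    label_map: np.ndarray
    pixel_size: float
    materials: dict[int, Material | None]
    concentrations: tuple[float, ...]
    stock_mg_per_ml: float
    insert_centers_cm: list[tuple[float, float]] = field(default_factory=list)
    insert_radius_cm: float = INSERT_RADIUS_CM

    @property
    def shape(self) -> tuple[int, int]:
        return self.label_map.shape

    @property
    def n_pixels(self) -> int:
        return self.label_map.size

    @property
    def insert_labels(self) -> list[int]:
        """Labels of the nine inserts (central water first)."""
        return [2] + [3 + i for i in range(len(self.concentrations))]

    def _per_label(self, fn, default=0.0) -> np.ndarray:
        out = np.full(self.shape, default, dtype=float)
        for lab, mat in self.materials.items():
            if mat is not None:
                out[self.label_map == lab] = fn(mat)
        return out

    @property
    def mass_density_map(self) -> np.ndarray:
        """g/cm^3."""
        return self._per_label(lambda m: m.density)

    @property
    def rho_map(self) -> np.ndarray:
        """Relative electron density (water = 1)."""
        return self._per_label(lambda m: m.relative_electron_density)

    @property
    def lam_map(self) -> np.ndarray:
        """(ny, nx, 3) mass fractions over (H, O, I); water rows in air."""
        out = np.zeros(self.shape + (3,))
        out[..., :2] = [WATER.composition["H"], WATER.composition["O"]]
        for lab, mat in self.materials.items():
            if mat is not None:
                out[self.label_map == lab] = mat.hoi_fractions
        return out

    @property
    def iodine_density_map(self) -> np.ndarray:
        """Ground-truth iodine density in mg/ml."""
        return self._per_label(
            lambda m: 1000.0 * m.density * m.composition.get("I", 0.0)
        )

    def insert_iodine_mg_per_ml(self) -> np.ndarray:
        """Ground-truth iodine density of the eight peripheral inserts."""
        return np.array([c * self.stock_mg_per_ml for c in self.concentrations])

    def elemental_density_maps(self) -> dict[str, np.ndarray]:
        """Per-element mass density maps (g/cm^3) for ray tracing."""
        symbols = set()
        for mat in self.materials.values():
            if mat is not None:
                symbols |= set(mat.composition)
        maps = {}
        for el in sorted(symbols):
            maps[el] = self._per_label(
                lambda m, el=el: m.density * m.composition.get(el, 0.0)
            )
        return maps

    def true_X(self, dictionary: MaterialDictionary) -> np.ndarray:
        """Ground-truth convexified coefficient matrix X = rho * V (M, E).

        Each solution voxel is represented as the mass-fraction mixture of
        the dictionary's water and pure-iodine entries, scaled by its
        relative electron density; air rows are zero.
        """
        M = self.n_pixels
        X = np.zeros((M, dictionary.n_materials))
        iw, ii = dictionary.water_index, dictionary.iodine_index
        labels = self.label_map.ravel()
        for lab, mat in self.materials.items():
            if mat is None:
                continue
            w_i = mat.composition.get("I", 0.0)
            rho = mat.relative_electron_density
            sel = labels == lab
            X[sel, iw] = rho * (1.0 - w_i)
            X[sel, ii] = rho * w_i
        return X


def build_insert_phantom(
    geometry: ScanGeometry,
    concentrations: tuple[float, ...] = DEFAULT_CONCENTRATIONS,
    stock_mg_per_ml: float = 175.0,
    body_radius_cm: float = BODY_RADIUS_CM,
    ring_radius_cm: float = RING_RADIUS_CM,
    insert_radius_cm: float = INSERT_RADIUS_CM,
) -> DigitalPhantom:
    """Voxelize the nine-insert cylinder onto the reconstruction grid."""
    for c in concentrations:
        if not 0.0 <= c <= 1.0:
            raise ValueError(f"concentration {c} outside [0, 1]")
    n_ins = len(concentrations)
    if n_ins:
        half_sep = ring_radius_cm * np.sin(np.pi / n_ins)
        if half_sep < insert_radius_cm and n_ins > 1:
            raise ValueError("peripheral inserts overlap with this geometry")
    if ring_radius_cm - insert_radius_cm < insert_radius_cm:
        raise ValueError("peripheral inserts overlap the central insert")
    if ring_radius_cm + insert_radius_cm > body_radius_cm:
        raise ValueError("inserts extend outside the phantom body")

    xs, ys = geometry.pixel_centers()
    X, Y = np.meshgrid(xs, ys)
    labels = np.zeros(geometry.image_shape, dtype=np.int32)
    labels[X**2 + Y**2 <= body_radius_cm**2] = 1
    labels[X**2 + Y**2 <= insert_radius_cm**2] = 2

    centers = []
    for i in range(n_ins):
        ang = 2.0 * np.pi * i / n_ins
        cx, cy = ring_radius_cm * np.cos(ang), ring_radius_cm * np.sin(ang)
        centers.append((cx, cy))
        labels[(X - cx) ** 2 + (Y - cy) ** 2 <= insert_radius_cm**2] = 3 + i

    materials: dict[int, Material | None] = {0: None, 1: WATER, 2: WATER}
    for i, c in enumerate(concentrations):
        materials[3 + i] = iodine_solution(c, stock_mg_per_ml)

    return DigitalPhantom(
        label_map=labels,
        pixel_size=geometry.pixel_size,
        materials=materials,
        concentrations=tuple(concentrations),
        stock_mg_per_ml=stock_mg_per_ml,
        insert_centers_cm=[(0.0, 0.0)] + centers,
        insert_radius_cm=insert_radius_cm,
    )
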