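"""Elemental-composition dictionary of human soft tissues plus pure iodine.

With the three-element (H, O, I) basis, each tissue's full composition is
reduced by renormalizing its H and O mass fractions to sum to one (carbon,
nitrogen and trace elements are folded into the H/O balance).  This keeps
the hard model constraint that per-voxel element fractions sum to unity.
Calcium-bearing tissues are excluded: the dictionary targets soft tissue
where contrast agent accumulates.

The packaged table holds ~20 representative soft tissues; users may supply
a larger table (CSV with columns name, h_mass_fraction, o_mass_fraction,
nominal_red) in the same format.
"""

from __future__ import annotations

import csv
import importlib.resources
import json
from dataclasses import dataclass

import numpy as np

from .spectral import (
    HOI_Z,
    PE_EXPONENT,
    RAYLEIGH_EXPONENT,
    AttenuationModelParams,
)

__all__ = [
    "TissueEntry",
    "MaterialDictionary",
    "KMatrices",
    "load_tissue_table",
    "build_dictionary",
    "compute_K_matrices",
]

IODINE_NAME = "iodine_pure"


@dataclass(frozen=True)
class TissueEntry:
    name: str
    h_fraction: float
    o_fraction: float
    nominal_red: float


def load_tissue_table(path=None) -> list[TissueEntry]:
    """Read a tissue table CSV; defaults to the packaged representative set."""
    if path is None:
        path = importlib.resources.files("meercbct") / "data" / "tissues.csv"
        fh = path.open()
    else:
        fh = open(path)
    with fh:
        entries = [
            TissueEntry(
                rec["name"],
                float(rec["h_mass_fraction"]),
                float(rec["o_mass_fraction"]),
                float(rec["nominal_red"]),
            )
            for rec in csv.DictReader(fh)
        ]
    return entries


@dataclass(frozen=True)
class MaterialDictionary:
    """Named materials with their (H, O, I) mass-fraction rows Lambda."""

    names: tuple[str, ...]
    Lambda: np.ndarray  # (E, 3)
    z: np.ndarray = None  # atomic numbers (1, 8, 53)

    def __post_init__(self):
        if self.z is None:
            object.__setattr__(self, "z", HOI_Z.copy())
        lam = np.asarray(self.Lambda, dtype=float)
        object.__setattr__(self, "Lambda", lam)
        if lam.shape != (len(self.names), 3):
            raise ValueError("Lambda must be (n_materials, 3)")
        if np.any(np.abs(lam.sum(axis=1) - 1.0) > 1e-12):
            raise ValueError("every dictionary row must sum to 1")
        if np.any((lam < 0) | (lam > 1)):
            raise ValueError("dictionary fractions must lie in [0, 1]")

    @property
    def n_materials(self) -> int:
        return len(self.names)

    @property
    def iodine_index(self) -> int:
        return self.names.index(IODINE_NAME)

    @property
    def water_index(self) -> int:
        return self.names.index("water")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "names": list(self.names),
                    "Lambda": self.Lambda.tolist(),
                    "z": self.z.tolist(),
                },
                fh,
                indent=1,
            )


def build_dictionary(
    tissue_table: list[TissueEntry] | None = None, include_iodine: bool = True
) -> MaterialDictionary:
    """Build the dictionary from a tissue table, optionally appending iodine.

    Tissue H/O fractions are renormalized to sum to 1; the iodine entry is
    the row (0, 0, 1).
    """
    if tissue_table is None:
        tissue_table = load_tissue_table()
    names, rows = [], []
    for t in tissue_table:
        tot = t.h_fraction + t.o_fraction
        if tot <= 0:
            raise ValueError(f"tissue {t.name!r} has zero H+O mass fraction")
        names.append(t.name)
        rows.append([t.h_fraction / tot, t.o_fraction / tot, 0.0])
    if include_iodine:
        names.append(IODINE_NAME)
        rows.append([0.0, 0.0, 1.0])
    return MaterialDictionary(names=tuple(names), Lambda=np.array(rows))


@dataclass(frozen=True)
class KMatrices:
    """Derived model matrices for a dictionary and calibrated parameters.

    ``K[d, i] = k_i^PE z_d^3.62 + k_i^R z_d^1.86``; ``k_c_row`` is the
    common Compton row shared by every row of the rank-one K_MC (M x N) and
    K_EC (E x N) matrices; ``A = Lambda K + K_EC`` is the (E, N) operator of
    the decomposition subproblem.
    """

    K: np.ndarray
    k_c_row: np.ndarray
    A: np.ndarray

    @property
    def n_channels(self) -> int:
        return self.K.shape[1]

    def K_MC(self, m_pixels: int) -> np.ndarray:
        """Materialized rank-one M x N Compton matrix."""
        return np.tile(self.k_c_row, (m_pixels, 1))

    def K_EC(self) -> np.ndarray:
        return np.tile(self.k_c_row, (self.A.shape[0], 1))


def compute_K_matrices(
    dictionary: MaterialDictionary, params: AttenuationModelParams
) -> KMatrices:
    """Assemble K, the Compton row, and A = Lambda K + K_EC."""
    z = dictionary.z
    K = np.outer(z**PE_EXPONENT, params.k_pe) + np.outer(
        z**RAYLEIGH_EXPONENT, params.k_rayleigh
    )
    k_c = params.k_compton.copy()
    A = dictionary.Lambda @ K + k_c[None, :]
    return KMatrices(K=K, k_c_row=k_c, A=A)
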