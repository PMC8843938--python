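"""X-ray spectra, elemental attenuation data, the empirical per-channel
attenuation model, scanner calibration, and HU conversion.

The tube spectrum is a filtered Kramers bremsstrahlung model (no
characteristic lines); elemental mass attenuation coefficients are compact
embedded reference tables (cm^2/g) interpolated log-log, with the iodine
K-edge at 33.17 keV represented by a table breakpoint.  Effective (fluence
averaged) linear attenuation is returned in cm^-1, consistent with the
projector's cm length convention.

The empirical decomposition model expresses the channel-i attenuation of a
voxel with relative electron density ``rho`` and elemental mass fractions
``lam`` over (H, O, I) as

    f_i = rho * (k_i^PE * sum_d lam_d z_d^3.62
                 + k_i^R * sum_d lam_d z_d^1.86 + k_i^C),

absorbing the channel's spectral shape into the three scanner-specific
coefficients (photoelectric, Rayleigh, Compton).  The exponents 3.62 and
1.86 are fixed constants of the model.
"""

from __future__ import annotations

import csv
import importlib.resources
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

__all__ = [
    "ELEMENTS",
    "PE_EXPONENT",
    "RAYLEIGH_EXPONENT",
    "WATER_COMPOSITION",
    "WATER_ELECTRONS_PER_GRAM_MOL",
    "Material",
    "Spectrum",
    "AttenuationModelParams",
    "ScannerCalibration",
    "mass_attenuation",
    "generate_spectrum",
    "effective_channel_attenuation",
    "mu_to_hu",
    "attenuation_from_composition",
    "calibrate_model",
    "calibrate_from_spectra",
    "harden_spectrum",
    "water_equivalent_transfer",
    "iodine_solution",
    "default_calibration_materials",
]

PE_EXPONENT = 3.62
RAYLEIGH_EXPONENT = 1.86

#: symbol -> (atomic number Z, atomic mass A in g/mol)
ELEMENTS: dict[str, tuple[int, float]] = {
    "H": (1, 1.008),
    "C": (6, 12.011),
    "N": (7, 14.007),
    "O": (8, 15.999),
    "Al": (13, 26.982),
    "Cl": (17, 35.453),
    "I": (53, 126.904),
}

WATER_COMPOSITION = {"H": 0.111894, "O": 0.888106}
#: mol of electrons per gram of water
WATER_ELECTRONS_PER_GRAM_MOL = sum(
    w * ELEMENTS[e][0] / ELEMENTS[e][1] for e, w in WATER_COMPOSITION.items()
)
#: atomic numbers of the modelled elements (H, O, I)
HOI_Z = np.array([1.0, 8.0, 53.0])
HOI_A = np.array([ELEMENTS["H"][1], ELEMENTS["O"][1], ELEMENTS["I"][1]])


@lru_cache(maxsize=1)
def _attenuation_tables() -> dict[str, tuple[np.ndarray, np.ndarray]]:
    path = importlib.resources.files("meercbct") / "data" / "elemental_mass_attenuation.csv"
    rows: dict[str, list[tuple[float, float]]] = {}
    with path.open() as fh:
        for rec in csv.DictReader(fh):
            rows.setdefault(rec["element"], []).append(
                (float(rec["energy_keV"]), float(rec["mu_over_rho_cm2_g"]))
            )
    out = {}
    for el, pairs in rows.items():
        pairs.sort()
        e = np.array([p[0] for p in pairs])
        v = np.array([p[1] for p in pairs])
        out[el] = (e, v)
    return out


def mass_attenuation(element: str, energies_kev: np.ndarray) -> np.ndarray:
    """Mass attenuation coefficient (cm^2/g) at the given energies (keV).

    Log-log interpolation between table breakpoints; the duplicated
    energies around the iodine K-edge keep the discontinuity sharp.
    """
    tables = _attenuation_tables()
    if element not in tables:
        raise KeyError(
            f"no attenuation table for element {element!r}; "
            f"available: {sorted(tables)}"
        )
    e_tab, v_tab = tables[element]
    e = np.atleast_1d(np.asarray(energies_kev, dtype=float))
    if np.any(e < e_tab[0]) or np.any(e > e_tab[-1]):
        raise ValueError(
            f"energy outside tabulated range [{e_tab[0]}, {e_tab[-1]}] keV"
        )
    out = np.exp(np.interp(np.log(e), np.log(e_tab), np.log(v_tab)))
    return out if np.ndim(energies_kev) else float(out[0])


@dataclass(frozen=True)
class Material:
    """A bulk material: elemental mass fractions and mass density (g/cm^3)."""

    name: str
    composition: dict[str, float]
    density: float

    def __post_init__(self):
        tot = sum(self.composition.values())
        if abs(tot - 1.0) > 1e-6:
            raise ValueError(
                f"{self.name}: mass fractions sum to {tot}, expected 1"
            )
        for el in self.composition:
            if el not in ELEMENTS:
                raise KeyError(f"{self.name}: unknown element symbol {el!r}")

    @property
    def relative_electron_density(self) -> float:
        """Electron density relative to water (water density 1.0 g/cm^3)."""
        mol_e_per_g = sum(
            w * ELEMENTS[e][0] / ELEMENTS[e][1] for e, w in self.composition.items()
        )
        return self.density * mol_e_per_g / WATER_ELECTRONS_PER_GRAM_MOL

    @property
    def hoi_fractions(self) -> np.ndarray:
        """Mass fractions over (H, O, I) only; raises if other elements present."""
        extra = set(self.composition) - {"H", "O", "I"}
        if extra:
            raise ValueError(
                f"{self.name} contains elements {sorted(extra)} outside the "
                "(H, O, I) model basis"
            )
        lam = np.array([self.composition.get(e, 0.0) for e in ("H", "O", "I")])
        return lam / lam.sum()


WATER = Material("water", dict(WATER_COMPOSITION), 1.0)


def iodine_solution(stock_fraction: float, stock_mg_per_ml: float = 175.0) -> Material:
    """Water-based iodine solution at the given dilution of the iodine stock.

    ``stock_fraction`` is the fraction of the 175 mgI/ml stock (0.025 means a
    2.5% dilution, i.e. 4.375 mgI/ml).  The solution is modelled as one cm^3
    of water plus the added iodine mass, neglecting volume change.
    """
    if not 0.0 <= stock_fraction <= 1.0:
        raise ValueError(f"stock fraction must be in [0, 1], got {stock_fraction}")
    d_i = stock_fraction * stock_mg_per_ml / 1000.0  # g iodine per cm^3
    density = 1.0 + d_i
    w_i = d_i / density
    comp = {
        "H": WATER_COMPOSITION["H"] / density,
        "O": WATER_COMPOSITION["O"] / density,
    }
    if w_i > 0:
        comp["I"] = w_i
    name = f"iodine_{100 * stock_fraction:g}pct" if stock_fraction else "water"
    return Material(name, comp, density)


@dataclass(frozen=True)
class Spectrum:
    """Normalized polyenergetic photon-fluence spectrum of one kVp channel."""

    kvp: float
    energies_kev: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0):
            raise ValueError("negative fluence weight")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("weights must be normalized to sum 1")
        if np.any(np.asarray(self.energies_kev) > self.kvp + 1e-9):
            raise ValueError("spectrum extends above the kVp endpoint")

    @property
    def mean_energy(self) -> float:
        return float(np.sum(self.energies_kev * self.weights))


E_MIN_KEV = 10.0
AL_DENSITY = 2.699  # g/cm^3


#: default added filtration; chosen so effective water attenuation of the
#: 80-120 kVp channels lies in the physically expected 0.15-0.30 cm^-1 range
DEFAULT_FILTRATION_MM_AL = 6.0


def generate_spectrum(
    kvp: float, filtration_mm_al: float = DEFAULT_FILTRATION_MM_AL
) -> Spectrum:
    """Filtered Kramers bremsstrahlung spectrum on a 1 keV grid.

    Photon fluence per keV is proportional to ``(kvp - E) / E`` attenuated by
    the aluminium filtration; energies below 10 keV are omitted (fully
    absorbed by any realistic filtration).
    """
    if not 40.0 <= kvp <= 150.0:
        raise ValueError(f"kvp {kvp} outside supported range [40, 150]")
    energies = np.arange(E_MIN_KEV, kvp + 0.5, 1.0)
    energies = energies[energies <= kvp]
    fluence = (kvp - energies) / energies
    mu_al = mass_attenuation("Al", energies) * AL_DENSITY  # cm^-1
    fluence = fluence * np.exp(-mu_al * filtration_mm_al / 10.0)
    total = fluence.sum()
    if total <= 0:
        raise ValueError("spectrum empty after filtration")
    return Spectrum(kvp=kvp, energies_kev=energies, weights=fluence / total)


def effective_channel_attenuation(material: Material, spectrum: Spectrum) -> float:
    """Fluence-weighted linear attenuation (cm^-1) of a material in a channel.

    Thin-object linearization: sum_E w(E) * rho_m * sum_e c_e (mu/rho)_e(E).
    """
    mu_rho = np.zeros_like(spectrum.energies_kev)
    for el, w in material.composition.items():
        mu_rho = mu_rho + w * mass_attenuation(el, spectrum.energies_kev)
    return material.density * float(np.sum(spectrum.weights * mu_rho))


def mu_to_hu(image: np.ndarray, water_reference: float | np.ndarray) -> np.ndarray:
    """Hounsfield conversion 1000 * (mu - mu_water) / mu_water.

    ``water_reference`` is scalar for a single channel or a length-N vector
    broadcast over the last axis of a multi-channel image.
    """
    ref = np.asarray(water_reference, dtype=float)
    if np.any(ref <= 0):
        raise ValueError("water reference attenuation must be positive")
    return 1000.0 * (np.asarray(image, dtype=float) - ref) / ref


@dataclass(frozen=True)
class AttenuationModelParams:
    """Per-channel (photoelectric, Rayleigh, Compton) model coefficients."""

    k_pe: np.ndarray
    k_rayleigh: np.ndarray
    k_compton: np.ndarray

    def __post_init__(self):
        for name in ("k_pe", "k_rayleigh", "k_compton"):
            object.__setattr__(self, name, np.atleast_1d(np.asarray(getattr(self, name), dtype=float)))
        n = len(self.k_pe)
        if len(self.k_rayleigh) != n or len(self.k_compton) != n:
            raise ValueError("parameter vectors must share the channel count")
        if not np.all(np.isfinite(self.k_pe)) or not np.all(np.isfinite(self.k_rayleigh)) or not np.all(np.isfinite(self.k_compton)):
            raise ValueError("non-finite model parameter")
        if np.any(self.k_compton <= 0):
            raise ValueError("Compton coefficients must be positive")

    @property
    def n_channels(self) -> int:
        return len(self.k_pe)


def attenuation_from_composition(
    rho: np.ndarray,
    lam: np.ndarray,
    params: AttenuationModelParams,
    z: np.ndarray = HOI_Z,
) -> np.ndarray:
    """Multi-channel attenuation F = rho * (lam K + K_MC) of the model.

    ``rho`` has shape (M,), ``lam`` shape (M, D) with rows summing to 1;
    returns (M, N).  Matrix form of the per-voxel empirical model (the two
    are algebraically identical).
    """
    rho = np.asarray(rho, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if np.any(rho < 0):
        raise ValueError("rho must be nonnegative")
    row_sums = lam.sum(axis=1)
    if np.any(np.abs(row_sums - 1.0) > 1e-6):
        raise ValueError("lam rows must sum to 1 within 1e-6")
    if np.any((lam < -1e-12) | (lam > 1 + 1e-12)):
        raise ValueError("lam entries must lie in [0, 1]")
    z = np.asarray(z, dtype=float)
    # K[d, i] = k_pe[i] z_d^3.62 + k_r[i] z_d^1.86
    K = np.outer(z**PE_EXPONENT, params.k_pe) + np.outer(
        z**RAYLEIGH_EXPONENT, params.k_rayleigh
    )
    return rho[:, None] * (lam @ K + params.k_compton[None, :])


def calibrate_model(
    materials: list[tuple[float, np.ndarray, np.ndarray]],
    z: np.ndarray = HOI_Z,
) -> AttenuationModelParams:
    """Least-squares fit of the per-channel model coefficients.

    Each entry of ``materials`` is ``(rho, lam, f)`` with ``f`` the measured
    per-channel linear attenuation (cm^-1).  Requires at least three
    materials whose regressor rows ``rho * (lam z^3.62, lam z^1.86, 1)`` are
    linearly independent; exact on noiseless model-generated data.
    """
    if len(materials) < 3:
        raise ValueError(
            f"calibration needs >= 3 materials, got {len(materials)} "
            "(underdetermined design)"
        )
    z = np.asarray(z, dtype=float)
    rows, fs = [], []
    for rho, lam, f in materials:
        lam = np.asarray(lam, dtype=float)
        rows.append(
            [
                rho * float(lam @ z**PE_EXPONENT),
                rho * float(lam @ z**RAYLEIGH_EXPONENT),
                rho,
            ]
        )
        fs.append(np.atleast_1d(np.asarray(f, dtype=float)))
    design = np.array(rows)
    # scale columns for a meaningful rank test (they span many decades)
    scale = np.linalg.norm(design, axis=0)
    if np.any(scale == 0) or np.linalg.matrix_rank(design / scale) < 3:
        raise ValueError(
            "rank-deficient calibration design: the material set does not "
            "separate photoelectric / Rayleigh / Compton contributions"
        )
    F = np.stack(fs)  # (n_materials, N)
    coef, *_ = np.linalg.lstsq(design, F, rcond=None)
    return AttenuationModelParams(
        k_pe=coef[0], k_rayleigh=coef[1], k_compton=coef[2]
    )


#: synthetic fat-like calibration material: adipose H/O mass fractions
#: renormalized over (H, O), density chosen for a realistic relative
#: electron density (~0.95).  Water and iodine dilutions alone span only a
#: two-dimensional subspace of the three-parameter regressor space, so a
#: material with a different H/O balance is required for full rank.
FAT_SURROGATE = Material("fat_surrogate", {"H": 0.2908, "O": 0.7092}, 0.82)


def default_calibration_materials() -> list[Material]:
    """Water, a fat-like H/O material, and iodine dilutions (1%, 3%, 5%)."""
    return [WATER, FAT_SURROGATE] + [iodine_solution(c) for c in (0.01, 0.03, 0.05)]


@dataclass(frozen=True)
class ScannerCalibration:
    """Calibrated model parameters plus the per-channel water references."""

    kvps: tuple[float, ...]
    params: AttenuationModelParams
    mu_water: np.ndarray  # cm^-1 per channel
    spectra: tuple[Spectrum, ...] = field(repr=False, default=())

    @property
    def n_channels(self) -> int:
        return len(self.kvps)


def harden_spectrum(spectrum: Spectrum, water_path_cm: float) -> Spectrum:
    """Spectrum after transmission through a water slab (renormalized).

    Used to build the representative in-phantom spectrum that scanner
    calibration sees: reconstructed voxel values reflect the beam after it
    has traversed surrounding material, not the unattenuated tube spectrum.
    """
    if water_path_cm < 0:
        raise ValueError("water path must be nonnegative")
    mu_w = np.zeros_like(spectrum.energies_kev)
    for el, w in WATER_COMPOSITION.items():
        mu_w = mu_w + w * mass_attenuation(el, spectrum.energies_kev)
    weights = spectrum.weights * np.exp(-mu_w * water_path_cm)
    return Spectrum(
        kvp=spectrum.kvp,
        energies_kev=spectrum.energies_kev,
        weights=weights / weights.sum(),
    )


#: representative water path (cm) for calibration: on the order of the
#: phantom radius, emulating a scanner calibration performed with the
#: calibration materials embedded in a body-sized water phantom, which
#: folds the bulk of the beam-hardening shift into the model coefficients
DEFAULT_CALIBRATION_WATER_PATH_CM = 10.0


def water_equivalent_transfer(spectrum: Spectrum, l_max_cm: float = 60.0):
    """Polyenergetic water transfer curve of one channel.

    Returns ``(lengths_cm, log_attenuation)`` with
    ``log_attenuation(L) = -log sum_E w(E) exp(-mu_w(E) L)`` on a dense
    grid -- the monotone map a water precorrection inverts to linearize
    measured projections.
    """
    mu_w = np.zeros_like(spectrum.energies_kev)
    for el, w in WATER_COMPOSITION.items():
        mu_w = mu_w + w * mass_attenuation(el, spectrum.energies_kev)
    lengths = np.linspace(0.0, l_max_cm, 1201)
    trans = np.exp(-np.outer(lengths, mu_w)) @ spectrum.weights
    return lengths, -np.log(trans)


def calibrate_from_spectra(
    spectra: list[Spectrum],
    materials: list[Material] | None = None,
    water_path_cm: float = DEFAULT_CALIBRATION_WATER_PATH_CM,
    linearized: bool = True,
) -> ScannerCalibration:
    """Calibrate the empirical model against per-channel attenuations.

    With ``linearized=True`` (matching the simulator's water-precorrected
    projections) the 'measured' attenuation of a calibration material is its
    water-equivalent slope at a representative in-phantom depth, rescaled to
    the channel's unattenuated water attenuation:
    ``f_m = mu_w(0) * mu_m(L*) / mu_w(L*)`` where ``mu(L*)`` denotes the
    effective attenuation under the spectrum hardened by ``water_path_cm``
    of water.  Water then calibrates exactly to its thin-limit value, which
    is also the HU reference.  With ``linearized=False`` the raw hardened
    effective attenuations are used.
    """
    if materials is None:
        materials = default_calibration_materials()
    eff = [harden_spectrum(s, water_path_cm) for s in spectra]
    mu_w0 = np.array([effective_channel_attenuation(WATER, s) for s in spectra])
    mu_wL = np.array([effective_channel_attenuation(WATER, s) for s in eff])
    triples = []
    for m in materials:
        f = np.array([effective_channel_attenuation(m, s) for s in eff])
        if linearized:
            f = mu_w0 * f / mu_wL
        triples.append((m.relative_electron_density, m.hoi_fractions, f))
    params = calibrate_model(triples)
    mu_water = mu_w0 if linearized else mu_wL
    return ScannerCalibration(
        kvps=tuple(s.kvp for s in spectra),
        params=params,
        mu_water=mu_water,
        spectra=tuple(spectra),
    )
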