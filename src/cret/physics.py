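"""Cerenkov photon production from radionuclide decay.

A charged particle moving through a dielectric of refractive index ``n``
faster than the local phase velocity of light (``v > c/n``) emits Cerenkov
radiation with the Frank--Tamm spectral density

    d2N / (dx dlambda) = 2 pi alpha / lambda**2 * (1 - 1/(beta**2 n**2))

photons per unit path per unit wavelength, where ``alpha`` is the fine
structure constant and ``beta = v/c``.  The emission threshold for a
particle of rest energy ``m c**2`` is the kinetic energy at which
``beta = 1/n``:

    T_thr = m c**2 * (1 / sqrt(1 - 1/n**2) - 1)

which evaluates to 264 keV for an electron in water (n = 1.33).

Beta decay releases electrons/positrons with a continuous kinetic energy
spectrum up to a branch-specific endpoint Q.  This module samples initial
energies from the allowed beta shape, slows each particle down through the
medium with a continuous-slowing-down (CSDA) range--energy model, and
accumulates Frank--Tamm photons along the track to obtain the expected
Cerenkov emission spectrum per radioactive decay.  Gamma branches emit no
Cerenkov light here; secondary processes (Bremsstrahlung, gamma-induced
radioluminescence) are deliberately out of model.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid, trapezoid

__all__ = [
    "FINE_STRUCTURE",
    "ELECTRON_REST_MEV",
    "DecayBranch",
    "Radionuclide",
    "Medium",
    "KatzPenfoldRange",
    "EmissionSpectrum",
    "BetaSpectrumSample",
    "NoThresholdError",
    "water",
    "default_wavelength_grid",
    "get_nuclide",
    "available_nuclides",
    "cherenkov_threshold_energy",
    "frank_tamm_spectral_density",
    "beta_spectrum_pdf",
    "sample_beta_energies",
    "cherenkov_photons_per_decay",
    "decay_correct",
    "write_spectrum",
    "read_spectrum",
]

FINE_STRUCTURE = 1.0 / 137.035999084
ELECTRON_REST_MEV = 0.51099895
_NM_PER_CM = 1.0e7


class NoThresholdError(ValueError):
    """Raised when the refractive index does not exceed 1 (no Cerenkov emission)."""


def default_wavelength_grid() -> np.ndarray:
    """Working wavelength grid: 300-900 nm at 1 nm steps."""
    return np.arange(300.0, 901.0, 1.0)


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class DecayBranch:
    """One decay branch: beta branches carry an endpoint Q, gamma a line energy."""

    mode: str  # "beta_plus" | "beta_minus" | "gamma"
    fraction: float
    energy_mev: float

    def __post_init__(self) -> None:
        if self.mode not in ("beta_plus", "beta_minus", "gamma"):
            raise ValueError(f"unknown decay mode {self.mode!r}")
        if not 0.0 < self.fraction <= 1.0:
            raise ValueError("branch fraction must be in (0, 1]")
        if self.energy_mev <= 0.0:
            raise ValueError("branch energy must be positive")

    @property
    def is_beta(self) -> bool:
        return self.mode in ("beta_plus", "beta_minus")


@dataclass(frozen=True)
class Radionuclide:
    name: str
    half_life_h: float
    atomic_number: int
    branches: tuple[DecayBranch, ...]

    def __post_init__(self) -> None:
        if self.half_life_h <= 0.0:
            raise ValueError("half-life must be positive")
        total = sum(b.fraction for b in self.branches)
        if total > 1.0 + 1e-9:
            raise ValueError("branch fractions must sum to at most 1")

    @property
    def beta_branches(self) -> tuple[DecayBranch, ...]:
        return tuple(b for b in self.branches if b.is_beta)


@dataclass(frozen=True)
class KatzPenfoldRange:
    """CSDA range-energy relation for electrons in low-Z media.

    R(E) = a * E**(b1 - b2*ln(E)) in g/cm2 with E in MeV; valid roughly for
    0.01 <= E <= 2.5 MeV, which covers every beta endpoint shipped here.
    """

    a: float = 0.412
    b1: float = 1.265
    b2: float = 0.0954

    def range_g_cm2(self, energy_mev):
        e = np.asarray(energy_mev, dtype=float)
        return self.a * e ** (self.b1 - self.b2 * np.log(e))

    def drde_g_cm2_mev(self, energy_mev):
        """dR/dE (g/cm2 per MeV): path length traversed per unit energy lost."""
        e = np.asarray(energy_mev, dtype=float)
        return self.range_g_cm2(e) * (self.b1 - 2.0 * self.b2 * np.log(e)) / e


@dataclass(frozen=True)
class Medium:
    """Dielectric the charged particle traverses.

    ``refractive_index`` may be a constant or a callable of wavelength (nm);
    the constant default reproduces the 264 keV water threshold.
    """

    name: str
    refractive_index: float | Callable[[np.ndarray], np.ndarray] = 1.33
    density_g_cm3: float = 1.0
    stopping_power: KatzPenfoldRange = field(default_factory=KatzPenfoldRange)

    def __post_init__(self) -> None:
        if self.density_g_cm3 <= 0.0:
            raise ValueError("density must be positive")

    def n(self, wavelength_nm):
        if callable(self.refractive_index):
            return np.asarray(self.refractive_index(np.asarray(wavelength_nm, float)))
        return np.broadcast_to(
            np.float64(self.refractive_index), np.shape(wavelength_nm)
        ) if np.ndim(wavelength_nm) else float(self.refractive_index)


def water() -> Medium:
    return Medium(name="water")


@dataclass(frozen=True)
class EmissionSpectrum:
    """Photon spectral density on a strictly increasing wavelength grid.

    ``density`` is photons per nm -- per decay or per second depending on
    provenance (tracked by the caller / sidecar metadata, not the type).
    """

    wavelengths_nm: np.ndarray
    density: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths_nm, dtype=float)
        d = np.asarray(self.density, dtype=float)
        if w.ndim != 1 or w.shape != d.shape:
            raise ValueError("wavelengths and density must be matching 1-D arrays")
        if w.size < 2 or np.any(np.diff(w) <= 0.0):
            raise ValueError("wavelength grid must be strictly increasing")
        if np.any(d < 0.0) or not np.all(np.isfinite(d)):
            raise ValueError("density must be finite and non-negative")
        object.__setattr__(self, "wavelengths_nm", w)
        object.__setattr__(self, "density", d)

    def total(self) -> float:
        """Integrated photon rate/yield over the full grid."""
        return float(trapezoid(self.density, self.wavelengths_nm))

    def scaled(self, factor: float) -> "EmissionSpectrum":
        if factor < 0.0:
            raise ValueError("scale factor must be non-negative")
        return EmissionSpectrum(self.wavelengths_nm, self.density * factor)

    def interp(self, wavelength_nm):
        return np.interp(wavelength_nm, self.wavelengths_nm, self.density,
                         left=0.0, right=0.0)

    @classmethod
    def zero(cls, wavelengths_nm: np.ndarray) -> "EmissionSpectrum":
        w = np.asarray(wavelengths_nm, dtype=float)
        return cls(w, np.zeros_like(w))


@dataclass(frozen=True)
class BetaSpectrumSample:
    """Sampled initial kinetic energies (MeV) from a beta branch."""

    energies_mev: np.ndarray
    seed: int


# ---------------------------------------------------------------------------
# nuclide table


def _data_path(name: str):
    return resources.files("cret.data").joinpath(name)


@lru_cache(maxsize=1)
def _nuclide_table() -> dict[str, Radionuclide]:
    rows: dict[str, list] = {}
    with _data_path("nuclides.csv").open() as fh:
        for row in csv.DictReader(fh):
            key = row["name"]
            rows.setdefault(key, []).append(row)
    table = {}
    for name, branch_rows in rows.items():
        branches = tuple(
            DecayBranch(r["mode"], float(r["fraction"]), float(r["energy_mev"]))
            for r in branch_rows
        )
        table[name] = Radionuclide(
            name=name,
            half_life_h=float(branch_rows[0]["half_life_h"]),
            atomic_number=int(branch_rows[0]["atomic_number"]),
            branches=branches,
        )
    return table


_ALIASES = {
    "18f": "F-18", "f18": "F-18", "f-18": "F-18", "fdg": "F-18",
    "64cu": "Cu-64", "cu64": "Cu-64", "cu-64": "Cu-64",
    "99mtc": "Tc-99m", "tc99m": "Tc-99m", "tc-99m": "Tc-99m",
}


def available_nuclides() -> list[str]:
    return sorted(_nuclide_table())


def get_nuclide(name: str) -> Radionuclide:
    """Look up a shipped radionuclide by name (aliases like '18F' accepted)."""
    table = _nuclide_table()
    if name in table:
        return table[name]
    key = _ALIASES.get(name.lower().replace("[", "").replace("]", ""))
    if key is None:
        raise KeyError(
            f"unknown nuclide {name!r}; available: {', '.join(available_nuclides())}"
        )
    return table[key]


# ---------------------------------------------------------------------------
# kinematics helpers


def _beta_of_kinetic(kinetic_mev, rest_mev: float = ELECTRON_REST_MEV):
    t = np.asarray(kinetic_mev, dtype=float)
    gamma = 1.0 + t / rest_mev
    return np.sqrt(np.clip(1.0 - 1.0 / gamma**2, 0.0, 1.0))


def _momentum_mev(kinetic_mev, rest_mev: float = ELECTRON_REST_MEV):
    t = np.asarray(kinetic_mev, dtype=float)
    return np.sqrt(t * (t + 2.0 * rest_mev))


# ---------------------------------------------------------------------------
# operations


def cherenkov_threshold_energy(
    medium: Medium,
    particle_rest_energy_mev: float = ELECTRON_REST_MEV,
    wavelength_nm: float = 550.0,
) -> float:
    """Kinetic energy (MeV) at which the particle's speed equals c/n.

    Raises :class:`NoThresholdError` when n(wavelength) <= 1, i.e. Cerenkov
    emission is impossible in the medium.
    """
    n = float(medium.n(wavelength_nm))
    if n <= 1.0:
        raise NoThresholdError(f"refractive index {n} <= 1: no Cerenkov threshold")
    return particle_rest_energy_mev * (1.0 / np.sqrt(1.0 - 1.0 / n**2) - 1.0)


def frank_tamm_spectral_density(beta, medium: Medium, wavelength_nm):
    """Frank--Tamm yield: photons per cm of path per nm of wavelength.

    Zero below threshold (beta*n <= 1); proportional to 1/lambda**2 above.
    ``beta`` in (0, 1]; scalar or array, broadcast against ``wavelength_nm``.
    """
    b = np.asarray(beta, dtype=float)
    if np.any(b <= 0.0) or np.any(b > 1.0):
        raise ValueError("beta must lie in (0, 1]")
    lam = np.asarray(wavelength_nm, dtype=float)
    n = np.asarray(medium.n(lam), dtype=float)
    factor = 1.0 - 1.0 / (b**2 * n**2)
    dens = 2.0 * np.pi * FINE_STRUCTURE / lam**2 * _NM_PER_CM * factor
    out = np.where(factor > 0.0, dens, 0.0)
    return float(out) if out.ndim == 0 else out


def _fermi_function(atomic_number: int, kinetic_mev, mode: str):
    """Nonrelativistic Fermi Coulomb correction F(Z, E).

    eta = +Z*alpha/beta for beta-minus (attraction), -Z*alpha/beta for
    beta-plus (repulsion, suppressing the low-energy end).
    """
    beta = _beta_of_kinetic(kinetic_mev)
    beta = np.clip(beta, 1e-12, 1.0)
    sign = 1.0 if mode == "beta_minus" else -1.0
    eta = sign * atomic_number * FINE_STRUCTURE / beta
    x = 2.0 * np.pi * eta
    # x/(1-exp(-x)) computed stably for large |x|
    with np.errstate(over="ignore", under="ignore"):
        f = np.where(
            np.abs(x) < 1e-8, 1.0, x / (1.0 - np.exp(-np.clip(x, -700.0, 700.0)))
        )
    return f


def _beta_shape(energy_mev, branch: DecayBranch, atomic_number: int,
                coulomb: bool = True):
    """Unnormalized allowed beta shape p * E_tot * (Q - E)**2 * F(Z, E)."""
    e = np.asarray(energy_mev, dtype=float)
    q = branch.energy_mev
    inside = (e > 0.0) & (e < q)
    e_safe = np.where(inside, e, 0.5 * q)
    shape = (
        _momentum_mev(e_safe)
        * (e_safe + ELECTRON_REST_MEV)
        * (q - e_safe) ** 2
    )
    if coulomb:
        shape = shape * _fermi_function(atomic_number, e_safe, branch.mode)
    return np.where(inside, shape, 0.0)


_PDF_GRID_POINTS = 4001


@lru_cache(maxsize=32)
def _beta_norm(q: float, mode: str, atomic_number: int, coulomb: bool) -> float:
    branch = DecayBranch(mode, 1.0, q)
    grid = np.linspace(0.0, q, _PDF_GRID_POINTS)
    return float(trapezoid(_beta_shape(grid, branch, atomic_number, coulomb), grid))


def beta_spectrum_pdf(energy_mev, branch: DecayBranch, atomic_number: int,
                      coulomb: bool = True):
    """Allowed-shape beta energy density (per MeV), unit integral over (0, Q).

    Zero outside [0, Q] by contract. ``atomic_number`` is the daughter Z used
    in the Coulomb correction; pass ``coulomb=False`` for the bare shape.
    """
    if not branch.is_beta:
        raise ValueError("beta_spectrum_pdf requires a beta branch")
    norm = _beta_norm(branch.energy_mev, branch.mode, atomic_number, coulomb)
    out = _beta_shape(energy_mev, branch, atomic_number, coulomb) / norm
    return float(out) if np.ndim(energy_mev) == 0 else out


def sample_beta_energies(branch: DecayBranch, n_samples: int, seed: int,
                         atomic_number: int = 8,
                         coulomb: bool = True) -> BetaSpectrumSample:
    """Draw i.i.d. initial kinetic energies by inverse-CDF sampling."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    q = branch.energy_mev
    grid = np.linspace(0.0, q, _PDF_GRID_POINTS)
    pdf = beta_spectrum_pdf(grid, branch, atomic_number, coulomb)
    cdf = cumulative_trapezoid(pdf, grid, initial=0.0)
    cdf /= cdf[-1]
    rng = np.random.default_rng(seed)
    u = rng.random(n_samples)
    energies = np.interp(u, cdf, grid)
    energies = np.clip(energies, np.nextafter(0.0, q), np.nextafter(q, 0.0))
    return BetaSpectrumSample(energies_mev=energies, seed=seed)


def _daughter_z(atomic_number: int, mode: str) -> int:
    return atomic_number + (1 if mode == "beta_minus" else -1)


def cherenkov_photons_per_decay(
    nuclide: Radionuclide,
    medium: Medium | None = None,
    wavelength_grid: np.ndarray | None = None,
    n_samples: int = 20000,
    seed: int = 0,
    coulomb: bool = True,
) -> EmissionSpectrum:
    """Expected Cerenkov spectrum per decay (photons / decay / nm).

    For each beta branch, initial energies are sampled from the allowed
    shape; each particle above the Cerenkov threshold deposits Frank--Tamm
    photons along its CSDA slowing-down path from its initial energy to the
    threshold.  Branch spectra are weighted by branch fraction and summed.
    Gamma-only nuclides yield an identically zero spectrum.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    medium = medium or water()
    lam = (np.asarray(wavelength_grid, float) if wavelength_grid is not None
           else default_wavelength_grid())
    total = np.zeros_like(lam)
    beta_branches = nuclide.beta_branches
    if not beta_branches:
        return EmissionSpectrum(lam, total)

    # threshold from the smallest n on the grid (constant n: exact)
    n_arr = np.asarray(medium.n(lam), dtype=float)
    n_min = float(np.min(n_arr))
    if n_min <= 1.0:
        return EmissionSpectrum(lam, total)
    t_thr = cherenkov_threshold_energy(
        Medium(medium.name, n_min, medium.density_g_cm3, medium.stopping_power)
    )

    for i, branch in enumerate(beta_branches):
        q = branch.energy_mev
        if q <= t_thr:
            continue
        # energy grid over the emitting range [t_thr, Q]
        e_grid = np.linspace(t_thr, q, 512)
        betas = _beta_of_kinetic(e_grid)
        # photons per cm per nm at each (E, lambda)
        ft = np.zeros((e_grid.size, lam.size))
        for j, (b, _) in enumerate(zip(betas, e_grid)):
            if b * n_min > 1.0:
                ft[j] = frank_tamm_spectral_density(min(b, 1.0), medium, lam)
        # path per unit energy: dR/dE in cm/MeV
        drde = medium.stopping_power.drde_g_cm2_mev(e_grid) / medium.density_g_cm3
        # cumulative photons/nm emitted while slowing from E down to threshold
        cum = cumulative_trapezoid(ft * drde[:, None], e_grid, axis=0, initial=0.0)

        sample = sample_beta_energies(
            branch, n_samples, seed=_substream_int(seed, f"branch{i}"),
            atomic_number=_daughter_z(nuclide.atomic_number, branch.mode),
            coulomb=coulomb,
        )
        # average cum(:, E_i) over samples via interpolation weights on e_grid
        e = np.clip(sample.energies_mev, t_thr, q)
        idx = np.clip(np.searchsorted(e_grid, e) - 1, 0, e_grid.size - 2)
        frac = (e - e_grid[idx]) / (e_grid[idx + 1] - e_grid[idx])
        w = np.zeros(e_grid.size)
        np.add.at(w, idx, 1.0 - frac)
        np.add.at(w, idx + 1, frac)
        w /= n_samples
        total += branch.fraction * (w @ cum)

    return EmissionSpectrum(lam, total)


def decay_correct(signal, elapsed_h: float, half_life_h: float):
    """Refer a measured signal back to calibration time: signal * 2**(t/T1/2)."""
    if half_life_h <= 0.0:
        raise ValueError("half-life must be positive")
    if elapsed_h < 0.0:
        raise ValueError("elapsed time must be non-negative")
    return signal * 2.0 ** (elapsed_h / half_life_h)


# ---------------------------------------------------------------------------
# seeding and spectrum I/O


def _substream_int(seed: int, key: str) -> int:
    """Stable child seed (< 2**31) derived from a base seed and a label."""
    import zlib

    ss = np.random.SeedSequence([int(seed), zlib.crc32(key.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


def write_spectrum(path: str | Path, spectrum: EmissionSpectrum,
                   header: dict | None = None) -> Path:
    """Two-column CSV (wavelength_nm, density) with a JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["wavelength_nm", "density"])
        for w, d in zip(spectrum.wavelengths_nm, spectrum.density):
            writer.writerow([f"{w:.6g}", f"{d:.10e}"])
    sidecar = dict(header or {})
    sidecar.setdefault("units", "photons per nm")
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True) + "\n"
    )
    return path


def read_spectrum(path: str | Path) -> tuple[EmissionSpectrum, dict]:
    path = Path(path)
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    header = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    return EmissionSpectrum(data[:, 0], data[:, 1]), header
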