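"""Förster theory: orientation factor, overlap integral, R0 and E(r).

Connects the geometry produced by the scaffold and ensemble modules to
expected energy transfer.  Conventions:

* the overlap integral ``J`` is in M^-1 cm^-1 nm^4, computed from the
  donor emission spectrum (normalized to unit area) and the acceptor
  molar absorptivity spectrum;
* with that unit the Förster radius in nm is
  ``R0 = 0.02108 * (kappa2 * n**-4 * Q_D * J) ** (1/6)``;
* transfer efficiency ``E = 1 / (1 + (r / R0)**6)`` for a donor-acceptor
  separation ``r`` in the same unit as ``R0``.

The static orientation factor ``kappa2`` lies in [0, 4]; its isotropic
dynamic average is 2/3.  Quantum yield and refractive index defaults are
literature-typical placeholders, not measured values, and should be
overridden when known.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import DegenerateInputError

__all__ = [
    "Spectrum",
    "DipolePair",
    "kappa_squared",
    "overlap_integral",
    "forster_radius",
    "fret_efficiency",
    "read_spectrum",
]

#: default refractive index of the aqueous buffer (literature-typical)
DEFAULT_REFRACTIVE_INDEX = 1.4

#: R0 prefactor for J in M^-1 cm^-1 nm^4 and R0 in nm
_R0_PREFACTOR_NM = 0.02108


@dataclass(frozen=True)
class Spectrum:
    """A wavelength grid (nm, strictly increasing) with non-negative values.

    ``kind`` tags the physical meaning: ``"emission"`` (arbitrary units)
    or ``"absorptivity"`` (M^-1 cm^-1).
    """

    wavelength_nm: np.ndarray
    values: np.ndarray
    kind: str = "emission"

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelength_nm, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelength_nm", wl)
        object.__setattr__(self, "values", vals)
        if wl.ndim != 1 or wl.size == 0:
            raise ValueError("wavelength grid must be a non-empty 1-D array")
        if wl.size != vals.size:
            raise ValueError("wavelength and value arrays differ in length")
        if not np.all(np.isfinite(wl)) or not np.all(np.isfinite(vals)):
            raise ValueError("spectrum contains non-finite entries")
        if wl.size > 1 and not np.all(np.diff(wl) > 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if np.any(vals < 0):
            raise ValueError("spectrum values must be non-negative")

    @property
    def peak_nm(self) -> float:
        return float(self.wavelength_nm[int(np.argmax(self.values))])


@dataclass(frozen=True)
class DipolePair:
    """Unit transition dipoles of donor and acceptor plus their separation."""

    donor_dipole: np.ndarray
    acceptor_dipole: np.ndarray
    separation: np.ndarray  # acceptor minus donor position, Å

    def __post_init__(self) -> None:
        d = np.asarray(self.donor_dipole, dtype=float)
        a = np.asarray(self.acceptor_dipole, dtype=float)
        r = np.asarray(self.separation, dtype=float)
        for name, v in (("donor_dipole", d), ("acceptor_dipole", a)):
            n = np.linalg.norm(v)
            if n == 0:
                raise DegenerateInputError(f"{name} has zero length")
            v = v / n
            object.__setattr__(self, name, v)
        object.__setattr__(self, "separation", r)
        if np.linalg.norm(r) == 0:
            raise DegenerateInputError("separation vector has zero length")

    @property
    def r(self) -> float:
        return float(np.linalg.norm(self.separation))


def kappa_squared(pair: DipolePair) -> float:
    """Static dipole orientation factor κ² in [0, 4].

    ``κ = d·a − 3 (d·r̂)(a·r̂)`` with unit dipoles d, a and unit
    separation direction r̂.
    """
    d = pair.donor_dipole
    a = pair.acceptor_dipole
    rhat = pair.separation / pair.r
    kappa = float(d @ a - 3.0 * (d @ rhat) * (a @ rhat))
    return kappa * kappa


def overlap_integral(donor_emission: Spectrum, acceptor_absorptivity: Spectrum) -> float:
    """Spectral overlap J = ∫ F_D(λ) ε_A(λ) λ⁴ dλ / ∫ F_D(λ) dλ.

    Both spectra are linearly resampled onto the finer of the two grids,
    restricted to the common wavelength range, before trapezoidal
    quadrature.  Donor emission is normalized by its own integral, so J
    is invariant to its overall scale.  Units: M^-1 cm^-1 nm^4.
    """
    wl_d, f_d = donor_emission.wavelength_nm, donor_emission.values
    wl_a, e_a = acceptor_absorptivity.wavelength_nm, acceptor_absorptivity.values
    if wl_d.size < 2 or wl_a.size < 2:
        raise ValueError("spectra need at least two grid points")
    lo = max(wl_d[0], wl_a[0])
    hi = min(wl_d[-1], wl_a[-1])
    if hi <= lo:
        warnings.warn("donor emission and acceptor absorption do not overlap; J = 0")
        return 0.0
    step_d = np.min(np.diff(wl_d))
    step_a = np.min(np.diff(wl_a))
    grid = np.arange(lo, hi + 0.5 * min(step_d, step_a), min(step_d, step_a))
    fd = np.interp(grid, wl_d, f_d)
    ea = np.interp(grid, wl_a, e_a)
    total_emission = np.trapezoid(np.interp(wl_d, wl_d, f_d), wl_d)
    if total_emission <= 0:
        raise DegenerateInputError("donor emission integrates to zero")
    return float(np.trapezoid(fd * ea * grid**4, grid) / total_emission)


def forster_radius(
    overlap_j: float,
    kappa2: float = 2.0 / 3.0,
    quantum_yield: float = 0.6,
    refractive_index: float = DEFAULT_REFRACTIVE_INDEX,
) -> float:
    """Förster radius R0 in nm from J (M^-1 cm^-1 nm^4), κ², Q_D and n."""
    if overlap_j < 0 or kappa2 < 0 or quantum_yield < 0:
        raise ValueError("J, kappa2 and quantum yield must be non-negative")
    if not 0 <= quantum_yield <= 1:
        raise ValueError("quantum yield must lie in [0, 1]")
    if refractive_index <= 0:
        raise ValueError("refractive index must be positive")
    return _R0_PREFACTOR_NM * (
        kappa2 * refractive_index**-4 * quantum_yield * overlap_j
    ) ** (1.0 / 6.0)


def fret_efficiency(r: float, r0: float) -> float:
    """E = 1 / (1 + (r/R0)^6); r and R0 in the same unit."""
    if r0 <= 0:
        raise ValueError("R0 must be positive")
    if r < 0:
        raise ValueError("distance must be non-negative")
    return 1.0 / (1.0 + (r / r0) ** 6)


def read_spectrum(path: str | Path, kind: str = "emission") -> Spectrum:
    """Read a two-column TSV (wavelength_nm, value); '#' comments allowed."""
    data = np.loadtxt(Path(path), comments="#")
    data = np.atleast_2d(data)
    return Spectrum(wavelength_nm=data[:, 0], values=data[:, 1], kind=kind)
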