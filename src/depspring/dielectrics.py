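"""Complex permittivities and single-shell Clausius–Mossotti (CM) factors.

A mammalian cell is idealized as a conducting cytoplasm sphere wrapped in a
thin, poorly conducting membrane shell (the *single-shell* model).  The shelled
particle is reduced to an equivalent homogeneous sphere via the standard
radius-ratio formula, and the CM factor

    CM(f) = (eps*_p - eps*_m) / (eps*_p + 2 eps*_m)

then sets the sign and magnitude of the dielectrophoretic force at frequency
``f``.  ``Re[CM]`` lies in [-0.5, 1.0]; negative values mean negative DEP
(the particle is pushed toward low-field regions).

Time convention: e^{+j omega t}, so eps* = eps - j sigma / omega.  ``Re[CM]``
is convention-independent; ``Im[CM]`` changes sign under the opposite
convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EPS0",
    "DielectricMaterial",
    "Medium",
    "ShelledCell",
    "FrequencyGrid",
    "CMSpectrum",
    "complex_permittivity",
    "equivalent_cell_permittivity",
    "cm_factor",
    "cm_spectrum",
]

#: Vacuum permittivity, F/m.
EPS0 = 8.8541878128e-12


@dataclass(frozen=True)
class DielectricMaterial:
    """A lossy dielectric: relative permittivity (multiples of eps0) and
    conductivity (S/m)."""

    relative_permittivity: float
    conductivity: float

    def __post_init__(self) -> None:
        if self.relative_permittivity <= 0:
            raise ValueError("relative_permittivity must be > 0")
        if self.conductivity < 0:
            raise ValueError("conductivity must be >= 0")


@dataclass(frozen=True)
class Medium:
    """The suspending medium; must conduct (its conductivity sets the DEP
    response baseline and is experimentally controlled)."""

    material: DielectricMaterial

    def __post_init__(self) -> None:
        if self.material.conductivity <= 0:
            raise ValueError("medium conductivity must be > 0")

    @property
    def relative_permittivity(self) -> float:
        return self.material.relative_permittivity

    @property
    def conductivity(self) -> float:
        return self.material.conductivity

    @property
    def absolute_permittivity(self) -> float:
        """Real permittivity eps0 * eps_r, F/m."""
        return EPS0 * self.material.relative_permittivity


#: Fixed phospholipid-bilayer thickness, m.
MEMBRANE_THICKNESS = 10e-9


@dataclass(frozen=True)
class ShelledCell:
    """Single-shell cell: cytoplasm sphere of radius ``outer_radius - membrane_thickness``
    wrapped in a membrane shell of fixed thickness (default 10 nm)."""

    outer_radius: float
    cytoplasm: DielectricMaterial
    membrane: DielectricMaterial
    membrane_thickness: float = MEMBRANE_THICKNESS

    def __post_init__(self) -> None:
        if not self.membrane_thickness > 0:
            raise ValueError("membrane_thickness must be > 0")
        if not self.outer_radius > self.membrane_thickness:
            raise ValueError("outer_radius must exceed membrane_thickness")

    @property
    def inner_radius(self) -> float:
        return self.outer_radius - self.membrane_thickness


@dataclass(frozen=True)
class FrequencyGrid:
    """Strictly increasing positive frequencies (Hz)."""

    frequencies: np.ndarray

    def __post_init__(self) -> None:
        freqs = np.asarray(self.frequencies, dtype=float)
        if freqs.ndim != 1 or freqs.size == 0:
            raise ValueError("frequencies must be a non-empty 1-D sequence")
        if np.any(freqs <= 0):
            raise ValueError("frequencies must be positive")
        if freqs.size > 1 and np.any(np.diff(freqs) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        object.__setattr__(self, "frequencies", freqs)

    @classmethod
    def log_spaced(cls, f_min: float, f_max: float, n: int = 100) -> "FrequencyGrid":
        """Logarithmically spaced grid, the default spacing convention."""
        if not (0 < f_min < f_max):
            raise ValueError("need 0 < f_min < f_max")
        if n < 2:
            raise ValueError("need at least 2 points")
        return cls(np.logspace(np.log10(f_min), np.log10(f_max), n))

    def __len__(self) -> int:
        return len(self.frequencies)


def complex_permittivity(material: DielectricMaterial, f) -> complex | np.ndarray:
    """Complex permittivity eps* = eps0*eps_r - j sigma/(2 pi f), in F/m.

    ``f`` may be a scalar or an array of frequencies (Hz, > 0).
    """
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequency must be positive")
    eps = np.asarray(
        EPS0 * material.relative_permittivity - 1j * material.conductivity / (2 * np.pi * f)
    )
    return eps if eps.ndim else complex(eps)


def _shell_reduce(eps_cyt, eps_mem, gamma3):
    """Smeared-out equivalent permittivity of a core/shell sphere.

    ``gamma3`` is (R/(R-d))^3.  Broadcasts over frequency axes.
    """
    k = (eps_cyt - eps_mem) / (eps_cyt + 2.0 * eps_mem)
    return eps_mem * (gamma3 + 2.0 * k) / (gamma3 - k)


def equivalent_cell_permittivity(cell: ShelledCell, f) -> complex | np.ndarray:
    """Equivalent homogeneous-sphere complex permittivity of a shelled cell.

    Uses the standard single-shell radius-ratio reduction with
    ratio ``(R/(R-d))^3``; continuous in all parameters, and reduces to the
    cytoplasm permittivity when the shell vanishes or matches the cytoplasm.
    """
    gamma3 = (cell.outer_radius / cell.inner_radius) ** 3
    eps_cyt = complex_permittivity(cell.cytoplasm, f)
    eps_mem = complex_permittivity(cell.membrane, f)
    out = _shell_reduce(eps_cyt, eps_mem, gamma3)
    out = np.asarray(out)
    return out if out.ndim else complex(out)


def cm_factor(particle, medium: Medium, f) -> complex | np.ndarray:
    """Clausius–Mossotti factor of a particle in a medium at frequency ``f``.

    ``particle`` may be a :class:`ShelledCell` (single-shell reduction is
    applied), a :class:`DielectricMaterial` (homogeneous sphere), or a complex
    permittivity value/array already evaluated at ``f``.
    """
    if isinstance(particle, ShelledCell):
        eps_p = equivalent_cell_permittivity(particle, f)
    elif isinstance(particle, DielectricMaterial):
        eps_p = complex_permittivity(particle, f)
    else:
        eps_p = np.asarray(particle, dtype=complex)
    eps_m = complex_permittivity(medium.material, f)
    out = np.asarray((eps_p - eps_m) / (eps_p + 2.0 * eps_m))
    return out if out.ndim else complex(out)


@dataclass(frozen=True)
class CMSpectrum:
    """CM factor evaluated on a frequency grid for one particle."""

    grid: FrequencyGrid
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=complex)
        if values.shape != self.grid.frequencies.shape:
            raise ValueError("values must match the grid length")
        object.__setattr__(self, "values", values)

    @property
    def re(self) -> np.ndarray:
        return self.values.real

    @property
    def im(self) -> np.ndarray:
        return self.values.imag

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frequency_hz": self.grid.frequencies,
                "re_cm": self.values.real,
                "im_cm": self.values.imag,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def dispersion_count(self) -> int:
        """Number of dispersions, counted as local maxima of |d Re[CM] / d log f|.

        A dispersion is a transition between Re[CM] plateaus; each produces one
        peak in the log-frequency derivative magnitude.  Shallow numerical
        ripples are suppressed by requiring a peak to exceed 10% of the
        largest derivative magnitude.
        """
        logf = np.log10(self.grid.frequencies)
        d = np.abs(np.gradient(self.values.real, logf))
        if d.max() == 0:
            return 0
        floor = 0.1 * d.max()
        interior = (d[1:-1] >= d[:-2]) & (d[1:-1] > d[2:]) & (d[1:-1] > floor)
        return int(np.count_nonzero(interior))


def cm_spectrum(cell, medium: Medium, grid: FrequencyGrid) -> CMSpectrum:
    """Element-wise CM factor of ``cell`` over ``grid``."""
    values = cm_factor(cell, medium, grid.frequencies)
    return CMSpectrum(grid=grid, values=np.atleast_1d(values))
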