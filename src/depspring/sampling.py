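"""Monte Carlo sampling of single-shell cell populations.

Populations are drawn parameter-wise from independent uniform distributions
over literature-informed ranges; the membrane thickness and the medium are
held fixed (experimentally controlled).  The default ranges are:

======================  =======================
cytoplasm conductivity  0.2 – 1.2 S/m
cytoplasm permittivity  20 – 80 eps0
membrane conductivity   10 nS/m – 1 uS/m
membrane permittivity   2 – 20 eps0
outer radius            2.0 – 8.0 um
membrane thickness      10 nm (fixed)
medium                  1.5 S/m, 78.5 eps0 (fixed)
======================  =======================
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

from .dielectrics import MEMBRANE_THICKNESS, DielectricMaterial, Medium, ShelledCell
from .errors import ConfigurationError

__all__ = ["ParameterRanges", "CellPopulation", "sample_population", "DEFAULT_MEDIUM"]

DEFAULT_MEDIUM = Medium(DielectricMaterial(relative_permittivity=78.5, conductivity=1.5))

_SAMPLED_FIELDS = (
    "cytoplasm_conductivity",
    "cytoplasm_permittivity",
    "membrane_conductivity",
    "membrane_permittivity",
    "outer_radius",
)


@dataclass(frozen=True)
class ParameterRanges:
    """(low, high) bounds per sampled parameter, plus the fixed quantities.

    Permittivities are in multiples of eps0, conductivities in S/m, radii in m.
    Degenerate bounds (low == high) are allowed and yield a deterministic
    parameter; low > high is a configuration error.
    """

    cytoplasm_conductivity: tuple[float, float] = (0.2, 1.2)
    cytoplasm_permittivity: tuple[float, float] = (20.0, 80.0)
    membrane_conductivity: tuple[float, float] = (10e-9, 1e-6)
    membrane_permittivity: tuple[float, float] = (2.0, 20.0)
    outer_radius: tuple[float, float] = (2.0e-6, 8.0e-6)
    membrane_thickness: float = MEMBRANE_THICKNESS
    medium: Medium = DEFAULT_MEDIUM
    #: Draw membrane conductivity uniformly in log10 space instead of linearly
    #: (its default range spans two decades).  Linear is the default.
    log_membrane_conductivity: bool = False

    def __post_init__(self) -> None:
        for name in _SAMPLED_FIELDS:
            lo, hi = getattr(self, name)
            if not (np.isfinite(lo) and np.isfinite(hi)) or lo > hi:
                raise ConfigurationError(f"invalid range for {name}: ({lo}, {hi})")
            if lo <= 0 and name != "membrane_conductivity":
                raise ConfigurationError(f"{name} must be positive")
        lo, _ = self.outer_radius
        if lo <= self.membrane_thickness:
            raise ConfigurationError("outer radius range must exceed membrane thickness")


@dataclass(frozen=True)
class CellPopulation:
    """An ordered collection of sampled cells, stored column-wise.

    Arrays are aligned by cell index; ``cells()`` yields :class:`ShelledCell`
    views for scalar use.
    """

    cytoplasm_conductivity: np.ndarray = field(repr=False)
    cytoplasm_permittivity: np.ndarray = field(repr=False)
    membrane_conductivity: np.ndarray = field(repr=False)
    membrane_permittivity: np.ndarray = field(repr=False)
    outer_radius: np.ndarray = field(repr=False)
    ranges: ParameterRanges
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.outer_radius)

    @property
    def membrane_thickness(self) -> float:
        return self.ranges.membrane_thickness

    @property
    def medium(self) -> Medium:
        return self.ranges.medium

    def cell(self, i: int) -> ShelledCell:
        return ShelledCell(
            outer_radius=float(self.outer_radius[i]),
            cytoplasm=DielectricMaterial(
                float(self.cytoplasm_permittivity[i]), float(self.cytoplasm_conductivity[i])
            ),
            membrane=DielectricMaterial(
                float(self.membrane_permittivity[i]), float(self.membrane_conductivity[i])
            ),
            membrane_thickness=self.membrane_thickness,
        )

    def cells(self) -> Iterator[ShelledCell]:
        for i in range(len(self)):
            yield self.cell(i)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({name: getattr(self, name) for name in _SAMPLED_FIELDS})

    def to_csv(self, path) -> None:
        """One row per cell; seed and fixed parameters in a header comment."""
        header = (
            f"# seed={self.seed} membrane_thickness_m={self.membrane_thickness}"
            f" medium_conductivity_S_per_m={self.medium.conductivity}"
            f" medium_relative_permittivity={self.medium.relative_permittivity}\n"
        )
        buf = io.StringIO()
        self.to_dataframe().to_csv(buf, index=False)
        with open(path, "w") as fh:
            fh.write(header)
            fh.write(buf.getvalue())


def sample_population(
    n: int, ranges: ParameterRanges | None = None, seed: int | None = None
) -> CellPopulation:
    """Draw ``n`` cells with each parameter marginally uniform on its range.

    A single RNG stream (PCG64 seeded with ``seed``) is used for the whole
    population, so equal ``(n, ranges, seed)`` give bit-identical populations.
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    ranges = ranges if ranges is not None else ParameterRanges()
    rng = np.random.default_rng(seed)
    columns = {}
    for name in _SAMPLED_FIELDS:
        lo, hi = getattr(ranges, name)
        if name == "membrane_conductivity" and ranges.log_membrane_conductivity:
            columns[name] = 10 ** rng.uniform(np.log10(lo), np.log10(hi), size=n)
        else:
            columns[name] = rng.uniform(lo, hi, size=n)
    return CellPopulation(ranges=ranges, seed=seed, **columns)
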