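"""Grid and polarization-field containers plus HDF5 persistence.

Fields live on periodic rectangular grids.  2-D grids still carry full
3-component polarization vectors (with d/dz = 0), so tetragonal,
orthorhombic and rhombohedral variants all remain representable in plane
simulations.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import h5py
import numpy as np


@dataclass(frozen=True)
class SimulationGrid:
    """Periodic simulation grid: 2 or 3 axes, uniform physical spacing (m)."""

    shape: tuple[int, ...]
    spacing: float = 1e-9
    periodic: bool = True

    def __post_init__(self) -> None:
        shape = tuple(int(n) for n in self.shape)
        object.__setattr__(self, "shape", shape)
        if len(shape) not in (2, 3):
            raise ValueError("grid must be 2-D or 3-D")
        if any(n < 8 or n % 2 for n in shape):
            raise ValueError("all grid axes must be even and >= 8 (spectral symmetry)")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if not self.periodic:
            raise ValueError("only periodic grids are supported")

    @property
    def dimensions(self) -> int:
        return len(self.shape)

    @property
    def n_cells(self) -> int:
        return int(np.prod(self.shape))


@dataclass(frozen=True)
class PolarizationField:
    """Per-cell 3-component polarization (C/m^2) on a periodic grid."""

    grid: SimulationGrid
    vectors: np.ndarray
    temperature: float = 298.0
    seed: int | None = None
    step_count: int = 0

    def __post_init__(self) -> None:
        vectors = np.asarray(self.vectors, dtype=float)
        if vectors.shape != (*self.grid.shape, 3):
            raise ValueError(
                f"vectors shape {vectors.shape} does not match grid {self.grid.shape} + component axis"
            )
        if not np.all(np.isfinite(vectors)):
            raise ValueError("polarization field contains non-finite entries")
        object.__setattr__(self, "vectors", vectors)

    def with_vectors(self, vectors: np.ndarray, extra_steps: int = 0) -> "PolarizationField":
        return replace(self, vectors=vectors, step_count=self.step_count + extra_steps)

    def mean_polarization(self) -> np.ndarray:
        """Spatial average of each component (C/m^2)."""
        return self.vectors.reshape(-1, 3).mean(axis=0)

    def magnitudes(self) -> np.ndarray:
        return np.linalg.norm(self.vectors, axis=-1)


def save_field(path: str | Path, field: PolarizationField, config_hash: str = "") -> None:
    """Write a field state to HDF5 (dataset /polarization[axis, x, y(, z)])."""
    with h5py.File(path, "w") as handle:
        dset = handle.create_dataset("polarization", data=np.moveaxis(field.vectors, -1, 0))
        dset.attrs["spacing"] = field.grid.spacing
        dset.attrs["temperature"] = field.temperature
        dset.attrs["seed"] = -1 if field.seed is None else field.seed
        dset.attrs["step_count"] = field.step_count
        if config_hash:
            dset.attrs["config_hash"] = config_hash


def load_field(path: str | Path) -> PolarizationField:
    """Read a field state written by :func:`save_field`."""
    with h5py.File(path, "r") as handle:
        dset = handle["polarization"]
        vectors = np.moveaxis(dset[...], 0, -1)
        grid = SimulationGrid(shape=vectors.shape[:-1], spacing=float(dset.attrs["spacing"]))
        seed = int(dset.attrs.get("seed", -1))
        return PolarizationField(
            grid=grid,
            vectors=vectors,
            temperature=float(dset.attrs.get("temperature", 298.0)),
            seed=None if seed < 0 else seed,
            step_count=int(dset.attrs.get("step_count", 0)),
        )
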