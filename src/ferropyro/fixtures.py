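"""Seeded synthetic-data generators for every pipeline input.

All generators are deterministic under a fixed seed.  A single integer
seed expands into independent per-generator streams through a documented
splitting scheme: each generator kind owns a fixed integer code, and the
stream is ``default_rng(SeedSequence((seed, kind_code)))`` — adding new
fixture kinds therefore never perturbs existing ones.
"""

from __future__ import annotations

import numpy as np

from .bands import AbsorbanceSpectrum
from .domains import PHASE_ORDER, VariantMap, enumerate_variants
from .fields import PolarizationField, SimulationGrid

#: Stable kind codes of the seed-splitting scheme (never renumber).
KIND_CODES = {
    "random_field": 1,
    "defect_field": 2,
    "composite_variants": 3,
    "spectrum": 4,
    "protocol": 5,
}


def _rng(kind: str, seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), KIND_CODES[kind])))


def make_random_field(
    shape,
    amplitude: float = 0.1,
    seed: int = 0,
    spacing: float = 1e-9,
    temperature: float = 298.0,
) -> PolarizationField:
    """Random multiphase initial state: i.i.d. zero-mean uniform components
    in [-amplitude, amplitude] (C/m^2)."""
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    grid = SimulationGrid(shape=tuple(shape), spacing=spacing)
    rng = _rng("random_field", seed)
    vectors = rng.uniform(-amplitude, amplitude, size=(*grid.shape, 3)) if amplitude else np.zeros((*grid.shape, 3))
    return PolarizationField(grid=grid, vectors=vectors, temperature=temperature, seed=seed)


def make_defect_field(shape, concentration: float = 0.05, sigma_e: float = 5e5, seed: int = 0) -> np.ndarray:
    """Static random-defect field E_RF for the TDGL configuration.

    Exactly round(c*N) cells, drawn without replacement, carry i.i.d.
    zero-mean Gaussian 3-component fields of standard deviation ``sigma_e``
    (V/m); all other cells are zero.
    """
    if not 0.0 <= concentration <= 1.0:
        raise ValueError("concentration must lie in [0, 1]")
    if sigma_e < 0:
        raise ValueError("sigma_e must be >= 0")
    shape = tuple(int(n) for n in shape)
    n_cells = int(np.prod(shape))
    n_occupied = int(round(concentration * n_cells))
    rng = _rng("defect_field", seed)
    field = np.zeros((n_cells, 3))
    if n_occupied:
        sites = rng.choice(n_cells, size=n_occupied, replace=False)
        field[sites] = rng.normal(0.0, sigma_e, size=(n_occupied, 3))
    return field.reshape(*shape, 3)


def make_composite_variant_field(
    shape,
    fractions,
    ps_magnitude: float = 0.25,
    seed: int = 0,
    spacing: float = 1e-9,
    temperature: float = 298.0,
) -> tuple[PolarizationField, VariantMap]:
    """Composite field with known phase composition and ground-truth map.

    ``fractions`` maps {para, T, O, R} (dict or 4-sequence in that order)
    to cell fractions summing to 1.  Polar cells point along a uniformly
    chosen variant direction of their phase with |P| = ps_magnitude; para
    cells are zero.  Returns (field, ground-truth VariantMap).
    """
    if isinstance(fractions, dict):
        fracs = [float(fractions.get(k, 0.0)) for k in ("para", *PHASE_ORDER)]
    else:
        fracs = [float(v) for v in fractions]
    if len(fracs) != 4 or any(f < 0 for f in fracs):
        raise ValueError("fractions must give non-negative weights for (para, T, O, R)")
    if abs(sum(fracs) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1 (got {sum(fracs)!r})")

    grid = SimulationGrid(shape=tuple(shape), spacing=spacing)
    rng = _rng("composite_variants", seed)
    n_cells = grid.n_cells
    phase_pick = rng.choice(4, size=n_cells, p=np.asarray(fracs) / sum(fracs))

    variants = enumerate_variants()
    phase_variant_codes = {
        phase: [i + 1 for i, v in enumerate(variants) if v.phase == phase] for phase in PHASE_ORDER
    }
    codes = np.zeros(n_cells, dtype=np.int8)
    for phase_idx, phase in enumerate(PHASE_ORDER, start=1):
        mask = phase_pick == phase_idx
        if np.any(mask):
            codes[mask] = rng.choice(phase_variant_codes[phase], size=int(mask.sum()))

    directions = np.vstack([np.zeros(3), np.stack([v.direction for v in variants])])
    vectors = (directions[codes] * ps_magnitude).reshape(*grid.shape, 3)
    field = PolarizationField(grid=grid, vectors=vectors, temperature=temperature, seed=seed)
    truth = VariantMap(
        grid=grid, codes=codes.reshape(grid.shape), threshold=0.5 * ps_magnitude
    )
    return field, truth


def make_spectrum(
    eg: float,
    exponent: str = "direct",
    noise_sd: float = 0.0,
    seed: int = 0,
    e_min: float = 2.5,
    e_max: float = 4.0,
    n_points: int = 301,
    urbach_width: float | None = None,
) -> AbsorbanceSpectrum:
    """Synthetic absorption-edge spectrum obeying the Tauc law.

    Direct gaps follow alpha = A (h nu - Eg)^(1/2) / (h nu) above the gap
    (so the (alpha h nu)^2 Tauc plot is exactly linear), indirect gaps the
    squared analogue; below the gap the absorbance is zero unless an
    exponential Urbach tail of the given width (eV) is requested.
    Multiplicative Gaussian noise of relative s.d. ``noise_sd`` is applied
    and the result clipped at zero.
    """
    if not e_min < eg < e_max:
        raise ValueError("eg must lie inside the generated energy range")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    energies = np.linspace(e_min, e_max, n_points)
    above = np.clip(energies - eg, 0.0, None)
    if exponent == "direct":
        alpha = np.sqrt(above) / energies
    elif exponent == "indirect":
        alpha = above**2 / energies
    else:
        raise ValueError("exponent must be 'direct' or 'indirect'")
    if urbach_width:
        edge_scale = np.interp(eg + urbach_width, energies, alpha)
        tail = edge_scale * np.exp((energies - eg - urbach_width) / urbach_width)
        alpha = np.where(energies < eg + urbach_width, np.minimum(tail, np.max(alpha)), alpha)
    if noise_sd:
        rng = _rng("spectrum", seed)
        alpha = alpha * (1.0 + rng.normal(0.0, noise_sd, size=alpha.shape))
    return AbsorbanceSpectrum(
        photon_energies=energies, absorbance=np.clip(alpha, 0.0, None), tauc_exponent=exponent
    )


def make_thermal_protocol(seed: int = 0, **overrides):
    """Calibrated default thermal protocol (deterministic; the seed is
    accepted for interface uniformity and ignored)."""
    from .photothermal import calibrate_protocol

    return calibrate_protocol(**overrides)
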