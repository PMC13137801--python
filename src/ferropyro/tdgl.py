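"""Phase-field evolution of ferroelectric polarization (TDGL dynamics).

The polarization field relaxes down the total free energy

    F = f_bulk(P) + f_grad(P) + f_elastic(P) + f_elec(P, E)

by the time-dependent Ginzburg-Landau gradient flow dP_i/dt = -L dF/dP_i,
integrated with a semi-implicit Fourier spectral scheme on periodic grids:
the linear gradient operator (and, when enabled, the longitudinal
depolarization operator) is treated implicitly in k-space, while the
nonlinear bulk, elastic and defect driving forces are explicit.

Time is dimensionless: t* = t * L * kappa(T), where kappa is the largest
linearized bulk stiffness at the working temperature (see
:func:`ferropyro.landau.bulk_curvature_scale`).  In these units the
explicit-bulk stability bound is dt* < ~2/1.5; the documented safe bound is
``DT_STABILITY_BOUND`` = 0.5 and the default step is 0.05.

Electrostatics follows the standard convention f_elec = -E_appl.P
- (1/2) E_dep.P (applied-field work plus dipolar self-energy); the k = 0
depolarization mode is zero by default (periodic short-circuit), with an
open-circuit flag.  Elasticity is the zero-mean-stress periodic
microelasticity (eigenstrain spectral) solution with homogeneous cubic
stiffness obtained by inverting the configured compliances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field, replace

import numpy as np
from scipy import constants

from .fields import PolarizationField, SimulationGrid
from .landau import (
    bulk_curvature_scale,
    bulk_energy,
    bulk_energy_derivative,
    largest_ps,
)
from .materials import MaterialParameterization, coefficients_at, get_material

EPS0 = constants.epsilon_0

#: Documented dimensionless step-size bound for the semi-implicit scheme.
DT_STABILITY_BOUND = 0.5


class DivergenceError(RuntimeError):
    """Raised when |P| runs away; usually means dt above the stability bound."""


@dataclass(frozen=True)
class GradientSet:
    """Gradient-energy coefficients: G110 scale plus the cubic ratios."""

    g110: float = 7.04e-11  # C^-2 m^4 N
    g11_ratio: float = 1.5
    g12_ratio: float = 0.0
    g44_ratio: float = 0.75

    @property
    def g11(self) -> float:
        return self.g11_ratio * self.g110

    @property
    def g12(self) -> float:
        return self.g12_ratio * self.g110

    @property
    def g44(self) -> float:
        return self.g44_ratio * self.g110


@dataclass(frozen=True)
class ElasticSet:
    """Electrostrictive constants and cubic compliances (SI).

    The shear convention is the tensor one: eigenstrain eps0_ij = Q44/2 *
    Pi*Pj for i != j, i.e. the engineering shear is Q44*Pi*Pj.
    """

    q11: float = 0.1
    q12: float = -0.034
    q44: float = 0.029
    s11: float = 9.1e-12
    s12: float = -3.2e-10
    s44: float = 8.2e-10
    enabled: bool = True

    def compliance_matrix(self) -> np.ndarray:
        S = np.diag([self.s11] * 3 + [self.s44] * 3).astype(float)
        for i in range(3):
            for j in range(3):
                if i != j:
                    S[i, j] = self.s12
        return S

    def stiffness(self) -> tuple[float, float, float]:
        """(C11, C12, C44) from inverting the compliance matrix in Voigt
        cubic form; raises if the inversion is ill-conditioned."""
        S = self.compliance_matrix()
        cond = np.linalg.cond(S)
        if not np.isfinite(cond) or cond > 1e12:
            raise np.linalg.LinAlgError(
                f"compliance matrix is ill-conditioned (cond={cond:.3g}); check s11/s12/s44"
            )
        C = np.linalg.inv(S)
        return float(C[0, 0]), float(C[0, 1]), float(C[3, 3])

    def stiffness_tensor(self) -> np.ndarray:
        """Full cubic C_ijkl (3,3,3,3) in Pa."""
        c11, c12, c44 = self.stiffness()
        C = np.zeros((3, 3, 3, 3))
        for i in range(3):
            for j in range(3):
                C[i, i, j, j] += c12
                C[i, j, i, j] += c44
                C[i, j, j, i] += c44
        for i in range(3):
            C[i, i, i, i] += c11 - c12 - 2 * c44
        return C


@dataclass
class TdglConfig:
    """Full configuration of one TDGL run."""

    material: str | MaterialParameterization = "btz"
    dt: float = 0.05
    gradient: GradientSet = dc_field(default_factory=GradientSet)
    elastic: ElasticSet = dc_field(default_factory=ElasticSet)
    electrostatic_mode: str = "depolarization"  # or "off"
    background_permittivity: float = 50.0
    open_circuit: bool = False
    applied_field: np.ndarray = dc_field(default_factory=lambda: np.zeros(3))
    defect_field: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.material = get_material(self.material)
        self.applied_field = np.asarray(self.applied_field, dtype=float).reshape(3)
        if self.electrostatic_mode not in ("off", "depolarization"):
            raise ValueError("electrostatic_mode must be 'off' or 'depolarization'")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.background_permittivity <= 0:
            raise ValueError("background_permittivity must be positive")

    def check_defect_field(self, grid: SimulationGrid) -> None:
        if self.defect_field is not None and self.defect_field.shape != (*grid.shape, 3):
            raise ValueError(
                f"defect field shape {self.defect_field.shape} does not match grid {grid.shape}"
            )


# ---------------------------------------------------------------------------
# spectral helpers


def _wavevectors(grid: SimulationGrid) -> list[np.ndarray]:
    """Angular wavevector component arrays, one per spatial axis, broadcast
    to the grid shape; a zero array stands in for the missing z axis in 2-D."""
    ndim = grid.dimensions
    ks = []
    for axis in range(3):
        if axis < ndim:
            k1 = 2.0 * np.pi * np.fft.fftfreq(grid.shape[axis], d=grid.spacing)
            shape = [1] * ndim
            shape[axis] = grid.shape[axis]
            ks.append(k1.reshape(shape))
        else:
            ks.append(np.zeros((1,) * ndim))
    return ks


def _gradient_operator(grid: SimulationGrid, gradient: GradientSet) -> np.ndarray:
    """Per-k 3x3 gradient stiffness K with K_ii = G11 k_i^2 + 2 G44 sum_{j!=i}
    k_j^2 and K_ij = G12 k_i k_j (variational form of f_grad)."""
    ks = _wavevectors(grid)
    k2 = sum(k * k for k in ks)
    K = np.zeros((*np.broadcast_shapes(*(k.shape for k in ks)), 3, 3))
    for i in range(3):
        K[..., i, i] = gradient.g11 * ks[i] ** 2 + 2.0 * gradient.g44 * (k2 - ks[i] ** 2)
        for j in range(3):
            if j != i:
                K[..., i, j] += gradient.g12 * ks[i] * ks[j]
    return K


def _unit_k(grid: SimulationGrid) -> np.ndarray:
    ks = _wavevectors(grid)
    kvec = np.stack(np.broadcast_arrays(*ks), axis=-1).astype(float)
    norm = np.linalg.norm(kvec, axis=-1, keepdims=True)
    norm[norm == 0] = 1.0
    return kvec / norm


def _depolarization_operator(grid: SimulationGrid, background_permittivity: float) -> np.ndarray:
    """Longitudinal projector n n^T / (eps0 * eps_b) per k; zero at k = 0."""
    n = _unit_k(grid)
    op = np.einsum("...i,...j->...ij", n, n) / (EPS0 * background_permittivity)
    op[(0,) * grid.dimensions] = 0.0
    return op


def _fftn(arr: np.ndarray, ndim: int) -> np.ndarray:
    return np.fft.fftn(arr, axes=tuple(range(ndim)))


def _ifftn(arr: np.ndarray, ndim: int) -> np.ndarray:
    return np.fft.ifftn(arr, axes=tuple(range(ndim))).real


# ---------------------------------------------------------------------------
# initialization


def initialize_field(
    grid: SimulationGrid,
    mode: str = "random",
    amplitude: float = 0.1,
    seed: int | None = 0,
    temperature: float = 298.0,
    uniform_value=None,
) -> PolarizationField:
    """Create a reproducible initial polarization field.

    Modes: ``random`` draws i.i.d. zero-mean uniform components in
    [-amplitude, amplitude]; ``uniform`` tiles ``uniform_value`` (or
    (0, 0, amplitude)); ``seeded-variant-mix`` assigns each cell one of the
    26 polar variant directions at the given amplitude.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if mode == "uniform":
        value = np.asarray(
            uniform_value if uniform_value is not None else (0.0, 0.0, amplitude), dtype=float
        )
        vectors = np.broadcast_to(value, (*grid.shape, 3)).copy()
        return PolarizationField(grid=grid, vectors=vectors, temperature=temperature, seed=seed)
    rng = np.random.default_rng(seed)
    if mode == "random":
        vectors = rng.uniform(-amplitude, amplitude, size=(*grid.shape, 3))
    elif mode == "seeded-variant-mix":
        from .domains import enumerate_variants

        directions = np.stack([v.direction for v in enumerate_variants()])
        picks = rng.integers(0, len(directions), size=grid.n_cells)
        vectors = (directions[picks] * amplitude).reshape(*grid.shape, 3)
    else:
        raise ValueError("mode must be 'random', 'uniform' or 'seeded-variant-mix'")
    return PolarizationField(grid=grid, vectors=vectors, temperature=temperature, seed=seed)


# ---------------------------------------------------------------------------
# energies and fields


def depolarization_field(
    field: PolarizationField,
    background_permittivity: float = 50.0,
    open_circuit: bool = False,
) -> np.ndarray:
    """Spectral solution of the bound-charge Poisson equation.

    E_dep(k) = -n (n . P(k)) / (eps0 eps_b) with n = k/|k|; the k = 0 mode
    is zero under the periodic short-circuit convention, or -P_mean/(eps0
    eps_b) in open-circuit mode.
    """
    ndim = field.grid.dimensions
    Pk = _fftn(field.vectors, ndim)
    n = _unit_k(field.grid)
    longitudinal = np.einsum("...i,...i->...", n, Pk)
    Ek = -n * longitudinal[..., None] / (EPS0 * background_permittivity)
    zero = (0,) * ndim
    if open_circuit:
        Ek[zero] = -Pk[zero] / (EPS0 * background_permittivity)
    else:
        Ek[zero] = 0.0
    return _ifftn(Ek, ndim)


def _eigenstrain(P: np.ndarray, elastic: ElasticSet) -> np.ndarray:
    """Electrostrictive eigenstrain tensor eps0_ij = Q_ijkl P_k P_l."""
    eps0 = np.zeros((*P.shape[:-1], 3, 3))
    p2 = P * P
    total = p2.sum(axis=-1)
    for i in range(3):
        eps0[..., i, i] = elastic.q11 * p2[..., i] + elastic.q12 * (total - p2[..., i])
    half_q44 = 0.5 * elastic.q44
    for i, j in ((0, 1), (0, 2), (1, 2)):
        shear = half_q44 * P[..., i] * P[..., j]
        eps0[..., i, j] = shear
        eps0[..., j, i] = shear
    return eps0


class _ElasticSolver:
    """Zero-mean-stress periodic microelasticity for a fixed grid/config."""

    def __init__(self, grid: SimulationGrid, elastic: ElasticSet):
        self.grid = grid
        self.elastic = elastic
        self.C = elastic.stiffness_tensor()
        n = _unit_k(grid)
        acoustic = np.einsum("ijkl,...j,...l->...ik", self.C, n, n)
        acoustic[(0,) * grid.dimensions] = np.eye(3)  # k=0 handled separately
        self.omega = np.linalg.inv(acoustic)
        self.n = n

    def solve(self, P: np.ndarray) -> tuple[np.ndarray, float]:
        """Return the stress field sigma (..., 3, 3) and the mean elastic
        energy density (J/m^3) for polarization P."""
        ndim = self.grid.dimensions
        eps0 = _eigenstrain(P, self.elastic)
        sigma0 = np.einsum("ijkl,...kl->...ij", self.C, eps0)
        sigma0_k = _fftn(sigma0, ndim)
        t = np.einsum("...ij,...j->...i", sigma0_k, self.n)
        u_dir = np.einsum("...ij,...j->...i", self.omega, t)
        eps_het_k = 0.5 * (
            np.einsum("...i,...j->...ij", self.n, u_dir)
            + np.einsum("...i,...j->...ij", u_dir, self.n)
        )
        eps_het_k[(0,) * ndim] = 0.0
        eps = _ifftn(eps_het_k, ndim)
        eps += eps0.reshape(-1, 3, 3).mean(axis=0)  # homogeneous strain: zero mean stress
        delta = eps - eps0
        sigma = np.einsum("ijkl,...kl->...ij", self.C, delta)
        energy = 0.5 * float(np.mean(np.einsum("...ij,...ij->...", sigma, delta)))
        return sigma, energy

    def driving_force(self, P: np.ndarray, sigma: np.ndarray) -> np.ndarray:
        """Elastic contribution to dF/dP_i: -sigma_kl d(eps0_kl)/dP_i."""
        el = self.elastic
        trace = np.einsum("...ii->...", sigma)
        force = np.empty_like(P)
        for i in range(3):
            diag = sigma[..., i, i]
            shear = sum(sigma[..., i, l] * P[..., l] for l in range(3) if l != i)
            force[..., i] = -(
                2.0 * el.q11 * diag * P[..., i]
                + 2.0 * el.q12 * (trace - diag) * P[..., i]
                + el.q44 * shear
            )
        return force


@dataclass(frozen=True)
class EnergyBreakdown:
    """Domain-averaged free-energy terms (J/m^3)."""

    bulk: float
    gradient: float
    elastic: float
    electrostatic: float
    applied: float = 0.0
    defect: float = 0.0
    depolarization: float = 0.0

    @property
    def total(self) -> float:
        return self.bulk + self.gradient + self.elastic + self.electrostatic


def total_free_energy(field: PolarizationField, config: TdglConfig) -> EnergyBreakdown:
    """Domain-averaged total free energy with a per-term breakdown."""
    config.check_defect_field(field.grid)
    ndim = field.grid.dimensions
    P = field.vectors
    coeffs = coefficients_at(config.material, field.temperature)
    e_bulk = float(np.mean(bulk_energy(P, coeffs)))

    Pk = _fftn(P, ndim)
    ks = _wavevectors(field.grid)
    grads = []  # dP_i/dx_j
    for j in range(3):
        grads.append(_ifftn(1j * ks[j][..., None] * Pk, ndim))
    g = config.gradient
    diag = [grads[i][..., i] for i in range(3)]
    e_grad = 0.5 * g.g11 * sum(np.mean(d * d) for d in diag)
    e_grad += g.g12 * (
        np.mean(diag[0] * diag[1]) + np.mean(diag[1] * diag[2]) + np.mean(diag[0] * diag[2])
    )
    e_grad += g.g44 * sum(
        np.mean(grads[j][..., i] ** 2) for i in range(3) for j in range(3) if i != j
    )
    e_grad = float(e_grad)

    if config.elastic.enabled:
        _, e_elastic = _ElasticSolver(field.grid, config.elastic).solve(P)
    else:
        e_elastic = 0.0

    mean_p = field.mean_polarization()
    e_applied = -float(np.dot(config.applied_field, mean_p))
    e_defect = 0.0
    if config.defect_field is not None:
        e_defect = -float(np.mean(np.einsum("...i,...i->...", config.defect_field, P)))
    e_dep = 0.0
    if config.electrostatic_mode == "depolarization":
        Edep = depolarization_field(field, config.background_permittivity, config.open_circuit)
        e_dep = -0.5 * float(np.mean(np.einsum("...i,...i->...", Edep, P)))
    return EnergyBreakdown(
        bulk=e_bulk,
        gradient=e_grad,
        elastic=float(e_elastic),
        electrostatic=e_applied + e_defect + e_dep,
        applied=e_applied,
        defect=e_defect,
        depolarization=e_dep,
    )


# ---------------------------------------------------------------------------
# evolution


def evolve(field: PolarizationField, config: TdglConfig, steps: int) -> PolarizationField:
    """Advance the TDGL flow by ``steps`` semi-implicit spectral updates.

    Deterministic for fixed inputs.  Raises :class:`DivergenceError` when
    any |P| exceeds 10x the largest Landau minimum, which indicates a step
    size above the stability bound.
    """
    if steps < 0:
        raise ValueError("steps must be >= 0")
    config.check_defect_field(field.grid)
    ndim = field.grid.dimensions
    coeffs = coefficients_at(config.material, field.temperature)
    kappa = bulk_curvature_scale(coeffs)
    dt_eff = config.dt / kappa

    K = _gradient_operator(field.grid, config.gradient)
    if config.electrostatic_mode == "depolarization":
        K = K + _depolarization_operator(field.grid, config.background_permittivity)
    M = np.eye(3) + dt_eff * K
    Minv = np.linalg.inv(M)

    elastic_solver = _ElasticSolver(field.grid, config.elastic) if config.elastic.enabled else None
    p_limit = 10.0 * max(largest_ps(coeffs), 0.3)
    drive = config.applied_field.copy()
    if config.defect_field is not None:
        drive = drive + config.defect_field  # broadcast to grid

    P = field.vectors.copy()
    for _ in range(steps):
        force = bulk_energy_derivative(P, coeffs)
        force -= drive
        if elastic_solver is not None:
            sigma, _ = elastic_solver.solve(P)
            force += elastic_solver.driving_force(P, sigma)
        Pk = _fftn(P, ndim) - dt_eff * _fftn(force, ndim)
        P = _ifftn(np.einsum("...ij,...j->...i", Minv, Pk), ndim)
        peak = float(np.max(np.abs(P)))
        if not math.isfinite(peak) or peak > p_limit:
            raise DivergenceError(
                f"|P| reached {peak:.3g} C/m^2 (> {p_limit:.3g}); reduce dt below "
                f"the stability bound {DT_STABILITY_BOUND}"
            )
    return field.with_vectors(P, extra_steps=steps)


# ---------------------------------------------------------------------------
# hysteresis protocol


@dataclass(frozen=True)
class HysteresisLoop:
    """Triangular applied-field sweep vs mean swept-component polarization.

    The sweep runs 0 -> +max -> -max -> +max; the initial poling ramp
    (indices before the first +max) is kept for inspection, while the
    closed loop proper is the portion from the first +max sample onward.
    """

    field_values: np.ndarray
    mean_polarization: np.ndarray
    temperature: float
    equilibration_steps: int
    component: int = 0

    def __post_init__(self) -> None:
        if len(self.field_values) != len(self.mean_polarization):
            raise ValueError("field and polarization series lengths differ")
        if self.field_values[0] != self.field_values[-1] and not self.is_closed:
            raise ValueError("sweep does not close on a repeated field value")

    @property
    def loop_start(self) -> int:
        return int(np.argmax(self.field_values))

    @property
    def is_closed(self) -> bool:
        return bool(np.isclose(self.field_values[self.loop_start], self.field_values[-1]))

    def loop(self) -> tuple[np.ndarray, np.ndarray]:
        """(field, polarization) of the closed loop portion."""
        s = self.loop_start
        return self.field_values[s:], self.mean_polarization[s:]

    def saturation_polarization(self) -> float:
        return float(np.max(np.abs(self.mean_polarization)))

    def branches(self) -> tuple[tuple[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]]:
        """Descending (+max -> -max) and ascending (-max -> +max) branches."""
        E, Pm = self.loop()
        turn = int(np.argmin(E))
        return (E[: turn + 1], Pm[: turn + 1]), (E[turn:], Pm[turn:])


def triangular_sweep(max_field: float, n_steps: int) -> np.ndarray:
    """Field samples 0 -> +max (n_steps), +max -> -max, -max -> +max."""
    if n_steps < 8:
        raise ValueError("n_steps must be >= 8")
    if max_field <= 0:
        raise ValueError("max_field must be positive")
    up = np.linspace(0.0, max_field, n_steps + 1)
    down = np.linspace(max_field, -max_field, 2 * n_steps + 1)[1:]
    back = np.linspace(-max_field, max_field, 2 * n_steps + 1)[1:]
    return np.concatenate([up, down, back])


def run_hysteresis(
    field: PolarizationField,
    config: TdglConfig,
    component: int = 0,
    max_field: float = 5e6,
    n_steps: int = 20,
    equilibration_steps: int = 200,
) -> HysteresisLoop:
    """Drive a triangular field sweep, equilibrating the TDGL flow at each
    field value and recording the spatial mean of the swept component."""
    sweep = triangular_sweep(max_field, n_steps)
    means = np.empty_like(sweep)
    state = field
    for idx, value in enumerate(sweep):
        applied = np.zeros(3)
        applied[component] = value
        step_config = replace(config, applied_field=applied)
        state = evolve(state, step_config, equilibration_steps)
        means[idx] = state.mean_polarization()[component]
    return HysteresisLoop(
        field_values=sweep,
        mean_polarization=means,
        temperature=field.temperature,
        equilibration_steps=equilibration_steps,
        component=component,
    )
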