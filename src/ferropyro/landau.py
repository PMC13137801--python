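"""Landau-Devonshire thermodynamics of the cubic ferroelectric.

The zero-strain bulk free-energy density is the sextic expansion

    f(P) = a1 (P1^2+P2^2+P3^2) + a11 (P1^4+P2^4+P3^4)
         + a12 (P1^2 P2^2 + P2^2 P3^2 + P1^2 P3^2)
         + a111 (P1^6+P2^6+P3^6)
         + a112 [P1^4(P2^2+P3^2) + P2^4(P1^2+P3^2) + P3^4(P1^2+P2^2)]
         + a123 P1^2 P2^2 P3^2                                (J/m^3)

with P in C/m^2.  Along each high-symmetry line of the cubic parent the
energy reduces to ``A p^2 + B p^4 + C p^6`` in the common component
magnitude p, so the constrained minima of the tetragonal (one nonzero
component), orthorhombic (two equal components) and rhombohedral (three
equal components) phases are found analytically from the stationarity
condition, a quadratic in p^2.  On top of the minima the module provides
the stable-phase Ps(T) curve, the pyroelectric coefficient dPs/dT, and
energy profiles along polarization-rotation paths between phase minima.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .materials import LandauCoefficientSet, MaterialParameterization, coefficients_at

PHASES = ("paraelectric", "T", "O", "R")
FERRO_PHASES = ("T", "O", "R")

#: Representative unit directions used to embed a phase minimum in P-space.
_PHASE_DIRECTIONS = {
    "T": np.array([0.0, 0.0, 1.0]),
    "O": np.array([1.0, 1.0, 0.0]),
    "R": np.array([1.0, 1.0, 1.0]),
}


def j_per_m3_to_j_per_cm3(value: float) -> float:
    """Convert an energy density from J/m^3 to J/cm^3."""
    return value * 1e-6


def j_per_cm3_to_j_per_m3(value: float) -> float:
    """Convert an energy density from J/cm^3 to J/m^3."""
    return value * 1e6


def bulk_energy(P, coeffs: LandauCoefficientSet):
    """Sextic bulk free-energy density (J/m^3) of polarization ``P``.

    ``P`` is an array whose last axis holds the three polarization
    components in C/m^2; the result drops that axis.
    """
    P = np.asarray(P, dtype=float)
    p2 = P * P
    p4 = p2 * p2
    s2 = p2.sum(axis=-1)
    c = coeffs
    return (
        c.alpha1 * s2
        + c.alpha11 * p4.sum(axis=-1)
        + c.alpha12 * (p2[..., 0] * p2[..., 1] + p2[..., 1] * p2[..., 2] + p2[..., 0] * p2[..., 2])
        + c.alpha111 * (p4 * p2).sum(axis=-1)
        + c.alpha112
        * (
            p4[..., 0] * (p2[..., 1] + p2[..., 2])
            + p4[..., 1] * (p2[..., 0] + p2[..., 2])
            + p4[..., 2] * (p2[..., 0] + p2[..., 1])
        )
        + c.alpha123 * p2[..., 0] * p2[..., 1] * p2[..., 2]
    )


def bulk_energy_derivative(P, coeffs: LandauCoefficientSet):
    """Gradient of :func:`bulk_energy` with respect to the components of P.

    Returns an array of the same shape as ``P``; units are V/m (J/m^3 per
    C/m^2).  This is the thermodynamic driving force used by the phase-field
    solver.
    """
    P = np.asarray(P, dtype=float)
    p2 = P * P
    p4 = p2 * p2
    c = coeffs
    out = np.empty_like(P)
    for i in range(3):
        j, k = (i + 1) % 3, (i + 2) % 3
        out[..., i] = P[..., i] * (
            2.0 * c.alpha1
            + 4.0 * c.alpha11 * p2[..., i]
            + 2.0 * c.alpha12 * (p2[..., j] + p2[..., k])
            + 6.0 * c.alpha111 * p4[..., i]
            + c.alpha112 * (4.0 * p2[..., i] * (p2[..., j] + p2[..., k]) + 2.0 * (p4[..., j] + p4[..., k]))
            + 2.0 * c.alpha123 * p2[..., j] * p2[..., k]
        )
    return out


@dataclass(frozen=True)
class PhaseMinimum:
    """Constrained minimum of the bulk energy on one phase's symmetry line."""

    phase: str
    component_magnitude: float
    total_ps: float
    energy_density: float
    temperature: float
    metastable: bool = False

    @property
    def is_ferroelectric(self) -> bool:
        return self.phase != "paraelectric"

    def polarization_vector(self) -> np.ndarray:
        """Representative polarization vector of the minimum (C/m^2)."""
        if not self.is_ferroelectric:
            return np.zeros(3)
        return _PHASE_DIRECTIONS[self.phase] * self.component_magnitude


def phase_line_coefficients(phase: str, coeffs: LandauCoefficientSet) -> tuple[float, float, float, int]:
    """Coefficients (A, B, C, n) of ``f = A p^2 + B p^4 + C p^6`` along a
    phase's symmetry line, p being the shared component magnitude and n the
    number of nonzero components."""
    c = coeffs
    if phase == "T":
        return c.alpha1, c.alpha11, c.alpha111, 1
    if phase == "O":
        return 2 * c.alpha1, 2 * c.alpha11 + c.alpha12, 2 * c.alpha111 + 2 * c.alpha112, 2
    if phase == "R":
        return 3 * c.alpha1, 3 * (c.alpha11 + c.alpha12), 3 * c.alpha111 + 6 * c.alpha112 + c.alpha123, 3
    raise ValueError(f"phase must be one of {FERRO_PHASES}, got {phase!r}")


def _paraelectric(temperature: float) -> PhaseMinimum:
    return PhaseMinimum("paraelectric", 0.0, 0.0, 0.0, temperature)


def minimize_phase(
    phase: str, coeffs: LandauCoefficientSet, allow_metastable: bool = False
) -> PhaseMinimum:
    """Analytic constrained minimizer of the bulk energy for one phase.

    The stationarity condition along the symmetry line, ``A + 2B u + 3C u^2
    = 0`` with ``u = p^2``, is solved exactly; among the real positive roots
    only genuine local minima (positive on-line curvature) are kept, and the
    lower-energy one wins (degenerate roots resolve toward larger |P|).
    Unless ``allow_metastable`` is set, a minimum whose energy is >= 0 is
    reported as paraelectric, matching global-stability bookkeeping; with
    the flag, metastable ferroelectric minima are returned as such.
    """
    if phase == "paraelectric":
        return _paraelectric(coeffs.temperature)
    A, B, C, n = phase_line_coefficients(phase, coeffs)

    roots: list[float] = []
    if C != 0.0:
        disc = 4.0 * B * B - 12.0 * C * A
        if disc >= 0.0:
            sq = math.sqrt(disc)
            roots = [(-2.0 * B + sq) / (6.0 * C), (-2.0 * B - sq) / (6.0 * C)]
    elif B != 0.0:
        roots = [-A / (2.0 * B)]

    candidates: list[tuple[float, float]] = []  # (energy, u)
    for u in roots:
        if u <= 0.0 or not math.isfinite(u):
            continue
        curvature = 2.0 * A + 12.0 * B * u + 30.0 * C * u * u  # d2f/dp2 on the line
        if curvature <= 0.0:
            continue
        energy = A * u + B * u * u + C * u ** 3
        candidates.append((energy, u))
    if not candidates:
        return _paraelectric(coeffs.temperature)
    energy, u = min(candidates, key=lambda item: (item[0], -item[1]))
    if energy >= 0.0 and not allow_metastable:
        return _paraelectric(coeffs.temperature)
    p = math.sqrt(u)
    return PhaseMinimum(
        phase=phase,
        component_magnitude=p,
        total_ps=p * math.sqrt(n),
        energy_density=energy,
        temperature=coeffs.temperature,
        metastable=energy >= 0.0,
    )


@dataclass(frozen=True)
class PsTCurve:
    """Spontaneous polarization of the globally stable phase versus T."""

    temperatures: np.ndarray
    ps_values: np.ndarray
    stable_phase: tuple[str, ...]
    material_id: str
    conditions: str = "constant stress, constant (zero) field"

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        if t.ndim != 1 or t.size == 0:
            raise ValueError("temperatures must be a non-empty 1-D array")
        if np.any(np.diff(t) <= 0):
            raise ValueError("temperatures must be strictly increasing")


def stable_phase_diagram(material: str | MaterialParameterization, temperatures) -> PsTCurve:
    """Minimum-energy phase among {paraelectric, T, O, R} at each temperature."""
    temps = np.asarray(temperatures, dtype=float)
    ps = np.zeros_like(temps)
    phases: list[str] = []
    material_id = ""
    for idx, T in enumerate(temps):
        coeffs = coefficients_at(material, float(T))
        material_id = coeffs.material_id
        best = _paraelectric(float(T))
        for phase in FERRO_PHASES:
            candidate = minimize_phase(phase, coeffs)
            if candidate.energy_density < best.energy_density:
                best = candidate
        ps[idx] = best.total_ps
        phases.append(best.phase)
    return PsTCurve(temperatures=temps, ps_values=ps, stable_phase=tuple(phases), material_id=material_id)


@dataclass(frozen=True)
class PyroCoefficientSeries:
    """Pyroelectric coefficient rho = dPs/dT along a Ps(T) curve.

    ``rho`` keeps the signed derivative convention (negative approaching a
    transition on heating); :attr:`magnitudes` serves communities quoting
    |rho|.  Units: uC m^-2 K^-1.
    """

    temperatures: np.ndarray
    rho: np.ndarray

    @property
    def magnitudes(self) -> np.ndarray:
        return np.abs(self.rho)

    def peak_temperature(self) -> float:
        """Temperature of maximal |rho|."""
        return float(self.temperatures[int(np.argmax(self.magnitudes))])


def pyroelectric_coefficient(curve: PsTCurve) -> PyroCoefficientSeries:
    """Finite-difference dPs/dT in uC m^-2 K^-1 (central interior,
    one-sided at the ends); requires >= 3 uniformly spaced temperatures."""
    t = np.asarray(curve.temperatures, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 temperature points")
    steps = np.diff(t)
    if not np.allclose(steps, steps[0], rtol=1e-8, atol=0.0):
        raise ValueError("temperature grid must be uniformly spaced")
    rho = np.gradient(np.asarray(curve.ps_values, dtype=float), t) * 1e6
    return PyroCoefficientSeries(temperatures=t, rho=rho)


def enhancement_percent(rho_test: float, rho_ref: float) -> float:
    """Percent enhancement of one pyroelectric coefficient over a reference,
    computed on magnitudes: 100*(|rho_test| - |rho_ref|)/|rho_ref|."""
    if rho_ref == 0:
        raise ValueError("reference pyroelectric coefficient must be nonzero")
    return 100.0 * (abs(rho_test) - abs(rho_ref)) / abs(rho_ref)


@dataclass(frozen=True)
class EnergyBarrierProfile:
    """Bulk energy sampled along a path between two phase minima."""

    path_parameter: np.ndarray
    energy_density: np.ndarray
    endpoints: tuple[PhaseMinimum, PhaseMinimum]
    path_mode: str = "linear"
    polarization_path: np.ndarray = field(default=None, repr=False)

    @property
    def barrier_heights(self) -> tuple[float, float]:
        """(max-over-path minus energy of endpoint a, same for endpoint b)."""
        peak = float(self.energy_density.max())
        return (peak - self.endpoints[0].energy_density, peak - self.endpoints[1].energy_density)

    @property
    def energy_gap(self) -> float:
        """Absolute inter-minimum energy difference (J/m^3)."""
        return abs(self.endpoints[0].energy_density - self.endpoints[1].energy_density)

    @property
    def energy_gap_j_per_cm3(self) -> float:
        return j_per_m3_to_j_per_cm3(self.energy_gap)


def barrier_profile(
    phase_a: str,
    phase_b: str,
    coeffs: LandauCoefficientSet,
    n_points: int = 101,
    path_mode: str = "linear",
) -> EnergyBarrierProfile:
    """Energy profile along a polarization-rotation path between two phases.

    Endpoints are the analytic (meta)stable minima of each phase.  The
    default path is the straight segment in P-space; ``path_mode='arc'``
    interpolates the direction on the unit sphere with the magnitude varying
    linearly, a constant-|P|-style rotation path.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    minima = []
    for phase in (phase_a, phase_b):
        m = minimize_phase(phase, coeffs, allow_metastable=True)
        if not m.is_ferroelectric:
            raise ValueError(
                f"phase {phase!r} has no ferroelectric minimum at {coeffs.temperature} K; no rotation path exists"
            )
        minima.append(m)
    pa, pb = (m.polarization_vector() for m in minima)
    s = np.linspace(0.0, 1.0, n_points)
    if path_mode == "linear":
        path = pa[None, :] * (1.0 - s[:, None]) + pb[None, :] * s[:, None]
    elif path_mode == "arc":
        na, nb = pa / np.linalg.norm(pa), pb / np.linalg.norm(pb)
        angle = math.acos(float(np.clip(np.dot(na, nb), -1.0, 1.0)))
        if angle < 1e-12:
            dirs = np.repeat(na[None, :], n_points, axis=0)
        else:
            dirs = (
                np.sin((1.0 - s)[:, None] * angle) * na[None, :] + np.sin(s[:, None] * angle) * nb[None, :]
            ) / math.sin(angle)
        mags = np.linalg.norm(pa) * (1.0 - s) + np.linalg.norm(pb) * s
        path = dirs * mags[:, None]
    else:
        raise ValueError("path_mode must be 'linear' or 'arc'")
    energy = bulk_energy(path, coeffs)
    return EnergyBarrierProfile(
        path_parameter=s,
        energy_density=energy,
        endpoints=(minima[0], minima[1]),
        path_mode=path_mode,
        polarization_path=path,
    )


def bulk_curvature_scale(coeffs: LandauCoefficientSet, safety: float = 1.5) -> float:
    """Largest linearized bulk stiffness |d2f/dP2| over the phase minima and
    the origin, times a safety factor.  Used to nondimensionalize TDGL time
    so that the explicit-bulk stability bound is grid- and T-independent."""
    scales = [abs(2.0 * coeffs.alpha1)]
    for phase in FERRO_PHASES:
        m = minimize_phase(phase, coeffs, allow_metastable=True)
        if m.is_ferroelectric:
            A, B, C, _ = phase_line_coefficients(phase, coeffs)
            u = m.component_magnitude ** 2
            scales.append(abs(2.0 * A + 12.0 * B * u + 30.0 * C * u * u))
    return safety * max(max(scales), 1e3)


def largest_ps(coeffs: LandauCoefficientSet) -> float:
    """Largest total spontaneous polarization among the (meta)stable phase
    minima (C/m^2); 0 if the material is paraelectric at this temperature."""
    best = 0.0
    for phase in FERRO_PHASES:
        m = minimize_phase(phase, coeffs, allow_metastable=True)
        best = max(best, m.total_ps)
    return best
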