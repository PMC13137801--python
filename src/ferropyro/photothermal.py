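"""Lumped photothermal cycling and pyroelectric device response.

Laser-driven heating/cooling of a nanoparticle suspension is modelled as a
single thermal node with Newtonian exchange: during the on-stage the
temperature relaxes exponentially toward a steady state set by the
absorbed power over the loss coefficient, and during the off-stage it
decays back to ambient.  Each stage is a closed-form exponential segment,
so traces carry no ODE discretization error.

The device response uses the lumped relations

    V = p * dT * a / (eps_r * eps0)     (open-circuit pyro-potential)
    i = p * A * dT/dt                   (pyro-current)
    Q = p * A * dT                      (released charge per half-cycle)

with the pyroelectric coefficient p in uC m^-2 K^-1, the characteristic
size a in m, and eps interpreted as the absolute permittivity eps_r*eps0
(the only reading under which the relation is dimensionally a voltage).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import constants

EPS0 = constants.epsilon_0


@dataclass(frozen=True)
class ThermalCycleProtocol:
    """Lumped on/off laser heating protocol.

    ``flux`` is the irradiance in W/cm^2; the absorbed power is
    ``absorption_efficiency * flux * absorbing_area`` (area in m^2).
    ``heat_capacity_eff`` (J/K) and ``loss_coefficient`` (W/K) define the
    thermal time constant tau = C/k.
    """

    flux: float = 1.0
    on_duration: float = 70.0
    off_duration: float = 100.0
    n_cycles: int = 2
    ambient: float = 308.15  # 35 C
    absorption_efficiency: float = 1.0
    absorbing_area: float = 9e-12  # m^2, (3000 nm)^2 cross-section
    heat_capacity_eff: float = 2.63e-7  # J/K
    loss_coefficient: float = 7.89e-9  # W/K

    def __post_init__(self) -> None:
        if self.on_duration <= 0 or self.off_duration <= 0:
            raise ValueError("stage durations must be positive")
        if self.flux < 0:
            raise ValueError("flux must be >= 0")
        if self.loss_coefficient <= 0 or self.heat_capacity_eff <= 0:
            raise ValueError("loss and heat-capacity coefficients must be positive")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")

    @property
    def tau(self) -> float:
        """Thermal time constant C/k (s)."""
        return self.heat_capacity_eff / self.loss_coefficient

    @property
    def absorbed_power(self) -> float:
        """eta * flux * area, in W (flux converted from W/cm^2)."""
        return self.absorption_efficiency * self.flux * 1e4 * self.absorbing_area

    @property
    def steady_state_rise(self) -> float:
        """Asymptotic on-stage temperature rise above ambient (K)."""
        return self.absorbed_power / self.loss_coefficient


@dataclass(frozen=True)
class ThermalTrace:
    """Time series of lumped temperature under a cycling protocol.

    ``rates`` holds the exact analytic dT/dt (K/s) of each sample, not a
    finite difference, so downstream charge integrals carry no
    differentiation error.
    """

    times: np.ndarray
    temperatures: np.ndarray
    rates: np.ndarray
    protocol: ThermalCycleProtocol

    def peak_rise(self) -> float:
        return float(self.temperatures.max() - self.protocol.ambient)

    def stage_endpoints(self) -> np.ndarray:
        """Exact temperatures at every stage switch (including start/end)."""
        tau = self.protocol.tau
        T = self.protocol.ambient
        points = [T]
        for _ in range(self.protocol.n_cycles):
            for duration, target in (
                (self.protocol.on_duration, self.protocol.ambient + self.protocol.steady_state_rise),
                (self.protocol.off_duration, self.protocol.ambient),
            ):
                T = target - (target - T) * math.exp(-duration / tau)
                points.append(T)
        return np.array(points)


def simulate_thermal_cycles(
    protocol: ThermalCycleProtocol, samples_per_stage: int = 200
) -> ThermalTrace:
    """Exact exponential-segment solution of the lumped thermal model.

    On-stage: T(t) = T_ss - (T_ss - T_start) exp(-t/tau) with T_ss =
    ambient + steady_state_rise; off-stage decays toward ambient with the
    same tau.  Segments stitch continuously; switch-point samples are kept
    once (no duplicated times).
    """
    tau = protocol.tau
    if not math.isfinite(tau) or tau <= 0:
        raise ValueError("thermal time constant must be positive and finite")
    times: list[np.ndarray] = []
    temps: list[np.ndarray] = []
    rates: list[np.ndarray] = []
    t0 = 0.0
    T_current = protocol.ambient
    first = True
    for _ in range(protocol.n_cycles):
        for duration, target in (
            (protocol.on_duration, protocol.ambient + protocol.steady_state_rise),
            (protocol.off_duration, protocol.ambient),
        ):
            t_local = np.linspace(0.0, duration, samples_per_stage)
            seg = target - (target - T_current) * np.exp(-t_local / tau)
            rate = (target - seg) / tau
            keep = slice(None) if first else slice(1, None)
            times.append(t0 + t_local[keep])
            temps.append(seg[keep])
            rates.append(rate[keep])
            t0 += duration
            T_current = float(seg[-1])
            first = False
    return ThermalTrace(
        times=np.concatenate(times),
        temperatures=np.concatenate(temps),
        rates=np.concatenate(rates),
        protocol=protocol,
    )


def calibrate_protocol(
    peak_rise: float = 10.0,
    residual: float = 0.5,
    flux: float = 1.0,
    on_duration: float = 70.0,
    off_duration: float = 100.0,
    ambient: float = 308.15,
    n_cycles: int = 2,
    absorption_efficiency: float = 1.0,
    absorbing_area: float = 9e-12,
) -> ThermalCycleProtocol:
    """Solve the lumped coefficients from two observable conditions.

    The pair {on-stage rise of ``peak_rise`` K after ``on_duration`` s,
    decay to within ``residual`` K of ambient after ``off_duration`` s of
    cooling} determines the time constant in closed form, tau =
    off_duration / ln(peak_rise / residual), and then the loss coefficient
    from the absorbed power; deterministic, no free parameters left.
    """
    if not 0 < residual < peak_rise:
        raise ValueError("need 0 < residual < peak_rise")
    tau = off_duration / math.log(peak_rise / residual)
    ss_rise = peak_rise / (1.0 - math.exp(-on_duration / tau))
    absorbed = absorption_efficiency * flux * 1e4 * absorbing_area
    if absorbed <= 0:
        raise ValueError("absorbed power must be positive to calibrate")
    loss = absorbed / ss_rise
    return ThermalCycleProtocol(
        flux=flux,
        on_duration=on_duration,
        off_duration=off_duration,
        n_cycles=n_cycles,
        ambient=ambient,
        absorption_efficiency=absorption_efficiency,
        absorbing_area=absorbing_area,
        heat_capacity_eff=tau * loss,
        loss_coefficient=loss,
    )


@dataclass(frozen=True)
class PyroDeviceParams:
    """Lumped pyroelectric device parameters."""

    pyro_coefficient: float = 400.0  # uC m^-2 K^-1
    relative_permittivity: float = 2400.0
    characteristic_size: float = 3000e-9  # m
    electrode_area: float | None = None  # m^2

    def __post_init__(self) -> None:
        if self.relative_permittivity <= 1:
            raise ValueError("relative permittivity must exceed 1")
        if self.characteristic_size <= 0:
            raise ValueError("characteristic size must be positive")


def pyro_potential(params: PyroDeviceParams, delta_T: float) -> float:
    """Open-circuit pyroelectric potential V = p dT a / (eps_r eps0), in V."""
    p_si = params.pyro_coefficient * 1e-6  # C m^-2 K^-1
    return p_si * delta_T * params.characteristic_size / (params.relative_permittivity * EPS0)


def pyro_current(params: PyroDeviceParams, dT_dt) -> np.ndarray | float:
    """Signed pyro-current i = p A dT/dt (A); requires electrode_area."""
    if params.electrode_area is None:
        raise ValueError("electrode_area must be set to compute a pyro-current")
    return params.pyro_coefficient * 1e-6 * params.electrode_area * np.asarray(dT_dt, dtype=float)


def charge_per_halfcycle(params: PyroDeviceParams, delta_T: float) -> float:
    """Released charge over one monotone thermal stage, Q = p A dT (C)."""
    if params.electrode_area is None:
        raise ValueError("electrode_area must be set to compute released charge")
    return params.pyro_coefficient * 1e-6 * params.electrode_area * delta_T
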