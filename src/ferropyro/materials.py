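"""Material coefficient sets for the Landau-Devonshire free energy.

A material is described by six sextic-polynomial coefficients, each
parameterized linearly in temperature as ``alpha(T) = slope*(T - t_ref) +
offset``.  Coefficient sets for Ba(Ti0.85Zr0.15)O3 (``btz``) and BaTiO3
(``bto``) ship as TOML files under :mod:`ferropyro.data`; additional
materials can be loaded from user TOML files of the same layout.

Units are SI throughout: alpha1 in C^-2 m^2 N, alpha11/alpha12 in
C^-4 m^6 N, alpha111/alpha112/alpha123 in C^-6 m^10 N, temperature in K.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

COEFFICIENT_NAMES = ("alpha1", "alpha11", "alpha12", "alpha111", "alpha112", "alpha123")

_BUILTIN = ("btz", "bto")


class UnknownMaterialError(KeyError):
    """Requested material id is not registered."""


@dataclass(frozen=True)
class CoefficientFormula:
    """Linear-in-temperature coefficient: ``slope*(T - t_ref) + offset``."""

    slope: float
    t_ref: float
    offset: float

    def __call__(self, temperature: float) -> float:
        return self.slope * (temperature - self.t_ref) + self.offset

    @property
    def temperature_dependent(self) -> bool:
        return self.slope != 0.0


@dataclass(frozen=True)
class MaterialParameterization:
    """A named set of temperature-dependent Landau coefficient formulas."""

    material_id: str
    formulas: dict[str, CoefficientFormula]
    source: str = ""

    def __post_init__(self) -> None:
        missing = set(COEFFICIENT_NAMES) - set(self.formulas)
        if missing:
            raise ValueError(f"material {self.material_id!r} missing coefficients: {sorted(missing)}")


@dataclass(frozen=True)
class LandauCoefficientSet:
    """Sextic free-energy coefficients of one material at one temperature."""

    material_id: str
    temperature: float
    alpha1: float
    alpha11: float
    alpha12: float
    alpha111: float
    alpha112: float
    alpha123: float


def _parse_material(payload: dict, origin: str) -> MaterialParameterization:
    try:
        material_id = payload["material_id"]
        formulas = {
            name: CoefficientFormula(
                slope=float(payload[name]["slope"]),
                t_ref=float(payload[name]["t_ref"]),
                offset=float(payload[name]["offset"]),
            )
            for name in COEFFICIENT_NAMES
        }
    except KeyError as exc:
        raise ValueError(f"malformed material file {origin}: missing key {exc}") from exc
    return MaterialParameterization(material_id=material_id, formulas=formulas, source=payload.get("source", origin))


def load_material(path: str | Path) -> MaterialParameterization:
    """Load a material parameterization from a TOML file."""
    path = Path(path)
    with path.open("rb") as handle:
        return _parse_material(tomllib.load(handle), str(path))


def _load_builtin(material_id: str) -> MaterialParameterization:
    data = resources.files("ferropyro.data").joinpath(f"{material_id}.toml").read_bytes()
    return _parse_material(tomllib.loads(data.decode()), f"builtin:{material_id}")


def available_materials() -> tuple[str, ...]:
    return _BUILTIN


def get_material(material: str | MaterialParameterization) -> MaterialParameterization:
    """Resolve a material id (or pass a parameterization through)."""
    if isinstance(material, MaterialParameterization):
        return material
    key = str(material).lower()
    if key not in _BUILTIN:
        raise UnknownMaterialError(
            f"unknown material {material!r}; available sets: {', '.join(_BUILTIN)}"
        )
    return _load_builtin(key)


def coefficients_at(material: str | MaterialParameterization, temperature: float) -> LandauCoefficientSet:
    """Evaluate a material's Landau coefficients at one temperature (K)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive (got {temperature} K)")
    param = get_material(material)
    values = {name: formula(temperature) for name, formula in param.formulas.items()}
    return LandauCoefficientSet(material_id=param.material_id, temperature=float(temperature), **values)
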