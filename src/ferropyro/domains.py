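"""Classification of polarization vectors into ferroelectric phase variants.

A cubic paraelectric parent admits 26 polar variants: 6 tetragonal <100>,
12 orthorhombic <110> and 8 rhombohedral <111> directions.  Cells whose
polarization magnitude falls below a threshold are labelled paraelectric;
every other cell takes the variant whose unit direction maximizes the
cosine with the local polarization.  The canonical variant order (T block,
then O, then R, each block sorted lexicographically by direction
components) fixes tie-breaking and export codes.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from .fields import PolarizationField, SimulationGrid

PHASE_ORDER = ("T", "O", "R")
PARA_LABEL = "para"


@dataclass(frozen=True)
class Variant:
    label: str
    phase: str
    direction: np.ndarray


def _sorted_directions(raw: list[tuple[float, float, float]]) -> list[np.ndarray]:
    arr = [np.array(v, dtype=float) for v in raw]
    arr.sort(key=lambda v: tuple(v))
    return [v / np.linalg.norm(v) for v in arr]


def _build_variants() -> tuple[Variant, ...]:
    t_dirs = [tuple(s * np.eye(3)[i]) for i in range(3) for s in (+1.0, -1.0)]
    o_dirs = []
    for i, j in ((0, 1), (0, 2), (1, 2)):
        for si, sj in product((+1.0, -1.0), repeat=2):
            v = [0.0, 0.0, 0.0]
            v[i], v[j] = si, sj
            o_dirs.append(tuple(v))
    r_dirs = [tuple(s) for s in product((+1.0, -1.0), repeat=3)]
    variants: list[Variant] = []
    for phase, dirs in zip(PHASE_ORDER, (t_dirs, o_dirs, r_dirs)):
        for idx, direction in enumerate(_sorted_directions(dirs), start=1):
            variants.append(Variant(label=f"{phase}{idx}", phase=phase, direction=direction))
    return tuple(variants)


_VARIANTS = _build_variants()
_DIRECTIONS = np.stack([v.direction for v in _VARIANTS])  # (26, 3)
#: code 0 is paraelectric; codes 1..26 index the canonical variant order.
LABELS = (PARA_LABEL,) + tuple(v.label for v in _VARIANTS)


def enumerate_variants() -> tuple[Variant, ...]:
    """The 26 polar variants of the cubic parent in canonical order."""
    return _VARIANTS


def variant_code(label: str) -> int:
    return LABELS.index(label)


@dataclass(frozen=True)
class VariantMap:
    """Per-cell variant codes plus the classification parameters used."""

    grid: SimulationGrid
    codes: np.ndarray  # integer grid, 0 = para, 1..26 = variants
    threshold: float
    angle_tolerance: float = 15.0

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes)
        if codes.shape != self.grid.shape:
            raise ValueError("codes shape does not match grid")
        if codes.min() < 0 or codes.max() > 26:
            raise ValueError("variant codes must lie in 0..26")
        object.__setattr__(self, "codes", codes.astype(np.int8))

    def labels(self) -> np.ndarray:
        return np.asarray(LABELS, dtype=object)[self.codes]


@dataclass(frozen=True)
class PhaseFractionReport:
    fractions: dict[str, float]
    variant_counts: dict[str, int]

    @property
    def n_variant_classes(self) -> int:
        """Number of distinct non-paraelectric variants present."""
        return sum(1 for label, count in self.variant_counts.items() if count and label != PARA_LABEL)


def classify_cell(P, threshold: float, angle_tolerance: float = 15.0) -> str:
    """Variant label of a single polarization vector."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    P = np.asarray(P, dtype=float)
    norm = np.linalg.norm(P)
    if norm < threshold or norm == 0.0:
        return PARA_LABEL
    return _VARIANTS[int(np.argmax(_DIRECTIONS @ (P / norm)))].label


def classify_field(
    field: PolarizationField, threshold: float, angle_tolerance: float = 15.0
) -> VariantMap:
    """Classify every cell of a polarization field (vectorized)."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    vectors = field.vectors.reshape(-1, 3)
    norms = np.linalg.norm(vectors, axis=1)
    codes = np.zeros(vectors.shape[0], dtype=np.int8)
    polar = norms >= max(threshold, 1e-300)
    if np.any(polar):
        cosines = vectors[polar] @ _DIRECTIONS.T
        codes[polar] = np.argmax(cosines, axis=1) + 1
    return VariantMap(
        grid=field.grid,
        codes=codes.reshape(field.grid.shape),
        threshold=threshold,
        angle_tolerance=angle_tolerance,
    )


def default_threshold(material, temperature: float) -> float:
    """Default paraelectric cutoff: 5% of the largest single-domain Ps at
    this temperature (separates polar-region interiors from walls)."""
    from .landau import largest_ps
    from .materials import coefficients_at

    return 0.05 * largest_ps(coefficients_at(material, temperature))


def phase_fractions(variant_map: VariantMap) -> PhaseFractionReport:
    """Normalized phase fractions and per-variant counts of a variant map."""
    counts = np.bincount(variant_map.codes.ravel(), minlength=27)
    total = counts.sum()
    variant_counts = {label: int(c) for label, c in zip(LABELS, counts)}
    fractions = {PARA_LABEL: float(counts[0] / total)}
    for phase in PHASE_ORDER:
        idx = [i for i, v in enumerate(_VARIANTS, start=1) if v.phase == phase]
        fractions[phase] = float(counts[idx].sum() / total)
    return PhaseFractionReport(fractions=fractions, variant_counts=variant_counts)
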