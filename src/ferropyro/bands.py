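"""Band alignment on the NHE scale and optical bandgap extraction.

The valence-band maximum is placed on the normal-hydrogen-electrode scale
from XPS observables via E_NHE/V = phi + Ef - 4.44 (phi the work function
of the spectrometer, Ef the VB-XPS edge below the Fermi level, 4.44 eV the
absolute potential of the NHE).  The conduction-band minimum follows from
the optical bandgap, CBM = VBM - Eg, identifying eV and V for
single-electron levels.  Against a ladder of ROS half-reactions, a
reduction is feasible when the CBM lies below (more negative than) the
reaction potential, an oxidation when the VBM lies above it.

Optical bandgaps come from Tauc analysis of absorbance spectra: the
transformed signal (alpha*h*nu)^2 (direct) or (alpha*h*nu)^(1/2)
(indirect) is fit linearly over the steepest well-linear window and
extrapolated to its x-intercept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

NHE_ABSOLUTE_POTENTIAL = 4.44  # eV, absolute electrode potential of the NHE


class TaucExtractionError(RuntimeError):
    """No sufficiently linear absorption-edge window was found."""


def nhe_from_xps(work_function: float, vb_edge: float) -> float:
    """Electrode potential (V vs NHE) of a VB-XPS level: phi + Ef - 4.44."""
    if work_function <= 0:
        raise ValueError("work function must be positive")
    return work_function + vb_edge - NHE_ABSOLUTE_POTENTIAL


def cbm_from_vbm(vbm_nhe: float, bandgap: float) -> float:
    """Conduction-band minimum on the NHE scale: VBM - Eg."""
    if bandgap < 0:
        raise ValueError("bandgap must be non-negative")
    return vbm_nhe - bandgap


@dataclass(frozen=True)
class BandAlignment:
    """VBM/CBM on the NHE scale plus the XPS inputs that produced them."""

    vbm_nhe: float
    cbm_nhe: float
    bandgap: float
    work_function: float | None = None
    vb_edge: float | None = None

    def __post_init__(self) -> None:
        if self.bandgap <= 0:
            raise ValueError("bandgap must be positive")
        if abs(self.cbm_nhe - (self.vbm_nhe - self.bandgap)) > 1e-9:
            raise ValueError("inconsistent alignment: CBM must equal VBM - Eg")

    @classmethod
    def from_vbm(cls, vbm_nhe: float, bandgap: float) -> "BandAlignment":
        return cls(vbm_nhe=vbm_nhe, cbm_nhe=cbm_from_vbm(vbm_nhe, bandgap), bandgap=bandgap)

    @classmethod
    def from_xps(cls, work_function: float, vb_edge: float, bandgap: float) -> "BandAlignment":
        vbm = nhe_from_xps(work_function, vb_edge)
        return cls(
            vbm_nhe=vbm,
            cbm_nhe=cbm_from_vbm(vbm, bandgap),
            bandgap=bandgap,
            work_function=work_function,
            vb_edge=vb_edge,
        )


@dataclass(frozen=True)
class HalfReaction:
    name: str
    potential_nhe: float  # V vs NHE
    kind: str  # "reduction" or "oxidation"

    def __post_init__(self) -> None:
        if self.kind not in ("reduction", "oxidation"):
            raise ValueError("kind must be 'reduction' or 'oxidation'")


#: ROS half-reactions relevant to pyro-catalytic therapy.
DEFAULT_LADDER: tuple[HalfReaction, ...] = (
    HalfReaction("O2/.O2-", -0.33, "reduction"),
    HalfReaction("H2O2/.OH", +0.73, "reduction"),
    HalfReaction("OH-/.OH", +1.5, "oxidation"),
)


@dataclass(frozen=True)
class ReactionVerdict:
    reaction: HalfReaction
    margin: float  # V; positive means thermodynamically permitted
    feasible: bool


@dataclass(frozen=True)
class FeasibilityReport:
    alignment: BandAlignment
    verdicts: tuple[ReactionVerdict, ...]

    @property
    def all_feasible(self) -> bool:
        return all(v.feasible for v in self.verdicts)

    def __getitem__(self, name: str) -> ReactionVerdict:
        for v in self.verdicts:
            if v.reaction.name == name:
                return v
        raise KeyError(name)


def ros_feasibility(
    alignment: BandAlignment, ladder: tuple[HalfReaction, ...] = DEFAULT_LADDER
) -> FeasibilityReport:
    """Thermodynamic feasibility of each half-reaction given the alignment.

    Reduction margin = E_reaction - CBM (electrons fall down); oxidation
    margin = VBM - E_reaction (holes fall up).  A reaction is permitted for
    a strictly positive margin.
    """
    verdicts = []
    for reaction in ladder:
        if reaction.kind == "reduction":
            margin = reaction.potential_nhe - alignment.cbm_nhe
        else:
            margin = alignment.vbm_nhe - reaction.potential_nhe
        verdicts.append(ReactionVerdict(reaction=reaction, margin=margin, feasible=margin > 0))
    return FeasibilityReport(alignment=alignment, verdicts=tuple(verdicts))


@dataclass(frozen=True)
class AbsorbanceSpectrum:
    """Absorbance vs photon energy, with the Tauc exponent convention."""

    photon_energies: np.ndarray  # eV, strictly increasing
    absorbance: np.ndarray  # arbitrary units, >= 0
    tauc_exponent: str = "direct"  # plot (alpha h nu)^2; "indirect" -> ^(1/2)

    def __post_init__(self) -> None:
        e = np.asarray(self.photon_energies, dtype=float)
        a = np.asarray(self.absorbance, dtype=float)
        if e.ndim != 1 or e.shape != a.shape:
            raise ValueError("energies and absorbance must be matching 1-D arrays")
        if np.any(np.diff(e) <= 0):
            raise ValueError("photon energies must be strictly increasing")
        if np.any(a < 0):
            raise ValueError("absorbance must be non-negative")
        if self.tauc_exponent not in ("direct", "indirect"):
            raise ValueError("tauc_exponent must be 'direct' or 'indirect'")
        object.__setattr__(self, "photon_energies", e)
        object.__setattr__(self, "absorbance", a)

    def tauc_signal(self) -> np.ndarray:
        power = 2.0 if self.tauc_exponent == "direct" else 0.5
        return (self.absorbance * self.photon_energies) ** power


@dataclass(frozen=True)
class TaucFit:
    bandgap: float  # eV
    slope: float
    intercept: float
    r_squared: float
    window: tuple[int, int]  # [start, stop) indices of the fitted run


def _window_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2)


def tauc_bandgap(spectrum: AbsorbanceSpectrum, fit_window: tuple[int, int] | None = None) -> TaucFit:
    """Optical bandgap from linear extrapolation of the Tauc plot.

    With ``fit_window=None`` the window is auto-selected: among sliding
    windows the maximal-slope one with R^2 >= 0.995 wins; if none
    qualifies, the fit falls back to the points whose smoothed local slope
    sits in the top quartile.  An explicit ``(start, stop)`` index window
    bypasses the search for reproducibility.  Raises
    :class:`TaucExtractionError` when the best achievable R^2 < 0.9.
    """
    e = spectrum.photon_energies
    y = spectrum.tauc_signal()
    n = e.size
    if n < 20:
        raise ValueError("need at least 20 spectral points spanning the absorption edge")

    if fit_window is not None:
        start, stop = fit_window
        slope, intercept, r2 = _window_fit(e[start:stop], y[start:stop])
        if slope <= 0:
            raise TaucExtractionError("explicit window has non-positive slope")
        return TaucFit(-intercept / slope, slope, intercept, r2, (start, stop))

    width = max(10, n // 10)
    best: TaucFit | None = None
    for start in range(0, n - width + 1):
        stop = start + width
        slope, intercept, r2 = _window_fit(e[start:stop], y[start:stop])
        if slope <= 0 or r2 < 0.995:
            continue
        if best is None or slope > best.slope:
            best = TaucFit(-intercept / slope, slope, intercept, r2, (start, stop))
    if best is not None:
        return best

    # fallback: fit across the top-slope quartile of the smoothed derivative
    smooth = signal.savgol_filter(y, window_length=min(n - (n + 1) % 2, max(11, width | 1)), polyorder=2)
    local_slope = np.gradient(smooth, e)
    cutoff = np.quantile(local_slope, 0.75)
    mask = local_slope >= cutoff
    if mask.sum() < 5:
        raise TaucExtractionError("absorption edge too short for a quartile fallback fit")
    slope, intercept, r2 = _window_fit(e[mask], y[mask])
    if slope <= 0 or r2 < 0.9:
        raise TaucExtractionError(
            f"no linear absorption-edge window found (best fallback R^2={r2:.3f}, slope={slope:.3g})"
        )
    idx = np.flatnonzero(mask)
    return TaucFit(-intercept / slope, slope, intercept, r2, (int(idx[0]), int(idx[-1]) + 1))
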