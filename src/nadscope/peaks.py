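"""Prior-knowledge peak library for cardiac 31P spectra.

The fitting model is driven entirely by a structured library of peak
specifications: for each resonance a nominal chemical shift, a multiplet
pattern (singlet / doublet / quartet from J-coupling), the relative
amplitudes of the multiplet components, and a line-width constraint class.
All non-ATP metabolites share one line width within a fit; the
mitochondrial NAD(P)H resonance is allowed a width of 1.5-3x the shared
width, reflecting the broader line produced by the matrix environment.

Default chemical shifts follow the convention of referencing PCr to
-2.54 ppm.  They are configurable placeholders, not calibrated constants:
quantitative correctness is always established against synthetic ground
truth generated from the same library.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

__all__ = [
    "PeakSpec",
    "PeakModel",
    "PEAK_NAMES",
    "default_library",
    "load_peak_library",
    "save_peak_library",
]

PEAK_NAMES = (
    "PCr",
    "gammaATP",
    "alphaATP",
    "NADplus",
    "NADH_cyt",
    "NADPplus",
    "NADPH_cyt",
    "UDPglucose",
    "mitoNADPH",
)

_MULTIPLICITY_SIZE = {"singlet": 1, "doublet": 2, "quartet": 4}


@dataclass(frozen=True)
class PeakSpec:
    """One resonance: position, multiplet pattern and width class.

    ``coupling_ppm`` is the spacing between adjacent multiplet components;
    it must be 0 for a singlet and positive otherwise.  ``component_ratios``
    are the relative amplitudes of the components and are normalized to
    sum to 1.  ``width_class`` is ``"shared"`` for peaks tied to the common
    line width and ``"mito_scaled"`` for the mitochondrial NAD(P)H peak.
    """

    name: str
    center_ppm: float
    multiplicity: str = "singlet"
    coupling_ppm: float = 0.0
    component_ratios: tuple[float, ...] = ()
    width_class: str = "shared"

    def __post_init__(self) -> None:
        if self.multiplicity not in _MULTIPLICITY_SIZE:
            raise ValueError(
                f"peak {self.name!r}: unknown multiplicity {self.multiplicity!r}"
            )
        n = _MULTIPLICITY_SIZE[self.multiplicity]
        ratios = self.component_ratios
        if not ratios:
            ratios = tuple(1.0 for _ in range(n))
        if len(ratios) != n:
            raise ValueError(
                f"peak {self.name!r}: {self.multiplicity} needs {n} component "
                f"ratios, got {len(ratios)}"
            )
        if any(r <= 0 for r in ratios):
            raise ValueError(f"peak {self.name!r}: component ratios must be positive")
        total = float(sum(ratios))
        object.__setattr__(self, "component_ratios", tuple(r / total for r in ratios))
        if self.multiplicity == "singlet" and self.coupling_ppm != 0:
            raise ValueError(f"peak {self.name!r}: singlet must have coupling_ppm = 0")
        if self.multiplicity != "singlet" and self.coupling_ppm <= 0:
            raise ValueError(
                f"peak {self.name!r}: {self.multiplicity} needs coupling_ppm > 0"
            )
        if self.width_class not in ("shared", "mito_scaled"):
            raise ValueError(
                f"peak {self.name!r}: unknown width_class {self.width_class!r}"
            )

    @property
    def n_components(self) -> int:
        return _MULTIPLICITY_SIZE[self.multiplicity]

    def component_offsets(self) -> np.ndarray:
        """Offsets of multiplet components from the multiplet center, in ppm."""
        n = self.n_components
        return (np.arange(n) - (n - 1) / 2.0) * self.coupling_ppm


@dataclass(frozen=True)
class PeakModel:
    """The full prior-knowledge library plus the fit's box constraints."""

    peaks: tuple[PeakSpec, ...]
    shared_width_bounds: tuple[float, float] = (0.01, 0.40)
    mito_width_ratio_bounds: tuple[float, float] = (1.5, 3.0)
    center_jitter_bound: float = 0.05

    def __post_init__(self) -> None:
        object.__setattr__(self, "peaks", tuple(self.peaks))
        for lo, hi, label in (
            (*self.shared_width_bounds, "shared_width_bounds"),
            (*self.mito_width_ratio_bounds, "mito_width_ratio_bounds"),
        ):
            if not (0 < lo < hi):
                raise ValueError(f"{label} must satisfy 0 < lower < upper")
        if self.center_jitter_bound < 0:
            raise ValueError("center_jitter_bound must be >= 0")
        names = [p.name for p in self.peaks]
        if len(set(names)) != len(names):
            raise ValueError("duplicate peak names in library")
        n_mito = sum(p.width_class == "mito_scaled" for p in self.peaks)
        if n_mito > 1:
            raise ValueError("at most one peak may have width_class='mito_scaled'")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.peaks)

    def __getitem__(self, name: str) -> PeakSpec:
        for p in self.peaks:
            if p.name == name:
                return p
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(p.name == name for p in self.peaks)

    def subset(self, names: Iterable[str]) -> "PeakModel":
        keep = tuple(n for n in names)
        return replace(self, peaks=tuple(self[n] for n in keep))

    def span(self, margin: float = 0.5) -> tuple[float, float]:
        """ppm interval covering every multiplet component, padded by *margin*."""
        lo = min(p.center_ppm + p.component_offsets().min() for p in self.peaks)
        hi = max(p.center_ppm + p.component_offsets().max() for p in self.peaks)
        return (lo - margin, hi + margin)


def default_library() -> PeakModel:
    """Library of nine cardiac 31P resonances (PCr anchored at -2.54 ppm).

    gamma/alpha-ATP are 1:1 doublets from P-P coupling; NAD(P)+ resonances
    are modeled as quartets of near-equal components; the mitochondrial
    NAD(P)H peak is a broad singlet shifted from the cytosolic pool.
    """
    j = 0.21  # ~17 Hz P-P coupling at 81 MHz, in ppm
    peaks = (
        PeakSpec("PCr", -2.54, "singlet"),
        PeakSpec("gammaATP", -5.02, "doublet", j, (1, 1)),
        PeakSpec("alphaATP", -10.05, "doublet", j, (1, 1)),
        PeakSpec("NADPplus", -10.50, "singlet"),
        PeakSpec("NADplus", -10.78, "quartet", 0.07, (1, 1.2, 1.2, 1)),
        PeakSpec("NADH_cyt", -11.08, "doublet", 0.07, (1, 1)),
        PeakSpec("mitoNADPH", -11.33, "singlet", width_class="mito_scaled"),
        PeakSpec("NADPH_cyt", -11.60, "doublet", 0.07, (1, 1)),
        PeakSpec("UDPglucose", -11.92, "doublet", 0.12, (1, 1)),
    )
    return PeakModel(peaks=peaks)


def nad_region_library() -> PeakModel:
    """The seven-peak alpha-ATP/NAD(P)(H)/UDP-glucose fitting region."""
    lib = default_library()
    return lib.subset(n for n in lib.names if n not in ("PCr", "gammaATP"))


def save_peak_library(model: PeakModel, path: str | Path) -> None:
    doc = {
        "shared_width_bounds": list(model.shared_width_bounds),
        "mito_width_ratio_bounds": list(model.mito_width_ratio_bounds),
        "center_jitter_bound": model.center_jitter_bound,
        "peaks": [
            {
                "name": p.name,
                "center_ppm": p.center_ppm,
                "multiplicity": p.multiplicity,
                "coupling_ppm": p.coupling_ppm,
                "component_ratios": list(p.component_ratios),
                "width_class": p.width_class,
            }
            for p in model.peaks
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_peak_library(path: str | Path) -> PeakModel:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"peak library file not found: {path}")
    doc = yaml.safe_load(path.read_text())
    peaks = tuple(
        PeakSpec(
            name=entry["name"],
            center_ppm=float(entry["center_ppm"]),
            multiplicity=entry.get("multiplicity", "singlet"),
            coupling_ppm=float(entry.get("coupling_ppm", 0.0)),
            component_ratios=tuple(entry.get("component_ratios", ())),
            width_class=entry.get("width_class", "shared"),
        )
        for entry in doc["peaks"]
    )
    return PeakModel(
        peaks=peaks,
        shared_width_bounds=tuple(doc.get("shared_width_bounds", (0.01, 0.40))),
        mito_width_ratio_bounds=tuple(doc.get("mito_width_ratio_bounds", (1.5, 3.0))),
        center_jitter_bound=float(doc.get("center_jitter_bound", 0.05)),
    )
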