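"""Synthetic ground-truth generators for spectra and metabolite matrices.

Every downstream stage is validated against data produced here, so the
generators are pure functions of (parameters, seed) and always return
their ground truth alongside the data.

Spectra are generated complex-valued — a sum of Lorentzian multiplets
plus a polynomial baseline, rotated by an injected zero/first-order phase
error, with i.i.d. Gaussian noise on both channels — so that phasing,
baseline removal, alignment and fitting are all exercisable.

Metabolite matrices are log-normal with additive (log2-scale) group,
batch and protein-concentration effects, and left-censored missingness:
a cell whose log2 value falls below the limit of detection is recorded
as missing.  Censoring is a hard threshold by default because the
downstream imputation model is a truncated distribution; a logistic
soft-censor is available but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .peaks import PeakModel, default_library
from .fitting import multiplet_profile
from .spectrum import Spectrum, write_spectrum

__all__ = [
    "SpectrumTruth",
    "MetabolomeTruth",
    "default_spectrum_truth",
    "simulate_spectrum",
    "simulate_mrs_cohort",
    "default_metabolome_truth",
    "simulate_metabolome",
    "write_cohort",
    "write_metabolome",
]

GROUPS = ("Young", "OldControl", "OldSS31", "OldNMN", "OldCombined")

# Relative truth areas for the default cardiac spectrum.  PCr/gamma-ATP
# gives a resting PCr/ATP ratio of 1.8; the minor metabolites sit at
# levels (relative to alpha-ATP) of the order seen in the in vivo
# comparison of MRS and metabolomics.
DEFAULT_AREAS: Mapping[str, float] = {
    "PCr": 3.0,
    "gammaATP": 3.0 / 1.8,
    "alphaATP": 1.6,
    "NADplus": 0.45,
    "NADH_cyt": 0.15,
    "NADPplus": 0.25,
    "NADPH_cyt": 0.20,
    "UDPglucose": 0.20,
    "mitoNADPH": 0.25,
}

DEFAULT_SHARED_HWHM = 0.08  # ppm
DEFAULT_MITO_RATIO = 2.0


@dataclass(frozen=True)
class SpectrumTruth:
    """Ground truth for one simulated spectrum.

    ``peaks`` holds (name, center_ppm, area, half_width_ppm); multiplet
    structure (coupling, ratios) comes from ``model``.  ``noise_sd`` is in
    intensity units per channel.
    """

    peaks: tuple[tuple[str, float, float, float], ...]
    baseline_coeffs: tuple[float, ...] = (0.0,)
    phase0_rad: float = 0.0
    phase1_rad_per_ppm: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0
    model: PeakModel | None = None

    def __post_init__(self) -> None:
        for name, _c, area, hw in self.peaks:
            if area < 0:
                raise ValueError(f"peak {name!r}: area must be >= 0")
            if hw <= 0:
                raise ValueError(f"peak {name!r}: half_width_ppm must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def areas(self) -> dict[str, float]:
        return {name: a for name, _c, a, _w in self.peaks}

    def scale_areas(self, factors: Mapping[str, float]) -> "SpectrumTruth":
        peaks = tuple(
            (n, c, a * factors.get(n, 1.0), w) for n, c, a, w in self.peaks
        )
        return replace(self, peaks=peaks)


def default_spectrum_truth(
    snr: float = 20.0,
    *,
    areas: Mapping[str, float] | None = None,
    shared_hwhm: float = DEFAULT_SHARED_HWHM,
    mito_ratio: float = DEFAULT_MITO_RATIO,
    baseline_coeffs: Sequence[float] = (0.0,),
    phase0_rad: float = 0.0,
    phase1_rad_per_ppm: float = 0.0,
    seed: int = 0,
    model: PeakModel | None = None,
    names: Sequence[str] | None = None,
) -> SpectrumTruth:
    """Truth for the default nine-resonance cardiac spectrum.

    ``snr`` is the ratio of the tallest noiseless peak apex to the
    per-channel noise SD; ``snr=inf`` (or <= 0) gives a noiseless truth.
    """
    lib = model if model is not None else default_library()
    if names is not None:
        lib = lib.subset(names)
    area_map = dict(DEFAULT_AREAS)
    if areas:
        area_map.update(areas)
    peaks = []
    apex = 0.0
    for p in lib.peaks:
        a = float(area_map.get(p.name, 0.0))
        w = shared_hwhm * mito_ratio if p.width_class == "mito_scaled" else shared_hwhm
        peaks.append((p.name, p.center_ppm, a, w))
        apex = max(apex, a * max(p.component_ratios) / (np.pi * w))
    noise_sd = 0.0 if not np.isfinite(snr) or snr <= 0 else apex / snr
    return SpectrumTruth(
        peaks=tuple(peaks),
        baseline_coeffs=tuple(baseline_coeffs),
        phase0_rad=phase0_rad,
        phase1_rad_per_ppm=phase1_rad_per_ppm,
        noise_sd=noise_sd,
        seed=seed,
        model=lib,
    )


def default_axis(
    lo: float = -13.5, hi: float = 1.5, step: float = 0.005
) -> np.ndarray:
    return np.arange(lo, hi + step / 2, step)


def _evaluate_truth(truth: SpectrumTruth, axis: np.ndarray) -> np.ndarray:
    """Noiseless absorptive signal (no baseline, no phase)."""
    lib = truth.model if truth.model is not None else default_library()
    out = np.zeros_like(axis, dtype=float)
    for name, center, area, hw in truth.peaks:
        spec = lib[name]
        out += multiplet_profile(axis, spec, center, hw, area)
    return out


def simulate_spectrum(
    truth: SpectrumTruth, axis: np.ndarray | None = None
) -> tuple[Spectrum, SpectrumTruth]:
    """Forward-simulate one complex-valued spectrum from ground truth.

    Real channel = absorptive Lorentzian multiplets; imaginary channel =
    the matching dispersive lineshape (the Hilbert pair of a Lorentzian
    in closed form).  The polynomial baseline is added to the real
    channel, the complex signal is rotated by the injected phase error,
    and Gaussian noise of SD ``noise_sd`` is added to both channels.
    """
    if axis is None:
        axis = default_axis()
    axis = np.asarray(axis, dtype=float)
    d = np.diff(axis)
    if axis.ndim != 1 or axis.size < 2 or not (np.all(d > 0) or np.all(d < 0)):
        raise ValueError("ppm axis must be 1-D and strictly monotonic")

    lib = truth.model if truth.model is not None else default_library()
    absorptive = np.zeros_like(axis)
    dispersive = np.zeros_like(axis)
    for name, center, area, hw in truth.peaks:
        spec = lib[name]
        for off, r in zip(spec.component_offsets(), spec.component_ratios):
            c = center + off
            a = area * r
            denom = (axis - c) ** 2 + hw**2
            absorptive += (a * hw / np.pi) / denom
            dispersive += (a * (axis - c) / np.pi) / denom

    baseline = np.polynomial.polynomial.polyval(
        axis - axis.mean(), np.asarray(truth.baseline_coeffs, dtype=float)
    )
    z = (absorptive + baseline) + 1j * dispersive
    z = z * np.exp(1j * (truth.phase0_rad + truth.phase1_rad_per_ppm * axis))
    if truth.noise_sd > 0:
        rng = np.random.default_rng(truth.seed)
        z = z + rng.normal(0.0, truth.noise_sd, axis.size) + 1j * rng.normal(
            0.0, truth.noise_sd, axis.size
        )
    spec = Spectrum(axis, z.real, z.imag, meta={"simulated": True, "seed": truth.seed})
    return spec, truth


@dataclass(frozen=True)
class CohortSpectra:
    """Paired pre/post spectra for a simulated cohort plus the truth table."""

    spectra: dict[tuple[str, str], Spectrum]  # (animal_id, state) -> Spectrum
    truth: pd.DataFrame  # animal_id, group, state, peak, area
    manifest: pd.DataFrame  # animal_id, group, state

    def truth_areas(self, animal_id: str, state: str) -> dict[str, float]:
        t = self.truth
        sel = t[(t.animal_id == animal_id) & (t.state == state)]
        return dict(zip(sel.peak, sel.area))


DEFAULT_EFFECT_PROFILE: Mapping[str, Mapping[str, float]] = {
    # post/pre area multipliers per group; PCr depletion under workload in
    # old controls, partial normalization under treatment.
    "Young": {},
    "OldControl": {"PCr": 0.8},
    "OldSS31": {"PCr": 0.93, "mitoNADPH": 1.15},
    "OldNMN": {"PCr": 0.93, "NADplus": 1.2},
    "OldCombined": {"PCr": 0.95},
}


def simulate_mrs_cohort(
    n_per_group: int = 11,
    effect_profile: Mapping[str, Mapping[str, float]] | None = None,
    seed: int = 0,
    *,
    snr: float = 20.0,
    animal_sd: float = 0.10,
    occasion_sd: float = 0.05,
    axis: np.ndarray | None = None,
    baseline_coeffs: Sequence[float] = (0.0,),
    groups: Sequence[str] | None = None,
) -> CohortSpectra:
    """Simulate paired pre/post-dobutamine spectra for each animal.

    Each animal carries a log-normal biological effect per peak
    (``animal_sd``, shared between states) and each acquisition adds a
    log-normal occasion effect per peak (``occasion_sd``).  Post-state
    areas are additionally scaled by the group's effect-profile
    multipliers.  Peak positions and widths are shared within an animal.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    profile = dict(
        DEFAULT_EFFECT_PROFILE if effect_profile is None else effect_profile
    )
    use_groups = tuple(groups) if groups is not None else tuple(profile.keys())
    for g in use_groups:
        for name, m in profile.get(g, {}).items():
            if m <= 0:
                raise ValueError(
                    f"effect multiplier for {g}/{name} must be > 0, got {m}"
                )
    rng = np.random.default_rng(seed)
    base = default_spectrum_truth(snr=snr, baseline_coeffs=baseline_coeffs)
    names = [p[0] for p in base.peaks]

    spectra: dict[tuple[str, str], Spectrum] = {}
    truth_rows = []
    manifest_rows = []
    for g in use_groups:
        for i in range(n_per_group):
            animal = f"{g}_{i + 1:02d}"
            bio = {
                n: float(np.exp(rng.normal(0.0, animal_sd))) for n in names
            }
            for state in ("pre", "post"):
                occ = {
                    n: float(np.exp(rng.normal(0.0, occasion_sd))) for n in names
                }
                eff = profile.get(g, {}) if state == "post" else {}
                factors = {
                    n: bio[n] * occ[n] * eff.get(n, 1.0) for n in names
                }
                truth = base.scale_areas(factors)
                truth = replace(
                    truth, seed=int(rng.integers(0, 2**31 - 1))
                )
                spec, truth = simulate_spectrum(truth, axis=axis)
                spec = spec.with_meta(animal_id=animal, group=g, state=state)
                spectra[(animal, state)] = spec
                manifest_rows.append(
                    {"animal_id": animal, "group": g, "state": state}
                )
                for n, a in truth.areas.items():
                    truth_rows.append(
                        {
                            "animal_id": animal,
                            "group": g,
                            "state": state,
                            "peak": n,
                            "area": a,
                        }
                    )
    return CohortSpectra(
        spectra=spectra,
        truth=pd.DataFrame(truth_rows),
        manifest=pd.DataFrame(manifest_rows),
    )


# ---------------------------------------------------------------------------
# metabolome simulation


@dataclass(frozen=True)
class MetabolomeTruth:
    """Ground truth for a simulated metabolite matrix (log2 scale)."""

    log2_means: np.ndarray  # per metabolite
    group_effects: pd.DataFrame  # metabolites x groups, log2 units
    batch_effects: np.ndarray  # per batch, log2 units
    protein_slope: float  # log2 per SD of protein concentration
    noise_sd: float  # log2 units
    lod: float  # log2 censoring threshold
    seed: int = 0
    soft_censor_scale: float = 0.0  # 0 => hard threshold at lod

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        bad = set(self.group_effects.columns) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")


def default_metabolome_truth(
    n_metabolites: int = 200,
    *,
    seed: int = 0,
    n_affected: int = 30,
    effect_log2: float = 1.0,
    noise_sd: float = 0.5,
    batch_sd: float = 0.3,
    n_batches: int = 3,
    protein_slope: float = 0.2,
    lod_quantile: float = 0.01,
) -> MetabolomeTruth:
    """Truth emulating the study's targeted-metabolomics matrix.

    The first ``n_affected`` metabolites receive a +/- ``effect_log2``
    Young-vs-OldControl effect (alternating signs, fold changes of the
    magnitude seen in the study's significant metabolites); the LOD is
    placed at the ``lod_quantile`` of the marginal log2 distribution so
    post-filter missingness lands around 1%.
    """
    rng = np.random.default_rng(seed)
    means = rng.normal(20.0, 2.0, n_metabolites)
    ge = pd.DataFrame(0.0, index=range(n_metabolites), columns=list(GROUPS))
    k = min(n_affected, n_metabolites)
    if k > 0:
        signs = np.where(np.arange(k) % 2 == 0, 1.0, -1.0)
        ge.loc[: k - 1, "Young"] = signs * effect_log2
    batch_effects = rng.normal(0.0, batch_sd, n_batches)
    # marginal distribution of log2 values ~ N(mean_i, sqrt(2^2 + noise^2));
    # place the LOD at the requested marginal quantile
    from scipy.stats import norm

    marginal_sd = float(np.sqrt(2.0**2 + noise_sd**2 + batch_sd**2))
    lod = float(norm.ppf(lod_quantile, loc=20.0, scale=marginal_sd))
    return MetabolomeTruth(
        log2_means=means,
        group_effects=ge,
        batch_effects=batch_effects,
        protein_slope=protein_slope,
        noise_sd=noise_sd,
        lod=lod,
        seed=seed,
    )


# sample sizes per group in the study's metabolomics cohort
DEFAULT_SAMPLES_PER_GROUP: Mapping[str, int] = {
    "Young": 12,
    "OldControl": 10,
    "OldSS31": 12,
    "OldNMN": 11,
    "OldCombined": 8,
}


def simulate_metabolome(
    n_metabolites: int | None = None,
    samples_per_group: int | Mapping[str, int] | None = None,
    truth: MetabolomeTruth | None = None,
    *,
    metabolite_names: Sequence[str] | None = None,
):
    """Simulate a raw-scale metabolite matrix with left-censored missingness.

    Raw intensity = 2^(mean + group effect + batch effect +
    protein_slope * protein_z + noise).  A cell is missing when its log2
    value falls below ``truth.lod`` (hard censoring), or with probability
    ``sigmoid((lod - x)/scale)`` when a soft-censor scale is set.

    Returns ``(IntensityMatrix, MetabolomeTruth)``; the matrix is on the
    raw scale with missing cells as NaN and carries group, batch and
    protein covariates.
    """
    from .metabolomics import IntensityMatrix

    if truth is None:
        truth = default_metabolome_truth(
            n_metabolites if n_metabolites is not None else 200
        )
    n_met = len(truth.log2_means)
    if n_metabolites is not None and n_metabolites != n_met:
        raise ValueError("n_metabolites disagrees with truth.log2_means length")
    if n_met < 1:
        raise ValueError("need at least one metabolite")

    if samples_per_group is None:
        samples_per_group = dict(DEFAULT_SAMPLES_PER_GROUP)
    if isinstance(samples_per_group, int):
        if samples_per_group < 1:
            raise ValueError("samples_per_group must be >= 1")
        samples_per_group = {g: samples_per_group for g in truth.group_effects.columns}

    rng = np.random.default_rng(truth.seed)
    n_batches = len(truth.batch_effects)
    sample_names, groups_v, batches, protein = [], [], [], []
    i = 0
    for g, n in samples_per_group.items():
        for j in range(n):
            sample_names.append(f"{g}_{j + 1:02d}")
            groups_v.append(g)
            batches.append(i % n_batches)
            protein.append(float(rng.normal(0.0, 1.0)))
            i += 1
    n_samp = len(sample_names)

    log2 = np.empty((n_met, n_samp))
    for s in range(n_samp):
        g = groups_v[s]
        log2[:, s] = (
            truth.log2_means
            + truth.group_effects[g].to_numpy()
            + truth.batch_effects[batches[s]]
            + truth.protein_slope * protein[s]
            + rng.normal(0.0, truth.noise_sd, n_met)
        )

    if truth.soft_censor_scale > 0:
        p_miss = expit((truth.lod - log2) / truth.soft_censor_scale)
        missing = rng.uniform(size=log2.shape) < p_miss
    else:
        missing = log2 < truth.lod

    raw = np.power(2.0, log2)
    raw[missing] = np.nan

    row_names = [f"met_{k + 1:03d}" for k in range(n_met)]
    if metabolite_names:
        if len(metabolite_names) > n_met:
            raise ValueError("more metabolite_names than metabolites")
        for k, nm in enumerate(metabolite_names):
            row_names[k] = nm
    values = pd.DataFrame(raw, index=row_names, columns=sample_names)
    meta = pd.DataFrame(
        {
            "group": groups_v,
            "prep_batch": [f"batch_{b + 1}" for b in batches],
            "protein_conc": protein,
        },
        index=sample_names,
    )
    matrix = IntensityMatrix(values=values, sample_meta=meta, log_scale=False)
    return matrix, truth


# ---------------------------------------------------------------------------
# file export


def write_cohort(cohort: CohortSpectra, outdir: str | Path, *, fmt: str = "3col") -> Path:
    """Write one spectrum file per animal-state plus a manifest CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for (animal, state), spec in cohort.spectra.items():
        fname = f"{animal}_{state}.csv"
        write_spectrum(spec, outdir / fname, fmt=fmt)
        g = spec.meta.get("group", "")
        rows.append(
            {"animal_id": animal, "group": g, "state": state, "path": fname}
        )
    manifest = pd.DataFrame(rows).sort_values(["group", "animal_id", "state"])
    manifest_path = outdir / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    cohort.truth.to_csv(outdir / "truth.csv", index=False)
    return manifest_path


def write_metabolome(matrix, truth: MetabolomeTruth, outdir: str | Path) -> None:
    """Write matrix CSV (missing cells empty), metadata CSV and truth CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix.values.to_csv(outdir / "matrix.csv")
    matrix.sample_meta.to_csv(outdir / "metadata.csv", index_label="sample")
    truth_df = truth.group_effects.copy()
    truth_df.insert(0, "log2_mean", truth.log2_means)
    truth_df.index = matrix.values.index
    truth_df.to_csv(outdir / "truth.csv", index_label="metabolite")
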