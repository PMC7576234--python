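"""Empirical-Bayes moderated linear models for metabolite matrices.

Each metabolite's log2 intensity is regressed on group (treatment-coded
against a reference group), preparation batch, and standardized protein
concentration.  Residual variances are then shrunk toward a common prior:
assuming s2_g | sigma2_g ~ sigma2_g * chi2_d / d and an inverse-chi-square
prior sigma2_g ~ s0^2 * d0 / chi2_{d0}, the posterior variance is

    s2_tilde = (d0 * s0^2 + d * s2_g) / (d0 + d)

and the moderated t-statistic beta / (s_tilde * sqrt(v)) has d0 + d
degrees of freedom.  The hyperparameters (d0, s0^2) are estimated by
matching the first two moments of log(s2_g) to the log scaled-F
distribution (digamma/trigamma inversion).  This "borrowing strength"
across metabolites stabilizes variance estimates at small n and improves
power.

Multiple testing is controlled per contrast with Benjamini-Hochberg,
flagging metabolites at adjusted p < 0.1 by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .metabolomics import IntensityMatrix

__all__ = [
    "ModeratedLinearModel",
    "ModeratedStatsResults",
    "fit_moderated_model",
    "bh_fdr",
    "fold_changes",
    "estimate_variance_prior",
    "trigamma_inverse",
]


def trigamma_inverse(y: float, max_iter: int = 50, tol: float = 1e-10) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration.

    Uses the monotone decreasing trigamma on (0, inf); returns inf when
    y <= 0 (no finite solution).
    """
    if not np.isfinite(y) or y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)


def estimate_variance_prior(
    s2: np.ndarray, df: float
) -> tuple[float, float]:
    """Moment-matching estimate of (d0, s0^2) from residual variances.

    Works on z = log(s2): under the scaled-F model, E[z] and Var[z] are
    known in terms of digamma/trigamma of d/2 and d0/2; inverting the
    variance equation gives d0 and then the mean equation gives s0^2.
    Returns ``d0 = inf`` when the observed spread of log-variances is no
    larger than expected from the chi-square sampling noise alone.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 2:
        return np.inf, float(np.median(s2[ok])) if ok.any() else np.nan
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    ebar = float(e.mean())
    n = e.size
    evar = float(((e - ebar) ** 2).sum() / (n - 1)) - float(
        special.polygamma(1, df / 2.0)
    )
    if evar <= 0:
        return np.inf, float(np.exp(ebar))
    d0 = 2.0 * trigamma_inverse(evar)
    if not np.isfinite(d0):
        return np.inf, float(np.exp(ebar))
    s0_sq = float(np.exp(ebar + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModeratedStatsResults:
    """Per-metabolite, per-contrast moderated statistics.

    ``table`` has a row per (metabolite, contrast) with columns
    ``beta_log2, se_beta_ols, se_beta, s2_g, d_g, s2_tilde, t_moderated,
    p, q, fc, se_fc, significant``.  ``d0`` and ``s0_sq`` are the
    estimated prior degrees of freedom and prior variance.
    """

    table: pd.DataFrame
    d0: float
    s0_sq: float
    q_level: float
    contrasts: tuple[str, ...]
    reference: str
    design_columns: tuple[str, ...]

    def contrast(self, name: str) -> pd.DataFrame:
        sel = self.table[self.table.contrast == name]
        if sel.empty:
            raise KeyError(f"unknown contrast {name!r}; have {self.contrasts}")
        return sel.set_index("metabolite")

    def significant(self, contrast: str | None = None) -> pd.DataFrame:
        t = self.table if contrast is None else self.contrast(contrast).reset_index()
        return t[t.significant]

    def summary(self, max_rows: int = 10) -> str:
        lines = [
            "Moderated linear model (empirical-Bayes variance shrinkage)",
            "=" * 66,
            f"prior df d0 = {self.d0:.3g}   prior variance s0^2 = {self.s0_sq:.4g}",
            f"reference group: {self.reference}   BH flag level: q < {self.q_level}",
        ]
        for c in self.contrasts:
            sub = self.contrast(c)
            nsig = int(sub.significant.sum())
            lines.append(
                f"\ncontrast {c} vs {self.reference}: "
                f"{nsig}/{len(sub)} significant (q < {self.q_level})"
            )
            top = sub.sort_values("fc", ascending=False).head(max_rows)
            lines.append(
                top[["fc", "se_fc", "beta_log2", "t_moderated", "p", "q"]]
                .round(4)
                .to_string()
            )
        return "\n".join(lines)


class ModeratedLinearModel:
    """Metabolite-wise linear model with empirical-Bayes moderation.

    Parameters
    ----------
    matrix
        Complete (imputed) log2-scale :class:`IntensityMatrix`.
    reference
        Reference group for treatment coding (contrasts are each other
        group vs this one).
    covariates
        Whether to adjust for preparation batch and protein
        concentration (the protein covariate is z-scored internally for
        conditioning; contrast coefficients are unaffected).
    """

    def __init__(
        self,
        matrix: IntensityMatrix,
        reference: str = "OldControl",
        *,
        batch_covariate: bool = True,
        protein_covariate: bool = True,
    ) -> None:
        if not matrix.log_scale:
            raise ValueError("moderated model expects a log2-scale matrix")
        if matrix.values.isna().any().any():
            raise ValueError("matrix must be complete (impute first)")
        meta = matrix.sample_meta
        if reference not in set(meta.group):
            raise ValueError(f"reference group {reference!r} not present")
        self.matrix = matrix
        self.reference = reference

        cols: dict[str, np.ndarray] = {"Intercept": np.ones(len(meta))}
        groups = [g for g in pd.unique(meta.group) if g != reference]
        for g in groups:
            cols[f"group[{g}]"] = (meta.group == g).to_numpy(dtype=float)
        if batch_covariate:
            batches = list(pd.unique(meta.prep_batch))[1:]
            for b in batches:
                cols[f"batch[{b}]"] = (meta.prep_batch == b).to_numpy(dtype=float)
        if protein_covariate:
            prot = meta.protein_conc.to_numpy(dtype=float)
            sd = prot.std(ddof=1)
            if sd > 0:  # a constant covariate carries no information
                cols["protein_z"] = (prot - prot.mean()) / sd
        self.design = pd.DataFrame(cols, index=meta.index)
        self.contrast_names = tuple(groups)

        x = self.design.to_numpy()
        rank = np.linalg.matrix_rank(x)
        if rank < x.shape[1]:
            # name the aliased columns by testing rank without each one
            aliased = []
            for k, name in enumerate(self.design.columns):
                xk = np.delete(x, k, axis=1)
                if np.linalg.matrix_rank(xk) == rank:
                    aliased.append(name)
            raise ValueError(
                f"design matrix is rank-deficient; aliased columns: {aliased}"
            )

    def fit(self, q_level: float = 0.10, joint_adjust: bool = False) -> ModeratedStatsResults:
        """OLS per metabolite, then variance moderation, BH and fold changes."""
        y = self.matrix.values.to_numpy(dtype=float).T  # samples x metabolites
        x = self.design.to_numpy()
        n, p = x.shape
        d_g = n - p
        if d_g < 1:
            raise ValueError("no residual degrees of freedom")
        xtx_inv = np.linalg.inv(x.T @ x)
        beta = xtx_inv @ x.T @ y  # p x n_met
        resid = y - x @ beta
        rss = (resid**2).sum(axis=0)
        s2_g = rss / d_g
        v = np.diag(xtx_inv)

        d0, s0_sq = estimate_variance_prior(s2_g, d_g)
        if np.isfinite(d0):
            s2_tilde = (d0 * s0_sq + d_g * s2_g) / (d0 + d_g)
            df_total = d0 + d_g
        else:
            warnings.warn(
                "variance prior estimation found no excess spread in the "
                "log residual variances; statistics are unmoderated",
                RuntimeWarning,
                stacklevel=2,
            )
            s2_tilde = s2_g.copy()
            df_total = float(d_g)

        metabolites = self.matrix.values.index
        rows = []
        for c in self.contrast_names:
            k = list(self.design.columns).index(f"group[{c}]")
            b = beta[k]
            se_ols = np.sqrt(s2_g * v[k])
            se_mod = np.sqrt(s2_tilde * v[k])
            t_mod = b / se_mod
            pvals = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
            rows.append(
                pd.DataFrame(
                    {
                        "metabolite": metabolites,
                        "contrast": c,
                        "beta_log2": b,
                        "se_beta_ols": se_ols,
                        "se_beta": se_mod,
                        "s2_g": s2_g,
                        "d_g": float(d_g),
                        "s2_tilde": s2_tilde,
                        "t_moderated": t_mod,
                        "p": pvals,
                    }
                )
            )
        table = pd.concat(rows, ignore_index=True)

        if joint_adjust:
            q, flags = bh_fdr(table.p.to_numpy(), q_level=q_level)
            table["q"] = q
            table["significant"] = flags
        else:
            table["q"] = np.nan
            table["significant"] = False
            for c in self.contrast_names:
                sel = table.contrast == c
                q, flags = bh_fdr(table.loc[sel, "p"].to_numpy(), q_level=q_level)
                table.loc[sel, "q"] = q
                table.loc[sel, "significant"] = flags

        table["fc"] = np.power(2.0, table.beta_log2)
        table["se_fc"] = np.log(2.0) * table.fc * table.se_beta
        return ModeratedStatsResults(
            table=table,
            d0=float(d0),
            s0_sq=float(s0_sq),
            q_level=q_level,
            contrasts=self.contrast_names,
            reference=self.reference,
            design_columns=tuple(self.design.columns),
        )


def fit_moderated_model(
    matrix: IntensityMatrix,
    reference: str = "OldControl",
    q_level: float = 0.10,
    **kwargs,
) -> ModeratedStatsResults:
    """Fit the moderated linear model (functional form)."""
    return ModeratedLinearModel(matrix, reference=reference, **kwargs).fit(
        q_level=q_level
    )


def bh_fdr(
    p: Sequence[float] | np.ndarray, q_level: float = 0.10
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted p-values and flags.

    Returns ``(q, significant)`` with ``significant = q < q_level``,
    matching the "FDR < 0.1" significance convention.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q, q < q_level


def fold_changes(stats_result: ModeratedStatsResults, contrast: str | None = None) -> pd.DataFrame:
    """Untransformed fold changes with delta-method SEs, ordered by FC.

    fc = 2^beta and se_fc = ln(2) * 2^beta * se_beta; rows are sorted by
    fold change descending with the BH significance flag attached.
    """
    if contrast is None:
        t = stats_result.table.copy()
    else:
        t = stats_result.contrast(contrast).reset_index()
    cols = ["metabolite", "contrast", "fc", "se_fc", "beta_log2", "se_beta", "p", "q", "significant"]
    return t[cols].sort_values("fc", ascending=False).reset_index(drop=True)
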