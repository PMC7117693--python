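"""IRT condition checks: item fit, unidimensionality, local independence.

Three conditions are verified before any DIF analysis:

* **item fit** — information-weighted (infit) and unweighted (outfit)
  mean-square standardized residuals; values near 1 indicate good fit and
  the conventional acceptance band is [0.7, 1.3];
* **unidimensionality** — principal component analysis of the standardized
  residual matrix: once the fitted model is removed, no dominant residual
  component should remain;
* **local independence** — Spearman correlations between item residuals:
  strongly correlated residual pairs (|r| above a threshold, default 0.4)
  indicate redundant or locally dependent items, and the later-indexed item
  of each flagged pair is recommended for removal.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .cohort import ResponseMatrix
from .grm import ItemBank, ThetaEstimates, icc_probability

__all__ = [
    "DiagnosticsReport",
    "standardized_residuals",
    "infit_outfit",
    "residual_pca",
    "local_independence",
    "run_diagnostics",
]

log = logging.getLogger(__name__)

PROB_CLAMP = 1e-10
FIT_RANGE = (0.7, 1.3)
LOCAL_DEP_THRESHOLD = 0.4


def _probability_matrix(df: pd.DataFrame, bank: ItemBank, theta: np.ndarray) -> np.ndarray:
    sub = bank.params.loc[list(df.columns)]
    P = np.column_stack(
        [icc_probability(theta, row.a, row.b) for row in sub.itertuples()]
    )
    n_clamped = int(((P < PROB_CLAMP) | (P > 1 - PROB_CLAMP)).sum())
    if n_clamped:
        log.info("clamped %d fitted probabilities at eps=%g", n_clamped, PROB_CLAMP)
    return np.clip(P, PROB_CLAMP, 1 - PROB_CLAMP)


def standardized_residuals(
    m: ResponseMatrix | pd.DataFrame,
    bank: ItemBank,
    theta: ThetaEstimates,
) -> pd.DataFrame:
    """Standardized Pearson residuals z_ij = (y_ij - P_ij) / sqrt(P_ij(1-P_ij))
    at the EAP trait estimates."""
    df = m.responses if isinstance(m, ResponseMatrix) else m
    P = _probability_matrix(df, bank, theta.theta.to_numpy())
    Z = (df.to_numpy(dtype=float) - P) / np.sqrt(P * (1 - P))
    return pd.DataFrame(Z, index=df.index, columns=df.columns)


def infit_outfit(
    residuals: pd.DataFrame,
    probabilities: pd.DataFrame | np.ndarray,
    fit_range: tuple[float, float] = FIT_RANGE,
) -> pd.DataFrame:
    """Per-item mean-square fit statistics.

    outfit_j = mean_i z_ij^2 (outlier-sensitive); infit_j is the
    information-weighted version with weights W_ij = P_ij (1 - P_ij).
    """
    Z = residuals.to_numpy()
    P = np.asarray(probabilities, dtype=float)
    if P.shape != Z.shape:
        raise ValueError("residuals and probabilities must be conformable")
    W = P * (1 - P)
    tw = W.sum(axis=0)
    if np.any(tw <= 0):
        raise ValueError("zero total information weight for some item")
    outfit = (Z**2).mean(axis=0)
    infit = (W * Z**2).sum(axis=0) / tw
    lo, hi = fit_range
    out = pd.DataFrame(
        {"infit": infit, "outfit": outfit}, index=residuals.columns
    )
    out["in_range"] = (out["infit"].between(lo, hi)) & (out["outfit"].between(lo, hi))
    return out


def residual_pca(
    residuals: pd.DataFrame, dominance_ratio: float = 2.0
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Eigen-decomposition of the residual correlation matrix.

    Returns (descending eigenvalues, first-component loadings,
    unidimensional verdict). The verdict is a configurable rule: the first
    eigenvalue is not "dominant" if it is smaller than ``dominance_ratio``
    times the second.
    """
    Z = residuals.to_numpy()
    n, J = Z.shape
    if n <= J:
        raise ValueError("need more respondents than items for residual PCA")
    C = np.corrcoef(Z, rowvar=False)
    if not np.all(np.isfinite(C)):
        log.warning("rank-deficient or constant residual column; PCA unreliable")
        C = np.nan_to_num(C, nan=0.0)
        np.fill_diagonal(C, 1.0)
    vals, vecs = np.linalg.eigh(C)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    unidimensional = bool(vals[0] < dominance_ratio * vals[1])
    return np.maximum(vals, 0.0), vecs[:, 0], unidimensional


def local_independence(
    residuals: pd.DataFrame,
    flag_threshold: float = LOCAL_DEP_THRESHOLD,
) -> tuple[pd.DataFrame, list[tuple[str, str, float]], list[str]]:
    """Residual Spearman correlation matrix, flagged pairs, removal advice.

    Pairs with |rho| >= ``flag_threshold`` are flagged; for each flagged
    pair the later-indexed item is recommended for removal (the established
    convention when one of two near-duplicate items must go).
    """
    if (residuals.nunique() <= 1).any():
        raise ValueError("constant residual column")
    cols = list(residuals.columns)
    rho = spearmanr(residuals.to_numpy()).statistic
    rho = np.atleast_2d(rho)
    R = pd.DataFrame(rho, index=cols, columns=cols)
    flagged, removal = [], []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            r = float(R.iloc[i, j])
            if abs(r) >= flag_threshold:
                flagged.append((cols[i], cols[j], r))
                if cols[j] not in removal:
                    removal.append(cols[j])
    return R, flagged, removal


@dataclass
class DiagnosticsReport:
    item_fit: pd.DataFrame  # infit, outfit, in_range per item
    eigenvalues: np.ndarray
    first_loadings: np.ndarray
    unidimensional: bool
    residual_spearman: pd.DataFrame
    flagged_pairs: list[tuple[str, str, float]]
    removal_recommendation: list[str]
    per_group: dict[str, "DiagnosticsReport"] | None = None

    @property
    def max_offdiag_correlation(self) -> float:
        R = self.residual_spearman.to_numpy()
        mask = ~np.eye(len(R), dtype=bool)
        return float(np.abs(R[mask]).max())

    def summary(self) -> dict:
        return {
            "all_items_in_fit_range": bool(self.item_fit["in_range"].all()),
            "eigenvalues": [round(float(v), 6) for v in self.eigenvalues],
            "unidimensional": self.unidimensional,
            "flagged_pairs": [
                {"item_a": a, "item_b": b, "spearman_r": round(r, 6)}
                for a, b, r in self.flagged_pairs
            ],
            "removal_recommendation": list(self.removal_recommendation),
            "max_offdiag_residual_correlation": round(self.max_offdiag_correlation, 6),
        }

    def to_json(self, path) -> None:
        s = self.summary()
        if self.per_group:
            s["per_group"] = {g: r.summary() for g, r in self.per_group.items()}
        with open(path, "w") as fh:
            json.dump(s, fh, indent=2, sort_keys=True)

    def to_tsv(self, fit_path, corr_path) -> None:
        self.item_fit.to_csv(fit_path, sep="\t", float_format="%.10g")
        self.residual_spearman.to_csv(corr_path, sep="\t", float_format="%.10g")


def run_diagnostics(
    m: ResponseMatrix,
    bank: ItemBank,
    theta: ThetaEstimates,
    flag_threshold: float = LOCAL_DEP_THRESHOLD,
    by_groups: bool = True,
) -> DiagnosticsReport:
    """Full diagnostics pass, overall and (optionally) per covariate group."""

    def _one(df: pd.DataFrame, th: ThetaEstimates) -> DiagnosticsReport:
        Z = standardized_residuals(df, bank, th)
        P = _probability_matrix(df, bank, th.theta.to_numpy())
        fit = infit_outfit(Z, P)
        vals, load, unidim = residual_pca(Z)
        R, flagged, removal = local_independence(Z, flag_threshold)
        return DiagnosticsReport(fit, vals, load, unidim, R, flagged, removal)

    rep = _one(m.responses, theta)
    if by_groups:
        per_group = {}
        for cov in m.covariates:
            for g, sub in m.responses.groupby(m.groups[cov]):
                th_g = ThetaEstimates(theta.estimates.loc[sub.index])
                try:
                    per_group[f"{cov}={g}"] = _one(sub, th_g)
                except ValueError as exc:  # tiny or degenerate subgroup
                    log.warning("skipping diagnostics for %s=%s: %s", cov, g, exc)
        rep.per_group = per_group
    return rep
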