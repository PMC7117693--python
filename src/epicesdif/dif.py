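"""Differential item functioning via hybrid (ordinal) logistic regression.

For each item and each group comparison, three nested logistic models of the
item response are compared, conditioning on the IRT latent-trait estimate
theta-hat (the "hybrid" in HOLR — the conditioning score comes from a GRM
rather than the raw sum score):

* model 1 (no DIF):          logit P(y=1) = b0 + b1 theta
* model 2 (uniform DIF):     ... + b2 group
* model 3 (non-uniform DIF): ... + b3 (theta x group)

Significance comes from likelihood-ratio tests; an item is *flagged* for
DIF by the omnibus model-3-vs-model-1 LRT at ``alpha`` (default 0.01), the
single alpha-level detection test. DIF *type* and *magnitude* follow the
classification rule: non-uniform when the 3-vs-2 LRT is significant (size
read from the McFadden pseudo-R-squared gain of model 3 over model 2), else
uniform when the 2-vs-1 LRT is significant (size from model 2 over model 1),
else no DIF; magnitudes below 0.035 are negligible, from 0.035 to below
0.07 moderate, and 0.07 or above important, and magnitude is not assessed
when the corresponding LRT is non-significant.

Items here are binary, so the ordinal logistic reduces to ordinary binary
logistic regression; the design-matrix construction is written against the
cumulative-logit layout so polytomous items can slot in later.

Purification (on by default): respondents' theta-hat is iteratively
re-estimated from the items *not* currently flagged, so that DIF in one item
does not contaminate the conditioning score used to test the others.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import expit, log_expit
from scipy.stats import chi2 as chi2_dist

from .cohort import ResponseMatrix
from .grm import ItemBank, ThetaEstimates, eap_scores, fit_grm

__all__ = [
    "NestedFit",
    "DIFResult",
    "fit_logistic",
    "fit_nested_models",
    "lrt",
    "mcfadden_delta",
    "classify_dif",
    "detect_dif",
]

log = logging.getLogger(__name__)

ALPHA = 0.01
BANDS = (0.035, 0.07)
NESTING_TOL = 1e-6
_SEPARATION_ETA = 25.0


def fit_logistic(X: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray, bool]:
    """ML binary logistic fit by Newton-Raphson with step halving.

    Returns (log-likelihood, coefficients, stable). ``stable`` is False
    under (quasi-)complete separation — diverging linear predictor — in
    which case the log-likelihood is still the best value reached.
    """
    n, p = X.shape
    beta = np.zeros(p)

    def ll(b):
        eta = X @ b
        return float(np.sum(y * log_expit(eta) + (1 - y) * log_expit(-eta)))

    f0 = ll(beta)
    stable = True
    for _ in range(60):
        eta = X @ beta
        mu = expit(eta)
        g = X.T @ (y - mu)
        if np.abs(g).max() < 1e-9:
            break
        w = mu * (1 - mu)
        H = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(H + 1e-12 * np.eye(p), g)
        except np.linalg.LinAlgError:
            stable = False
            break
        t = 1.0
        f1 = f0
        for _ in range(30):
            f1 = ll(beta + t * step)
            if f1 >= f0 - 1e-12:
                break
            t /= 2
        beta = beta + t * step
        if np.abs(X @ beta).max() > _SEPARATION_ETA:
            stable = False  # separation: likelihood flat at the boundary
        if f1 - f0 < 1e-12:
            f0 = f1
            break
        f0 = f1
    return f0, beta, stable


@dataclass(frozen=True)
class NestedFit:
    """Log-likelihoods of the intercept-only and three nested DIF models."""

    ll_null: float
    ll1: float
    ll2: float
    ll3: float
    df_group: int  # parameters added by the group main effect (G-1)
    stable: bool

    def __post_init__(self) -> None:
        if not (self.ll1 <= self.ll2 + NESTING_TOL and self.ll2 <= self.ll3 + NESTING_TOL):
            raise RuntimeError(
                f"model nesting violated: ll1={self.ll1:.6f}, "
                f"ll2={self.ll2:.6f}, ll3={self.ll3:.6f} (optimizer failure)"
            )


def fit_nested_models(
    y: np.ndarray | pd.Series,
    theta: np.ndarray | pd.Series,
    groups: np.ndarray | pd.Series,
) -> NestedFit:
    """Fit the no-DIF / uniform-DIF / non-uniform-DIF logistic models.

    Group enters via treatment coding with the alphabetically first category
    as reference; LRT statistics and McFadden gains are invariant to this
    choice.
    """
    y = np.asarray(y, dtype=float)
    th = np.asarray(theta, dtype=float)
    g = np.asarray(groups)
    if not np.all(np.isfinite(th)):
        raise ValueError("theta must be finite")
    cats = np.unique(g)
    if len(cats) < 2:
        raise ValueError("need at least 2 groups in the comparison")
    D = np.column_stack([(g == c).astype(float) for c in cats[1:]])  # treatment coding

    n = len(y)
    ones = np.ones((n, 1))
    p1 = float(y.mean())
    if p1 in (0.0, 1.0):
        raise ValueError("degenerate item: single response category")
    ll_null = float(n * (p1 * np.log(p1) + (1 - p1) * np.log(1 - p1)))

    X1 = np.column_stack([ones, th])
    X2 = np.column_stack([X1, D])
    X3 = np.column_stack([X2, th[:, None] * D])
    ll1, _, s1 = fit_logistic(X1, y)
    ll2, _, s2 = fit_logistic(X2, y)
    ll3, _, s3 = fit_logistic(X3, y)
    # Newton can stall a hair short on the smaller model; enforce nesting
    # numerically within tolerance.
    ll2 = max(ll2, ll1)
    ll3 = max(ll3, ll2)
    return NestedFit(ll_null, ll1, ll2, ll3, df_group=len(cats) - 1,
                     stable=s1 and s2 and s3)


def lrt(ll_small: float, ll_big: float, df: int) -> tuple[float, float]:
    """Likelihood-ratio chi-square test between nested fits."""
    stat = 2.0 * (ll_big - ll_small)
    if stat < -NESTING_TOL:
        raise ValueError(f"negative LRT statistic {stat:.3g}: models not nested?")
    stat = max(stat, 0.0)
    return stat, float(chi2_dist.sf(stat, df))


def mcfadden_delta(ll_null: float, ll_small: float, ll_big: float) -> float:
    """Gain in McFadden pseudo-R^2 = 1 - ll/ll_null between nested models."""
    if ll_null >= 0:
        raise ValueError("degenerate intercept-only likelihood")
    r2_small = 1.0 - ll_small / ll_null
    r2_big = 1.0 - ll_big / ll_null
    return r2_big - r2_small


def _magnitude(delta_r2: float, bands: tuple[float, float]) -> str:
    lo, hi = bands
    if abs(delta_r2 - lo) < 1e-6 or abs(delta_r2 - hi) < 1e-6:
        log.info("McFadden gain %.8f within 1e-6 of a band boundary", delta_r2)
    if delta_r2 >= hi:
        return "important"
    if delta_r2 >= lo:
        return "moderate"
    return "negligible"


def classify_dif(
    p21: float,
    p32: float,
    delta_r2_21: float,
    delta_r2_32: float,
    alpha: float = ALPHA,
    bands: tuple[float, float] = BANDS,
) -> tuple[str, str]:
    """Classify one item x comparison into DIF type and magnitude.

    Returns (type, magnitude) with type in {"none", "uniform",
    "non-uniform"} and magnitude in {"negligible", "moderate", "important",
    "not-assessed"}. Band boundaries belong to the higher band ("between
    0.035 and 0.07 moderate, above 0.07 important" read as left-closed).
    """
    if p32 < alpha:
        return "non-uniform", _magnitude(delta_r2_32, bands)
    if p21 < alpha:
        return "uniform", _magnitude(delta_r2_21, bands)
    return "none", "not-assessed"


@dataclass(frozen=True)
class DIFResult:
    """Statistics for one item in one group comparison."""

    item: str
    comparison: str
    chi2_21: float
    p_21: float
    chi2_32: float
    p_32: float
    chi2_31: float
    p_31: float
    delta_r2_21: float
    delta_r2_32: float
    flagged: bool  # omnibus model-3-vs-1 LRT at alpha
    dif_type: str
    magnitude: str
    stable: bool


def _item_dif(y, theta, groups, item, comparison, alpha, bands) -> DIFResult:
    fits = fit_nested_models(y, theta, groups)
    c21, p21 = lrt(fits.ll1, fits.ll2, fits.df_group)
    c32, p32 = lrt(fits.ll2, fits.ll3, fits.df_group)
    c31, p31 = lrt(fits.ll1, fits.ll3, 2 * fits.df_group)
    d21 = mcfadden_delta(fits.ll_null, fits.ll1, fits.ll2)
    d32 = mcfadden_delta(fits.ll_null, fits.ll2, fits.ll3)
    kind, mag = classify_dif(p21, p32, d21, d32, alpha, bands)
    if not fits.stable:
        log.warning("separation in item %s (%s); comparison unstable", item, comparison)
    return DIFResult(item, comparison, c21, p21, c32, p32, c31, p31,
                     d21, d32, bool(p31 < alpha), kind, mag, fits.stable)


def _purified_theta(
    df: pd.DataFrame,
    flagged: set[str],
    quadrature_points: int,
) -> np.ndarray:
    anchors = [c for c in df.columns if c not in flagged]
    if len(anchors) < 2:
        log.warning("fewer than 2 anchor items; using all items for theta")
        anchors = list(df.columns)
    bank = fit_grm(df[anchors], quadrature_points=quadrature_points)
    return eap_scores(df[anchors], bank).theta.to_numpy()


def detect_dif(
    m: ResponseMatrix,
    covariate: str,
    pairwise: bool = True,
    purify: bool = True,
    max_purify_iter: int = 10,
    alpha: float = ALPHA,
    bands: tuple[float, float] = BANDS,
    quadrature_points: int = 49,
) -> pd.DataFrame:
    """Run the three-model DIF procedure for every item x group comparison.

    Multi-category covariates are analysed pairwise (e.g. Dijon-FWI,
    Dijon-FG, FWI-FG) when ``pairwise`` is true, otherwise in a single
    omnibus comparison with all categories. The conditioning theta-hat is
    the EAP score from a GRM fitted on the comparison's respondents; with
    ``purify`` the theta is re-estimated from non-flagged items until the
    flag set stabilizes (or ``max_purify_iter``).
    """
    if covariate not in m.covariates:
        raise KeyError(f"covariate {covariate!r} not declared")
    labels = m.groups[covariate]
    cats = sorted(labels.unique())
    if len(cats) < 2:
        raise ValueError(f"covariate {covariate!r} has fewer than 2 groups")
    pairs = list(combinations(cats, 2)) if pairwise and len(cats) > 2 else [tuple(cats)]

    rows: list[DIFResult] = []
    for pair in pairs:
        mask = labels.isin(pair).to_numpy()
        df = m.responses.loc[mask]
        g = labels.loc[mask].to_numpy()
        comparison = " vs ".join(pair)
        flagged: set[str] = set()
        results: list[DIFResult] = []
        for it in range(max_purify_iter + 1):
            theta = _purified_theta(df, flagged, quadrature_points)
            results = [
                _item_dif(df[col].to_numpy(), theta, g, col, comparison, alpha, bands)
                for col in df.columns
            ]
            new_flags = {r.item for r in results if r.flagged}
            if not purify or new_flags == flagged:
                break
            flagged = new_flags
            log.info("purification pass %d (%s): flags=%s", it + 1, comparison,
                     sorted(flagged) or "none")
        rows.extend(results)

    return pd.DataFrame([dataclasses.asdict(r) for r in rows])


def dif_table(results: pd.DataFrame) -> pd.DataFrame:
    """Report-style table: one row per item x comparison with p-values,
    McFadden gains (shown only when the corresponding LRT is significant)
    and the classification."""

    def fmt_p(p):
        return "<0.001" if p < 0.001 else f"{p:.3f}"

    out = pd.DataFrame({
        "item": results["item"],
        "comparison": results["comparison"],
        "p_21": results["p_21"].map(fmt_p),
        "p_32": results["p_32"].map(fmt_p),
        "delta_R2_21": [
            f"{d:.3f}" if t == "uniform" else "-"
            for d, t in zip(results["delta_r2_21"], results["dif_type"])
        ],
        "delta_R2_32": [
            f"{d:.3f}" if t == "non-uniform" else "-"
            for d, t in zip(results["delta_r2_32"], results["dif_type"])
        ],
        "dif_type": results["dif_type"],
        "magnitude": results["magnitude"],
    })
    return out
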