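"""Unidimensional graded response model, binary case (= two-parameter
logistic), fitted by marginal maximum likelihood.

Estimation is Bock–Aitkin EM over a Gauss–Hermite quadrature grid with the
latent trait fixed to Normal(0, 1) for identification. Each item follows

    P(y_ij = 1 | theta_i) = logistic(a_j (theta_i - b_j)),   a_j > 0,

where ``b_j`` (difficulty) is the trait level at which a respondent has a
50% chance of endorsing the item and ``a_j`` (slope) is its discriminant
capacity. Latent-trait scores are expected-a-posteriori (EAP) means under
the standard-normal prior.

Orientation convention: the pipeline aligns item coding so that the
endorsed (1) response is the *less* precarious answer, hence higher theta
means lower deprivation; weighted deprivation sum scores therefore
correlate negatively with theta.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, log_expit

from .cohort import ResponseMatrix

__all__ = ["ItemBank", "ThetaEstimates", "icc_probability", "fit_grm", "eap_scores"]

log = logging.getLogger(__name__)

SLOPE_BOUNDS = (0.05, 10.0)
DIFFICULTY_BOUND = 6.0


def _gh_grid(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Probabilists' Gauss-Hermite nodes/weights for a N(0,1) prior."""
    nodes, weights = np.polynomial.hermite_e.hermegauss(n)
    return nodes, weights / weights.sum()


def icc_probability(theta, a: float, b: float):
    """Item characteristic curve: P(endorse | theta) = logistic(a(theta-b))."""
    if a <= 0:
        raise ValueError(f"slope must be positive, got {a}")
    return expit(a * (np.asarray(theta, dtype=float) - b))


@dataclass
class ItemBank:
    """Fitted item parameters plus fit metadata.

    ``params`` has one row per item with columns ``a`` (slope) and ``b``
    (difficulty). ``group_params``, when present, holds group-specific
    overrides for DIF-aware estimation (columns item, group, a, b).
    """

    params: pd.DataFrame
    log_likelihood: float = float("nan")
    n_iter: int = 0
    converged: bool = True
    ll_history: list[float] = field(default_factory=list)
    group_params: pd.DataFrame | None = None

    @property
    def items(self) -> list[str]:
        return list(self.params.index)

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return self.params["a"].to_numpy(), self.params["b"].to_numpy()

    def to_tsv(self, path) -> None:
        out = self.params.copy()
        out.insert(0, "item", out.index)
        out.to_csv(path, sep="\t", index=False, float_format="%.10g")


@dataclass
class ThetaEstimates:
    """Per-respondent EAP latent-trait estimates with posterior SDs."""

    estimates: pd.DataFrame  # columns theta, posterior_sd

    @property
    def theta(self) -> pd.Series:
        return self.estimates["theta"]

    def to_tsv(self, path) -> None:
        self.estimates.to_csv(path, sep="\t", float_format="%.10g")


def _item_loglik_grid(X: np.ndarray, logP: np.ndarray, log1mP: np.ndarray) -> np.ndarray:
    """log L_ik = sum_j x_ij log P_jk + (1-x_ij) log(1-P_jk); X is n x J,
    logP is J x K; returns n x K."""
    return X @ logP + (1 - X) @ log1mP


def _posterior(X: np.ndarray, a: np.ndarray, b: np.ndarray,
               nodes: np.ndarray, logw: np.ndarray) -> tuple[np.ndarray, float]:
    Z = a[:, None] * (nodes[None, :] - b[:, None])  # J x K
    ll = _item_loglik_grid(X, log_expit(Z), log_expit(-Z)) + logw[None, :]
    m = ll.max(axis=1, keepdims=True)
    w = np.exp(ll - m)
    s = w.sum(axis=1, keepdims=True)
    marginal = float(np.sum(m[:, 0] + np.log(s[:, 0])))
    return w / s, marginal


def _mstep_item(r: np.ndarray, n: np.ndarray, nodes: np.ndarray,
                a0: float, b0: float) -> tuple[float, float]:
    """Maximize sum_k r_k log P + (n_k - r_k) log(1-P) over (a, b) with
    logit P = alpha * t + beta; Newton with step halving."""
    alpha, beta = a0, -a0 * b0

    def nll(al, be):
        z = al * nodes + be
        return -float(np.sum(r * log_expit(z) + (n - r) * log_expit(-z)))

    f0 = nll(alpha, beta)
    for _ in range(50):
        p = expit(alpha * nodes + beta)
        w = n * p * (1 - p)
        g = np.array([np.sum((r - n * p) * nodes), np.sum(r - n * p)])
        H = np.array([[np.sum(w * nodes**2), np.sum(w * nodes)],
                      [np.sum(w * nodes), np.sum(w)]])
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        t = 1.0
        for _ in range(30):
            f1 = nll(alpha + t * step[0], beta + t * step[1])
            if f1 <= f0:
                break
            t /= 2
        alpha, beta = alpha + t * step[0], beta + t * step[1]
        if f0 - f1 < 1e-10 and np.abs(step).max() * t < 1e-8:
            f0 = f1
            break
        f0 = f1
    a = alpha
    clipped = False
    if not SLOPE_BOUNDS[0] <= a <= SLOPE_BOUNDS[1]:
        a = float(np.clip(a, *SLOPE_BOUNDS))
        clipped = True
    b = -beta / a if a != 0 else 0.0
    if abs(b) > DIFFICULTY_BOUND:
        b = float(np.clip(b, -DIFFICULTY_BOUND, DIFFICULTY_BOUND))
        clipped = True
    if clipped:
        log.info("item parameter bounds active (a=%.3f, b=%.3f)", a, b)
        # projecting onto the bounds may undo the Newton gain; fall back to
        # the incoming parameters if so, which keeps EM monotone
        if nll(a, -a * b) > nll(a0, -a0 * b0):
            return a0, b0
    return a, b


def fit_grm(
    m: ResponseMatrix | pd.DataFrame | np.ndarray,
    quadrature_points: int = 49,
    tol: float = 1e-5,
    max_iter: int = 500,
) -> ItemBank:
    """Fit the binary GRM (2PL) by marginal maximum likelihood EM.

    The marginal log-likelihood is non-decreasing across EM iterations (an
    internal assertion); iteration stops when it changes by less than
    ``tol``. Non-convergence at ``max_iter`` is flagged on the returned
    bank, never silent. Items must show both response categories.
    """
    if isinstance(m, ResponseMatrix):
        df = m.responses
    elif isinstance(m, pd.DataFrame):
        df = m
    else:
        df = pd.DataFrame(np.asarray(m))
        df.columns = [f"item{j + 1:02d}" for j in range(df.shape[1])]
    if df.shape[1] < 2:
        raise ValueError("need at least 2 items")
    means = df.mean()
    degenerate = means[(means == 0) | (means == 1)]
    if len(degenerate):
        raise ValueError(
            f"degenerate (constant) item(s): {list(degenerate.index)}"
        )

    X = df.to_numpy(dtype=float)
    nodes, weights = _gh_grid(quadrature_points)
    logw = np.log(weights)

    p = means.to_numpy()
    a = np.ones(df.shape[1])
    b = -np.log(p / (1 - p))  # logit-based start under a=1

    history: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        post, ll = _posterior(X, a, b, nodes, logw)
        if history and ll < history[-1] - 1e-8:
            raise RuntimeError(
                f"EM log-likelihood decreased at iteration {it}: "
                f"{history[-1]:.8f} -> {ll:.8f}"
            )
        history.append(ll)
        if len(history) > 1 and abs(history[-1] - history[-2]) < tol:
            converged = True
            break
        nk = post.sum(axis=0)  # expected count at each node
        R = X.T @ post  # J x K expected endorsements
        for j in range(df.shape[1]):
            a[j], b[j] = _mstep_item(R[j], nk, nodes, a[j], b[j])
    if not converged:
        log.warning("GRM EM did not converge in %d iterations (|dll|=%.3g)",
                    max_iter, abs(history[-1] - history[-2]) if len(history) > 1 else np.nan)

    params = pd.DataFrame({"a": a, "b": b}, index=df.columns)
    params.index.name = "item"
    return ItemBank(params=params, log_likelihood=history[-1], n_iter=it,
                    converged=converged, ll_history=history)


def eap_scores(
    m: ResponseMatrix | pd.DataFrame,
    bank: ItemBank,
    grid_points: int = 121,
    grid_bound: float = 6.0,
) -> ThetaEstimates:
    """Expected-a-posteriori latent-trait scores under a Normal(0,1) prior.

    The posterior is evaluated on an equally spaced grid on
    ``[-grid_bound, grid_bound]``; respondents with identical response
    patterns receive identical estimates. Invariant to item ordering.
    """
    df = m.responses if isinstance(m, ResponseMatrix) else m
    missing = [c for c in df.columns if c not in bank.params.index]
    if missing:
        raise ValueError(f"items not covered by the bank: {missing}")
    sub = bank.params.loc[list(df.columns)]
    a = sub["a"].to_numpy()
    b = sub["b"].to_numpy()

    t = np.linspace(-grid_bound, grid_bound, grid_points)
    log_prior = -0.5 * t**2
    Z = a[:, None] * (t[None, :] - b[:, None])
    X = df.to_numpy(dtype=float)
    ll = _item_loglik_grid(X, log_expit(Z), log_expit(-Z)) + log_prior[None, :]
    mx = ll.max(axis=1, keepdims=True)
    w = np.exp(ll - mx)
    w /= w.sum(axis=1, keepdims=True)
    mean = w @ t
    var = w @ t**2 - mean**2
    est = pd.DataFrame(
        {"theta": mean, "posterior_sd": np.sqrt(np.maximum(var, 0.0))},
        index=df.index,
    )
    return ThetaEstimates(estimates=est)
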