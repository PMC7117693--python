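"""Classical-test-theory companions to the IRT pipeline.

* Cronbach's alpha for internal consistency (on direction-aligned codes);
* Pearson chi-square comparisons of item endorsement across subgroups;
* multiple correspondence analysis (MCA) of the binary indicator matrix to
  explore sub-dimensions, with an orthogonal varimax-type rotation of the
  retained dimensions so that item contributions concentrate and the
  dimensions become interpretable. Rotation redistributes variance within
  the retained block but leaves the block total unchanged.

MCA is computed directly as the correspondence analysis of the complete
disjunctive (indicator) table: each binary item contributes two category
columns, row masses are uniform, and the SVD of the standardized residual
matrix yields principal inertias (eigenvalues), category coordinates and
contributions.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency
from statsmodels.multivariate.factor_rotation import rotate_factors

from .cohort import ResponseMatrix

__all__ = [
    "MCAResult",
    "cronbach_alpha",
    "chi2_endorsement",
    "mca_fit",
    "rotate_mca",
    "contribution_table",
]

log = logging.getLogger(__name__)


def cronbach_alpha(
    m: ResponseMatrix | pd.DataFrame,
    items: list[str] | None = None,
) -> float:
    """Cronbach's alpha: (J/(J-1)) (1 - sum(var_j)/var(total)).

    Computed on the matrix's current (direction-aligned) coding; reversal
    state does not change the value as long as items are aligned.
    """
    df = m.responses if isinstance(m, ResponseMatrix) else m
    if items is not None:
        df = df[items]
    J = df.shape[1]
    if J < 2:
        raise ValueError("alpha needs at least 2 items")
    item_vars = df.var(axis=0, ddof=1)
    total_var = df.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("zero total-score variance")
    return float(J / (J - 1) * (1.0 - item_vars.sum() / total_var))


def chi2_endorsement(
    m: ResponseMatrix,
    covariate: str,
    alpha: float = 0.05,
    correction: bool = False,
) -> pd.DataFrame:
    """Per-item Pearson chi-square on the item x group endorsement table.

    Yates continuity correction is off by default; ``correction=True``
    enables it for 2x2 tables.
    """
    if covariate not in m.covariates:
        raise KeyError(f"covariate {covariate!r} not declared")
    g = m.groups[covariate]
    rows = {}
    for lab in m.item_labels:
        tab = pd.crosstab(m.responses[lab], g)
        if (tab.to_numpy() == 0).any() or tab.shape[0] < 2:
            raise ValueError(f"empty contingency cell for item {lab!r}")
        res = chi2_contingency(tab.to_numpy(), correction=correction)
        rows[lab] = {"chi2": float(res.statistic), "p": float(res.pvalue),
                     "significant": bool(res.pvalue < alpha)}
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# Multiple correspondence analysis


@dataclass
class MCAResult:
    """Eigen-structure of the indicator-matrix MCA.

    ``loadings`` are mass-weighted category coordinates whose squared column
    sums equal the dimension variances; ``category_contributions`` columns
    each sum to 1. Only the first ``n_keep`` dimensions are retained for
    rotation and reporting.
    """

    eigenvalues: np.ndarray  # principal inertias, descending (all dims)
    pct_variance: np.ndarray  # percent of total inertia (all dims)
    loadings: pd.DataFrame  # categories x retained dims
    category_contributions: pd.DataFrame  # categories x retained dims
    category_coords: pd.DataFrame  # principal coordinates, retained dims
    category_masses: pd.Series
    item_of_category: dict[str, str]
    total_inertia: float
    n_keep: int
    rotated: bool = False
    benzecri: bool = False

    @property
    def retained_variance(self) -> np.ndarray:
        """Variance carried by each retained dimension (post-rotation aware)."""
        return (self.loadings**2).sum(axis=0).to_numpy()

    def to_json(self, path) -> None:
        d = {
            "eigenvalues": [float(v) for v in self.eigenvalues],
            "pct_variance": [float(v) for v in self.pct_variance],
            "total_inertia": float(self.total_inertia),
            "n_keep": self.n_keep,
            "rotated": self.rotated,
            "benzecri": self.benzecri,
            "category_contributions": json.loads(
                self.category_contributions.to_json(orient="index")),
        }
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2, sort_keys=True)


def _indicator(df: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, str]]:
    cols, item_of = {}, {}
    for lab in df.columns:
        for cat in (0, 1):
            name = f"{lab}={cat}"
            cols[name] = (df[lab] == cat).astype(float)
            item_of[name] = lab
    return pd.DataFrame(cols, index=df.index), item_of


def mca_fit(
    m: ResponseMatrix | pd.DataFrame,
    n_keep: int = 4,
    benzecri: bool = False,
) -> MCAResult:
    """MCA of the complete disjunctive table of binary items.

    The sum of the principal inertias equals the total inertia of the
    indicator table (K/J - 1 = 1 for all-binary items). ``n_keep``
    dimensions are retained for rotation/reporting; ``benzecri`` applies the
    Benzécri inertia adjustment to the reported percentages (the raw
    eigenvalues are kept alongside).
    """
    df = m.responses if isinstance(m, ResponseMatrix) else m
    n, J = df.shape
    if n <= 2 * J:
        raise ValueError("need n > 2J respondents for a stable MCA")
    if n_keep < 2:
        raise ValueError("n_keep must be at least 2")
    if (df.nunique() < 2).any():
        bad = df.columns[df.nunique() < 2].tolist()
        raise ValueError(f"constant item column(s): {bad}")

    Z, item_of = _indicator(df)
    N = Z.to_numpy().sum()
    P = Z.to_numpy() / N
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    _, sv, Vt = np.linalg.svd(S, full_matrices=False)
    lam = sv**2
    keep_all = lam > 1e-12
    lam, sv, Vt = lam[keep_all], sv[keep_all], Vt[keep_all]
    total = float(lam.sum())
    pct = 100.0 * lam / total
    if benzecri:
        thresh = 1.0 / J
        adj = np.where(lam > thresh, ((J / (J - 1)) * (lam - thresh)) ** 2, 0.0)
        pct = 100.0 * adj / adj.sum()

    n_keep = min(n_keep, len(lam))
    dims = [f"dim{s + 1}" for s in range(n_keep)]
    V = Vt.T[:, :n_keep]
    # loading L_js = sqrt(c_j) * principal coord = v_js * sigma_s
    L = V * sv[:n_keep]
    coords = L / np.sqrt(c)[:, None]
    contrib = L**2 / lam[:n_keep]

    cats = list(Z.columns)
    return MCAResult(
        eigenvalues=lam,
        pct_variance=pct,
        loadings=pd.DataFrame(L, index=cats, columns=dims),
        category_contributions=pd.DataFrame(contrib, index=cats, columns=dims),
        category_coords=pd.DataFrame(coords, index=cats, columns=dims),
        category_masses=pd.Series(c, index=cats),
        item_of_category=item_of,
        total_inertia=total,
        n_keep=n_keep,
        benzecri=benzecri,
    )


def rotate_mca(res: MCAResult) -> MCAResult:
    """Varimax-type rotation of the retained-dimension block.

    An orthogonal rotation of the mass-weighted category loadings maximizes
    the varimax squared-loading-variance criterion; dimension variances and
    contributions are recomputed per rotated dimension and dimensions are
    reordered by decreasing rotated variance. The retained block's total
    variance is invariant.
    """
    if res.n_keep < 2:
        raise ValueError("rotation needs at least 2 retained dimensions")
    L = res.loadings.to_numpy()
    Lrot, _ = rotate_factors(L, "varimax")
    var = (Lrot**2).sum(axis=0)
    order = np.argsort(var)[::-1]
    Lrot, var = Lrot[:, order], var[order]
    # fix sign: make the largest-magnitude loading of each dimension positive
    for s in range(Lrot.shape[1]):
        if Lrot[np.abs(Lrot[:, s]).argmax(), s] < 0:
            Lrot[:, s] = -Lrot[:, s]
    dims = list(res.loadings.columns)
    cats = list(res.loadings.index)
    contrib = Lrot**2 / var
    pct = res.pct_variance.copy()
    pct[: res.n_keep] = 100.0 * var / res.total_inertia
    masses = res.category_masses.to_numpy()
    return dataclasses.replace(
        res,
        pct_variance=pct,
        loadings=pd.DataFrame(Lrot, index=cats, columns=dims),
        category_contributions=pd.DataFrame(contrib, index=cats, columns=dims),
        category_coords=pd.DataFrame(Lrot / np.sqrt(masses)[:, None],
                                     index=cats, columns=dims),
        rotated=True,
    )


def contribution_table(
    res: MCAResult, display_threshold: float = 0.2
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Item-level contributions per retained dimension.

    An item's contribution is the sum of its two categories' contributions
    (each dimension's column sums to 1). Returns ``(display, full)``:
    ``display`` blanks entries below ``display_threshold`` (report style),
    ``full`` keeps every value (machine output).
    """
    contrib = res.category_contributions.copy()
    contrib["item"] = [res.item_of_category[c] for c in contrib.index]
    full = contrib.groupby("item", sort=False).sum()
    # preserve original item order
    seen = dict.fromkeys(res.item_of_category.values())
    full = full.loc[list(seen)]
    display = full.copy().astype(object)
    display[full < display_threshold] = ""
    display[full >= display_threshold] = full[full >= display_threshold].round(3)
    pct_row = pd.DataFrame(
        [res.pct_variance[: res.n_keep].round(1)],
        index=["% of variance"], columns=full.columns,
    )
    display = pd.concat([pct_row, display])
    return display, full
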