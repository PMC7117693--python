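"""Synthetic cohorts with the structure the DIF pipeline assumes.

Respondents carry a unidimensional latent trait theta (higher = *less*
precarious, matching the reporting convention downstream); each binary item
follows a two-parameter logistic response process

    P(aligned answer = 1 | theta) = logistic(a_j * (theta - b_j)),

optionally with group-specific difficulty offsets (uniform DIF) and slope
multipliers (non-uniform DIF). True between-group differences in the latent
distribution ("impact") are modelled separately from DIF, so the pipeline's
central property — conditioning on theta absorbs impact but not DIF — is
directly testable. A locally dependent item pair is produced by response
copying: the dependent item copies its partner's answer with probability
``copy_prob`` and is otherwise redrawn from its own 2PL.

The generator emits the *raw* ("yes" as asked) coding: items listed in
``reversed_in_raw`` are stored flipped relative to the aligned coding, so a
realistic pipeline run must reverse them before IRT, exactly as with real
questionnaire data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .cohort import ResponseMatrix

__all__ = [
    "DifEffect",
    "SimulationConfig",
    "SimulationTruth",
    "generate_cohort",
    "india_like_preset",
    "marginal_yes_rate",
]

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite_e.hermegauss(61)
_GH_WEIGHTS = _GH_WEIGHTS / _GH_WEIGHTS.sum()


def marginal_yes_rate(a: float, b: float, mu: float = 0.0, sigma: float = 1.0) -> float:
    """E[logistic(a(theta-b))] for theta ~ Normal(mu, sigma^2), by quadrature."""
    t = mu + sigma * _GH_NODES
    return float(np.sum(_GH_WEIGHTS * expit(a * (t - b))))


def _difficulty_for_rate(a: float, target: float, mu: float = 0.0, sigma: float = 1.0) -> float:
    return brentq(lambda b: marginal_yes_rate(a, b, mu, sigma) - target, -8.0, 8.0)


@dataclass(frozen=True)
class DifEffect:
    """Group-specific item distortion: additive difficulty shift and/or
    multiplicative slope change (slope_mult != 1 makes the DIF non-uniform)."""

    delta_b: float = 0.0
    slope_mult: float = 1.0


@dataclass(frozen=True)
class SimulationConfig:
    group_sizes: Mapping[str, int]
    item_params: tuple[tuple[float, float], ...]  # (slope a_j, difficulty b_j)
    covariate_name: str = "area"
    item_labels: tuple[str, ...] | None = None
    dif_spec: Mapping[tuple[int, str], DifEffect] = field(default_factory=dict)
    impact: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    dependent_pair: tuple[int, int, float] | None = None  # (item_j, item_k, copy_prob)
    reversed_in_raw: frozenset[int] = frozenset()  # 1-based item indices
    extra_covariates: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    seed: int = 0

    @property
    def n_items(self) -> int:
        return len(self.item_params)

    @property
    def labels(self) -> tuple[str, ...]:
        if self.item_labels is not None:
            return self.item_labels
        return tuple(f"item{j + 1:02d}" for j in range(self.n_items))

    def validate(self) -> None:
        for g, n in self.group_sizes.items():
            if n <= 0:
                raise ValueError(f"group {g!r} has non-positive size {n}")
        for (j, g), eff in self.dif_spec.items():
            if not 1 <= j <= self.n_items:
                raise ValueError(f"dif_spec item index {j} out of range")
            a = self.item_params[j - 1][0] * eff.slope_mult
            if a <= 0:
                raise ValueError(f"non-positive slope for item {j} in group {g!r}")
        for a, _ in self.item_params:
            if a <= 0:
                raise ValueError("baseline slopes must be positive")
        if self.dependent_pair is not None:
            j, k, p = self.dependent_pair
            if not 0.5 <= p <= 1.0:
                raise ValueError("copy_prob must lie in [0.5, 1]")
            if j == k or not (1 <= j <= self.n_items and 1 <= k <= self.n_items):
                raise ValueError("dependent_pair indices invalid")


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth emitted alongside the data so detection stages can be
    scored for sensitivity/specificity."""

    theta: pd.Series  # true latent trait per respondent
    item_bank: pd.DataFrame  # baseline (a, b) per item
    group_params: pd.DataFrame  # effective (a, b) per item x group
    dif_items: dict[str, str]  # item label -> "uniform" | "non-uniform"

    def to_tsv(self, theta_path, params_path) -> None:
        self.theta.rename("true_theta").to_csv(theta_path, sep="\t")
        gp = self.group_params.copy()
        gp["dif_type"] = [self.dif_items.get(i, "none") for i in gp["item"]]
        gp.to_csv(params_path, sep="\t", index=False)


def _effective_params(cfg: SimulationConfig, group: str, j: int) -> tuple[float, float]:
    a, b = cfg.item_params[j - 1]
    eff = cfg.dif_spec.get((j, group))
    if eff is not None:
        a *= eff.slope_mult
        b += eff.delta_b
    return a, b


def generate_cohort(cfg: SimulationConfig) -> tuple[ResponseMatrix, SimulationTruth]:
    """Draw a cohort from the configured 2PL process.

    Identical configs (including seed) produce bitwise-identical output.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    labels = cfg.labels
    J = cfg.n_items

    group_col, theta_parts, resp_parts = [], [], []
    for g in cfg.group_sizes:  # insertion order: deterministic
        n_g = cfg.group_sizes[g]
        mu, sigma = cfg.impact.get(g, (0.0, 1.0))
        theta = rng.normal(mu, sigma, size=n_g)
        A = np.array([_effective_params(cfg, g, j + 1)[0] for j in range(J)])
        B = np.array([_effective_params(cfg, g, j + 1)[1] for j in range(J)])
        P = expit(A[None, :] * (theta[:, None] - B[None, :]))
        Y = (rng.random((n_g, J)) < P).astype(np.int8)
        if cfg.dependent_pair is not None:
            j, k, p = cfg.dependent_pair
            copy = rng.random(n_g) < p
            Y[copy, k - 1] = Y[copy, j - 1]
        group_col.extend([g] * n_g)
        theta_parts.append(theta)
        resp_parts.append(Y)

    theta = np.concatenate(theta_parts)
    Y = np.vstack(resp_parts)
    for j in cfg.reversed_in_raw:  # store raw "yes as asked" coding
        Y[:, j - 1] = 1 - Y[:, j - 1]

    n = len(theta)
    idx = pd.Index([f"r{i + 1:05d}" for i in range(n)], name="respondent_id")
    groups = pd.DataFrame({cfg.covariate_name: group_col}, index=idx)
    for cov, dist in cfg.extra_covariates.items():
        cats = list(dist)
        probs = np.asarray([dist[c] for c in cats], dtype=float)
        groups[cov] = rng.choice(cats, size=n, p=probs / probs.sum())

    m = ResponseMatrix(pd.DataFrame(Y, index=idx, columns=labels), groups)

    bank = pd.DataFrame(
        {"item": labels,
         "a": [p[0] for p in cfg.item_params],
         "b": [p[1] for p in cfg.item_params]}
    )
    gp_rows = []
    for g in cfg.group_sizes:
        for j, lab in enumerate(labels, start=1):
            a, b = _effective_params(cfg, g, j)
            gp_rows.append({"item": lab, "group": g, "a": a, "b": b})
    dif_items = {}
    for (j, g), eff in cfg.dif_spec.items():
        kind = "non-uniform" if eff.slope_mult != 1.0 else "uniform"
        lab = labels[j - 1]
        if dif_items.get(lab) != "non-uniform":
            dif_items[lab] = kind
    truth = SimulationTruth(
        theta=pd.Series(theta, index=idx, name="true_theta"),
        item_bank=bank,
        group_params=pd.DataFrame(gp_rows),
        dif_items=dif_items,
    )
    return m, truth


# ---------------------------------------------------------------------------
# Preset emulating the three-area stroke cohort

# Raw "% yes" targets per item for the whole sample (descriptive-table scale).
_RAW_YES_TARGETS = (0.109, 0.787, 0.547, 0.621, 0.335, 0.297, 0.314, 0.336,
                    0.844, 0.836, 0.822)
# Items whose raw "yes" marks the MORE precarious answer (flipped in raw coding).
_REVERSED_IN_RAW = frozenset({1, 5})
_SLOPES = (0.9, 1.2, 0.8, 1.1, 1.3, 1.0, 1.4, 1.2, 0.9, 1.7, 1.7)
_ITEM_LABELS = (
    "social_worker", "health_insurance", "couple", "homeowner",
    "financial_difficulties", "sports", "shows", "holidays",
    "family_contact", "shelter_support", "material_support",
)
_GROUP_SIZES = {"Dijon": 496, "FG": 289, "FWI": 768}
# Latent-mean shifts: the mainland group is on average less precarious.
_IMPACT = {"Dijon": (0.4, 1.0), "FG": (-0.3, 1.0), "FWI": (0.0, 1.0)}
# DIF echoing the kinds of distortion seen across contrasted areas: difficulty
# shifts (uniform) for financially-driven items, slope attenuation
# (non-uniform) where an item loses discriminant capacity in one area.
_DIF = {
    (1, "FWI"): DifEffect(slope_mult=0.4),
    (2, "FG"): DifEffect(delta_b=0.8),
    (4, "FG"): DifEffect(delta_b=0.5),
    (4, "FWI"): DifEffect(slope_mult=0.5),
    (5, "FG"): DifEffect(delta_b=0.8),
    (6, "Dijon"): DifEffect(delta_b=0.6),
}
_SAME_ANSWER_TARGET = 0.93


def _calibrated_copy_prob(
    params: Sequence[tuple[float, float]],
    j: int,
    k: int,
    impact: Mapping[str, tuple[float, float]],
    sizes: Mapping[str, int],
    target: float,
) -> float:
    """copy_prob such that the pair's observed same-answer proportion hits
    ``target``: solves p + (1-p) q = target, q = chance agreement given the
    latent mixture."""
    total = sum(sizes.values())
    q = 0.0
    for g, n_g in sizes.items():
        mu, sigma = impact.get(g, (0.0, 1.0))
        t = mu + sigma * _GH_NODES
        pj = expit(params[j - 1][0] * (t - params[j - 1][1]))
        pk = expit(params[k - 1][0] * (t - params[k - 1][1]))
        q += (n_g / total) * np.sum(_GH_WEIGHTS * (pj * pk + (1 - pj) * (1 - pk)))
    p = (target - q) / (1.0 - q)
    return float(min(1.0, max(0.5, p)))


def india_like_preset(
    n_items: int = 11,
    dif: bool = True,
    impact: bool = True,
    dependent_pair: bool = True,
    group_sizes: Mapping[str, int] | None = None,
    seed: int = 20200402,
) -> SimulationConfig:
    """Three unbalanced area groups (496/289/768, total 1553), 11 binary
    items whose no-DIF marginal yes-rates match the observed 9%-94% band.

    Difficulties are solved by quadrature so that, absent DIF and impact,
    each item's raw yes-rate equals its descriptive-table target. The
    dependent pair (items 10/11) is calibrated so its observed same-answer
    proportion is ~93%. ``dif``/``impact``/``dependent_pair`` switch those
    features off for null simulations; ``n_items=10`` drops the dependent
    duplicate item.
    """
    if n_items not in (10, 11):
        raise ValueError("n_items must be 10 or 11")
    sizes = dict(group_sizes or _GROUP_SIZES)
    # aligned-scale targets: flip the raw target for raw-reversed items
    aligned = [
        1.0 - t if (j + 1) in _REVERSED_IN_RAW else t
        for j, t in enumerate(_RAW_YES_TARGETS)
    ]
    params = tuple(
        (a, _difficulty_for_rate(a, t)) for a, t in zip(_SLOPES, aligned)
    )[:n_items]
    imp = dict(_IMPACT) if impact else {}
    dif_spec = {k: v for k, v in _DIF.items() if dif and k[0] <= n_items}
    pair = None
    if dependent_pair and n_items == 11:
        p = _calibrated_copy_prob(params, 10, 11, imp, sizes, _SAME_ANSWER_TARGET)
        pair = (10, 11, p)
    return SimulationConfig(
        group_sizes=sizes,
        item_params=params,
        item_labels=_ITEM_LABELS[:n_items],
        dif_spec=dif_spec,
        impact=imp,
        dependent_pair=pair,
        reversed_in_raw=_REVERSED_IN_RAW,
        extra_covariates={
            "gender": {"men": 890 / 1553, "women": 663 / 1553},
            "age_band": {"<65": 891 / 1553, ">=65": 662 / 1553},
        },
        seed=seed,
    )
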