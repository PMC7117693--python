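"""Response-table handling for binary deprivation questionnaires.

The single input object of the whole pipeline is a :class:`ResponseMatrix`:
a respondent-by-item table of binary codes (1 = "yes" as the question was
asked) plus one categorical grouping column per covariate of interest
(area of residence, gender, age band, ...).

Two coding conventions coexist and are tracked explicitly:

* **raw coding** — 1 means the respondent answered "yes" to the question as
  worded; descriptive tables use this coding;
* **direction-aligned coding** — after reversing the items whose "yes"
  indicates *higher* deprivation, code 0 denotes the more-precarious answer
  on every item; all IRT/DIF analyses use this coding.

Reversals are recorded in ``reversed_items`` so that either view can be
recovered at any point.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ResponseMatrix",
    "ScoreConfig",
    "load_responses",
    "save_responses",
    "reverse_items",
    "epices_score",
    "equal_weight_config",
    "descriptive_table",
]

_YES = {"1", "yes", "y", "true"}
_NO = {"0", "no", "n", "false"}


@dataclass(frozen=True)
class ResponseMatrix:
    """Respondent x item binary codes plus group labels.

    Parameters
    ----------
    responses
        ``n x J`` DataFrame of 0/1 integers, one column per item, indexed by
        respondent id.
    groups
        DataFrame aligned with ``responses`` holding one categorical column
        per covariate (e.g. ``area``, ``gender``, ``age_band``).
    reversed_items
        Labels of items whose coding has been direction-flipped relative to
        the raw "yes"=1 coding.
    """

    responses: pd.DataFrame
    groups: pd.DataFrame
    reversed_items: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        vals = self.responses.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("response codes must all be 0 or 1")
        if not self.responses.index.equals(self.groups.index):
            raise ValueError("responses and groups must share the same respondent index")
        if self.groups.isna().any().any():
            raise ValueError("every respondent needs a label for every covariate")

    @property
    def n(self) -> int:
        return len(self.responses)

    @property
    def item_labels(self) -> list[str]:
        return list(self.responses.columns)

    @property
    def covariates(self) -> list[str]:
        return list(self.groups.columns)

    def item_names(self, items: Iterable[str | int]) -> list[str]:
        """Resolve item references: strings are labels, ints are 1-based positions."""
        labels = self.item_labels
        out = []
        for it in items:
            if isinstance(it, (int, np.integer)):
                if not 1 <= int(it) <= len(labels):
                    raise IndexError(f"item index {it} out of range 1..{len(labels)}")
                out.append(labels[int(it) - 1])
            elif it in labels:
                out.append(str(it))
            else:
                raise KeyError(f"unknown item {it!r}")
        return out

    def aligned(self) -> pd.DataFrame:
        """Responses in the current (possibly reversed) coding — alias for clarity."""
        return self.responses

    def subset(self, mask: np.ndarray | pd.Series) -> "ResponseMatrix":
        return ResponseMatrix(
            self.responses.loc[mask], self.groups.loc[mask], self.reversed_items
        )

    def drop_items(self, items: Iterable[str | int]) -> "ResponseMatrix":
        names = self.item_names(items)
        return ResponseMatrix(
            self.responses.drop(columns=names),
            self.groups,
            frozenset(self.reversed_items - set(names)),
        )


def _parse_cell(value: object, row: object, col: str) -> int:
    s = str(value).strip().lower()
    if s in _YES:
        return 1
    if s in _NO:
        return 0
    raise ValueError(f"unparseable response {value!r} at row {row!r}, column {col!r}")


def load_responses(
    path: str | Path,
    covariates: Sequence[str],
    id_column: str | None = None,
    logger=None,
) -> ResponseMatrix:
    """Load a respondent CSV, keeping complete cases only.

    Every column that is neither a covariate nor the id column is treated as
    an item and must parse as 0/1/yes/no (case-insensitive). Rows with any
    missing item answer are dropped (complete-case rule) and the number of
    dropped rows is logged. A column named ``respondent_id`` (the name
    :func:`save_responses` writes) is used as the index automatically unless
    ``id_column`` says otherwise.
    """
    df = pd.read_csv(path, dtype=str)
    missing_cov = [c for c in covariates if c not in df.columns]
    if missing_cov:
        raise ValueError(f"covariate column(s) {missing_cov} not found in {path}")
    if id_column is None and "respondent_id" in df.columns:
        id_column = "respondent_id"
    if id_column is not None:
        df = df.set_index(id_column)
    item_cols = [c for c in df.columns if c not in covariates]
    if not item_cols:
        raise ValueError("no item columns found")

    complete = df[item_cols].notna().all(axis=1) & df[list(covariates)].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped and logger is not None:
        logger.info("dropped %d incomplete row(s); %d complete cases kept",
                    n_dropped, int(complete.sum()))
    df = df.loc[complete]
    if df.empty:
        raise ValueError("no complete rows after complete-case filtering")

    resp = pd.DataFrame(index=df.index)
    for col in item_cols:
        resp[col] = [_parse_cell(v, i, col) for i, v in df[col].items()]
    groups = df[list(covariates)].astype(str)
    return ResponseMatrix(resp.astype(np.int8), groups)


def save_responses(m: ResponseMatrix, path: str | Path) -> None:
    """Write responses + covariates back to CSV (raw 0/1 codes as stored)."""
    out = pd.concat([m.responses, m.groups], axis=1)
    out.to_csv(path, index=True, index_label="respondent_id")


def reverse_items(m: ResponseMatrix, items: Iterable[str | int]) -> ResponseMatrix:
    """Flip the coding (x -> 1-x) of the listed items.

    Reversal is an involution: applying it twice with the same item set
    restores the original matrix. ``reversed_items`` tracks the symmetric
    difference so the current coding is always known.
    """
    names = m.item_names(items)
    resp = m.responses.copy()
    resp[names] = 1 - resp[names]
    return ResponseMatrix(
        resp, m.groups, frozenset(m.reversed_items.symmetric_difference(names))
    )


@dataclass(frozen=True)
class ScoreConfig:
    """Weighted-sum score configuration.

    ``weights`` maps item label -> weight applied when the respondent gives
    the *precarious* answer; ``yes_is_precarious`` says, per item, whether
    the raw "yes" is the precarious answer. ``constant`` is added to every
    score. The EPICES preset declares a [0, 100] range with cut-offs at
    30.17 and 48.5; the true item weights are external configuration (they
    are published in the original validation study, not here) — see
    :func:`equal_weight_config` for the placeholder preset.
    """

    weights: Mapping[str, float]
    yes_is_precarious: Mapping[str, bool]
    constant: float = 0.0
    cutoffs: tuple[float, ...] = (30.17, 48.5)
    score_range: tuple[float, float] = (0.0, 100.0)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScoreConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(
            weights=dict(d["weights"]),
            yes_is_precarious=dict(d["yes_is_precarious"]),
            constant=float(d.get("constant", 0.0)),
            cutoffs=tuple(d.get("cutoffs", (30.17, 48.5))),
            score_range=tuple(d.get("score_range", (0.0, 100.0))),
        )

    def to_yaml(self, path: str | Path) -> None:
        d = {
            "weights": {k: float(v) for k, v in self.weights.items()},
            "yes_is_precarious": {k: bool(v) for k, v in self.yes_is_precarious.items()},
            "constant": float(self.constant),
            "cutoffs": [float(c) for c in self.cutoffs],
            "score_range": [float(r) for r in self.score_range],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


def equal_weight_config(
    item_labels: Sequence[str],
    yes_is_precarious: Mapping[str, bool] | None = None,
) -> ScoreConfig:
    """Placeholder preset: every item weighted 100/J, constant 0.

    This is NOT the published EPICES weighting (those weights are external
    configuration); it preserves the declared 0-100 range and the standard
    cut-offs so the scoring plumbing is fully exercisable.
    """
    J = len(item_labels)
    if yes_is_precarious is None:
        yes_is_precarious = {lab: False for lab in item_labels}
    return ScoreConfig(
        weights={lab: 100.0 / J for lab in item_labels},
        yes_is_precarious=dict(yes_is_precarious),
    )


def epices_score(m: ResponseMatrix, cfg: ScoreConfig) -> pd.DataFrame:
    """Per-respondent weighted deprivation score plus per-cutoff indicators.

    The score runs in the *precariousness* direction (higher = more
    deprived): ``score = constant + sum_j w_j * [answer_j is the precarious
    answer]``. Direction flags in the config refer to the raw coding; stored
    reversals are undone internally so the score is invariant to the
    matrix's current coding state.
    """
    missing = [lab for lab in m.item_labels if lab not in cfg.weights]
    if missing:
        raise ValueError(f"missing weight(s) for item(s) {missing}")
    raw = m.responses.copy()
    for lab in m.reversed_items:  # back to raw "yes"=1 coding
        raw[lab] = 1 - raw[lab]
    parts = []
    for lab in m.item_labels:
        yes_prec = cfg.yes_is_precarious.get(lab, False)
        indicator = raw[lab] if yes_prec else 1 - raw[lab]
        parts.append(cfg.weights[lab] * indicator)
    score = cfg.constant + sum(parts)
    lo, hi = cfg.score_range
    if (score < lo - 1e-9).any() or (score > hi + 1e-9).any():
        raise ValueError(
            f"scores fall outside the declared range [{lo}, {hi}]: "
            "check weights/constant configuration"
        )
    out = pd.DataFrame({"score": score})
    for c in cfg.cutoffs:
        out[f"above_{c:g}"] = (score > c).astype(int)
    return out


def descriptive_table(
    m: ResponseMatrix,
    covariates: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Percent "yes" per item, per subgroup and overall, with chi2 flags.

    Computed on the RAW coding (reversals undone), since descriptive tables
    are produced before any reversal. Significance flags come from a Pearson
    chi-square test of the item x group contingency table at ``alpha``.
    """
    from .psych import chi2_endorsement

    covariates = list(covariates or m.covariates)
    raw = m.responses.copy()
    for lab in m.reversed_items:
        raw[lab] = 1 - raw[lab]
    raw_m = ResponseMatrix(raw, m.groups)

    rows: dict[str, dict[str, float | str]] = {lab: {} for lab in m.item_labels}
    for cov in covariates:
        chi2 = chi2_endorsement(raw_m, cov, alpha=alpha)
        for g, sub in raw.groupby(m.groups[cov]):
            for lab in m.item_labels:
                rows[lab][f"{cov}:{g}"] = round(100.0 * sub[lab].mean(), 1)
        for lab in m.item_labels:
            rows[lab][f"{cov}:signif"] = "*" if chi2.loc[lab, "significant"] else ""
    for lab in m.item_labels:
        rows[lab]["whole_sample"] = round(100.0 * raw[lab].mean(), 1)
    return pd.DataFrame.from_dict(rows, orient="index")
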