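"""End-to-end study workflow: from a response table (real or synthetic) to
the full set of report artifacts.

Stage order mirrors the analysis protocol:

1. load (or simulate) the cohort;
2. descriptive endorsement table with chi-square subgroup flags — computed
   BEFORE any reversal, on raw codes;
3. reverse the inversely-worded items;
4. fit the GRM and run the IRT diagnostics;
5. remove locally dependent items per recommendation, re-fit, re-diagnose;
6. DIF screening per covariate (pairwise for multi-category covariates);
7. impact assessment (latent scores with and without DIF parameters,
   correlations with the weighted sum score);
8. Cronbach's alpha on the full and the reduced item sets;
9. MCA with varimax-type rotation, whole sample and per group, with and
   without the removed item.

Every invocation writes one run directory with machine-readable TSV/JSON
outputs plus a manifest recording the package version, seed, configuration
hash and a stage log; re-running the same configuration reproduces the
machine outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from ._version import __version__
from .cohort import (ResponseMatrix, ScoreConfig, descriptive_table,
                     epices_score, equal_weight_config, load_responses,
                     reverse_items, save_responses)
from .diagnostics import run_diagnostics
from .dif import detect_dif, dif_table
from .grm import eap_scores, fit_grm
from .impact import correlation_report, theta_dif_aware
from .psych import contribution_table, cronbach_alpha, mca_fit, rotate_mca
from .simulate import SimulationConfig, generate_cohort

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one analysis run needs.

    ``input`` is either a CSV path or a :class:`SimulationConfig`.
    ``reverse`` lists the inversely-worded items (1-based indices or
    labels). ``free_magnitudes`` selects which DIF tiers get group-specific
    parameters in the impact stage (default: moderate and important).
    """

    input: str | Path | SimulationConfig
    covariates: tuple[str, ...] = ("area",)
    reverse: tuple[int | str, ...] = ()
    alpha: float = 0.01
    bands: tuple[float, float] = (0.035, 0.07)
    local_dep_threshold: float = 0.4
    mca_dimensions: int = 4
    score_config: ScoreConfig | str | None = None
    free_magnitudes: tuple[str, ...] = ("moderate", "important")
    purify: bool = True
    outdir: str | Path = "runs"
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        lo, hi = self.bands
        if not lo < hi:
            raise ValueError("bands must be strictly increasing")
        if not self.covariates:
            raise ValueError("at least one covariate required")

    def digest(self) -> str:
        d = dataclasses.asdict(self)
        d["input"] = str(d["input"])
        d["score_config"] = str(d["score_config"])
        d.pop("outdir", None)  # where results land is not part of the analysis
        d.pop("log_level", None)
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)


def _mca_outputs(m: ResponseMatrix, n_keep: int, stem: Path, stage_log: list) -> None:
    res = rotate_mca(mca_fit(m, n_keep=n_keep))
    display, full = contribution_table(res)
    display.to_csv(stem.with_suffix(".tsv"), sep="\t")
    res.to_json(stem.with_suffix(".json"))
    stage_log.append(f"mca: {stem.name} ({m.n} respondents, "
                     f"{len(m.item_labels)} items)")


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute the full workflow; returns the run directory."""
    cfg.validate()
    logging.basicConfig(level=cfg.log_level)
    run_id = f"run_{cfg.digest()}_seed{cfg.seed}"
    outdir = Path(cfg.outdir) / run_id
    outdir.mkdir(parents=True, exist_ok=True)
    stage_log: list[str] = []

    def stage(name):
        log.info("stage: %s", name)
        stage_log.append(name)

    try:
        # -- load / simulate ------------------------------------------------
        stage("load")
        if isinstance(cfg.input, SimulationConfig):
            sim = dataclasses.replace(cfg.input, seed=cfg.seed)
            m, truth = generate_cohort(sim)
            save_responses(m, outdir / "cohort.csv")
            truth.to_tsv(outdir / "true_theta.tsv", outdir / "true_params.tsv")
            stage_log.append(f"simulated cohort: n={m.n}")
        else:
            m = load_responses(cfg.input, covariates=list(cfg.covariates), logger=log)
            stage_log.append(f"loaded cohort: n={m.n}")
        missing = [c for c in cfg.covariates if c not in m.covariates]
        if missing:
            raise ValueError(f"covariate(s) {missing} absent from input")

        # -- descriptives (pre-reversal, raw codes) -------------------------
        stage("descriptive_table")
        desc = descriptive_table(m, cfg.covariates)
        desc.to_csv(outdir / "table1_descriptives.tsv", sep="\t")

        # -- reversal -------------------------------------------------------
        stage("reversal")
        if cfg.reverse:
            m = reverse_items(m, list(cfg.reverse))
            stage_log.append(f"reversed items: {sorted(m.reversed_items)}")

        # -- GRM fit + diagnostics ------------------------------------------
        stage("grm_fit")
        bank = fit_grm(m)
        bank.to_tsv(outdir / "item_bank_full.tsv")
        theta = eap_scores(m, bank)
        stage("diagnostics")
        diag = run_diagnostics(m, bank, theta, cfg.local_dep_threshold)
        diag.to_json(outdir / "diagnostics_full.json")
        diag.to_tsv(outdir / "item_fit_full.tsv", outdir / "residual_corr_full.tsv")

        # -- item removal + re-fit ------------------------------------------
        removed = list(diag.removal_recommendation)
        m_red = m
        if removed:
            stage(f"item_removal: {removed}")
            stage_log.append(
                f"item count {len(m.item_labels)} -> {len(m.item_labels) - len(removed)}")
            m_red = m.drop_items(removed)
        stage("grm_refit")
        bank_red = fit_grm(m_red)
        bank_red.to_tsv(outdir / "item_bank_reduced.tsv")
        theta_red = eap_scores(m_red, bank_red)
        theta_red.to_tsv(outdir / "theta_reduced.tsv")
        diag_red = run_diagnostics(m_red, bank_red, theta_red, cfg.local_dep_threshold)
        diag_red.to_json(outdir / "diagnostics_reduced.json")

        # -- scoring --------------------------------------------------------
        stage("scoring")
        if isinstance(cfg.score_config, ScoreConfig):
            sc = cfg.score_config
        elif cfg.score_config is not None:
            sc = ScoreConfig.from_yaml(cfg.score_config)
        else:
            yes_prec = {lab: (lab in m.reversed_items) for lab in m.item_labels}
            sc = equal_weight_config(m.item_labels, yes_prec)
        scores = epices_score(m, sc)
        scores.to_csv(outdir / "scores.tsv", sep="\t", float_format="%.10g")

        # -- DIF + impact per covariate -------------------------------------
        for cov in cfg.covariates:
            stage(f"dif: {cov}")
            res = detect_dif(m_red, cov, purify=cfg.purify,
                             alpha=cfg.alpha, bands=cfg.bands)
            res.to_csv(outdir / f"dif_{cov}.tsv", sep="\t", index=False,
                       float_format="%.10g")
            dif_table(res).to_csv(outdir / f"table3_{cov}.tsv", sep="\t", index=False)
            with open(outdir / f"dif_{cov}.json", "w") as fh:
                json.dump(res.to_dict(orient="records"), fh, indent=2,
                          sort_keys=True, default=float)

            stage(f"impact: {cov}")
            freed = sorted(set(
                res.loc[res["magnitude"].isin(cfg.free_magnitudes), "item"]))
            if len(freed) >= len(m_red.item_labels):
                log.warning("all items DIF-flagged for %s; skipping impact", cov)
                continue
            th_aware, _ = theta_dif_aware(m_red, cov, freed)
            rep = correlation_report(scores["score"], theta_red.theta,
                                     th_aware.theta, cov, tuple(freed))
            rep.to_json(outdir / f"impact_{cov}.json")

        # -- classical psychometrics ----------------------------------------
        stage("cronbach")
        _write_json(
            {"alpha_full": round(cronbach_alpha(m), 6),
             "alpha_reduced": round(cronbach_alpha(m_red), 6),
             "n_items_full": len(m.item_labels),
             "n_items_reduced": len(m_red.item_labels)},
            outdir / "cronbach.json")

        stage("mca")
        _mca_outputs(m, cfg.mca_dimensions, outdir / "table4_whole_full", stage_log)
        _mca_outputs(m_red, cfg.mca_dimensions, outdir / "table4_whole_reduced",
                     stage_log)
        primary = cfg.covariates[0]
        for g, sub in m.responses.groupby(m.groups[primary]):
            sub_m = m.subset(m.groups[primary] == g)
            try:
                _mca_outputs(sub_m, cfg.mca_dimensions,
                             outdir / f"table4_{primary}_{g}_full", stage_log)
            except ValueError as exc:
                log.warning("MCA skipped for %s=%s: %s", primary, g, exc)

    except Exception as exc:
        stage_log.append(f"FAILED: {exc}")
        _write_json({"stages": stage_log, "error": str(exc)},
                    outdir / "manifest.json")
        raise RuntimeError(f"pipeline stage failed: {stage_log[-2] if len(stage_log) > 1 else '?'}: {exc}") from exc

    stage("manifest")
    _write_json(
        {"package_version": __version__,
         "seed": cfg.seed,
         "config_hash": cfg.digest(),
         "items_removed": removed,
         "stages": stage_log},
        outdir / "manifest.json")
    return outdir
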