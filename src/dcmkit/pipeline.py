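"""End-to-end analysis pipeline and its run configuration.

The pipeline chains the four analysis stages: (1) fit the saturated model
and select a per-item family member by Wald tests, (2) compute the
per-item screens (discrimination, S-X² fit, DIF), (3) iterate the
screening loop until no item is excluded, and (4) score respondents
(symptom marginals, posterior probability of diagnosis) and evaluate
reliability and — when a reference diagnosis is supplied — diagnostic
accuracy. Every artifact it writes echoes the package version, the
configuration hash, and the seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .estimation import GDINAEstimator, read_responses
from .evaluation import (
    classification_consistency,
    cronbach_alpha,
    diagnostic_accuracy,
    guttman_split_half,
    two_group_comparison,
)
from .latent import read_qmatrix
from .scoring import score_report
from .screening import screening_loop, screening_report
from .selection import select_all_items, selection_report

__all__ = ["RunConfig", "run_pipeline", "synthetic_validation_study"]


def synthetic_validation_study(seed: int, n_replicates: int = 3,
                               scenario_kwargs: dict = None) -> dict:
    """Run the default two-group synthetic validation end to end.

    For each replicate (child seeds derived from ``seed``): generate a
    study, calibrate the saturated model by EM on the calibration sample,
    score the validation sample, classify by the posterior probability of
    meeting the diagnostic rule, and measure accuracy against the true
    (generating) diagnosis. Returns replicate means of sensitivity,
    specificity, Mann-Whitney AUC, diagnostic odds ratio, and the
    group-wise mean rule probabilities.
    """
    from .evaluation import diagnostic_accuracy
    from .scoring import classify, ppia
    from .simulate import SimulationScenario, generate_two_group_study

    root = np.random.default_rng(seed)
    rows = []
    for _ in range(n_replicates):
        s = int(root.integers(2**31))
        sc = SimulationScenario(seed=s, **(scenario_kwargs or {}))
        study = generate_two_group_study(sc)
        est = GDINAEstimator(study.q, models="GDINA", random_state=s).fit(
            study.calibration_responses)
        post = est.predict_proba(study.responses)
        p = ppia(post, est.space_, m=sc.rule_m)
        acc = diagnostic_accuracy(classify(p), study.true_diagnosis, scores=p)
        rows.append({
            "sensitivity": acc.sensitivity,
            "specificity": acc.specificity,
            "auc": acc.auc,
            "dor": acc.dor,
            "ppia_healthy_mean": float(p[study.groups == 0].mean()),
            "ppia_ia_mean": float(p[study.groups == 1].mean()),
        })
    return {k: float(np.mean([r[k] for r in rows])) for k in rows[0]}


@dataclass
class RunConfig:
    """Configuration of one pipeline run; serialisable to YAML."""

    responses: str
    qmatrix: str
    out_dir: str
    validation: str = None       # optional separate respondents to score
    groups: str = None           # CSV of binary DIF grouping columns
    truth: str = None            # CSV with a reference `diagnosis` column
    alpha: float = 0.05
    disc_cut: float = 0.45
    ppia_m: int = 5
    ppia_threshold: float = 0.5
    min_group: int = 50
    consistency_reps: int = 2000
    seed: int = 0
    em: dict = field(default_factory=dict)  # forwarded to GDINAEstimator

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 <= self.disc_cut <= 1:
            raise ValueError("disc_cut must be in [0, 1]")
        if not 0 <= self.ppia_threshold <= 1:
            raise ValueError("ppia_threshold must be in [0, 1]")
        if self.ppia_m < 0:
            raise ValueError("ppia_m must be non-negative")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def _stamp(config: RunConfig) -> dict:
    return {
        "package": "dcmkit",
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the populated run directory.

    Writes ``selection.csv``, ``screening_round_<i>.csv``, ``fitted.json``,
    ``scores.csv``, ``evaluation.json``, and ``run.json``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = _stamp(config)

    def fail(stage, exc):
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    try:
        q = read_qmatrix(config.qmatrix)
        resp_df = read_responses(config.responses)
        X = resp_df.to_numpy(dtype=float)
        if list(resp_df.columns) != list(q.item_ids):
            raise ValueError("response columns do not match Q-matrix items")
    except Exception as exc:  # noqa: BLE001
        fail("load", exc)

    dif_groups = None
    if config.groups:
        gdf = pd.read_csv(config.groups)
        dif_groups = {c: gdf[c].to_numpy() for c in gdf.columns}

    em_kwargs = dict(config.em)
    em_kwargs.setdefault("random_state", config.seed)

    try:
        final_q, rounds = screening_loop(
            X, q, dif_groups, alpha=config.alpha, disc_cut=config.disc_cut,
            min_group=config.min_group, estimator_kwargs=em_kwargs)
        for i, recs in enumerate(rounds, start=1):
            rep = screening_report(recs)
            for key, val in stamp.items():
                rep[key] = val
            rep.to_csv(out / f"screening_round_{i}.csv", index=False)
    except Exception as exc:  # noqa: BLE001
        fail("screening", exc)

    try:
        keep_cols = [list(q.item_ids).index(i) for i in final_q.item_ids]
        Xf = X[:, keep_cols]
        sat = GDINAEstimator(final_q, models="GDINA", **em_kwargs).fit(Xf)
        records = select_all_items(sat, Xf, alpha=config.alpha)
        rep = selection_report(records)
        for key, val in stamp.items():
            rep[key] = val
        rep.to_csv(out / "selection.csv", index=False)
        assignment = [r.selected for r in records]
        fit = GDINAEstimator(final_q, models=assignment, **em_kwargs).fit(Xf)
        fit.to_json(out / "fitted.json", extra={"run": stamp})
    except Exception as exc:  # noqa: BLE001
        fail("fit", exc)

    try:
        if config.validation:
            val_df = read_responses(config.validation)
            Xv = val_df[list(final_q.item_ids)].to_numpy(dtype=float)
        else:
            Xv = Xf
        post = fit.predict_proba(Xv)
        scores = score_report(
            post, fit.space_, m=config.ppia_m,
            threshold=config.ppia_threshold,
            criterion_ids=final_q.criterion_ids)
        for key, val in stamp.items():
            scores[key] = val
        scores.to_csv(out / "scores.csv", index=False)
    except Exception as exc:  # noqa: BLE001
        fail("scoring", exc)

    try:
        evaluation = {
            "reliability": {
                "cronbach_alpha": cronbach_alpha(Xf),
                "guttman_split_half": guttman_split_half(Xf),
                "classification_consistency": classification_consistency(
                    fit, reps=config.consistency_reps,
                    seed=config.seed).tolist(),
            },
            "n_items_final": final_q.n_items,
            "n_rounds": len(rounds),
        }
        if config.truth:
            tdf = pd.read_csv(config.truth)
            truth = tdf["diagnosis"].to_numpy().astype(bool)
            ppia_scores = scores["ppia"].to_numpy()
            predicted = ppia_scores > config.ppia_threshold
            acc = diagnostic_accuracy(predicted, truth, scores=ppia_scores)
            evaluation["accuracy"] = acc.to_dict()
            if "group" in tdf.columns:
                g = tdf["group"].to_numpy()
                totals = np.nansum(Xv, axis=1)
                t, dfree, p, d = two_group_comparison(
                    totals[g == 1], totals[g == 0])
                evaluation["group_comparison"] = {
                    "t": t, "df": dfree, "p": p, "cohens_d": d}
        evaluation["run"] = stamp
        (out / "evaluation.json").write_text(json.dumps(evaluation, indent=2))
    except Exception as exc:  # noqa: BLE001
        fail("evaluation", exc)

    run_log = dict(stamp)
    run_log["config"] = asdict(config)
    run_log["final_items"] = list(final_q.item_ids)
    (out / "run.json").write_text(json.dumps(run_log, indent=2))
    return out
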