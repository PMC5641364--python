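"""Diagnosis scoring: symptom marginals, MAP profiles, and the posterior
probability of disorder.

Given a respondent's joint posterior over the 2**K symptom profiles, the
score report contains:

* the K per-criterion marginal probabilities (EAP marginals),
* the maximum-a-posteriori symptom profile,
* the posterior probability of meeting the diagnostic rule — the joint
  posterior mass on classes with at least ``m`` criteria present (the
  DSM-style rule is m = 5 of K = 9); this is **not** the product-of-
  marginals tail, which would ignore posterior dependence among criteria,
* the binary diagnosis: probability strictly greater than the threshold
  (default 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .latent import LatentClassSpace

__all__ = [
    "symptom_marginals",
    "ppia",
    "classify",
    "map_profile",
    "DiagnosisReport",
    "score_report",
]


def _as_posterior(posterior, space: LatentClassSpace) -> np.ndarray:
    p = np.atleast_2d(np.asarray(posterior, dtype=float))
    if p.shape[1] != space.n_classes:
        raise ValueError("posterior length does not match the class space")
    if (p < -1e-10).any() or np.abs(p.sum(axis=1) - 1).max() > 1e-8:
        raise ValueError("posterior rows must be simplex vectors")
    return p


def symptom_marginals(posterior, space: LatentClassSpace) -> np.ndarray:
    """Per-criterion posterior probability: sum of posterior mass over the
    classes in which the criterion is present."""
    p = _as_posterior(posterior, space)
    out = p @ space.profiles.astype(float)
    return out[0] if np.asarray(posterior).ndim == 1 else out


def ppia(posterior, space: LatentClassSpace, m: int = 5) -> np.ndarray | float:
    """Posterior probability of meeting >= m of the K criteria.

    Computed from the joint posterior (mass on classes whose profile count
    is at least m), never from the product of marginals.
    """
    if not (0 <= m <= space.n_criteria + 1):
        raise ValueError("threshold count m out of range")
    p = _as_posterior(posterior, space)
    out = p[:, space.counts >= m].sum(axis=1)
    return float(out[0]) if np.asarray(posterior).ndim == 1 else out


def classify(ppia_value, threshold: float = 0.5):
    """Binary diagnosis: strictly greater than the threshold."""
    arr = np.asarray(ppia_value, dtype=float)
    if (arr < 0).any() or (arr > 1).any():
        raise ValueError("probability outside [0, 1]")
    out = arr > threshold
    return bool(out) if arr.ndim == 0 else out


def map_profile(posterior, space: LatentClassSpace) -> np.ndarray:
    """Maximum-a-posteriori symptom profile.

    Ties are broken toward the profile with fewer criteria present, then
    toward the lowest class index (so a uniform posterior maps to the
    all-absent profile).
    """
    p = _as_posterior(posterior, space)
    single = np.asarray(posterior).ndim == 1
    # lexicographic: maximise prob, then minimise count, then index
    order = np.lexsort(
        (np.tile(np.arange(space.n_classes), (p.shape[0], 1))[0],
         space.counts,)
    )  # stable ordering of classes by (count, index)
    out = np.empty((p.shape[0], space.n_criteria), dtype=np.int8)
    for i in range(p.shape[0]):
        best = max(range(space.n_classes),
                   key=lambda c: (p[i, c], -space.counts[c], -c))
        out[i] = space.profiles[best]
    return out[0] if single else out


@dataclass
class DiagnosisReport:
    """Per-respondent score report row."""

    respondent_id: str
    symptom_marginals: np.ndarray
    map_profile: np.ndarray
    ppia: float
    diagnosis: bool


def score_report(posteriors, space: LatentClassSpace, *,
                 respondent_ids=None, m: int = 5,
                 threshold: float = 0.5,
                 criterion_ids=None) -> pd.DataFrame:
    """Score reports for a posterior matrix, one row per respondent.

    Columns: one marginal per criterion, the MAP profile (as a bit string),
    the posterior probability of diagnosis, and the binary diagnosis.
    """
    p = _as_posterior(posteriors, space)
    n = p.shape[0]
    if respondent_ids is None:
        respondent_ids = [f"r{i + 1}" for i in range(n)]
    if criterion_ids is None:
        criterion_ids = [f"S{k + 1}" for k in range(space.n_criteria)]
    marg = symptom_marginals(p, space)
    maps = map_profile(p, space)
    prob = ppia(p, space, m=m)
    df = pd.DataFrame(marg, columns=list(criterion_ids))
    df.insert(0, "respondent_id", list(respondent_ids))
    df["map_profile"] = ["".join(map(str, row)) for row in maps]
    df["ppia"] = prob
    df["diagnosis"] = classify(prob, threshold=threshold).astype(int)
    return df


def plot_symptom_spectrum(report: pd.DataFrame, criterion_ids, path=None):
    """Bar chart of per-criterion marginals for a few respondents."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ids = report["respondent_id"].tolist()
    k = len(criterion_ids)
    x = np.arange(k)
    width = 0.8 / max(len(ids), 1)
    fig, ax = plt.subplots(figsize=(8, 3.5))
    for i, rid in enumerate(ids):
        ax.bar(x + i * width, report.iloc[i][list(criterion_ids)].to_numpy(),
               width, label=str(rid))
    ax.set_xticks(x + width * (len(ids) - 1) / 2)
    ax.set_xticklabels(criterion_ids)
    ax.set_ylabel("posterior probability")
    ax.set_ylim(0, 1)
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
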