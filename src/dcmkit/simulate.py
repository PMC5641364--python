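"""Synthetic data with the statistical structure the analysis assumes.

The generator emulates a symptom-criterion instrument study: a Q-matrix
over K = 9 binary DSM-style criteria with mostly single-criterion items
(mean criteria per item about 1.46), item response functions from the
G-DINA family with all-vs-none discriminations in [0.45, 0.65], a general
calibration sample, and a two-group validation sample (healthy n = 199,
disordered n = 96) in which disordered respondents meet the >= 5-of-9
rule with high probability. True profiles, parameters and diagnoses are
returned so downstream estimates can be checked against the generating
truth.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml
from scipy import stats

from .irf import ItemParams, class_probability_table, design_matrix, expand_to_gdina
from .latent import QMatrix

__all__ = [
    "SimulationScenario",
    "StudyData",
    "generate_qmatrix",
    "generate_profiles",
    "generate_item_params",
    "generate_responses",
    "generate_two_group_study",
    "inject_dif",
]

DEFAULT_KSTAR_WEIGHTS = {1: 0.63, 2: 0.28, 3: 0.09}  # mean K_j* ~ 1.46


@dataclass
class SimulationScenario:
    """Study design for the synthetic two-group validation experiment.

    Defaults mirror the emulated study: K = 9 criteria, a 50-item
    instrument, a calibration sample of 1,263 general respondents, and a
    validation sample of 199 healthy plus 96 disordered respondents where
    a disordered respondent meets the >= ``rule_m``-criteria rule with
    probability ``ia_rule_prob``.
    """

    n_criteria: int = 9
    n_items: int = 50
    n_calibration: int = 1263
    n_healthy: int = 199
    n_ia: int = 96
    rule_m: int = 5
    kstar_weights: dict = field(
        default_factory=lambda: dict(DEFAULT_KSTAR_WEIGHTS))
    model_pool: tuple = ("GDINA", "ACDM", "LLM", "RRUM", "DINA", "DINO")
    disc_range: tuple = (0.45, 0.65)
    baseline_range: tuple = (0.10, 0.30)
    healthy_prevalence: float = 0.20
    healthy_borderline_share: float = 0.15
    borderline_prevalence: float = 0.45
    ia_rule_prob: float = 0.90
    ia_severity: float = 0.80
    calibration_ia_share: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        lo, hi = self.disc_range
        b0, b1 = self.baseline_range
        if not (0 < lo <= hi < 1 and 0 < b0 <= b1 < 1 and hi + b1 < 1):
            raise ValueError("discrimination/baseline ranges must keep "
                             "probabilities inside (0, 1)")

    def healthy_profile_spec(self) -> dict:
        """Profile distribution of the control group.

        Mostly low independent criterion prevalences (typical members meet
        at most a couple of criteria), with a minority borderline
        component at a moderate prevalence, truncated below the
        diagnostic rule: sub-threshold controls with elevated symptom
        load, as produced by screening on manifest behaviour rather than
        latent symptom status.
        """
        base = {"kind": "independent", "prevalence": self.healthy_prevalence,
                "n_criteria": self.n_criteria}
        if self.healthy_borderline_share <= 0:
            return base
        return {
            "kind": "mixture",
            "weights": [1 - self.healthy_borderline_share,
                        self.healthy_borderline_share],
            "components": [
                base,
                {"kind": "truncated_independent",
                 "prevalence": self.borderline_prevalence,
                 "n_criteria": self.n_criteria,
                 "max_count": self.rule_m - 1},
            ],
        }

    def ia_profile_spec(self) -> dict:
        """Profile distribution of the disordered group.

        A mixture: with probability ``ia_rule_prob`` a clinically severe
        profile — independent Bernoulli(``ia_severity``) per criterion,
        conditioned on meeting the >= ``rule_m`` rule — otherwise an
        unconditioned healthy-like draw (imperfectly recruited cases), so
        the group meets the diagnostic rule with about the configured
        probability and rule-meeting members are predominantly well above
        the boundary count.
        """
        return {
            "kind": "rule_mixture",
            "n_criteria": self.n_criteria,
            "rule_m": self.rule_m,
            "rule_prob": self.ia_rule_prob,
            "severity": self.ia_severity,
            "background_prevalence": self.healthy_prevalence,
        }

    def to_yaml(self, path=None) -> str:
        d = asdict(self)
        d["model_pool"] = list(self.model_pool)
        d["disc_range"] = list(self.disc_range)
        d["baseline_range"] = list(self.baseline_range)
        text = yaml.safe_dump(d, sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "SimulationScenario":
        if hasattr(source, "read"):
            d = yaml.safe_load(source.read())
        else:
            try:
                with open(source) as fh:
                    d = yaml.safe_load(fh)
            except (OSError, ValueError):
                d = yaml.safe_load(source)
        for key in ("model_pool", "disc_range", "baseline_range"):
            if key in d:
                d[key] = tuple(d[key])
        if "kstar_weights" in d:
            d["kstar_weights"] = {int(k): float(v)
                                  for k, v in d["kstar_weights"].items()}
        return cls(**d)


def generate_qmatrix(n_items: int, n_criteria: int, kstar_weights=None,
                     seed: int = 0, complete: bool = True) -> QMatrix:
    """Random Q-matrix: every item measures 1-3 criteria.

    With ``complete`` (default), the first K items form an identity block
    so each criterion has at least one single-criterion item — the
    completeness condition that keeps all 2**K classes identifiable.
    Remaining items draw their criteria favouring the least-covered ones,
    so the number of items per criterion stays balanced (roughly J * mean
    K_j* / K each) as in expert-built instruments.
    """
    if complete and n_items < n_criteria:
        raise ValueError("need at least one item per criterion for a "
                         "complete design")
    weights = dict(kstar_weights or DEFAULT_KSTAR_WEIGHTS)
    ks = np.array(sorted(weights))
    w = np.array([weights[k] for k in ks], dtype=float)
    if (ks < 1).any() or ks.max() > n_criteria:
        raise ValueError("K_j* weights out of range")
    w = w / w.sum()
    rng = np.random.default_rng(seed)
    rows = []
    n_fixed = n_criteria if complete else 0
    for k in range(n_fixed):
        row = np.zeros(n_criteria, dtype=np.int8)
        row[k] = 1
        rows.append(row)
    coverage = np.ones(n_criteria) if complete else np.zeros(n_criteria)
    for _ in range(n_items - n_fixed):
        kstar = int(rng.choice(ks, p=w))
        row = np.zeros(n_criteria, dtype=np.int8)
        # least-covered criteria first, random tie-breaking
        order = np.argsort(coverage + rng.uniform(0, 0.5, n_criteria))
        row[order[:kstar]] = 1
        coverage += row
        rows.append(row)
    return QMatrix(np.array(rows))


def generate_profiles(n: int, spec, seed: int = 0) -> np.ndarray:
    """Draw n latent symptom profiles.

    ``spec`` is either ``{"kind": "independent", "prevalence": p}`` with a
    scalar or per-criterion vector of prevalences and a required
    ``"n_criteria"`` when p is scalar, or ``{"kind": "table", "probs": pi,
    "n_criteria": K}`` giving a full distribution over the 2**K classes.
    """
    rng = np.random.default_rng(seed)
    if spec["kind"] == "independent":
        prev = np.asarray(spec["prevalence"], dtype=float)
        if prev.ndim == 0:
            prev = np.full(int(spec["n_criteria"]), float(prev))
        if (prev < 0).any() or (prev > 1).any():
            raise ValueError("prevalences must lie in [0, 1]")
        return (rng.random((n, prev.size)) < prev).astype(np.int8)
    if spec["kind"] == "table":
        probs = np.asarray(spec["probs"], dtype=float)
        K = int(spec["n_criteria"])
        if probs.size != 2**K:
            raise ValueError("probs must have length 2**K")
        classes = rng.choice(probs.size, size=n, p=probs / probs.sum())
        return ((classes[:, None] >> np.arange(K)) & 1).astype(np.int8)
    if spec["kind"] == "truncated_independent":
        prev = np.asarray(spec["prevalence"], dtype=float)
        if prev.ndim == 0:
            prev = np.full(int(spec["n_criteria"]), float(prev))
        max_count = int(spec["max_count"])
        out = np.zeros((n, prev.size), dtype=np.int8)
        for i in range(n):
            while True:  # rejection sampling below the count ceiling
                prof = (rng.random(prev.size) < prev).astype(np.int8)
                if prof.sum() <= max_count:
                    out[i] = prof
                    break
        return out
    if spec["kind"] == "mixture":
        weights = np.asarray(spec["weights"], dtype=float)
        weights = weights / weights.sum()
        comps = spec["components"]
        which = rng.choice(len(comps), size=n, p=weights)
        sub_seeds = rng.integers(2**31, size=len(comps))
        out = None
        for c, comp in enumerate(comps):
            drawn = generate_profiles(int((which == c).sum()), comp,
                                      seed=int(sub_seeds[c]))
            if out is None:
                out = np.zeros((n, drawn.shape[1]), dtype=np.int8)
            out[which == c] = drawn
        return out
    if spec["kind"] == "rule_mixture":
        K = int(spec["n_criteria"])
        m = int(spec["rule_m"])
        rule_prob = float(spec["rule_prob"])
        severe_prev = np.full(K, float(spec["severity"]))
        backgr_prev = np.full(K, float(spec["background_prevalence"]))
        severe = rng.random(n) < rule_prob
        out = (rng.random((n, K)) < backgr_prev).astype(np.int8)
        idx = np.flatnonzero(severe)
        for i in idx:
            # rejection sampling of a severe profile meeting the count rule
            while True:
                prof = (rng.random(K) < severe_prev).astype(np.int8)
                if prof.sum() >= m:
                    out[i] = prof
                    break
        return out
    raise ValueError(f"unknown profile spec kind {spec.get('kind')!r}")


def _split_effect(rng, total: float, parts: int) -> np.ndarray:
    """Split a total effect into unequal positive parts (Dirichlet(3))."""
    return total * rng.dirichlet(np.full(parts, 3.0))


def generate_item_params(q: QMatrix, seed: int = 0, *,
                         model_pool=("GDINA", "ACDM", "LLM", "RRUM",
                                     "DINA", "DINO"),
                         disc_range=(0.45, 0.65),
                         baseline_range=(0.10, 0.30),
                         models=None) -> list:
    """Draw item parameters with discriminations in ``disc_range``.

    Multi-criterion items take a model from ``model_pool`` (or the
    explicit per-item ``models`` list); single-criterion items are
    two-parameter regardless of tag. Baselines phi_j0 are uniform on
    ``baseline_range`` and the all-vs-none gap uniform on ``disc_range``,
    so every generated item clears the default screening cut.
    """
    rng = np.random.default_rng(seed)
    out = []
    for j in range(q.n_items):
        qrow = q.entries[j]
        kstar = int(qrow.sum())
        p0 = rng.uniform(*baseline_range)
        disc = rng.uniform(*disc_range)
        p1 = p0 + disc
        if models is not None:
            model = models[j]
        elif kstar == 1:
            model = "GDINA"
        else:
            model = model_pool[rng.integers(len(model_pool))]
        if kstar == 1:
            coeffs = np.array([p0, disc])
            out.append(ItemParams("GDINA", qrow, coeffs, item_id=q.item_ids[j]))
            continue
        if model == "GDINA":
            counts = ((np.arange(2**kstar)[:, None] >> np.arange(kstar)) & 1
                      ).sum(axis=1)
            table = np.empty(2**kstar)
            table[0], table[-1] = p0, p1
            mid = (counts > 0) & (counts < kstar)
            # interior classes: random but increasing in criteria count
            lo = p0 + disc * (counts[mid] - 0.7) / kstar
            hi = p0 + disc * (counts[mid] + 0.2) / kstar
            table[mid] = rng.uniform(lo, hi)
            coeffs = np.linalg.solve(design_matrix("GDINA", kstar), table)
        elif model == "ACDM":
            coeffs = np.concatenate([[p0], _split_effect(rng, disc, kstar)])
        elif model == "LLM":
            g = stats.logistic.ppf
            coeffs = np.concatenate(
                [[g(p0)], _split_effect(rng, g(p1) - g(p0), kstar)])
        elif model == "RRUM":
            coeffs = np.concatenate(
                [[np.log(p0)], _split_effect(rng, np.log(p1) - np.log(p0),
                                             kstar)])
        elif model == "DINA":
            coeffs = np.array([p0, disc])
        elif model == "DINO":
            coeffs = np.array([p0, disc])
        else:
            raise ValueError(f"unknown model tag {model!r}")
        out.append(ItemParams(model, qrow, coeffs, item_id=q.item_ids[j]))
    return out


def response_probabilities(profiles, q: QMatrix, item_params) -> np.ndarray:
    """(n, J) matrix of endorsement probabilities for given true profiles."""
    profiles = np.asarray(profiles, dtype=np.int64)
    n, K = profiles.shape
    if K != q.n_criteria:
        raise ValueError("profile width does not match the Q-matrix")
    P = np.empty((n, q.n_items))
    for j, params in enumerate(item_params):
        measured = np.flatnonzero(q.entries[j])
        idx = (profiles[:, measured] << np.arange(measured.size)).sum(axis=1)
        P[:, j] = class_probability_table(params)[idx]
    return P


def generate_responses(profiles, q: QMatrix, item_params,
                       seed: int = 0) -> np.ndarray:
    """Bernoulli responses X_ij ~ Bern(P(X_j = 1 | profile_i))."""
    rng = np.random.default_rng(seed)
    P = response_probabilities(profiles, q, item_params)
    return (rng.random(P.shape) < P).astype(np.int8)


def inject_dif(item_params: ItemParams, shift: float) -> ItemParams:
    """Focal-group parameters with the intercept shifted on the probability
    scale (a uniform shift of every class's endorsement probability).

    Raises if the shift pushes any class probability outside [0, 1].
    """
    sat = expand_to_gdina(item_params)
    coeffs = sat.coeffs.copy()
    coeffs[0] += shift
    return ItemParams("GDINA", sat.qrow, coeffs, item_id=sat.item_id)


@dataclass
class StudyData:
    """Everything the synthetic study produces, truths included."""

    scenario: SimulationScenario
    q: QMatrix
    item_params: list
    calibration_responses: np.ndarray
    calibration_profiles: np.ndarray
    responses: np.ndarray          # validation sample
    groups: np.ndarray             # 0 = healthy, 1 = disordered group
    true_profiles: np.ndarray      # validation sample
    true_diagnosis: np.ndarray     # DSM rule applied to the true profile


def generate_two_group_study(scenario: SimulationScenario) -> StudyData:
    """Generate the full synthetic study for a scenario.

    The validation sample stacks the healthy group (low independent
    criterion prevalences) on the disordered group (prevalence solved so
    the >= m rule holds with the configured probability); the reference
    diagnosis is the rule applied to the *true* profile. The calibration
    sample is a healthy/disordered mixture so all profile regions are
    observed during item calibration.
    """
    sc = scenario
    root = np.random.default_rng(sc.seed)
    seeds = root.integers(2**31, size=8)
    q = generate_qmatrix(sc.n_items, sc.n_criteria, sc.kstar_weights,
                         seed=int(seeds[0]))
    params = generate_item_params(
        q, seed=int(seeds[1]), model_pool=sc.model_pool,
        disc_range=sc.disc_range, baseline_range=sc.baseline_range)

    ia_spec = sc.ia_profile_spec()
    healthy_spec = sc.healthy_profile_spec()
    n_cal_ia = int(round(sc.calibration_ia_share * sc.n_calibration))
    cal_healthy = generate_profiles(
        sc.n_calibration - n_cal_ia, healthy_spec, seed=int(seeds[2]))
    cal_ia = generate_profiles(n_cal_ia, ia_spec, seed=int(seeds[3]))
    cal_profiles = np.vstack([cal_healthy, cal_ia])
    cal_responses = generate_responses(cal_profiles, q, params,
                                       seed=int(seeds[4]))

    healthy = generate_profiles(sc.n_healthy, healthy_spec,
                                seed=int(seeds[5]))
    ia = generate_profiles(sc.n_ia, ia_spec, seed=int(seeds[6]))
    val_profiles = np.vstack([healthy, ia])
    val_responses = generate_responses(val_profiles, q, params,
                                       seed=int(seeds[7]))
    groups = np.concatenate([np.zeros(sc.n_healthy, dtype=int),
                             np.ones(sc.n_ia, dtype=int)])
    true_dx = val_profiles.sum(axis=1) >= sc.rule_m
    return StudyData(scenario=sc, q=q, item_params=params,
                     calibration_responses=cal_responses,
                     calibration_profiles=cal_profiles,
                     responses=val_responses, groups=groups,
                     true_profiles=val_profiles, true_diagnosis=true_dx)
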