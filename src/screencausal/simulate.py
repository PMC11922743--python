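"""Synthetic screening-cohort generator with reading-behavior selection bias.

The generator reproduces the statistical structure the downstream causal
analysis assumes, without any real data:

* heterogeneous reader sets with skewed (log-normal) volumes,
* a latent screen-detectable cancer status driven by age, breast density
  and screening round,
* a continuous AI suspiciousness score in [0, 1] whose quantiles are
  calibrated to the normal-triage and safety-net target rates,
* per-reader self-selection of the AI-supported viewer whose log-odds
  shift with the visible normal tag ("reading behavior bias"), so the
  study group emerges from behavior rather than randomization,
* the outcome cascade consensus conference -> recall -> biopsy ->
  detected cancer, with the AI intervention acting through the safety
  net (escalating missed suspicious cases) and through suppression of
  false flags on normal-tagged examinations.

Two effect modes are supported.  ``"mechanistic"`` (default) realizes the
AI effect through the safety-net and suppression machinery above.
``"ratio"`` replaces the mechanism by a uniform multiplicative scaling of
the cancer cascade (``detection_ratio``) and the benign cascade
(``recall_ratio``) for AI-group examinations, which makes the true
causal rate ratio a configured constant - the configuration used by the
bias/power simulation study and the coverage checks.

Determinism: one master seed; every stage draws from an independently
spawned substream, so adding a stage never perturbs earlier draws.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .records import CohortTable

__all__ = [
    "SimulationConfig",
    "ConfigError",
    "CalibrationError",
    "simulate_cohort",
    "calibrate_thresholds",
    "placebo_config",
    "expected_marginals",
]


class ConfigError(ValueError):
    """Invalid generative parameterization."""


class CalibrationError(ValueError):
    """Threshold calibration impossible (degenerate or crossing quantiles)."""


@dataclass
class SimulationConfig:
    """Full generative parameterization of the synthetic screening program.

    Defaults emulate the study conditions of a large multicenter German
    screening implementation: ~547 reader sets averaging ~844 exams,
    crude detection near 6.2/1,000, recall near 42/1,000, a 60% normal
    triage target and 1.5% safety-net target, and adoption behavior
    producing an AI-group share near 56% with a higher normal-tag
    fraction in the AI group than in the control group.
    """

    n_women: int = 200_000
    # --- cohort structure -------------------------------------------------
    n_reader_sets: int = 547
    n_readers: int = 119
    volume_mean: float = 844.0      #: target mean exams per reader set (shape only)
    volume_sigma: float = 1.2       #: log-normal sigma of reader-set volumes
    volume_max: float = 9000.0      #: truncation of the volume distribution
    p_supervised: float = 0.05
    # --- covariates -------------------------------------------------------
    p_age_50_59: float = 0.438
    p_dense_young: float = 0.42     #: P(dense | age 50-59)
    p_dense_old: float = 0.28       #: P(dense | age 60-69)
    p_density_missing: float = 0.001
    p_first_round_young: float = 0.30
    p_first_round_old: float = 0.07
    # --- latent cancer ----------------------------------------------------
    p_cancer_base: float = 0.006714   #: screen-detectable prevalence, reference cell
    rr_age_60_69: float = 1.35
    rr_dense: float = 1.25
    rr_first_round: float = 1.40
    # --- AI score model ---------------------------------------------------
    score_noncancer: tuple = (2.0, 40.0)   #: Beta(a, b) for non-cancer exams
    score_cancer: tuple = (8.0, 3.0)       #: Beta(a, b) for cancer exams
    ai_miss_fraction: float = 0.03  #: cancers scored from the non-cancer family
    target_normal_rate: float = 0.60
    target_safetynet_rate: float = 0.015
    # --- viewer adoption (the selection mechanism) ------------------------
    adoption_mu: float = -0.7972      #: mean of per-reader-set log-odds alpha_k
    adoption_sigma: float = 1.5     #: s.d. of alpha_k across reader sets
    beta_normal: float = 0.3258       #: log-odds shift toward the AI viewer on normal tag
    # --- reading chain ----------------------------------------------------
    p_flag_cancer: float = 0.45     #: per-reader P(flag suspicious | cancer)
    p_flag_benign: float = 0.121365    #: per-reader P(flag suspicious | no cancer)
    normal_flag_ratio: float = 0.188056 #: benign flag-rate multiplier in the low-score (normal) region
    retention_cancer: float = 0.95  #: consensus -> recall, cancer
    retention_benign: float = 0.315815  #: consensus -> recall, benign
    p_biopsy_cancer: float = 0.97
    p_biopsy_benign: float = 0.110136
    p_detect_biopsy: float = 0.95   #: biopsy -> histological confirmation
    supervision_flag_rr: float = 1.10
    # --- AI intervention (mechanistic mode) -------------------------------
    p_safetynet_shown: float = 0.85
    p_safetynet_accept: float = 0.5087
    retention_sn_cancer: float = 0.95
    retention_sn_benign: float = 0.45
    normal_suppression: float = 0.388463  #: benign flag-rate multiplier, AI reader on normal tag
    # --- effect mode ------------------------------------------------------
    effect_mode: str = "mechanistic"   # "mechanistic" | "ratio"
    detection_ratio: float = 1.18      #: ratio mode: cancer-cascade multiplier, AI group
    recall_ratio: float = 0.975        #: ratio mode: benign-cascade multiplier, AI group
    placebo: bool = False
    # --- bookkeeping ------------------------------------------------------
    exclusion_missing: float = 0.001
    exclusion_cancelled: float = 0.001
    # class-conditional tumor attribute distributions
    p_invasiveness: tuple = (0.19, 0.79, 0.02)            # dcis, invasive, other
    p_stage_invasive: tuple = (0.642, 0.266, 0.024, 0.001, 0.035, 0.032)  # 1,2,3,4,X,missing
    p_grade: tuple = (0.226, 0.578, 0.127, 0.033, 0.036)  # 1,2,3,X,missing
    p_size: tuple = (0.360, 0.432, 0.203, 0.005)          # le10,10to20,gt20,missing

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        d = {k: (tuple(v) if isinstance(v, list) else v) for k, v in d.items()}
        return cls(**d)

    def validate(self) -> None:
        probs = [
            "p_supervised", "p_age_50_59", "p_dense_young", "p_dense_old",
            "p_density_missing", "p_first_round_young", "p_first_round_old",
            "p_cancer_base", "ai_miss_fraction", "target_normal_rate",
            "target_safetynet_rate", "p_flag_cancer", "p_flag_benign",
            "retention_cancer", "retention_benign", "p_biopsy_cancer",
            "p_biopsy_benign", "p_detect_biopsy", "p_safetynet_shown", "normal_flag_ratio",
            "p_safetynet_accept", "retention_sn_cancer", "retention_sn_benign",
            "exclusion_missing", "exclusion_cancelled",
        ]
        for name in probs:
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name}={v} is not a probability in [0, 1]")
        if self.n_women < 0:
            raise ConfigError("n_women must be >= 0")
        if self.n_reader_sets < 1 or self.n_readers < 2:
            raise ConfigError("need at least one reader set and two readers")
        if self.target_normal_rate + self.target_safetynet_rate > 1:
            raise ConfigError("normal and safety-net targets overlap")
        if self.effect_mode not in ("mechanistic", "ratio"):
            raise ConfigError(f"unknown effect_mode {self.effect_mode!r}")
        if self.detection_ratio < 0 or self.recall_ratio < 0:
            raise ConfigError("rate ratios must be nonnegative")
        if self.normal_suppression < 0:
            raise ConfigError("normal_suppression must be nonnegative")


def placebo_config(config: SimulationConfig) -> SimulationConfig:
    """Null all AI-effect parameters, preserving the adoption (bias) model.

    The safety-net acceptance probability and the normal-tag suppression
    are set to null effect, and the ratio-mode multipliers to 1; viewer
    adoption (including ``beta_normal``) is untouched, so the selection
    mechanism still operates while the true causal effect is zero.
    """
    return replace(
        config,
        placebo=True,
        p_safetynet_accept=0.0,
        normal_suppression=1.0,
        detection_ratio=1.0,
        recall_ratio=1.0,
    )


def calibrate_thresholds(scores, target_normal_rate: float,
                         target_safetynet_rate: float) -> tuple[float, float]:
    """Empirical-quantile calibration of the two AI decision thresholds.

    ``tau_normal`` is the ``target_normal_rate`` quantile (scores at or
    below it are tagged normal); ``tau_sn`` the upper
    ``target_safetynet_rate`` quantile (scores above it trigger the
    safety net).  The two regions must be disjoint.
    """
    s = np.asarray(scores, dtype=float)
    if s.size == 0:
        raise CalibrationError("no scores to calibrate on")
    if not (0 < target_normal_rate < 1 and 0 < target_safetynet_rate < 1):
        raise CalibrationError("targets must lie strictly inside (0, 1)")
    if target_normal_rate + target_safetynet_rate > 1:
        raise CalibrationError("target rates overlap")
    tau_normal = float(np.quantile(s, target_normal_rate))
    tau_sn = float(np.quantile(s, 1.0 - target_safetynet_rate))
    if not tau_normal < tau_sn:
        raise CalibrationError(
            f"degenerate calibration: tau_normal={tau_normal:.6g} >= tau_sn={tau_sn:.6g}")
    return tau_normal, tau_sn


# ---------------------------------------------------------------------------
# simulation


def _spawn_rngs(seed: int) -> dict[str, np.random.Generator]:
    names = ["structure", "covariates", "cancer", "scores", "adoption",
             "reading", "tumors", "exclusions"]
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _reader_sets(cfg: SimulationConfig, rng: np.random.Generator):
    """Volumes, member readers and adoption intercepts per reader set."""
    mu = np.log(cfg.volume_mean) - cfg.volume_sigma**2 / 2.0
    vol = rng.lognormal(mu, cfg.volume_sigma, size=cfg.n_reader_sets)
    vol = np.clip(vol, 1.0, cfg.volume_max)
    readers = np.empty((cfg.n_reader_sets, 2), dtype=np.int64)
    for k in range(cfg.n_reader_sets):
        readers[k] = rng.choice(cfg.n_readers, size=2, replace=False)
    alpha = rng.normal(cfg.adoption_mu, cfg.adoption_sigma, size=cfg.n_reader_sets)
    return vol, readers, alpha


def _draw_categorical(rng, p, n):
    p = np.asarray(p, dtype=float)
    return rng.choice(len(p), size=n, p=p / p.sum())


def simulate_cohort(config: SimulationConfig, seed: int) -> CohortTable:
    """Generate a cohort table satisfying every record-level invariant.

    Group assignment emerges from the per-reader adoption model; realized
    marginals converge to the configured targets as ``n_women`` grows
    (see :func:`expected_marginals` for the analytic composition).
    """
    cfg = config
    cfg.validate()
    n = cfg.n_women
    rngs = _spawn_rngs(seed)

    vol, set_readers, alpha = _reader_sets(cfg, rngs["structure"])

    if n == 0:
        df = _empty_frame()
        return CohortTable(df, provenance="simulated")

    # reader-set membership, proportional to volume
    p_set = vol / vol.sum()
    set_idx = rngs["structure"].choice(cfg.n_reader_sets, size=n, p=p_set)

    # covariates
    rc = rngs["covariates"]
    old = rc.random(n) >= cfg.p_age_50_59          # True: 60-69
    age = np.where(old, rc.integers(60, 70, size=n), rc.integers(50, 60, size=n))
    p_dense = np.where(old, cfg.p_dense_old, cfg.p_dense_young)
    dense = rc.random(n) < p_dense
    dens_missing = rc.random(n) < cfg.p_density_missing
    p_first = np.where(old, cfg.p_first_round_old, cfg.p_first_round_young)
    first = rc.random(n) < p_first
    supervised = rc.random(n) < cfg.p_supervised

    # latent cancer
    p_c = cfg.p_cancer_base * np.where(old, cfg.rr_age_60_69, 1.0)
    p_c = p_c * np.where(dense, cfg.rr_dense, 1.0) * np.where(first, cfg.rr_first_round, 1.0)
    cancer = rngs["cancer"].random(n) < np.clip(p_c, 0, 1)

    # AI scores and calibrated tags
    rs = rngs["scores"]
    a0, b0 = cfg.score_noncancer
    a1, b1 = cfg.score_cancer
    score = rs.beta(a0, b0, size=n)
    idx_c = np.flatnonzero(cancer)
    hit = rs.random(idx_c.size) >= cfg.ai_miss_fraction
    score[idx_c[hit]] = rs.beta(a1, b1, size=int(hit.sum()))
    tau_n, tau_sn = calibrate_thresholds(score, cfg.target_normal_rate,
                                         cfg.target_safetynet_rate)
    normal_tag = score <= tau_n
    triggered = score > tau_sn

    # per-reader viewer adoption: logit = alpha_k + beta_normal * normal_tag
    ra = rngs["adoption"]
    logit = alpha[set_idx] + cfg.beta_normal * normal_tag
    p_adopt = special.expit(logit)
    used1 = ra.random(n) < p_adopt
    used2 = ra.random(n) < p_adopt
    group_ai = used1 | used2

    # reading cascade
    rr = rngs["reading"]
    consensus, recall, biopsy, detected, shown, accepted = _reading_outcomes(
        cfg, rr, cancer, normal_tag, triggered, supervised, used1, used2, group_ai)

    # tumor attributes
    rt = rngs["tumors"]
    invasiveness = np.full(n, "none", dtype=object)
    stage = np.full(n, None, dtype=object)
    grade = np.full(n, None, dtype=object)
    size_class = np.full(n, None, dtype=object)
    det_idx = np.flatnonzero(detected)
    if det_idx.size:
        inv_codes = _draw_categorical(rt, cfg.p_invasiveness, det_idx.size)
        inv_tokens = np.array(["dcis", "invasive", "other"], dtype=object)
        invasiveness[det_idx] = inv_tokens[inv_codes]
        stage[det_idx[inv_codes == 0]] = "0"
        stage[det_idx[inv_codes == 2]] = "X"
        inv_i = det_idx[inv_codes == 1]
        st_tokens = np.array(["1", "2", "3", "4", "X", "missing"], dtype=object)
        stage[inv_i] = st_tokens[_draw_categorical(rt, cfg.p_stage_invasive, inv_i.size)]
        gr_tokens = np.array(["1", "2", "3", "X", "missing"], dtype=object)
        grade[inv_i] = gr_tokens[_draw_categorical(rt, cfg.p_grade, inv_i.size)]
        sz_tokens = np.array(["le10mm", "10to20mm", "gt20mm", "missing"], dtype=object)
        size_class[inv_i] = sz_tokens[_draw_categorical(rt, cfg.p_size, inv_i.size)]

    # administrative exclusions
    re_ = rngs["exclusions"]
    outcome_missing = re_.random(n) < cfg.exclusion_missing
    cancelled = re_.random(n) < cfg.exclusion_cancelled

    width = max(6, len(str(n)))
    df = pd.DataFrame({
        "woman_id": np.char.add("w", np.char.zfill(np.arange(n).astype(str), width)),
        "age_years": pd.array(age, dtype="Int64"),
        "density_class": np.where(dens_missing, "missing",
                                  np.where(dense, "dense", "nondense")).astype(object),
        "screening_round": np.where(first, "first", "followup").astype(object),
        "reader_set_id": np.char.add("rs", np.char.zfill(set_idx.astype(str), 3)).astype(object),
        "reader1_id": np.char.add("r", np.char.zfill(set_readers[set_idx, 0].astype(str), 3)).astype(object),
        "reader2_id": np.char.add("r", np.char.zfill(set_readers[set_idx, 1].astype(str), 3)).astype(object),
        "supervised": supervised.astype(np.int64),
        "reader1_used_ai": used1.astype(np.int64),
        "reader2_used_ai": used2.astype(np.int64),
        "study_group": np.where(group_ai, "ai", "control").astype(object),
        "ai_normal_tag": normal_tag.astype(np.int64),
        "safety_net_triggered": triggered.astype(np.int64),
        "safety_net_shown": pd.array(np.where(group_ai, shown.astype(float), np.nan), dtype="Int64"),
        "safety_net_accepted": pd.array(np.where(group_ai, accepted.astype(float), np.nan), dtype="Int64"),
        "consensus": consensus.astype(np.int64),
        "recall": recall.astype(np.int64),
        "biopsy": biopsy.astype(np.int64),
        "cancer_detected": detected.astype(np.int64),
        "invasiveness": invasiveness,
        "stage": pd.array(stage, dtype=object),
        "grade": pd.array(grade, dtype=object),
        "size_class": pd.array(size_class, dtype=object),
        "outcome_missing": outcome_missing.astype(np.int64),
        "cancelled": cancelled.astype(np.int64),
    })
    df["stage"] = df["stage"].where(df["stage"].notna(), pd.NA)
    df["grade"] = df["grade"].where(df["grade"].notna(), pd.NA)
    df["size_class"] = df["size_class"].where(df["size_class"].notna(), pd.NA)
    return CohortTable(df, provenance="simulated")


def _reading_outcomes(cfg, rng, cancer, normal_tag, triggered, supervised,
                      used1, used2, group_ai):
    """Vectorized consensus -> recall -> biopsy -> detection cascade."""
    n = cancer.size
    mech = cfg.effect_mode == "mechanistic"

    base = np.where(cancer, cfg.p_flag_cancer, cfg.p_flag_benign)
    # low-score (normal-region) exams draw fewer false flags from any
    # reader: the AI score and reader difficulty are correlated
    base = np.where(normal_tag & ~cancer, base * cfg.normal_flag_ratio, base)
    sup_mult = np.where(supervised, cfg.supervision_flag_rr, 1.0)

    def flag_prob(used):
        p = base * sup_mult
        if mech:
            suppress = used & normal_tag & ~cancer
            p = np.where(suppress, p * cfg.normal_suppression, p)
        return np.clip(p, 0.0, 1.0)

    f1 = rng.random(n) < flag_prob(used1)
    f2 = rng.random(n) < flag_prob(used2)
    any_flag = f1 | f2

    shown = np.zeros(n, dtype=bool)
    accepted = np.zeros(n, dtype=bool)
    if mech:
        eligible = triggered & group_ai & ~any_flag
        shown = eligible & (rng.random(n) < cfg.p_safetynet_shown)
        accepted = shown & (rng.random(n) < cfg.p_safetynet_accept)
    consensus = any_flag | accepted

    ret = np.where(accepted & ~any_flag,
                   np.where(cancer, cfg.retention_sn_cancer, cfg.retention_sn_benign),
                   np.where(cancer, cfg.retention_cancer, cfg.retention_benign))
    u_recall = rng.random(n)
    u_biopsy = rng.random(n)
    u_detect = rng.random(n)

    if mech:
        recall = consensus & (u_recall < ret)
        biopsy = recall & (u_biopsy < np.where(cancer, cfg.p_biopsy_cancer, cfg.p_biopsy_benign))
        detected = biopsy & cancer & (u_detect < cfg.p_detect_biopsy)
    else:
        # ratio mode: nested-uniform cascade scaled uniformly for AI-group exams
        q_flag = 1.0 - (1.0 - flag_prob(used1 & False)) * (1.0 - flag_prob(used2 & False))
        mult = np.where(group_ai,
                        np.where(cancer, cfg.detection_ratio, cfg.recall_ratio), 1.0)
        q_cons = np.clip(q_flag * mult, 0.0, 1.0)
        q_rec = q_cons * np.where(cancer, cfg.retention_cancer, cfg.retention_benign)
        q_bio = q_rec * np.where(cancer, cfg.p_biopsy_cancer, cfg.p_biopsy_benign)
        q_det = q_bio * np.where(cancer, cfg.p_detect_biopsy, 0.0)
        u = rng.random(n)
        consensus = u < q_cons
        recall = u < q_rec
        biopsy = u < q_bio
        detected = (u < q_det) & cancer
        shown[:] = False
        accepted[:] = False
    return consensus, recall, biopsy, detected, shown, accepted


def _empty_frame() -> pd.DataFrame:
    from .records import FIELDS
    cols = {}
    for f in FIELDS:
        if f.kind in ("int", "bool", "tribool"):
            cols[f.name] = pd.array([], dtype="Int64")
        else:
            cols[f.name] = pd.array([], dtype=object)
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# analytic composition of the configured Bernoulli chain


def _mixture_thresholds(cfg: SimulationConfig, prev: float) -> tuple[float, float]:
    """Population thresholds implied by the score mixture and target rates."""
    a0, b0 = cfg.score_noncancer
    a1, b1 = cfg.score_cancer
    m = cfg.ai_miss_fraction

    def F(t):
        f_c = (1 - m) * stats.beta.cdf(t, a1, b1) + m * stats.beta.cdf(t, a0, b0)
        return (1 - prev) * stats.beta.cdf(t, a0, b0) + prev * f_c

    tau_n = optimize.brentq(lambda t: F(t) - cfg.target_normal_rate, 1e-12, 1 - 1e-12)
    tau_sn = optimize.brentq(lambda t: F(t) - (1 - cfg.target_safetynet_rate), 1e-12, 1 - 1e-12)
    return tau_n, tau_sn


def expected_marginals(config: SimulationConfig, n_quad: int = 60) -> dict:
    """Closed-form composition of the configured generative chain.

    Integrates the per-reader-set adoption intercepts by Gauss-Hermite
    quadrature and enumerates the discrete states (cancer status, AI tag
    region, supervision, per-reader viewer usage), composing the cascade
    probabilities exactly as the generator draws them.

    Returns population values for the overall marginals (normal-tag,
    safety-net, consensus, recall, biopsy, detection rates), the AI-group
    share, crude per-group rates (confounded by the reading behavior),
    and the true causal detection/recall ratios in the overlap (ATO)
    population.
    """
    cfg = config
    cfg.validate()
    mech = cfg.effect_mode == "mechanistic"

    # marginal prevalence over covariate cells
    prev = 0.0
    for old, p_old in ((False, cfg.p_age_50_59), (True, 1 - cfg.p_age_50_59)):
        p_dense = cfg.p_dense_old if old else cfg.p_dense_young
        p_first = cfg.p_first_round_old if old else cfg.p_first_round_young
        for dense, p_d in ((True, p_dense), (False, 1 - p_dense)):
            for first, p_f in ((True, p_first), (False, 1 - p_first)):
                p_c = cfg.p_cancer_base
                p_c *= cfg.rr_age_60_69 if old else 1.0
                p_c *= cfg.rr_dense if dense else 1.0
                p_c *= cfg.rr_first_round if first else 1.0
                prev += p_old * p_d * p_f * min(p_c, 1.0)

    tau_n, tau_sn = _mixture_thresholds(cfg, prev)
    a0, b0 = cfg.score_noncancer
    a1, b1 = cfg.score_cancer
    m = cfg.ai_miss_fraction

    def region_probs(is_cancer: bool) -> dict[str, float]:
        if is_cancer:
            cdf = lambda t: (1 - m) * stats.beta.cdf(t, a1, b1) + m * stats.beta.cdf(t, a0, b0)
        else:
            cdf = lambda t: stats.beta.cdf(t, a0, b0)
        pn = cdf(tau_n)
        ps = 1 - cdf(tau_sn)
        return {"normal": pn, "mid": 1 - pn - ps, "sn": ps}

    # Gauss-Hermite nodes for alpha ~ N(mu, sigma^2)
    gh_x, gh_w = np.polynomial.hermite_e.hermegauss(n_quad)
    alpha = cfg.adoption_mu + cfg.adoption_sigma * gh_x
    w_alpha = gh_w / gh_w.sum()

    # accumulators
    tot = {k: 0.0 for k in ("normal", "sn", "consensus", "recall", "biopsy",
                            "detection", "group_ai")}
    grp = {g: {k: 0.0 for k in ("p", "consensus", "recall", "biopsy", "detection",
                                "normal")} for g in ("ai", "control")}
    # ATO accumulators per (alpha node, tag): potential-outcome style group rates
    n_tags = 3
    tags = ("normal", "mid", "sn")
    num = {g: {k: np.zeros((n_quad, n_tags))
               for k in ("recall", "detection", "recall_auto", "detection_auto")}
           for g in ("ai", "control")}
    den = {g: np.zeros((n_quad, n_tags)) for g in ("ai", "control")}
    p_state = np.zeros((n_quad, n_tags))

    for c, p_cancer in ((True, prev), (False, 1 - prev)):
        rp = region_probs(c)
        for ti, tag in enumerate(tags):
            p_tag = rp[tag]
            if p_tag <= 0:
                continue
            p_adopt = special.expit(alpha + cfg.beta_normal * (tag == "normal"))
            uconfigs = (((0, 0), (1 - p_adopt) ** 2),
                        ((1, 0), p_adopt * (1 - p_adopt)),
                        ((0, 1), (1 - p_adopt) * p_adopt),
                        ((1, 1), p_adopt ** 2))
            for sup, p_sup in ((True, cfg.p_supervised), (False, 1 - cfg.p_supervised)):
                base = cfg.p_flag_cancer if c else cfg.p_flag_benign
                if not c and tag == "normal":
                    base *= cfg.normal_flag_ratio
                base *= cfg.supervision_flag_rr if sup else 1.0
                for (u1, u2), p_u in uconfigs:
                    g_ai = (u1 + u2) > 0
                    pf = []
                    for u in (u1, u2):
                        p = base
                        if mech and u and tag == "normal" and not c:
                            p *= cfg.normal_suppression
                        pf.append(min(p, 1.0))
                    q_noflag = (1 - pf[0]) * (1 - pf[1])
                    q_any = 1 - q_noflag
                    if mech:
                        p_accept = (q_noflag * cfg.p_safetynet_shown * cfg.p_safetynet_accept
                                    if (tag == "sn" and g_ai) else 0.0)
                        cons = q_any + p_accept
                        ret = cfg.retention_cancer if c else cfg.retention_benign
                        ret_sn = cfg.retention_sn_cancer if c else cfg.retention_sn_benign
                        rec = q_any * ret + p_accept * ret_sn
                    else:
                        mult = ((cfg.detection_ratio if c else cfg.recall_ratio)
                                if g_ai else 1.0)
                        q0 = 1 - (1 - min(base, 1.0)) ** 2
                        cons = min(q0 * mult, 1.0)
                        ret = cfg.retention_cancer if c else cfg.retention_benign
                        rec = cons * ret
                    bio = rec * (cfg.p_biopsy_cancer if c else cfg.p_biopsy_benign)
                    det = bio * (cfg.p_detect_biopsy if c else 0.0)

                    w = p_cancer * p_tag * p_sup * p_u * w_alpha  # vector over nodes
                    tot["normal"] += float(np.sum(w)) * (tag == "normal")
                    tot["sn"] += float(np.sum(w)) * (tag == "sn")
                    tot["consensus"] += float(np.sum(w * cons)) if np.ndim(cons) else float(np.sum(w)) * cons
                    tot["recall"] += float(np.sum(w * rec)) if np.ndim(rec) else float(np.sum(w)) * rec
                    tot["biopsy"] += float(np.sum(w * bio)) if np.ndim(bio) else float(np.sum(w)) * bio
                    tot["detection"] += float(np.sum(w * det)) if np.ndim(det) else float(np.sum(w)) * det
                    tot["group_ai"] += float(np.sum(w)) * g_ai

                    gname = "ai" if g_ai else "control"
                    grp[gname]["p"] += float(np.sum(w))
                    for key, val in (("consensus", cons), ("recall", rec),
                                     ("biopsy", bio), ("detection", det)):
                        grp[gname][key] += float(np.sum(w * val)) if np.ndim(val) else float(np.sum(w)) * val
                    grp[gname]["normal"] += float(np.sum(w)) * (tag == "normal")

                    den[gname][:, ti] += w
                    # automation scenario: normal-tagged AI-group exams are
                    # auto-classified normal (outcome chain zeroed)
                    auto_zero = g_ai and tag == "normal"
                    for key, val in (("recall", rec), ("detection", det),
                                     ("recall_auto", 0.0 if auto_zero else rec),
                                     ("detection_auto", 0.0 if auto_zero else det)):
                        num[gname][key][:, ti] += w * val
                    p_state[:, ti] += w

    out = {
        "prevalence": prev,
        "tau_normal": tau_n,
        "tau_safetynet": tau_sn,
        "normal_rate": tot["normal"],
        "safetynet_rate": tot["sn"],
        "consensus_rate": tot["consensus"],
        "recall_rate": tot["recall"],
        "biopsy_rate": tot["biopsy"],
        "detection_rate": tot["detection"],
        "p_ai_group": tot["group_ai"],
    }
    for g in ("ai", "control"):
        pg = grp[g]["p"]
        for key in ("consensus", "recall", "biopsy", "detection", "normal"):
            out[f"{g}_{key}_rate"] = grp[g][key] / pg if pg > 0 else np.nan

    # true causal ratios in the overlap population
    e = den["ai"] / np.maximum(den["ai"] + den["control"], 1e-300)
    w_ato = p_state * e * (1 - e)
    for key in ("detection", "recall", "detection_auto", "recall_auto"):
        mu1 = num["ai"][key] / np.maximum(den["ai"], 1e-300)
        mu0 = num["control"][key] / np.maximum(den["control"], 1e-300)
        m1 = float(np.sum(w_ato * mu1) / np.sum(w_ato))
        m0 = float(np.sum(w_ato * mu0) / np.sum(w_ato))
        out[f"ato_{key}_mu1"] = m1
        out[f"ato_{key}_mu0"] = m0
        out[f"ato_{key}_ratio"] = m1 / m0 if m0 > 0 else np.nan
    # the automation comparison keeps the untouched control outcomes
    for key in ("detection", "recall"):
        m1 = out[f"ato_{key}_auto_mu1"]
        m0 = out[f"ato_{key}_mu0"]
        out[f"ato_{key}_automation_ratio"] = m1 / m0 if m0 > 0 else np.nan
    return out
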