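"""Robustness battery and the triage-automation scenario.

Every analysis here re-runs the main overlap-weighted pipeline under a
perturbation of the data or the model: resampling (bootstrap, 80%
subsets), alternative confounder parameterizations (individual readers
instead of reader sets), alternative adjustment (stratification,
trimmed inverse-propensity weighting), a placebo construction that
provably preserves the confounding structure while nulling any causal
effect, and the fictitious automation scenario in which AI-normal-
tagged examinations are never read by radiologists.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import CohortTable
from .estimation import (EffectEstimate, EstimationError, OUTCOME_COLUMNS,
                         analyze_endpoint, _zvec, DEFAULT_COVARIATES)

__all__ = [
    "SensitivityResult",
    "bootstrap_analysis",
    "subsample_analysis",
    "reader_level_analysis",
    "stratified_analysis",
    "placebo_permutation",
    "automation_scenario",
]


@dataclass
class SensitivityResult:
    """Replicate-level estimates with percentile aggregation."""

    analysis: str
    outcome: str
    replicates: list = field(default_factory=list)   # per-replicate pct_diff
    mean_pct: float = float("nan")
    ci_pct: tuple = (float("nan"), float("nan"))
    n_failed: int = 0
    detail: dict = field(default_factory=dict)

    def aggregate(self) -> "SensitivityResult":
        vals = np.asarray([r for r in self.replicates if np.isfinite(r)], dtype=float)
        if len(vals):
            self.mean_pct = float(vals.mean())
            self.ci_pct = tuple(np.percentile(vals, [2.5, 97.5]))
        return self


def _resample_run(table: CohortTable, outcome: str, covariates, scheme: str,
                  index_draw, B: int, tag: str) -> SensitivityResult:
    res = SensitivityResult(analysis=tag, outcome=outcome)
    df = table.df
    for b in range(B):
        idx = index_draw(b)
        sub = CohortTable(df.iloc[idx].reset_index(drop=True), table.provenance)
        try:
            est, _ = analyze_endpoint(sub, outcome, covariates, scheme)
            res.replicates.append(est.pct_diff)
        except (EstimationError, Exception):
            res.n_failed += 1
    return res.aggregate()


def bootstrap_analysis(table: CohortTable, outcome: str = "detection",
                       B: int = 1000, seed: int | None = None,
                       covariates=DEFAULT_COVARIATES,
                       scheme: str = "overlap") -> SensitivityResult:
    """Resample women with replacement, refitting PS and weights per
    replicate; reports the mean percentage difference and percentile CI."""
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(table.df)
    return _resample_run(table, outcome, covariates, scheme,
                         lambda b: rng.integers(0, n, size=n), B, "bootstrap")


def subsample_analysis(table: CohortTable, outcome: str = "detection",
                       fraction: float = 0.8, B: int = 1000,
                       seed: int | None = None,
                       covariates=DEFAULT_COVARIATES,
                       scheme: str = "overlap") -> SensitivityResult:
    """Without-replacement random subsets of the stated fraction."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    n = len(table.df)
    k = int(round(fraction * n))
    res = _resample_run(table, outcome, covariates, scheme,
                        lambda b: rng.choice(n, size=k, replace=False), B,
                        f"subsample{fraction:g}")
    res.detail["fraction"] = fraction
    return res


def reader_level_analysis(table: CohortTable, outcome: str = "detection",
                          scheme: str = "overlap"):
    """Adjust for each individual reader instead of the reader set.

    The PS design holds one indicator per reader; a record activates
    both of its readers' indicators, plus the AI prediction.
    """
    return analyze_endpoint(table, outcome,
                            covariates=("readers", "ai_normal_tag"),
                            scheme=scheme)


def stratified_analysis(table: CohortTable, outcome: str = "detection",
                        min_n: int = 0, *, n_boot: int = 200,
                        seed: int | None = None) -> EffectEstimate:
    """Stratification on reader set x AI prediction as the adjustment.

    Keeps strata with at least ``min_n`` records in each study group;
    within-stratum group rates are combined across strata weighted by
    stratum size.  The CI comes from a stratified (within-stratum)
    bootstrap of the woman-level data.
    """
    if min_n < 0:
        raise ValueError("min_n must be >= 0")
    df = table.df
    ycol = OUTCOME_COLUMNS[outcome]
    z = _zvec(table)
    y = df[ycol].to_numpy(float)
    strata = pd.factorize(df["reader_set_id"].astype(str) + "\x1f"
                          + df["ai_normal_tag"].astype(str))[0]

    def estimate(yv, zv, sv) -> tuple[float, float] | None:
        n1 = np.bincount(sv, weights=zv)
        n0 = np.bincount(sv, weights=1 - zv)
        keep = (n1 >= max(min_n, 1)) & (n0 >= max(min_n, 1))
        if not keep.any():
            return None
        e1 = np.bincount(sv, weights=zv * yv)
        e0 = np.bincount(sv, weights=(1 - zv) * yv)
        size = (n1 + n0)[keep]
        mu1 = np.sum(size * (e1[keep] / n1[keep])) / size.sum()
        mu0 = np.sum(size * (e0[keep] / n0[keep])) / size.sum()
        return mu1, mu0

    point = estimate(y, z, strata)
    if point is None:
        raise EstimationError(f"no stratum has >= {min_n} records per group")
    mu1, mu0 = point
    rng = np.random.default_rng(seed)
    n_strata = int(strata.max()) + 1
    order = np.argsort(strata, kind="stable")
    bounds = np.searchsorted(strata[order], np.arange(n_strata + 1))
    boots = []
    for _ in range(n_boot):
        # stratified resample: draw with replacement within each stratum
        parts = [order[rng.integers(bounds[s], bounds[s + 1], size=bounds[s + 1] - bounds[s])]
                 for s in range(n_strata) if bounds[s + 1] > bounds[s]]
        idx = np.concatenate(parts)
        est = estimate(y[idx], z[idx], strata[idx])
        if est is not None and est[1] > 0:
            boots.append(100.0 * (est[0] / est[1] - 1.0))
    pct = 100.0 * (mu1 / mu0 - 1.0) if mu0 > 0 else float("nan")
    ci = tuple(np.percentile(boots, [2.5, 97.5])) if boots else (np.nan, np.nan)
    cov = np.zeros((2, 2))
    out = EffectEstimate(outcome=outcome, mu1=mu1, mu0=mu0,
                         diff=(mu1 - mu0) * 1000.0, pct_diff=pct,
                         ci_diff=(np.nan, np.nan), ci_pct=ci, cov=cov,
                         variance_method=f"stratified_bootstrap(min_n={min_n})",
                         n1=int(z.sum()), n0=int((1 - z).sum()))
    return out


def placebo_permutation(table: CohortTable, seed: int | None = None,
                        outcome: str = "detection",
                        covariates=DEFAULT_COVARIATES,
                        scheme: str = "overlap"):
    """Permute group labels within reader-set x AI-prediction strata.

    The permutation preserves the propensity structure (stratum-wise
    group frequencies are unchanged, so the PS fit is identical) while
    destroying any causal link between group and outcome; the expected
    percentage difference is zero.
    """
    df = table.df.copy()
    rng = np.random.default_rng(seed)
    strata = pd.factorize(df["reader_set_id"].astype(str) + "\x1f"
                          + df["ai_normal_tag"].astype(str))[0]
    grp = df["study_group"].to_numpy(object).copy()
    order = np.argsort(strata, kind="stable")
    sorted_strata = strata[order]
    starts = np.flatnonzero(np.diff(sorted_strata, prepend=-1))
    for i, lo in enumerate(starts):
        hi = starts[i + 1] if i + 1 < len(starts) else len(order)
        idx = order[lo:hi]
        grp[idx] = grp[idx[rng.permutation(hi - lo)]]
    df["study_group"] = grp
    # viewer flags no longer meaningful after permutation; keep group only
    permuted = CohortTable(df, table.provenance)
    return analyze_endpoint(permuted, outcome, covariates, scheme)


def automation_scenario(table: CohortTable) -> tuple[CohortTable, float]:
    """Fictitious triage automation: AI-normal-tagged examinations in the
    AI group are never read, receiving the final classification normal.

    Consensus, recall, biopsy and detection are set to 0 for AI-group
    records with the normal tag; control records are untouched.  The
    returned workload fraction is the overall share of records carrying
    the normal tag (the double-reading volume saved if normal-tagged
    examinations were not read).
    """
    df = table.df.copy()
    tag = df["ai_normal_tag"].astype(bool).to_numpy()
    ai = (df["study_group"].to_numpy(object) == "ai")
    affected = tag & ai
    for col in ("consensus", "recall", "biopsy", "cancer_detected"):
        vals = df[col].to_numpy().copy()
        vals[affected] = 0
        df[col] = vals
    inv = df["invasiveness"].to_numpy(object).copy()
    inv[affected] = "none"
    df["invasiveness"] = inv
    for col in ("stage", "grade", "size_class"):
        df[col] = df[col].where(~affected, pd.NA)
    workload_fraction = float(tag.mean())
    return CohortTable(df, table.provenance, table.schema_version,
                       table.extra_columns), workload_fraction
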