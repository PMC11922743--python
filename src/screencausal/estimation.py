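"""Weighted outcome estimation with M-estimation sandwich inference.

The analysis model is deliberately simple: a weighted quasi-binomial
regression of each binary endpoint on the study-group indicator alone,
with confounding handled entirely by the propensity weights.  Because
the outcome model is saturated in the group, the model-based group
rates equal the weighted group means exactly; the machinery here
therefore computes weighted means and derives the covariance of
(mu_ai, mu_control) from stacked estimating equations that include the
propensity-score equations, so the variance accounts for the estimated
weights (empirical sandwich A^-1 B A^-T).

Relative (percentage) differences rho = 100 (mu1/mu0 - 1) get their
confidence interval from the delta method on log(mu1/mu0), back-
transformed, giving the asymmetric ratio-scale intervals typical of
screening-rate comparisons.  Noninferiority uses a +/-10% relative
margin with sequential superiority testing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .records import CohortTable
from .weighting import (PropensityFit, WeightScheme, fit_propensity,
                        ipw_weights_trimmed, overlap_weights, unweighted,
                        DEFAULT_COVARIATES, _aggregate)

__all__ = [
    "EstimationError",
    "EffectEstimate",
    "NoninferiorityDecision",
    "OUTCOME_COLUMNS",
    "weighted_rates",
    "sandwich_covariance",
    "effect_from_rates",
    "noninferiority_decision",
    "analyze_endpoint",
    "model_ppv",
    "subgroup_analysis",
    "category_decomposition",
    "make_scheme",
    "age_band",
]

Z975 = float(stats.norm.ppf(0.975))

OUTCOME_COLUMNS = {
    "detection": "cancer_detected",
    "recall": "recall",
    "consensus": "consensus",
    "biopsy": "biopsy",
}

#: endpoint direction for the noninferiority margin
HIGHER_IS_BETTER = {"detection": True, "recall": False, "consensus": False,
                    "biopsy": False}


class EstimationError(RuntimeError):
    pass


@dataclass
class EffectEstimate:
    outcome: str
    mu1: float                  # model-based AI-group rate
    mu0: float                  # model-based control-group rate
    diff: float                 # mu1 - mu0 (on the `per` scale)
    pct_diff: float             # 100 (mu1/mu0 - 1); NaN when mu0 = 0
    ci_diff: tuple
    ci_pct: tuple
    cov: np.ndarray             # 2x2 covariance of (mu1, mu0)
    per: float = 1000.0
    dispersion: float = float("nan")
    variance_method: str = "sandwich_stacked"
    n1: int = 0
    n0: int = 0

    @property
    def pct_defined(self) -> bool:
        return np.isfinite(self.pct_diff)

    def summary_row(self) -> dict:
        return {
            "outcome": self.outcome,
            "mu_ai": self.mu1 * self.per, "mu_control": self.mu0 * self.per,
            "abs_diff": self.diff,
            "abs_ci_low": self.ci_diff[0], "abs_ci_high": self.ci_diff[1],
            "pct_diff": self.pct_diff,
            "pct_ci_low": self.ci_pct[0], "pct_ci_high": self.ci_pct[1],
            "variance": self.variance_method, "n_ai": self.n1, "n_control": self.n0,
        }


@dataclass
class NoninferiorityDecision:
    endpoint: str
    higher_is_better: bool
    margin_pct: float
    ci_pct: tuple
    verdict: str  # "not_noninferior" | "noninferior" | "superior"

    @property
    def noninferior(self) -> bool:
        return self.verdict in ("noninferior", "superior")


def _zvec(table_or_z) -> np.ndarray:
    if isinstance(table_or_z, CohortTable):
        g = table_or_z.df["study_group"].to_numpy(object)
        return (g == "ai").astype(float)
    z = np.asarray(table_or_z)
    if z.dtype == object or z.dtype.kind in "US":
        return ((z == "ai") | (z == 1)).astype(float)
    return z.astype(float)


def weighted_rates(y, z, w) -> tuple[float, float]:
    """Weighted group means: the fitted rates of the weighted
    quasi-binomial group-only regression (saturated model)."""
    y = np.asarray(y, dtype=float)
    z = _zvec(z)
    w = np.asarray(w, dtype=float)
    out = []
    for g in (1.0, 0.0):
        m = z == g
        s = w[m].sum()
        if s <= 0:
            raise EstimationError(f"zero total weight in group {'ai' if g else 'control'}")
        out.append(float(np.dot(w[m], y[m]) / s))
    return out[0], out[1]


def _quasibinomial_dispersion(y, z, w, mu1, mu0) -> float:
    mu = np.where(_zvec(z) == 1, mu1, mu0)
    denom = mu * (1 - mu)
    ok = denom > 0
    if ok.sum() <= 2:
        return float("nan")
    x2 = np.sum(np.asarray(w)[ok] * (np.asarray(y, float)[ok] - mu[ok])**2 / denom[ok])
    return float(x2 / (ok.sum() - 2))


def sandwich_covariance(table: CohortTable, fit: PropensityFit,
                        scheme: WeightScheme, y, *,
                        ps: str = "stacked") -> np.ndarray:
    """Covariance of (mu1, mu0) from stacked estimating equations.

    The stacked system contains the propensity-score logistic score
    equations and the two weighted moment equations for the group
    rates; ``ps="fixed"`` treats the propensity (hence the weights) as
    known and keeps only the moment equations.
    """
    df = table.df
    y = np.asarray(y, dtype=float)
    z = _zvec(table)
    e = fit.e
    w = scheme.w
    mu1, mu0 = weighted_rates(y, z, w)

    a1 = np.sum(z * w)
    a0 = np.sum((1 - z) * w)
    psi1 = z * w * (y - mu1)
    psi0 = (1 - z) * w * (y - mu0)

    if ps == "fixed":
        b11 = np.sum(psi1**2)
        b00 = np.sum(psi0**2)
        b10 = np.sum(psi1 * psi0)  # zero: groups disjoint
        v = np.array([[b11 / a1**2, b10 / (a1 * a0)],
                      [b10 / (a1 * a0), b00 / a0**2]])
        return v

    if ps != "stacked":
        raise ValueError(f"unknown ps variant {ps!r}")

    # Aggregate to (covariate pattern, z, y) triples: every estimating
    # function is constant within a triple, so the stacked system is
    # assembled on a few thousand cells regardless of cohort size.
    codes, x_cells, _, _ = _aggregate(df, fit.design, z)
    yb = (y > 0).astype(np.int64)
    tri = codes * 4 + 2 * (z > 0).astype(np.int64) + yb
    uniq, inv_first, counts = np.unique(tri, return_index=True, return_counts=True)
    cc = uniq // 4
    cz = ((uniq % 4) // 2).astype(float)
    cy = (uniq % 2).astype(float)
    ce = fit.e[inv_first]
    cw = scheme.w[inv_first]
    cexcl = scheme.excluded[inv_first]

    xd = np.hstack([np.ones((len(cc), 1)), x_cells[cc]])
    p = xd.shape[1]

    # dw/deta per cell for each scheme
    if scheme.scheme == "overlap":
        dw = np.where(cz == 1, -ce * (1 - ce), ce * (1 - ce))
    elif scheme.scheme.startswith("ipw_trim"):
        dw = np.where(cz == 1, -(1 - ce) / ce, ce / (1 - ce))
        dw = np.where(cexcl, 0.0, dw)
    elif scheme.scheme == "unweighted":
        dw = np.zeros(len(cc))
    else:
        raise ValueError(f"unsupported scheme {scheme.scheme!r}")

    # A = -sum of derivative of psi wrt theta, theta = (beta, mu1, mu0)
    wts = counts * ce * (1 - ce)
    a_bb = (xd * wts[:, None]).T @ xd
    a_1b = -(counts * cz * (cy - mu1) * dw) @ xd
    a_0b = -(counts * (1 - cz) * (cy - mu0) * dw) @ xd

    dim = p + 2
    a = np.zeros((dim, dim))
    a[:p, :p] = a_bb
    a[p, :p] = a_1b
    a[p + 1, :p] = a_0b
    a[p, p] = a1
    a[p + 1, p + 1] = a0

    psi_b = xd * (cz - ce)[:, None]
    cpsi1 = cz * cw * (cy - mu1)
    cpsi0 = (1 - cz) * cw * (cy - mu0)
    psi = np.hstack([psi_b, cpsi1[:, None], cpsi0[:, None]])
    b = (psi * counts[:, None]).T @ psi

    try:
        ainv_b = np.linalg.solve(a, b)
        v = np.linalg.solve(a, ainv_b.T).T
    except np.linalg.LinAlgError:
        # redundant design directions (e.g., constant indicators): use the
        # generalized inverse, standard M-estimation practice
        ainv = np.linalg.pinv(a)
        v = ainv @ b @ ainv.T
    out = v[p:, p:]
    if not np.all(np.isfinite(out)):
        raise EstimationError(
            f"non-finite sandwich covariance (cond A = {np.linalg.cond(a):.3g})")
    return out


def effect_from_rates(mu1: float, mu0: float, cov: np.ndarray,
                      per: float = 1000.0, outcome: str = "",
                      variance_method: str = "sandwich_stacked",
                      n1: int = 0, n0: int = 0) -> EffectEstimate:
    """Absolute and percentage differences with normal-theory CIs.

    The percentage-difference CI comes from the delta method on
    log(mu1/mu0), back-transformed; it is flagged undefined (NaN) when
    mu0 = 0.
    """
    cov = np.asarray(cov, dtype=float)
    v11, v00, v01 = cov[0, 0], cov[1, 1], cov[0, 1]
    if v11 < 0 or v00 < 0:
        raise EstimationError("negative variance")
    diff = mu1 - mu0
    se_d = np.sqrt(max(v11 + v00 - 2 * v01, 0.0))
    ci_diff = ((diff - Z975 * se_d) * per, (diff + Z975 * se_d) * per)
    if mu0 > 0 and mu1 > 0:
        lr = np.log(mu1 / mu0)
        se_lr = np.sqrt(max(v11 / mu1**2 + v00 / mu0**2 - 2 * v01 / (mu1 * mu0), 0.0))
        pct = 100.0 * (mu1 / mu0 - 1.0)
        ci_pct = (100.0 * (np.exp(lr - Z975 * se_lr) - 1.0),
                  100.0 * (np.exp(lr + Z975 * se_lr) - 1.0))
    else:
        pct = float("nan")
        ci_pct = (float("nan"), float("nan"))
    return EffectEstimate(outcome=outcome, mu1=mu1, mu0=mu0,
                          diff=diff * per, pct_diff=pct,
                          ci_diff=ci_diff, ci_pct=ci_pct, cov=cov, per=per,
                          variance_method=variance_method, n1=n1, n0=n0)


def noninferiority_decision(ci_pct: tuple, higher_is_better: bool,
                            margin_pct: float = 10.0,
                            endpoint: str = "") -> NoninferiorityDecision:
    """Sequential noninferiority-then-superiority verdict on the relative CI.

    Higher-is-better endpoints (detection): noninferior iff the CI
    lower bound exceeds -margin; superior iff it exceeds 0.  Lower-is-
    better endpoints (recall): noninferior iff the upper bound is below
    +margin; superior iff below 0.
    """
    low, high = ci_pct
    if not (np.isfinite(low) and np.isfinite(high)):
        raise ValueError("confidence interval must be finite")
    if higher_is_better:
        if low > 0:
            verdict = "superior"
        elif low > -margin_pct:
            verdict = "noninferior"
        else:
            verdict = "not_noninferior"
    else:
        if high < 0:
            verdict = "superior"
        elif high < margin_pct:
            verdict = "noninferior"
        else:
            verdict = "not_noninferior"
    return NoninferiorityDecision(endpoint=endpoint,
                                  higher_is_better=higher_is_better,
                                  margin_pct=margin_pct, ci_pct=ci_pct,
                                  verdict=verdict)


def make_scheme(fit: PropensityFit, z, scheme: str = "overlap",
                trim_alpha: float = 0.05) -> WeightScheme:
    if scheme == "overlap":
        return overlap_weights(fit.e, z)
    if scheme == "ipw_trim":
        return ipw_weights_trimmed(fit.e, z, trim_alpha)
    if scheme == "unweighted":
        return unweighted(len(fit.e))
    raise ValueError(f"unknown scheme {scheme!r}")


def analyze_endpoint(table: CohortTable, outcome: str = "detection",
                     covariates=DEFAULT_COVARIATES, scheme: str = "overlap",
                     *, trim_alpha: float = 0.05, margin_pct: float = 10.0,
                     variance: str = "stacked",
                     fit: PropensityFit | None = None
                     ) -> tuple[EffectEstimate, NoninferiorityDecision]:
    """Full pipeline for one endpoint: PS fit -> weights -> rates ->
    sandwich -> effect -> noninferiority verdict."""
    if outcome not in OUTCOME_COLUMNS:
        raise ValueError(f"unsupported outcome {outcome!r}")
    y = table.df[OUTCOME_COLUMNS[outcome]].to_numpy(float)
    z = _zvec(table)
    if fit is None:
        fit = fit_propensity(table, covariates)
    ws = make_scheme(fit, z, scheme, trim_alpha)
    mu1, mu0 = weighted_rates(y, z, ws.w)
    cov = sandwich_covariance(table, fit, ws, y,
                              ps="stacked" if variance == "stacked" else "fixed")
    est = effect_from_rates(mu1, mu0, cov, outcome=outcome,
                            variance_method=f"sandwich_{variance}",
                            n1=int(z.sum()), n0=int((1 - z).sum()))
    est.dispersion = _quasibinomial_dispersion(y, z, ws.w, mu1, mu0)
    if est.pct_defined and np.all(np.isfinite(est.ci_pct)):
        dec = noninferiority_decision(est.ci_pct, HIGHER_IS_BETTER[outcome],
                                      margin_pct, endpoint=outcome)
    else:
        dec = None  # relative difference undefined (zero control rate)
    return est, dec


def model_ppv(table: CohortTable, denominator: str = "recall",
              covariates=DEFAULT_COVARIATES, scheme: str = "overlap",
              *, n_boot: int = 200, seed: int | None = None) -> dict:
    """Model-based PPV per group: rate(detection) / rate(denominator).

    The CI is a woman-level bootstrap that refits the propensity model
    per replicate, propagating both endpoints jointly (they share the
    weights).
    """
    if denominator not in ("recall", "biopsy"):
        raise ValueError("denominator must be 'recall' or 'biopsy'")
    rng = np.random.default_rng(seed)
    df = table.df

    def ppvs(t: CohortTable):
        fit = fit_propensity(t, covariates)
        z = _zvec(t)
        ws = make_scheme(fit, z, scheme)
        det1, det0 = weighted_rates(t.df["cancer_detected"].to_numpy(float), z, ws.w)
        den1, den0 = weighted_rates(t.df[OUTCOME_COLUMNS[denominator]].to_numpy(float),
                                    z, ws.w)
        p1 = 100.0 * det1 / den1 if den1 > 0 else float("nan")
        p0 = 100.0 * det0 / den0 if den0 > 0 else float("nan")
        return p1, p0

    p1, p0 = ppvs(table)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, len(df), size=len(df))
        try:
            boots.append(ppvs(CohortTable(df.iloc[idx].reset_index(drop=True),
                                          table.provenance)))
        except (EstimationError, Exception):
            continue
    boots = np.array(boots, dtype=float)
    out = {"ppv_ai": p1, "ppv_control": p0, "denominator": denominator,
           "n_boot": len(boots)}
    if len(boots):
        out["ci_ai"] = tuple(np.percentile(boots[:, 0], [2.5, 97.5]))
        out["ci_control"] = tuple(np.percentile(boots[:, 1], [2.5, 97.5]))
        d = boots[:, 0] - boots[:, 1]
        out["ppv_diff"] = p1 - p0
        out["ci_diff"] = tuple(np.percentile(d, [2.5, 97.5]))
    return out


def age_band(table: CohortTable) -> pd.Series:
    """Derive the 50-59 / 60-69 age bands used by the subgroup analyses."""
    age = table.df["age_years"]
    return pd.Series(np.where(age.isna(), "missing",
                              np.where(age.fillna(0) < 60, "50-59", "60-69")),
                     index=table.df.index, dtype=object)


def subgroup_analysis(table: CohortTable, subgroup, outcome: str = "detection",
                      covariates=DEFAULT_COVARIATES, scheme: str = "overlap",
                      *, refit_ps: bool = True, margin_pct: float = 10.0) -> dict:
    """Per-level endpoint analysis with the PS model refit within levels.

    ``subgroup`` is a column name ("screening_round", "density_class")
    or the string "age_band".  Levels in which only one study group is
    present are flagged NA (value None).
    """
    df = table.df
    levels_col = age_band(table) if subgroup == "age_band" else df[subgroup]
    out = {}
    full_fit = None if refit_ps else fit_propensity(table, covariates)
    for level in sorted(levels_col.dropna().unique()):
        mask = (levels_col == level).to_numpy()
        sub = CohortTable(df.loc[mask].reset_index(drop=True), table.provenance)
        groups = set(sub.df["study_group"])
        if groups != {"ai", "control"}:
            out[level] = None
            continue
        if refit_ps:
            est, dec = analyze_endpoint(sub, outcome, covariates, scheme,
                                        margin_pct=margin_pct)
        else:
            subfit = replace(full_fit, e=full_fit.predict(sub.df))
            est, dec = analyze_endpoint(sub, outcome, covariates, scheme,
                                        margin_pct=margin_pct, fit=subfit)
        out[level] = (est, dec)
    return out


CATEGORY_SPECS = {
    "invasiveness": ("invasiveness", ("dcis", "invasive", "other")),
    "stage": ("stage", ("0", "1", "2", "3", "4", "X", "missing")),
    "grade": ("grade", ("1", "2", "3", "X", "missing")),
    "size_class": ("size_class", ("le10mm", "10to20mm", "gt20mm", "missing")),
}


def category_decomposition(table: CohortTable, category: str = "invasiveness",
                           covariates=DEFAULT_COVARIATES,
                           scheme: str = "overlap",
                           fit: PropensityFit | None = None) -> dict:
    """Detection decomposed by tumor category under shared weights.

    Each category value becomes its own binary detection outcome; the
    per-category model-based rates sum exactly to the total detection
    rate (grade and size partition invasive detections only).
    """
    if category not in CATEGORY_SPECS:
        raise ValueError(f"unknown category column {category!r}")
    col, levels = CATEGORY_SPECS[category]
    df = table.df
    observed = set(df[col].dropna().unique()) - {"none"}
    bad = observed - set(levels)
    if bad:
        raise ValueError(f"unexpected {category} value(s): {sorted(bad)}")
    if fit is None:
        fit = fit_propensity(table, covariates)
    z = _zvec(table)
    ws = make_scheme(fit, z, scheme)
    det = df["cancer_detected"].to_numpy(float)
    out = {}
    for level in levels:
        y = (det * (df[col].to_numpy(object) == level)).astype(float)
        mu1, mu0 = weighted_rates(y, z, ws.w)
        cov = sandwich_covariance(table, fit, ws, y)
        out[level] = effect_from_rates(mu1, mu0, cov,
                                       outcome=f"detection[{category}={level}]",
                                       n1=int(z.sum()), n0=int((1 - z).sum()))
    return out
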