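"""Propensity-score fitting and weighting schemes.

The propensity model is a maximum-likelihood logistic regression of AI
group membership on the reader set (indicator-coded, largest set as
reference) and the AI prediction, optionally extended with age band,
screening round, breast density and supervision, or re-parameterized
with one indicator per individual reader (a record activates both of
its readers' indicators).

Records are aggregated to unique covariate patterns before fitting, so
the Newton iterations work on at most a few thousand cells regardless
of cohort size; fitted propensities are clipped away from {0, 1} (with a surfaced
count of extreme fits) when reader sets are completely separated
(some sets never or always used the AI viewer).  Records are never
dropped: under overlap weighting, separated records' influence
vanishes by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from .records import CohortTable

__all__ = [
    "PropensityFit",
    "WeightScheme",
    "FitError",
    "build_design",
    "fit_propensity",
    "overlap_weights",
    "ipw_weights_trimmed",
    "balance_table",
]

CLIP = 1e-9
DEFAULT_COVARIATES = ("reader_set_id", "ai_normal_tag")


class FitError(RuntimeError):
    """Propensity model failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass
class DesignInfo:
    """Frozen encoding of the covariate specification.

    ``columns`` are cohort columns; object-dtype columns are indicator
    coded against their highest-volume reference level.  The sentinel
    covariate name ``"readers"`` expands to one indicator per individual
    reader, activating both of a record's readers.
    """

    columns: tuple
    references: dict = field(default_factory=dict)   # col -> reference level
    levels: dict = field(default_factory=dict)       # col -> kept levels (order)
    readers: tuple = ()                              # reader ids (reader coding)
    names: tuple = ()                                # design column names

    @property
    def n_params(self) -> int:
        return 1 + len(self.names)


def _infer_design(df: pd.DataFrame, covariates) -> DesignInfo:
    info = DesignInfo(columns=tuple(covariates))
    names = []
    for col in covariates:
        if col == "readers":
            readers = sorted(set(df["reader1_id"]) | set(df["reader2_id"]))
            # largest-volume reader as reference
            counts = pd.concat([df["reader1_id"], df["reader2_id"]]).value_counts()
            ref = counts.idxmax()
            kept = tuple(r for r in readers if r != ref)
            info.readers = kept
            info.references[col] = ref
            names += [f"reader[{r}]" for r in kept]
        elif df[col].dtype == object or str(df[col].dtype) == "string":
            counts = df[col].value_counts()
            ref = counts.idxmax()
            kept = tuple(l for l in sorted(counts.index) if l != ref)
            info.references[col] = ref
            info.levels[col] = kept
            names += [f"{col}[{l}]" for l in kept]
        else:
            names.append(col)
    info.names = tuple(names)
    return info


def build_design(df: pd.DataFrame, info: DesignInfo) -> np.ndarray:
    """Dense design matrix (without intercept) for the given records."""
    blocks = []
    for col in info.columns:
        if col == "readers":
            idx = {r: i for i, r in enumerate(info.readers)}
            x = np.zeros((len(df), len(info.readers)))
            for rc in ("reader1_id", "reader2_id"):
                codes = df[rc].map(idx)
                ok = codes.notna().to_numpy()
                x[np.flatnonzero(ok), codes[ok].astype(int).to_numpy()] += 1.0
            blocks.append(x)
        elif col in info.levels:
            vals = df[col].to_numpy(object)
            x = np.column_stack([(vals == l).astype(float) for l in info.levels[col]]) \
                if info.levels[col] else np.zeros((len(df), 0))
            blocks.append(x)
        else:
            blocks.append(df[col].to_numpy(float)[:, None])
    return np.hstack(blocks) if blocks else np.zeros((len(df), 0))


@dataclass
class PropensityFit:
    design: DesignInfo
    coef: np.ndarray          # [intercept, design columns...]
    e: np.ndarray             # fitted propensity per record, clipped
    converged: bool
    n_clipped: int
    loglik: float
    n_iter: int
    firth: bool = False

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        """Reproduce fitted propensities from the coefficients."""
        x = build_design(df, self.design)
        eta = self.coef[0] + x @ self.coef[1:]
        return np.clip(special.expit(eta), CLIP, 1 - CLIP)


def _aggregate(df: pd.DataFrame, info: DesignInfo, z: np.ndarray):
    """Collapse records to unique covariate patterns (trials, events)."""
    keys = []
    for col in info.columns:
        if col == "readers":
            keys.append(df["reader1_id"].astype(str) + "|" + df["reader2_id"].astype(str))
        else:
            keys.append(df[col].astype(str))
    if keys:
        key = keys[0].str.cat(keys[1:], sep="\x1f") if len(keys) > 1 else keys[0]
        codes, uniques = pd.factorize(key)
    else:
        codes, uniques = np.zeros(len(df), dtype=int), np.array([""])
    m = len(uniques)
    trials = np.bincount(codes, minlength=m).astype(float)
    events = np.bincount(codes, weights=z, minlength=m)
    first = np.zeros(m, dtype=int)
    first[codes[::-1]] = np.arange(len(df) - 1, -1, -1)
    x_cells = build_design(df.iloc[first], info)
    return codes, x_cells, trials, events


def _newton_logistic(x, trials, events, *, tol=1e-8, max_iter=100, firth=False):
    m, p = x.shape
    xd = np.hstack([np.ones((m, 1)), x])
    beta = np.zeros(p + 1)
    beta[0] = special.logit(np.clip(events.sum() / trials.sum(), 1e-12, 1 - 1e-12))

    def loglik(b):
        eta = np.clip(xd @ b, -35, 35)
        return float(events @ eta - trials @ np.logaddexp(0.0, eta))

    ll = loglik(beta)
    for it in range(1, max_iter + 1):
        eta = np.clip(xd @ beta, -35, 35)
        mu = special.expit(eta)
        w = trials * mu * (1 - mu)
        score = xd.T @ (events - trials * mu)
        if firth:
            xw = xd * np.sqrt(w)[:, None]
            fisher = xw.T @ xw
            try:
                h = np.einsum("ij,ji->i", xw, np.linalg.solve(fisher, xw.T))
            except np.linalg.LinAlgError:
                h = np.einsum("ij,ji->i", xw, np.linalg.pinv(fisher) @ xw.T)
            score = xd.T @ (events - trials * mu + h * (0.5 - mu))
        fisher = (xd * w[:, None]).T @ xd
        fisher[np.diag_indices_from(fisher)] += 1e-10
        try:
            step = np.linalg.solve(fisher, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(fisher, score, rcond=None)[0]
        # step halving for stability
        new_ll, shrink = None, 1.0
        for _ in range(30):
            cand = beta + shrink * step
            new_ll = loglik(cand)
            if firth or new_ll >= ll - 1e-12:
                break
            shrink /= 2.0
        beta = beta + shrink * step
        prev, ll = ll, loglik(beta)
        denom = abs(prev) + 1e-12
        if abs(ll - prev) / denom < tol:
            # polish: drive the score itself toward zero so downstream
            # exact-balance identities hold to tight numerical tolerance;
            # steps are accepted only while the score norm improves
            def score_norm(b):
                mu = special.expit(np.clip(xd @ b, -35, 35))
                return np.max(np.abs(xd.T @ (events - trials * mu)))

            best = score_norm(beta)
            for extra in range(it + 1, min(it + 25, max_iter) + 1):
                if best < 1e-9 * trials.sum():
                    break
                eta = np.clip(xd @ beta, -35, 35)
                mu = special.expit(eta)
                score = xd.T @ (events - trials * mu)
                w = trials * mu * (1 - mu)
                fisher = (xd * w[:, None]).T @ xd
                fisher[np.diag_indices_from(fisher)] += 1e-10
                try:
                    step = np.linalg.solve(fisher, score)
                except np.linalg.LinAlgError:
                    step = np.linalg.lstsq(fisher, score, rcond=None)[0]
                cand, accepted = beta, False
                shrink = 1.0
                for _ in range(20):
                    trial = beta + shrink * step
                    if score_norm(trial) < best:
                        cand, accepted = trial, True
                        break
                    shrink /= 2.0
                if not accepted:
                    break
                beta = cand
                best = score_norm(beta)
            return beta, loglik(beta), True, it
    return beta, ll, False, max_iter


def fit_propensity(table: CohortTable, covariates=DEFAULT_COVARIATES, *,
                   interaction: bool = False, firth: bool = False,
                   tol: float = 1e-8, max_iter: int = 100) -> PropensityFit:
    """Maximum-likelihood logistic fit of P(group = ai | covariates).

    ``interaction=True`` adds the reader-set x AI-prediction interaction
    by fitting on the crossed pattern (saturated in the two covariates).
    Fitted values are clipped away from {0, 1}; the number of records
    with extreme fits is surfaced on the fit (separation warning count).
    """
    df = table.df
    if "study_group" not in df.columns:
        raise FitError("exposure column 'study_group' missing")
    z = (df["study_group"].to_numpy(object) == "ai").astype(float)
    covariates = list(covariates)
    work = df
    if interaction:
        crossed = df["reader_set_id"].astype(str) + "*" + df["ai_normal_tag"].astype(str)
        work = df.assign(_crossed=crossed.astype(object))
        covariates = ["_crossed"] + [c for c in covariates
                                     if c not in ("reader_set_id", "ai_normal_tag")]
    info = _infer_design(work, covariates)
    codes, x_cells, trials, events = _aggregate(work, info, z)
    beta, ll, converged, n_iter = _newton_logistic(
        x_cells, trials, events, tol=tol, max_iter=max_iter, firth=firth)
    if not converged:
        raise FitError(
            f"propensity model did not converge in {max_iter} iterations",
            diagnostics={"loglik": ll, "n_cells": len(trials),
                         "n_params": info.n_params})
    eta = np.clip(np.hstack([np.ones((len(trials), 1)), x_cells]) @ beta, -35, 35)
    e_cells = special.expit(eta)
    n_clipped = int(np.sum(trials[(e_cells < CLIP) | (e_cells > 1 - CLIP)]))
    e = np.clip(e_cells, CLIP, 1 - CLIP)[codes]
    return PropensityFit(design=info, coef=beta, e=e, converged=converged,
                         n_clipped=n_clipped, loglik=ll, n_iter=n_iter, firth=firth)


# ---------------------------------------------------------------------------
# weighting schemes


@dataclass
class WeightScheme:
    """Per-record weights with an exclusion mask."""

    scheme: str               # "overlap" | "ipw_trim(a)" | "unweighted"
    w: np.ndarray
    excluded: np.ndarray      # bool mask; excluded records have w = 0
    trim_alpha: float | None = None

    def effective_sample_size(self, z: np.ndarray) -> dict:
        out = {}
        for g, mask in (("ai", z == 1), ("control", z == 0)):
            w = self.w[mask]
            s = w.sum()
            out[g] = float(s**2 / np.sum(w**2)) if s > 0 else 0.0
        return out


def _check_ez(e, z):
    e = np.asarray(e, dtype=float)
    z = np.asarray(z)
    if z.dtype == object or z.dtype.kind in "US":
        z = ((z == "ai") | (z == 1)).astype(float)
    z = z.astype(float)
    if e.shape != z.shape:
        raise ValueError(f"length mismatch: e has {e.shape}, z has {z.shape}")
    if np.any((e <= 0) | (e >= 1)):
        raise ValueError("propensities must lie strictly inside (0, 1)")
    return e, z


def overlap_weights(e, z) -> WeightScheme:
    """ATO weights: 1 - e for AI-group records, e for controls; no exclusions.

    Under an exactly solved MLE logistic propensity model these weights
    balance every model covariate's mean exactly between the groups.
    """
    e, z = _check_ez(e, z)
    w = np.where(z == 1, 1 - e, e)
    return WeightScheme("overlap", w, np.zeros(len(w), dtype=bool))


def ipw_weights_trimmed(e, z, alpha: float = 0.0) -> WeightScheme:
    """Inverse-propensity weights with symmetric trimming at ``alpha``.

    Records with e outside [alpha, 1 - alpha] are excluded (weight 0);
    retained AI records get 1/e, controls 1/(1 - e).
    """
    if not 0 <= alpha < 0.5:
        raise ValueError("trimming threshold must lie in [0, 0.5)")
    e, z = _check_ez(e, z)
    excluded = (e < alpha) | (e > 1 - alpha)
    w = np.where(z == 1, 1 / e, 1 / (1 - e))
    w[excluded] = 0.0
    return WeightScheme(f"ipw_trim({alpha:g})", w, excluded, trim_alpha=alpha)


def unweighted(n: int) -> WeightScheme:
    return WeightScheme("unweighted", np.ones(n), np.zeros(n, dtype=bool))


def balance_table(table: CohortTable, fit: PropensityFit,
                  scheme: WeightScheme, n_bins: int = 20) -> dict:
    """Weighted/unweighted covariate balance and PS-distribution summaries.

    Returns per design column the group means (raw and weighted) and
    standardized differences (pooled raw SD denominator), plus weighted
    propensity histograms per group.
    """
    df = table.df
    z = (df["study_group"].to_numpy(object) == "ai").astype(float)
    x = build_design(df, fit.design)
    names = fit.design.names
    w = scheme.w
    rows = []
    for j, name in enumerate(names):
        col = x[:, j]
        m1, m0 = col[z == 1].mean(), col[z == 0].mean()
        sd = np.sqrt((col[z == 1].var(ddof=1) + col[z == 0].var(ddof=1)) / 2)
        w1, w0 = w[z == 1], w[z == 0]
        wm1 = np.average(col[z == 1], weights=w1) if w1.sum() > 0 else np.nan
        wm0 = np.average(col[z == 0], weights=w0) if w0.sum() > 0 else np.nan
        rows.append({
            "covariate": name, "mean_ai": m1, "mean_control": m0,
            "smd_unweighted": (m1 - m0) / sd if sd > 0 else 0.0,
            "wmean_ai": wm1, "wmean_control": wm0,
            "wdiff": wm1 - wm0,
            "smd_weighted": (wm1 - wm0) / sd if sd > 0 else 0.0,
        })
    bins = np.linspace(0, 1, n_bins + 1)
    hists = {}
    for g, mask in (("ai", z == 1), ("control", z == 0)):
        h, _ = np.histogram(fit.e[mask], bins=bins, weights=w[mask])
        tot = h.sum()
        hists[g] = h / tot if tot > 0 else h
    return {"covariates": pd.DataFrame(rows), "ps_bins": bins, "ps_hist": hists}
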