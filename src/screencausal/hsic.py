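"""Kernel-based independence testing (Hilbert-Schmidt independence criterion).

Marginal HSIC with a Gaussian kernel (median-heuristic bandwidth) for
continuous variables and a delta kernel for categorical ones; p-values
from a permutation null by default, with a moment-matched gamma
approximation as a fast option.  Conditional claims with discrete
conditioning sets are tested by a stratified HSIC whose per-stratum
statistics are summed and whose permutations act within strata.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .dag import CausalDAG, IndependenceClaim, implied_independences
from .records import CohortTable

__all__ = [
    "DegenerateInputError",
    "UnsupportedConditioningError",
    "hsic_statistic",
    "hsic_test",
    "stratified_hsic_test",
    "test_all_implications",
    "DEFAULT_NODE_COLUMNS",
]


class DegenerateInputError(ValueError):
    """Constant input vector: independence testing is undefined."""


class UnsupportedConditioningError(ValueError):
    """Conditioning set contains a continuous variable."""


def _as_column(v) -> np.ndarray:
    a = np.asarray(v)
    if a.ndim == 1:
        a = a[:, None]
    return a


def _is_categorical(a: np.ndarray, kind: str) -> bool:
    if kind == "categorical":
        return True
    if kind == "continuous":
        return False
    if a.dtype == object or a.dtype.kind in "USb":
        return True
    return np.unique(a).size <= 10  # low-cardinality numerics as discrete


def _gram(a: np.ndarray, kind: str) -> np.ndarray:
    """Gaussian (median-heuristic) or delta Gram matrix."""
    if _is_categorical(a, kind):
        codes = pd.factorize(a.ravel() if a.ndim > 1 else a)[0]
        if np.unique(codes).size < 2:
            raise DegenerateInputError("constant vector")
        return (codes[:, None] == codes[None, :]).astype(float)
    x = _as_column(a).astype(float)
    sq = np.sum(x * x, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (x @ x.T)
    np.maximum(d2, 0.0, out=d2)
    off = d2[np.triu_indices_from(d2, k=1)]
    med = np.median(off[off > 0]) if np.any(off > 0) else 0.0
    if med <= 0:
        raise DegenerateInputError("constant vector")
    return np.exp(-d2 / med)  # bandwidth: sigma^2 = median distance^2 / 2


def _center(k: np.ndarray) -> np.ndarray:
    k = k - k.mean(axis=0, keepdims=True)
    return k - k.mean(axis=1, keepdims=True)


def hsic_statistic(x, y, x_kind: str = "auto", y_kind: str = "auto") -> float:
    """Biased HSIC estimate, trace(KHLH)/n^2."""
    kx = _center(_gram(np.asarray(x), x_kind))
    ky = _center(_gram(np.asarray(y), y_kind))
    n = kx.shape[0]
    return float(np.sum(kx * ky) / n**2)


def _perm_pvalue(kc: np.ndarray, lc: np.ndarray, n_permutations: int,
                 rng: np.random.Generator) -> tuple[float, float]:
    n = kc.shape[0]
    obs = float(np.sum(kc * lc))
    count = 0
    for _ in range(n_permutations):
        p = rng.permutation(n)
        if float(np.sum(kc * lc[np.ix_(p, p)])) >= obs:
            count += 1
    return obs / n**2, (1.0 + count) / (n_permutations + 1.0)


def _gamma_pvalue(kx: np.ndarray, ky: np.ndarray) -> tuple[float, float]:
    """Moment-matched gamma null for m * HSIC_b."""
    m = kx.shape[0]
    kc, lc = _center(kx), _center(ky)
    test_stat = float(np.sum(kc * lc)) / m
    v = (kc * lc / 6.0) ** 2
    var_hsic = (v.sum() - np.trace(v)) / m / (m - 1)
    var_hsic = var_hsic * 72.0 * (m - 4) * (m - 5) / m / (m - 1) / (m - 2) / (m - 3)
    k0 = kx - np.diag(np.diag(kx))
    l0 = ky - np.diag(np.diag(ky))
    mu_x = k0.sum() / m / (m - 1)
    mu_y = l0.sum() / m / (m - 1)
    m_hsic = (1.0 + mu_x * mu_y - mu_x - mu_y) / m
    var_hsic = max(var_hsic, 1e-300)
    m_hsic = max(m_hsic, 1e-300)
    al = m_hsic**2 / var_hsic
    bet = var_hsic * m / m_hsic
    p = float(sps.gamma.sf(test_stat, al, scale=bet))
    return test_stat / m, p


def hsic_test(x, y, n_permutations: int = 1000, seed: int | None = None,
              method: str = "permutation", x_kind: str = "auto",
              y_kind: str = "auto") -> IndependenceClaim:
    """Test X _||_ Y; returns a claim carrying statistic and p-value.

    ``method="permutation"`` (default) uses ``n_permutations`` random
    relabelings; ``"gamma"`` uses the moment-matched gamma null.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape[0] != y.shape[0]:
        raise ValueError("x and y must have equal length")
    if x.shape[0] < 10:
        raise ValueError("need at least 10 observations")
    kx = _gram(x, x_kind)
    ky = _gram(y, y_kind)
    if method == "gamma":
        stat, p = _gamma_pvalue(kx, ky)
        nper = 0
    else:
        rng = np.random.default_rng(seed)
        stat, p = _perm_pvalue(_center(kx), _center(ky), n_permutations, rng)
        nper = n_permutations
    return IndependenceClaim(x="x", y="y", statistic=stat, p_value=p,
                             n_permutations=nper)


def stratified_hsic_test(x, y, strata, n_permutations: int = 1000,
                         seed: int | None = None, min_stratum: int = 10,
                         x_kind: str = "auto", y_kind: str = "auto"
                         ) -> IndependenceClaim:
    """Conditional test: per-stratum HSIC summed, within-stratum permutations.

    Strata smaller than ``min_stratum`` are skipped (too few exchangeable
    records to permute meaningfully).
    """
    x = np.asarray(x)
    y = np.asarray(y)
    codes = pd.factorize(np.asarray(strata, dtype=object))[0] if np.ndim(strata) == 1 \
        else pd.factorize(pd.MultiIndex.from_arrays(strata).to_numpy())[0]
    rng = np.random.default_rng(seed)
    kcs, lcs, sizes = [], [], []
    n_used = 0
    for s in np.unique(codes):
        idx = np.flatnonzero(codes == s)
        if idx.size < min_stratum:
            continue
        try:
            kc = _center(_gram(x[idx], x_kind))
            lc = _center(_gram(y[idx], y_kind))
        except DegenerateInputError:
            continue  # constant within stratum: no evidence either way
        kcs.append(kc)
        lcs.append(lc)
        sizes.append(idx.size)
        n_used += idx.size
    if not kcs:
        raise DegenerateInputError("no stratum large and variable enough to test")
    obs = sum(float(np.sum(kc * lc)) / ns for kc, lc, ns in zip(kcs, lcs, sizes))
    count = 0
    for _ in range(n_permutations):
        tot = 0.0
        for kc, lc, ns in zip(kcs, lcs, sizes):
            p = rng.permutation(ns)
            tot += float(np.sum(kc * lc[np.ix_(p, p)])) / ns
        if tot >= obs:
            count += 1
    pval = (1.0 + count) / (n_permutations + 1.0)
    return IndependenceClaim(x="x", y="y", statistic=obs / n_used,
                             p_value=pval, n_permutations=n_permutations)


#: default mapping from DAG nodes to cohort columns (kind: how to kernelize)
DEFAULT_NODE_COLUMNS: dict[str, tuple[str, str]] = {
    "age": ("age_years", "continuous"),
    "round": ("screening_round", "categorical"),
    "density": ("density_class", "categorical"),
    "ai_prediction": ("ai_normal_tag", "categorical"),
    "reader_set": ("reader_set_id", "categorical"),
    "supervision": ("supervised", "categorical"),
    "ai_use": ("study_group", "categorical"),
    "outcome": ("cancer_detected", "categorical"),
}


def test_all_implications(dag: CausalDAG, table: CohortTable, alpha: float = 0.05,
                          seed: int | None = None, n_permutations: int = 200,
                          node_columns: dict | None = None,
                          min_stratum: int = 10,
                          max_n: int | None = 2_000) -> list[IndependenceClaim]:
    """Test every implied observed (conditional) independence on a cohort.

    Conditional claims require every conditioning variable to be
    discrete (age is treated as discrete yearly values); continuous
    conditioning raises :class:`UnsupportedConditioningError`.  With
    ``max_n`` set, a deterministic subsample keeps kernel matrices
    tractable on large cohorts.
    """
    cols = dict(DEFAULT_NODE_COLUMNS)
    if node_columns:
        cols.update(node_columns)
    df = table.df
    if max_n is not None and len(df) > max_n:
        df = df.sample(n=max_n, random_state=np.random.default_rng(seed).integers(2**31))
        df = df.reset_index(drop=True)
    claims = implied_independences(dag)
    rng = np.random.default_rng(seed)
    results = []
    for claim in claims:
        cx, kx = cols[claim.x]
        cy, ky = cols[claim.y]
        x = df[cx].to_numpy()
        y = df[cy].to_numpy()
        sub_seed = int(rng.integers(2**31))
        if claim.z:
            zcols = []
            for zn in claim.z:
                cz, kz = cols[zn]
                if kz == "continuous" and df[cz].dtype.kind == "f":
                    raise UnsupportedConditioningError(
                        f"cannot condition on continuous variable {zn!r}")
                zcols.append(df[cz].astype(str).to_numpy())
            strata = zcols[0] if len(zcols) == 1 else \
                np.array([" / ".join(t) for t in zip(*zcols)], dtype=object)
            res = stratified_hsic_test(x, y, strata, n_permutations=n_permutations,
                                       seed=sub_seed, min_stratum=min_stratum,
                                       x_kind=kx, y_kind=ky)
        else:
            res = hsic_test(x, y, n_permutations=n_permutations, seed=sub_seed,
                            x_kind=kx, y_kind=ky)
        results.append(IndependenceClaim(
            x=claim.x, y=claim.y, z=claim.z, implied=True,
            statistic=res.statistic, p_value=res.p_value,
            n_permutations=res.n_permutations, holds=res.p_value > alpha))
    return results
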