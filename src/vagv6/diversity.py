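"""Alpha diversity and richness coverage: Shannon entropy, bias-corrected
Chao1, ACE, analytic rarefaction, and the coverage census across a cohort.

All logarithms are natural; Shannon diversity is reported in nats,
``H = -sum p_i ln p_i``, which is 0 for a single-taxon community and
``ln k`` for k equally abundant taxa.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.special import gammaln


def shannon(p) -> float:
    """Shannon entropy (nats) of a proportion vector; 0*ln0 := 0."""
    p = np.asarray(p, float)
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def _rare_counts(counts) -> np.ndarray:
    c = np.asarray(counts)
    if c.ndim != 1 or (c < 0).any():
        raise ValueError("counts must be a nonnegative 1-d integer vector")
    c = c[c > 0]
    if c.size == 0:
        raise ValueError("all-zero count vector")
    return c


def chao1(counts, bias_corrected: bool = True) -> float:
    """Chao1 richness, bias-corrected by default:
    ``S_obs + F1 (F1 - 1) / (2 (F2 + 1))``."""
    c = _rare_counts(counts)
    s_obs = c.size
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    if bias_corrected:
        return s_obs + f1 * (f1 - 1) / (2 * (f2 + 1))
    if f2 == 0:
        return s_obs + f1 * (f1 - 1) / 2
    return s_obs + f1 ** 2 / (2 * f2)


def ace(counts, rare_cutoff: int = 10) -> float:
    """Abundance-based coverage estimator with the standard rare/abundant
    split at ``rare_cutoff`` reads; falls back to Chao1 (with a warning)
    when the sample coverage of the rare class is zero."""
    c = _rare_counts(counts)
    rare = c[c <= rare_cutoff]
    s_abund = int((c > rare_cutoff).sum())
    s_rare = rare.size
    if s_rare == 0:
        return float(s_abund)
    n_rare = int(rare.sum())
    f1 = int((rare == 1).sum())
    c_ace = 1 - f1 / n_rare
    if c_ace == 0:
        warnings.warn("ACE coverage is zero (all rare taxa are singletons); "
                      "falling back to Chao1", stacklevel=2)
        return chao1(c)
    freqs = np.arange(1, rare_cutoff + 1)
    fis = np.array([(rare == i).sum() for i in freqs])
    gamma2 = max(
        (s_rare / c_ace) * (freqs * (freqs - 1) @ fis)
        / (n_rare * (n_rare - 1)) - 1,
        0.0,
    )
    return s_abund + s_rare / c_ace + (f1 / c_ace) * gamma2


def rarefaction_curve(counts, depths) -> np.ndarray:
    """Expected richness ``E[S_n]`` at each subsampling depth, computed
    analytically with log-binomials:
    ``E[S_n] = sum_i 1 - C(N - N_i, n) / C(N, n)``."""
    c = _rare_counts(counts)
    n_total = int(c.sum())
    depths = np.atleast_1d(np.asarray(depths, int))
    if (depths < 0).any() or (depths > n_total).any():
        raise ValueError("depths must lie in [0, total reads]")

    def log_choose(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    out = np.empty(depths.size)
    for j, n in enumerate(depths):
        absent = np.zeros(c.size)
        ok = (n_total - c) >= n
        absent[ok] = np.exp(log_choose(n_total - c[ok], n)
                            - log_choose(n_total, n))
        out[j] = float((1 - absent).sum())
    return out


def rarefaction_asymptote(counts, n_points: int = 20) -> float:
    """Asymptotic richness from a two-parameter saturating (Michaelis-Menten)
    fit ``S(n) = a n / (b + n)`` to the analytic rarefaction curve."""
    c = _rare_counts(counts)
    n_total = int(c.sum())
    depths = np.unique(np.linspace(1, n_total, n_points).astype(int))
    ys = rarefaction_curve(c, depths)
    s_obs = float(c.size)
    try:
        (a, b), _ = curve_fit(lambda n, a, b: a * n / (b + n),
                              depths.astype(float), ys,
                              p0=[s_obs, max(n_total / 10, 1.0)],
                              maxfev=10000)
        return float(max(a, s_obs))
    except RuntimeError:
        return s_obs


def richness_summary(counts) -> dict:
    """All per-sample richness figures in one dict."""
    c = _rare_counts(counts)
    s_obs = int(c.size)
    ch = chao1(c)
    ac = ace(c)
    rar = rarefaction_asymptote(c)
    return {
        "s_obs": s_obs,
        "f1": int((c == 1).sum()),
        "f2": int((c == 2).sum()),
        "chao1": ch,
        "ace": ac,
        "rarefaction": rar,
        "coverage_chao1": s_obs / ch,
        "coverage_ace": s_obs / ac if ac > 0 else np.nan,
        "coverage_rarefaction": s_obs / rar,
    }


def coverage_census(counts_table: pd.DataFrame,
                    thresholds: tuple[float, ...] = (0.90, 0.95)
                    ) -> pd.DataFrame:
    """Per-estimator counts of samples whose observed richness strictly
    exceeds each coverage threshold of the estimated richness (the
    Table-1-shaped grid: estimators x thresholds)."""
    rows = {est: {f"N>{t:g}": 0 for t in thresholds}
            for est in ("rarefaction", "ace", "chao1")}
    for _, counts in counts_table.iterrows():
        s = richness_summary(counts.to_numpy())
        for est in rows:
            cov = s[f"coverage_{est}"]
            for t in thresholds:
                if cov > t:
                    rows[est][f"N>{t:g}"] += 1
    out = pd.DataFrame(rows).T
    out.index.name = "method"
    return out


def diversity_table(counts_table: pd.DataFrame) -> pd.Series:
    """Shannon diversity per sample from a samples x OTUs count table."""
    props = counts_table.div(counts_table.sum(axis=1), axis=0)
    return props.apply(shannon, axis=1).rename("shannon")
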