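"""Association statistics for lactobacilli fractions vs clinical variables.

Three tools:

* Kendall's tau-b rank correlation with tie-corrected p-values (exact
  enumeration of the permutation null for very small n, normal approximation
  otherwise).
* A Kullback-Leibler "association strength": population fractions are
  converted to percentile ranks, the rank distribution within each level of
  the ordinal variable is binned with a uniform Dirichlet prior, and the
  per-level divergence of the uniform density from the empirical density is
  averaged. By a Chernoff-Stein argument the probability of mistaking the
  observed association for independence after N evaluations decays like
  exp(-N D), so N = ln(1/alpha)/D subjects suffice to establish the
  association with confidence 1 - alpha. Large N ~ weak association.
* A paired Wilcoxon signed-rank test with midranks for ties and an exact
  null distribution (dynamic programming over sign patterns) for small n.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

N_REQUIRED_CAP = 10 ** 6
EXACT_TAU_MAX_N = 8
EXACT_WILCOXON_MAX_N = 15


@dataclass(frozen=True)
class AssociationResult:
    variable: str
    proportion: str
    n_pairs: int
    tau: float
    p_value: float


@dataclass(frozen=True)
class StrengthResult:
    divergence: float          # weighted KL, nats
    n_required: int            # subjects needed for >=95% confidence
    capped: bool
    alpha: float
    bins: int


# ---------------------------------------------------------------------------
# Kendall tau


def _tau_b(x: np.ndarray, y: np.ndarray) -> float:
    res = stats.kendalltau(x, y, variant="b")
    return float(res.statistic)


def kendall_tau(x, y, variable: str = "y", proportion: str = "x"
                ) -> AssociationResult:
    """Tie-corrected Kendall tau-b with p-value.

    Pairs with a missing value on either side are dropped. For n <= 8 the
    p-value is exact (two-sided over all n! orderings of y, valid with
    ties); above that the tie-adjusted normal approximation is used.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = x.size
    if n < 2 or np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("tau undefined: fewer than 2 distinct values")
    tau = _tau_b(x, y)
    if n <= EXACT_TAU_MAX_N:
        taus = np.array([_tau_b(x, np.array(perm))
                         for perm in permutations(y)])
        p = float((np.abs(taus) >= abs(tau) - 1e-12).mean())
    else:
        p = float(stats.kendalltau(x, y, variant="b",
                                   method="asymptotic").pvalue)
    return AssociationResult(variable, proportion, n, tau, p)


# ---------------------------------------------------------------------------
# KL strength


def association_strength(x, y, alpha: float = 0.05,
                         bins: int | None = None) -> StrengthResult:
    """KL-divergence association strength between an interval-scale variable
    ``x`` and an ordinal grouping ``y``.

    Steps: percentile-rank x into (0,1); for each level of y bin the ranks
    into ``bins`` equal bins (default ceil(sqrt(min group size))) and form
    posterior-mean bin probabilities under a flat Dirichlet prior; per-level
    divergence D_g = sum_b (1/B) ln[(1/B)/q_gb]; pooled D = sum_g (n_g/n) D_g.

    A finite sample shows positive divergence even under independence, so
    the raw D is calibrated against its null distribution (asymptotically
    2nD ~ chi-square with g(B-1) degrees of freedom): the (1-alpha) null
    quantile is subtracted before the Chernoff-Stein conversion
    N = ceil(ln(1/alpha) / (D - D0)), capped at 10^6. When D does not clear
    the null quantile the association is indistinguishable from none and
    the cap is reported.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    levels, counts = np.unique(y, return_counts=True)
    usable = levels[counts >= 2]
    if usable.size < 2:
        raise ValueError("need >=2 levels of y with >=2 members each")
    keep = np.isin(y, usable)
    x, y = x[keep], y[keep]
    n = x.size
    ranks = stats.rankdata(x) / (n + 1)          # percentile ranks in (0,1)
    if bins is None:
        bins = max(2, math.ceil(math.sqrt(min(
            (y == g).sum() for g in usable))))
    edges = np.linspace(0, 1, bins + 1)
    uniform = 1.0 / bins
    d_total = 0.0
    for g in usable:
        r = ranks[y == g]
        counts_g, _ = np.histogram(r, bins=edges)
        q = (counts_g + 1) / (r.size + bins)     # Dirichlet(1,..,1) posterior mean
        d_g = float((uniform * np.log(uniform / q)).sum())
        d_total += (r.size / n) * max(d_g, 0.0)
    df = usable.size * (bins - 1)
    d_null = float(stats.chi2.ppf(1 - alpha, df)) / (2 * n)
    d_signal = d_total - d_null
    if d_signal <= 0:
        return StrengthResult(d_total, N_REQUIRED_CAP, True, alpha, bins)
    n_req = math.ceil(math.log(1 / alpha) / d_signal)
    capped = n_req > N_REQUIRED_CAP
    return StrengthResult(d_total, min(n_req, N_REQUIRED_CAP), capped,
                          alpha, bins)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank


def _signed_rank_stat(d: np.ndarray) -> tuple[float, np.ndarray]:
    ranks = stats.rankdata(np.abs(d))            # midranks for ties
    w_plus = float(ranks[d > 0].sum())
    return w_plus, ranks


def _exact_sf_distribution(ranks: np.ndarray) -> dict:
    """Distribution of W+ over all 2^n equiprobable sign patterns, via
    convolution over (doubled, integer) ranks."""
    scaled = np.round(ranks * 2).astype(int)     # midranks -> integers
    dist = {0: 1.0}
    for r in scaled:
        new = {}
        for w, p in dist.items():
            new[w] = new.get(w, 0.0) + p / 2
            new[w + r] = new.get(w + r, 0.0) + p / 2
        dist = new
    return dist


def wilcoxon_signed_rank(before, after, alternative: str = "two-sided"
                         ) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test on ``after - before``.

    Zero differences are dropped; ties get midranks. Exact enumeration of
    the sign-pattern null for n <= 15, normal approximation (with tie
    correction) above. Returns (W+, p).
    """
    before = np.asarray(before, float)
    after = np.asarray(after, float)
    if before.shape != after.shape:
        raise ValueError("before/after must pair up")
    d = after - before
    d = d[~np.isnan(d)]
    d = d[d != 0]
    n = d.size
    if n < 2:
        raise ValueError("fewer than 2 nonzero differences")
    w_plus, ranks = _signed_rank_stat(d)
    if n <= EXACT_WILCOXON_MAX_N:
        dist = _exact_sf_distribution(ranks)
        w2 = round(w_plus * 2)
        ge = sum(p for w, p in dist.items() if w >= w2)
        le = sum(p for w, p in dist.items() if w <= w2)
        if alternative == "greater":
            p = ge
        elif alternative == "less":
            p = le
        else:
            p = min(1.0, 2 * min(ge, le))
    else:
        mean = n * (n + 1) / 4
        _, tie_sizes = np.unique(np.abs(d), return_counts=True)
        tie_term = float(((tie_sizes ** 3 - tie_sizes).sum()) / 48)
        var = n * (n + 1) * (2 * n + 1) / 24 - tie_term
        z = (w_plus - mean) / math.sqrt(var)
        if alternative == "greater":
            p = float(stats.norm.sf(z))
        elif alternative == "less":
            p = float(stats.norm.cdf(z))
        else:
            p = float(2 * stats.norm.sf(abs(z)))
    return w_plus, float(min(p, 1.0))


# ---------------------------------------------------------------------------
# the lactobacilli association report


CLINICAL_VARIABLES = [
    ("ph", "continuous"),
    ("nugent", "ordinal"),
    ("amsel_score", "ordinal"),
    ("amsel_odor", "binary"),
    ("amsel_clue", "binary"),
    ("amsel_discharge", "binary"),
]


def lactobacilli_association_table(cohort, taxon_map: dict[str, str],
                                   alpha: float = 0.05) -> pd.DataFrame:
    """Association report: each clinical variable vs the *L. iners* fraction
    and the summed *L. iners* + *L. crispatus* fraction.

    ``taxon_map`` maps the roles ``"L. iners"`` and ``"L. crispatus"`` to
    OTU/taxon column names of the cohort table. pH is used continuously for
    tau but dichotomised at 4.5 for the strength statistic. Rows whose
    clinical column is entirely missing are skipped with a warning.
    """
    missing = [r for r in ("L. iners", "L. crispatus") if r not in taxon_map]
    if missing:
        raise ValueError(f"taxon_map lacks roles: {missing}")
    for role, col in taxon_map.items():
        if col not in cohort.otu_columns:
            raise ValueError(f"{role} column {col!r} not in the OTU table")
    props = cohort.proportions().reset_index(drop=True)
    iners = props[taxon_map["L. iners"]]
    both = iners + props[taxon_map["L. crispatus"]]
    fractions = [("L. iners", iners), ("L. iners & L. crispatus", both)]
    rows = []
    for var, kind in CLINICAL_VARIABLES:
        yv = cohort.df[var].astype(float)
        if yv.notna().sum() == 0:
            warnings.warn(f"clinical column {var!r} entirely missing; "
                          "row omitted", stacklevel=2)
            continue
        pool = fractions if var == "ph" else fractions[1:]
        for frac_name, xv in pool:
            res = kendall_tau(xv, yv, variable=var, proportion=frac_name)
            y_strength = ((yv > 4.5).astype(float).where(yv.notna())
                          if var == "ph" else yv)
            try:
                s = association_strength(xv, y_strength, alpha=alpha)
                strength = s.n_required
            except ValueError:
                strength = np.nan
            rows.append({"Variable": var, "Proportion": frac_name,
                         "Pairs": res.n_pairs, "Association": res.tau,
                         "p": res.p_value, "Strength": strength})
    return pd.DataFrame(rows)
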