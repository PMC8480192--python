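"""The enzyme-repertoire diversity index and small-sample group tests.

The diversity index is a Brillouin-type measure in bits per gene,

    D = (1/N) * [log2(N!) - sum_i log2(n_i!)],   N = sum_i n_i,

where ``n_i`` is the (possibly non-integer, e.g. group-average) gene count
of enzyme family *i*.  Non-integer counts are handled through the
log-gamma extension of the factorial, log x! = lgamma(x+1).

Group comparisons use one-tailed exact binomial and Fisher tests (wrapping
scipy) with Bonferroni correction, plus a phylogenetic one-way ANOVA whose
null distribution is obtained by simulating the trait under Brownian
motion on the species tree (phylANOVA-style).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .coreio import Tree

__all__ = [
    "diversity_index",
    "exact_binomial_test",
    "fisher_exact",
    "bonferroni_adjust",
    "bm_rate_ml",
    "phyl_anova",
]

_LN2 = np.log(2.0)


def diversity_index(n_i) -> float:
    """Brillouin-type diversity of a family-count vector, in bits per gene.

    Zero-count families contribute nothing (lgamma(1) = 0); the index is 0
    exactly when a single family holds all genes.
    """
    n = np.asarray(n_i, float)
    if (n < 0).any():
        raise ValueError("family counts must be >= 0")
    N = n.sum()
    if N <= 0:
        raise ValueError("total gene number must be positive")
    log2_fact_N = gammaln(N + 1.0) / _LN2
    log2_fact_n = gammaln(n + 1.0).sum() / _LN2
    return float((log2_fact_N - log2_fact_n) / N)


def exact_binomial_test(x: int, n: int, p0: float = 0.5,
                        alternative: str = "greater") -> float:
    """One-tailed exact binomial test (tail sum of the binomial pmf)."""
    if not 0 <= x <= n:
        raise ValueError("need 0 <= x <= n")
    if not 0 < p0 < 1:
        raise ValueError("null probability must be in (0, 1)")
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    return float(stats.binomtest(x, n, p0, alternative=alternative).pvalue)


def fisher_exact(table, alternative: str = "greater") -> float:
    """One-tailed Fisher exact test on a 2x2 table (hypergeometric tail)."""
    t = np.asarray(table, int)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("table entries must be >= 0")
    if t.sum() == 0:
        raise ValueError("empty table")
    return float(stats.fisher_exact(t, alternative=alternative)[1])


def bonferroni_adjust(p_list) -> np.ndarray:
    """Bonferroni family-wise correction: min(1, m * p)."""
    p = np.asarray(p_list, float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(1.0, len(p) * p)


# ---------------------------------------------------------------------------
# Phylogenetic ANOVA
# ---------------------------------------------------------------------------

def _anova_F(y: np.ndarray, codes: np.ndarray, k: int) -> np.ndarray:
    """Classical one-way F; vectorized over columns of a 2-D ``y``."""
    y = np.atleast_2d(y.T).T  # (n, m)
    n = y.shape[0]
    grand = y.mean(axis=0)
    sst = ((y - grand) ** 2).sum(axis=0)
    ssw = np.zeros(y.shape[1])
    for g in range(k):
        sel = codes == g
        if sel.sum() == 0:
            continue
        ssw += ((y[sel] - y[sel].mean(axis=0)) ** 2).sum(axis=0)
    ssb = sst - ssw
    df1, df2 = k - 1, n - k
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / df1) / (ssw / df2)
    F = np.where(ssw == 0, np.where(ssb == 0, 0.0, np.inf), F)
    F = np.where(sst == 0, 0.0, F)
    return F


def bm_rate_ml(C: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """ML (GLS) Brownian-motion rate and root state for a trait.

    ``C`` is the BM covariance of the tips (shared path lengths);
    returns ``(sigma2_hat, mu_hat)`` with sigma2 the rate per unit branch
    length and mu the phylogenetic (GLS) mean.
    """
    n = len(y)
    Ci = np.linalg.inv(C)
    one = np.ones(n)
    mu = float(one @ Ci @ y / (one @ Ci @ one))
    r = y - mu
    sigma2 = float(r @ Ci @ r / n)
    return sigma2, mu


def phyl_anova(tree: Tree, trait: pd.Series, groups: pd.Series,
               n_sim: int = 1000, seed: int = 0) -> tuple[float, float]:
    """Phylogenetic one-way ANOVA of a species trait across groups.

    The F statistic is the classical one; significance comes from
    simulating the trait under Brownian motion on the tree at the ML rate
    and recomputing F (add-one Monte-Carlo p).
    """
    from .ordination import bm_covariance

    tips = tree.tip_names
    y = trait.reindex(tips).to_numpy(float)
    if np.isnan(y).any():
        raise ValueError("trait missing for some tips")
    labs = groups.reindex(tips)
    if labs.isna().any():
        raise ValueError("group missing for some tips")
    cats = sorted(labs.unique())
    if len(cats) < 2:
        raise ValueError("phyl_anova needs at least two groups")
    codes = np.array([cats.index(v) for v in labs])
    C = bm_covariance(tree).to_numpy()
    F_obs = float(_anova_F(y, codes, len(cats))[0])
    if np.ptp(y) == 0:
        return 0.0, 1.0
    sigma2, _ = bm_rate_ml(C, y)
    L = np.linalg.cholesky(C + 1e-10 * np.eye(len(y)))
    rng = np.random.default_rng(seed)
    sims = np.sqrt(sigma2) * (L @ rng.standard_normal((len(y), n_sim)))
    F_sim = _anova_F(sims, codes, len(cats))
    p = float((1 + np.sum(F_sim >= F_obs)) / (n_sim + 1))
    return F_obs, p
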