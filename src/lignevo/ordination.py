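"""Phylogenetic PCA, phylomorphospace projection, and PERMANOVA.

pPCA follows the standard evolutionary-covariance construction: with C the
Brownian-motion species covariance implied by the dated tree (C_ij = shared
root-to-MRCA path length), the phylogenetic mean is
a = (1'C^-1 1)^-1 1'C^-1 X, the evolutionary covariance
R = (X-1a)' C^-1 (X-1a)/(n-1) is eigendecomposed, and species scores are
S = (X-1a)V.  Ancestral (internal-node) scores are maximum-likelihood
Brownian-motion estimates, which projected into the PC plane give the
phylomorphospace.  Lifestyle separation in score space is tested by
PERMANOVA (pseudo-F on partitioned squared Euclidean distances, label
permutations) with Benjamini-Hochberg-corrected pairwise comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .coreio import Tree

__all__ = [
    "PpcaResult",
    "bm_covariance",
    "node_covariance",
    "ppca",
    "ancestral_scores",
    "PermanovaResult",
    "permanova",
    "pairwise_permanova_fdr",
    "plot_phylomorphospace",
]

RIDGE = 1e-8


def bm_covariance(tree: Tree) -> pd.DataFrame:
    """Brownian-motion covariance of the tips: shared path length from the
    root to the most recent common ancestor of each pair."""
    depths = tree.depths()
    tips = tree.tip_indices
    names = tree.tip_names
    n = len(tips)
    C = np.zeros((n, n))
    # accumulate each node's branch length onto all tip pairs below it
    for v in range(1, tree.n_nodes):
        below = tree.subtree_tips(v)
        idx = [tips.index(t) for t in below]
        C[np.ix_(idx, idx)] += tree.blen[v]
    np.fill_diagonal(C, depths[tips])
    return pd.DataFrame(C, index=names, columns=names)


def node_covariance(tree: Tree) -> pd.DataFrame:
    """BM covariance over *all* nodes (tips and internal): depth of the MRCA."""
    n = tree.n_nodes
    C = np.zeros((n, n))
    depths = tree.depths()
    for v in range(1, tree.n_nodes):
        desc = _descendants(tree, v)
        C[np.ix_(desc, desc)] += tree.blen[v]
    np.fill_diagonal(C, depths)
    return pd.DataFrame(C, index=tree.names, columns=tree.names)


def _descendants(tree: Tree, v: int) -> list[int]:
    out, stack = [], [v]
    while stack:
        u = stack.pop()
        out.append(u)
        stack.extend(tree.children[u])
    return out


@dataclass
class PpcaResult:
    """Phylogenetic PCA decomposition."""

    mean: pd.Series            # phylogenetic (GLS) mean per feature
    evol_cov: pd.DataFrame     # evolutionary covariance R
    eigenvalues: np.ndarray    # sorted descending
    loadings: pd.DataFrame     # features x components
    scores: pd.DataFrame       # species x components
    percent_variance: np.ndarray

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)


def ppca(tree: Tree, X: pd.DataFrame, mode: str = "cov") -> PpcaResult:
    """Phylogenetic PCA of a species x feature matrix on a dated tree.

    ``mode='cov'`` (default) eigendecomposes the evolutionary covariance;
    ``'corr'`` the evolutionary correlation.  A tiny ridge is added to C
    when it is numerically singular.
    """
    tips = tree.tip_names
    if len(tips) < 3:
        raise ValueError("pPCA needs at least 3 species")
    Xm = X.reindex(tips).to_numpy(float)
    if np.isnan(Xm).any():
        raise ValueError("feature matrix missing some tree tips")
    C = bm_covariance(tree).to_numpy()
    n, m = Xm.shape
    try:
        Ci = np.linalg.inv(C)
    except np.linalg.LinAlgError:
        Ci = np.linalg.inv(C + RIDGE * np.eye(n))
    one = np.ones(n)
    denom = one @ Ci @ one
    a = (one @ Ci @ Xm) / denom
    Xc = Xm - a
    R = Xc.T @ Ci @ Xc / (n - 1)
    if np.allclose(R, 0):
        raise ValueError("constant feature matrix: rank-0 covariance")
    if mode == "corr":
        d = np.sqrt(np.diag(R))
        d[d == 0] = 1.0
        R_use = R / np.outer(d, d)
    elif mode == "cov":
        R_use = R
    else:
        raise ValueError("mode must be 'cov' or 'corr'")
    evals, evecs = np.linalg.eigh(R_use)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    k = min(n - 1, m)
    evals, evecs = evals[:k], evecs[:, :k]
    # deterministic sign: largest-|loading| entry positive
    for j in range(evecs.shape[1]):
        i_max = np.argmax(np.abs(evecs[:, j]))
        if evecs[i_max, j] < 0:
            evecs[:, j] *= -1
    if mode == "corr":
        d = np.sqrt(np.diag(R))
        d[d == 0] = 1.0
        scores = (Xc / d) @ evecs
    else:
        scores = Xc @ evecs
    pcs = [f"PC{j + 1}" for j in range(len(evals))]
    pct = 100.0 * evals / evals.sum()
    return PpcaResult(
        mean=pd.Series(a, index=X.columns, name="phylo_mean"),
        evol_cov=pd.DataFrame(R, index=X.columns, columns=X.columns),
        eigenvalues=evals,
        loadings=pd.DataFrame(evecs, index=X.columns, columns=pcs),
        scores=pd.DataFrame(scores, index=tips, columns=pcs),
        percent_variance=pct,
    )


def ancestral_scores(tree: Tree, scores: pd.DataFrame) -> pd.DataFrame:
    """ML Brownian-motion estimates of each score column at internal nodes.

    Uses the GLS/BLUP form: y_hat(v) = mu + C_vT C_TT^-1 (y - mu), with mu
    the phylogenetic mean of the column; the root estimate equals mu.
    """
    Call = node_covariance(tree).to_numpy()
    tips = tree.tip_indices
    internal = tree.internal_indices
    Ctt = Call[np.ix_(tips, tips)]
    Cvt = Call[np.ix_(internal, tips)]
    try:
        Cti = np.linalg.inv(Ctt)
    except np.linalg.LinAlgError:
        Cti = np.linalg.inv(Ctt + RIDGE * np.eye(len(tips)))
    one = np.ones(len(tips))
    denom = one @ Cti @ one
    Y = scores.reindex(tree.tip_names).to_numpy(float)
    mu = (one @ Cti @ Y) / denom
    est = mu + Cvt @ Cti @ (Y - mu)
    return pd.DataFrame(est, index=[tree.names[i] for i in internal],
                        columns=scores.columns)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclass
class PermanovaResult:
    pseudo_F: float
    p_value: float
    df_between: int
    df_within: int
    n_permutations: int
    degenerate: bool = False


def _sq_dists(X: np.ndarray) -> np.ndarray:
    sq = (X ** 2).sum(axis=1)
    D2 = sq[:, None] + sq[None, :] - 2 * X @ X.T
    np.clip(D2, 0, None, out=D2)
    return D2


def _permanova_F(D2: np.ndarray, codes: np.ndarray, k: int) -> float:
    n = len(codes)
    sst = D2[np.triu_indices(n, 1)].sum() / n
    ssw = 0.0
    for g in range(k):
        sel = np.where(codes == g)[0]
        ng = len(sel)
        if ng:
            ssw += D2[np.ix_(sel, sel)][np.triu_indices(ng, 1)].sum() / ng
    ssb = sst - ssw
    df1, df2 = k - 1, n - k
    if ssw <= 0:
        return np.inf if ssb > 0 else 0.0
    return (ssb / df1) / (ssw / df2)


def permanova(X, groups: pd.Series, n_perm: int = 999,
              seed: int = 0, is_distance: bool = False) -> PermanovaResult:
    """PERMANOVA (adonis-style) on score rows or a distance matrix.

    Euclidean distances on the rows of ``X`` by default; pseudo-F from the
    partition of squared inter-point distances, p by complete label
    permutation with the add-one rule.
    """
    if isinstance(X, pd.DataFrame):
        labs = groups.reindex(X.index)
        if labs.isna().any():
            raise ValueError("group missing for some rows")
        M = X.to_numpy(float)
    else:
        M = np.asarray(X, float)
        labs = pd.Series(groups)
    cats = sorted(labs.unique())
    if len(cats) < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    counts = labs.value_counts()
    if (counts < 1).any():
        raise ValueError("every group needs at least one member")
    codes = np.array([cats.index(v) for v in labs])
    D2 = M ** 2 if is_distance else _sq_dists(M)
    if is_distance:
        D2 = np.asarray(D2, float)
    n, k = len(codes), len(cats)
    if D2.max() <= 1e-24:
        return PermanovaResult(np.nan, np.nan, k - 1, n - k, n_perm,
                               degenerate=True)
    F_obs = _permanova_F(D2, codes, k)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        if _permanova_F(D2, perm, k) >= F_obs - 1e-12:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return PermanovaResult(float(F_obs), float(p), k - 1, n - k, n_perm)


def pairwise_permanova_fdr(X: pd.DataFrame, groups: pd.Series,
                           n_perm: int = 999, seed: int = 0) -> pd.DataFrame:
    """All pairwise group PERMANOVAs with Benjamini-Hochberg adjustment.

    Pairs are ordered deterministically (sorted group names); each pair's
    permutation stream derives from ``seed`` and the pair rank.
    """
    labs = groups.reindex(X.index)
    cats = sorted(labs.unique())
    rows = []
    for r, (g1, g2) in enumerate(
            (a, b) for i, a in enumerate(cats) for b in cats[i + 1:]):
        sel = labs.isin([g1, g2])
        res = permanova(X.loc[sel], labs[sel], n_perm=n_perm,
                        seed=seed + 7919 * r)
        rows.append((g1, g2, res.pseudo_F, res.p_value))
    df = pd.DataFrame(rows, columns=["group1", "group2", "pseudo_F", "p_raw"])
    df["p_adj"] = multipletests(df["p_raw"].to_numpy(), method="fdr_bh")[1]
    return df


# ---------------------------------------------------------------------------
# Plotting
# ---------------------------------------------------------------------------

def plot_phylomorphospace(tree: Tree, scores: pd.DataFrame,
                          anc: pd.DataFrame, groups: pd.Series | None,
                          path: str, pcs=("PC1", "PC2")) -> None:
    """2-D phylomorphospace: tree edges drawn in PC space, tips colored by
    lifestyle, internal nodes in black."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pos = pd.concat([scores[list(pcs)], anc[list(pcs)]])
    fig, ax = plt.subplots(figsize=(7, 6))
    for i in range(1, tree.n_nodes):
        a, b = tree.names[tree.parent[i]], tree.names[i]
        if a in pos.index and b in pos.index:
            ax.plot(pos.loc[[a, b], pcs[0]], pos.loc[[a, b], pcs[1]],
                    color="0.7", lw=0.8, zorder=1)
    if groups is not None:
        cats = sorted(groups.dropna().unique())
        cmap = plt.get_cmap("tab10")
        for j, g in enumerate(cats):
            sel = [s for s in scores.index if groups.get(s) == g]
            ax.scatter(scores.loc[sel, pcs[0]], scores.loc[sel, pcs[1]],
                       s=35, color=cmap(j % 10), label=g, zorder=3)
        ax.legend(fontsize=8)
    else:
        ax.scatter(scores[pcs[0]], scores[pcs[1]], s=35, zorder=3)
    ax.scatter(anc[pcs[0]], anc[pcs[1]], s=12, color="k", zorder=2)
    ax.set_xlabel(pcs[0])
    ax.set_ylabel(pcs[1])
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
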