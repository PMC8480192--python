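"""Gene-family evolution under a linear birth-death process on copy number.

This is the CAFE-style model: along every branch of a dated species tree a
family's copy number evolves by a linear birth-death process in which each
gene copy is duplicated or lost at the same global rate ``lambda`` (events
per gene per million years).  With ``alpha = lambda*t / (1 + lambda*t)``
the transition probability from ``s`` parent copies to ``c`` child copies
over a branch of ``t`` My has the closed form

    P(c | s, t) = sum_{j=0..min(s,c)} C(s, j) * C(s+c-j-1, s-1)
                  * alpha^(s+c-2j) * (1-2*alpha)^j          (s >= 1),

with ``P(0|0)=1`` (zero is absorbing).  On top of the kernel the module
provides the pruning likelihood over a truncated state space {0..n_max},
maximum-likelihood estimation of the single global rate, joint most
probable (max-product / Viterbi) ancestral copy numbers, Monte-Carlo
family-wide p-values for detecting fast-evolving families, and per-branch
"Viterbi" p-values locating significant expansions and contractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln

from .coreio import GeneCountMatrix, Tree

__all__ = [
    "BDPModel",
    "FamilyEvolResult",
    "transition_prob",
    "transition_matrix",
    "family_loglik",
    "loglik_many",
    "estimate_lambda",
    "ancestral_counts",
    "simulate_families",
    "familywide_pvalue",
    "null_loglik_sample",
    "viterbi_branch_pvalues",
    "classify_fast_families",
    "default_n_max",
    "analyze_families",
]

LAMBDA_BOUNDS = (1e-6, 10.0)


@dataclass
class BDPModel:
    """Global birth-death model: rate, state cap and root prior.

    ``root_prior`` is a distribution over states {0..n_max}; the default
    (None) is uniform over {1..n_max}, i.e. the family is conditioned to be
    present at the root.
    """

    lam: float
    n_max: int
    root_prior: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if self.n_max < 1:
            raise ValueError("n_max must be >= 1")
        if self.root_prior is None:
            p = np.zeros(self.n_max + 1)
            p[1:] = 1.0 / self.n_max
            self.root_prior = p
        else:
            self.root_prior = np.asarray(self.root_prior, float)
            if self.root_prior.shape != (self.n_max + 1,):
                raise ValueError("root_prior must have length n_max+1")
            self.root_prior = self.root_prior / self.root_prior.sum()


@dataclass
class FamilyEvolResult:
    """Per-family inference summary: likelihood, ancestral states, branch calls."""

    family: str
    loglik: float
    node_counts: pd.Series           # most-probable count per node (all nodes)
    branch_table: pd.DataFrame       # parent_count, child_count, direction, viterbi_p
    family_wide_p: float = field(default=np.nan)


def default_n_max(tip_counts) -> int:
    """State cap for one family: twice the largest observed count, floor 10
    (headroom capped at +50 states above the largest count)."""
    m = int(np.max(tip_counts)) if len(tip_counts) else 0
    return max(10, min(2 * m, m + 50))


# ---------------------------------------------------------------------------
# Transition kernel
# ---------------------------------------------------------------------------

_COMB_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _comb_tensor(n_max: int) -> tuple[np.ndarray, np.ndarray]:
    """Cache the alpha-independent part of the kernel: the tensor
    M[s, c, j] = C(s, j) * C(s+c-j-1, s-1) and the power index s+c-2j."""
    if n_max in _COMB_CACHE:
        return _COMB_CACHE[n_max]
    S = n_max + 1
    G = gammaln(np.arange(2 * S + 2) + 1.0)   # lgamma lookup: log(n!)

    def log_comb(n, k):
        return G[n] - G[k] - G[n - k]

    s = np.arange(S)[:, None, None]
    c = np.arange(S)[None, :, None]
    j = np.arange(S)[None, None, :]
    valid = (j <= np.minimum(s, c)) & (s >= 1)
    n1 = np.broadcast_to(s, (S, S, S))
    k1 = np.minimum(np.broadcast_to(j, (S, S, S)), n1)
    n2 = np.maximum(s + c - j - 1, 0)
    k2 = np.minimum(np.broadcast_to(s, (S, S, S)) - 1, n2)
    M = np.where(valid, np.exp(log_comb(n1, k1) + log_comb(n2, np.maximum(k2, 0))), 0.0)
    powidx = np.clip(s + c - 2 * j, 0, 2 * S + 1)
    out = (M, np.broadcast_to(powidx, (S, S, S)))
    if len(_COMB_CACHE) >= 4:   # bound memory: a few hundred MB at most
        _COMB_CACHE.pop(next(iter(_COMB_CACHE)))
    _COMB_CACHE[n_max] = out
    return out


def transition_matrix(lam: float, t: float, n_max: int) -> np.ndarray:
    """(n_max+1) x (n_max+1) matrix P[s, c] of birth-death transition
    probabilities over a branch of length ``t``; states truncated at n_max.
    """
    if lam < 0 or t < 0:
        raise ValueError("lambda and t must be >= 0")
    S = n_max + 1
    lt = lam * t
    if lt == 0:
        return np.eye(S)
    alpha = lt / (1.0 + lt)
    base = 1.0 - 2.0 * alpha                 # may be negative for lam*t > 1
    M, powidx = _comb_tensor(n_max)
    apow = alpha ** np.arange(2 * S + 2, dtype=float)
    bpow = np.sign(base) ** np.arange(S) * np.abs(base) ** np.arange(S)
    P = np.einsum("scj,scj,j->sc", M, apow[powidx], bpow)
    P[0, :] = 0.0
    P[0, 0] = 1.0
    np.clip(P, 0.0, 1.0, out=P)
    return P


def transition_prob(s: int, c: int, t: float, lam: float) -> float:
    """P(child count = c | parent count = s) over a branch of t My."""
    if s < 0 or c < 0:
        raise ValueError("counts must be >= 0")
    n_max = max(s, c, 1)
    return float(transition_matrix(lam, t, n_max)[s, c])


def _branch_matrices(tree: Tree, lam: float, n_max: int) -> list[np.ndarray | None]:
    """Transition matrix per node (None at the root), cached by branch length."""
    cache: dict[float, np.ndarray] = {}
    out: list[np.ndarray | None] = [None] * tree.n_nodes
    for i in range(1, tree.n_nodes):
        t = float(tree.blen[i])
        if t not in cache:
            cache[t] = transition_matrix(lam, t, n_max)
        out[i] = cache[t]
    return out


# ---------------------------------------------------------------------------
# Pruning likelihood
# ---------------------------------------------------------------------------

def _tip_count_array(tree: Tree, tip_counts) -> np.ndarray:
    """Normalize per-species counts to a 2-D (n_families, n_tips) array in
    tree tip order.  Accepts a dict/Series (one family) or DataFrame
    (species rows x family columns)."""
    tips = tree.tip_names
    if isinstance(tip_counts, pd.DataFrame):
        missing = set(tips) - set(tip_counts.index)
        if missing:
            raise KeyError(f"tips absent from counts: {sorted(missing)}")
        return tip_counts.loc[tips].to_numpy().T.astype(int)
    if isinstance(tip_counts, pd.Series):
        tip_counts = tip_counts.to_dict()
    if isinstance(tip_counts, dict):
        missing = set(tips) - set(tip_counts)
        if missing:
            raise KeyError(f"tips absent from counts: {sorted(missing)}")
        return np.array([[int(tip_counts[t]) for t in tips]])
    arr = np.asarray(tip_counts, int)
    if arr.ndim == 1:
        arr = arr[None, :]
    return arr


def loglik_many(tree: Tree, counts: np.ndarray, model: BDPModel,
                Ps: list[np.ndarray | None] | None = None) -> np.ndarray:
    """Pruning log-likelihood for many families at once.

    ``counts``: (n_families, n_tips) in ``tree.tip_names`` order.
    """
    counts = np.asarray(counts, int)
    if counts.max(initial=0) > model.n_max:
        raise ValueError("tip count exceeds n_max")
    F = counts.shape[0]
    S = model.n_max + 1
    if Ps is None:
        Ps = _branch_matrices(tree, model.lam, model.n_max)
    tip_pos = {i: k for k, i in enumerate(tree.tip_indices)}
    partial: list[np.ndarray | None] = [None] * tree.n_nodes
    logscale = np.zeros(F)
    for i in tree.postorder():
        if tree.is_tip(i):
            L = np.zeros((F, S))
            L[np.arange(F), counts[:, tip_pos[i]]] = 1.0
        else:
            L = np.ones((F, S))
            for ch in tree.children[i]:
                msg = partial[ch] @ Ps[ch].T  # (F,S): sum_c P[s,c] L_child[c]
                L *= msg
                partial[ch] = None
            mx = L.max(axis=1)
            mx[mx == 0] = 1.0
            L /= mx[:, None]
            logscale += np.log(mx)
        partial[i] = L
    lik = partial[tree.root] @ model.root_prior
    with np.errstate(divide="ignore"):
        return np.log(lik) + logscale


def family_loglik(tree: Tree, tip_counts, model: BDPModel) -> float:
    """Log-likelihood of one family's tip counts under the model."""
    arr = _tip_count_array(tree, tip_counts)
    return float(loglik_many(tree, arr, model)[0])


# ---------------------------------------------------------------------------
# Rate estimation
# ---------------------------------------------------------------------------

def _grouped_counts(tree: Tree, counts, families=None):
    """Yield (family names, count block, n_max) grouped by common n_max."""
    if isinstance(counts, GeneCountMatrix):
        counts = counts.counts
    if families is not None:
        counts = counts[list(families)]
    arr = _tip_count_array(tree, counts)
    names = list(counts.columns) if isinstance(counts, pd.DataFrame) else [
        f"F{i}" for i in range(arr.shape[0])]
    nmax = np.array([default_n_max(arr[i]) for i in range(arr.shape[0])])
    for nm in np.unique(nmax):
        sel = np.where(nmax == nm)[0]
        yield [names[i] for i in sel], arr[sel], int(nm)


def estimate_lambda(tree: Tree, counts, families=None,
                    bounds: tuple[float, float] = LAMBDA_BOUNDS,
                    rtol: float = 1e-6) -> tuple[float, float]:
    """ML estimate of the single global birth/death rate over all families.

    Returns ``(lambda_hat, total_loglik)``.  Bounded scalar optimization on
    a log grid refined by Brent search.
    """
    groups = list(_grouped_counts(tree, counts, families))
    if not groups:
        raise ValueError("no families supplied")
    if all(block.sum() == 0 for _, block, _ in groups):
        raise ValueError("all-zero count matrix")

    def neg_total(lam: float) -> float:
        tot = 0.0
        for _, block, nm in groups:
            tot += loglik_many(tree, block, BDPModel(lam=lam, n_max=nm)).sum()
        return -tot

    res = minimize_scalar(neg_total, bounds=bounds, method="bounded",
                          options={"xatol": rtol * bounds[1] * 1e-3})
    lam_hat = float(res.x)
    # the bounded search can stall on the flat lower edge; check the boundary
    if neg_total(bounds[0]) < res.fun:
        lam_hat, res_fun = bounds[0], neg_total(bounds[0])
    else:
        res_fun = res.fun
    return lam_hat, -float(res_fun)


# ---------------------------------------------------------------------------
# Ancestral counts (max-product / Viterbi)
# ---------------------------------------------------------------------------

def ancestral_counts(tree: Tree, tip_counts, model: BDPModel,
                     return_logprob: bool = False):
    """Joint most-probable copy number at every node (max-product DP).

    Ties are broken toward the smaller count.  Returns a Series indexed by
    node name (tips carry their observed counts); with
    ``return_logprob=True`` also the log probability of the joint
    assignment (root prior included).
    """
    arr = _tip_count_array(tree, tip_counts)
    if arr.shape[0] != 1:
        raise ValueError("ancestral_counts works on one family at a time")
    obs = arr[0]
    S = model.n_max + 1
    Ps = _branch_matrices(tree, model.lam, model.n_max)
    tip_pos = {i: k for k, i in enumerate(tree.tip_indices)}
    with np.errstate(divide="ignore"):
        logPs = [None if P is None else np.log(P) for P in Ps]
        logprior = np.log(model.root_prior)
    delta: list[np.ndarray | None] = [None] * tree.n_nodes
    back: list[np.ndarray | None] = [None] * tree.n_nodes
    for i in tree.postorder():
        if tree.is_tip(i):
            d = np.full(S, -np.inf)
            d[obs[tip_pos[i]]] = 0.0
        else:
            d = np.zeros(S)
            for ch in tree.children[i]:
                scores = logPs[ch] + delta[ch][None, :]   # [s_parent, c_child]
                back[ch] = np.argmax(scores, axis=1)      # first max = smallest c
                d += scores[np.arange(S), back[ch]]
        delta[i] = d
    root_scores = logprior + delta[tree.root]
    states = np.zeros(tree.n_nodes, int)
    states[tree.root] = int(np.argmax(root_scores))
    for i in tree.preorder()[1:]:
        states[i] = back[i][states[tree.parent[i]]]
    out = pd.Series(states, index=tree.names, name="count")
    if return_logprob:
        return out, float(root_scores[states[tree.root]])
    return out


# ---------------------------------------------------------------------------
# Simulation and family-wide p-values
# ---------------------------------------------------------------------------

def simulate_families(tree: Tree, model: BDPModel, n_fam: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Forward-simulate families from the root prior using the analytic
    transition kernel; returns (n_fam, n_nodes) states for all nodes."""
    Ps = _branch_matrices(tree, model.lam, model.n_max)
    # renormalize rows: sampling must stay inside the truncated state space
    cum = [None if P is None else
           np.cumsum(P, axis=1) / P.sum(axis=1, keepdims=True) for P in Ps]
    states = np.zeros((n_fam, tree.n_nodes), int)
    states[:, tree.root] = rng.choice(model.n_max + 1, size=n_fam,
                                      p=model.root_prior)
    for i in tree.preorder()[1:]:
        u = rng.random(n_fam)
        rows = cum[i][states[:, tree.parent[i]]]
        states[:, i] = (u[:, None] > rows).sum(axis=1)
    return states


def _tip_states(tree: Tree, states: np.ndarray) -> np.ndarray:
    return states[:, tree.tip_indices]


def null_loglik_sample(tree: Tree, model: BDPModel, n_sim: int,
                       seed: int) -> np.ndarray:
    """Log-likelihoods of ``n_sim`` families forward-simulated under the model."""
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    rng = np.random.default_rng(seed)
    sims = _tip_states(tree, simulate_families(tree, model, n_sim, rng))
    return loglik_many(tree, sims, model)


def familywide_pvalue(tree: Tree, tip_counts, model: BDPModel,
                      n_sim: int = 1000, seed: int = 0,
                      null_logliks: np.ndarray | None = None) -> float:
    """Monte-Carlo family-wide p-value (add-one estimator).

    p = (1 + #{simulated loglik <= observed loglik}) / (n_sim + 1): small
    when the observed configuration is less likely than nearly all families
    the fitted global rate can produce.
    """
    obs = family_loglik(tree, tip_counts, model)
    if null_logliks is None:
        null_logliks = null_loglik_sample(tree, model, n_sim, seed)
    n = len(null_logliks)
    return float((1 + np.sum(null_logliks <= obs + 1e-12)) / (n + 1))


def classify_fast_families(family_p: pd.Series, alpha: float = 0.01) -> list[str]:
    """Families with family-wide p below ``alpha``, in deterministic order."""
    p = pd.Series(family_p)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    hits = p[p < alpha]
    return sorted(hits.index, key=lambda f: (float(p[f]), str(f)))


# ---------------------------------------------------------------------------
# Per-branch Viterbi p-values
# ---------------------------------------------------------------------------

def viterbi_branch_pvalues(tree: Tree, tip_counts, model: BDPModel) -> pd.DataFrame:
    """Exact per-branch tail p-values for the most-probable transitions.

    For each branch with Viterbi parent/child states (s*, c*), p is the
    total probability of child states whose transition probability from s*
    is as small or smaller than that of c* ("as-or-less-likely" tail over
    the truncated state space).
    """
    states = ancestral_counts(tree, tip_counts, model)
    Ps = _branch_matrices(tree, model.lam, model.n_max)
    rows = []
    for i in tree.preorder()[1:]:
        s_star = int(states.iloc[tree.parent[i]])
        c_star = int(states.iloc[i])
        row = Ps[i][s_star]
        p = float(row[row <= row[c_star] * (1 + 1e-12)].sum())
        p = min(p, 1.0)
        direction = ("expansion" if c_star > s_star
                     else "contraction" if c_star < s_star else "none")
        rows.append((tree.names[tree.parent[i]], tree.names[i],
                     s_star, c_star, direction, p))
    return pd.DataFrame(rows, columns=["parent", "child", "parent_count",
                                       "child_count", "direction", "viterbi_p"])


# ---------------------------------------------------------------------------
# Whole-matrix convenience driver
# ---------------------------------------------------------------------------

def analyze_families(tree: Tree, gcm: GeneCountMatrix, n_sim: int = 1000,
                     seed: int = 0, alpha: float = 0.01,
                     lam: float | None = None) -> dict:
    """Fit the global rate on all families (focal + background), then score
    every family: log-likelihood, family-wide p (one shared null sample per
    state-cap group), ancestral counts, and per-branch Viterbi p-values.
    """
    if lam is None:
        lam, total_ll = estimate_lambda(tree, gcm)
    else:
        total_ll = np.nan
    fam_rows = {}
    results: dict[str, FamilyEvolResult] = {}
    anc = {}
    for k, (names, block, nm) in enumerate(_grouped_counts(tree, gcm.counts)):
        model = BDPModel(lam=lam, n_max=nm)
        null_ll = null_loglik_sample(tree, model, n_sim, seed + 104729 * k)
        lls = loglik_many(tree, block, model)
        for fam, ll, cnts in zip(names, lls, block):
            p = float((1 + np.sum(null_ll <= ll + 1e-12)) / (len(null_ll) + 1))
            fam_rows[fam] = (ll, p)
            ser = ancestral_counts(tree, cnts, model)
            anc[fam] = ser
            bt = viterbi_branch_pvalues(tree, cnts, model)
            results[fam] = FamilyEvolResult(
                family=fam, loglik=float(ll), node_counts=ser,
                branch_table=bt, family_wide_p=p)
    fam_table = pd.DataFrame(
        {f: {"loglik": v[0], "family_wide_p": v[1]} for f, v in fam_rows.items()}
    ).T.loc[gcm.families]
    anc_table = pd.DataFrame(anc).loc[tree.names, gcm.families]
    fast = classify_fast_families(fam_table["family_wide_p"], alpha=alpha)
    return {
        "lambda_hat": lam,
        "total_loglik": total_ll,
        "family_table": fam_table,
        "ancestral_counts": anc_table,
        "fast_families": fast,
        "per_family": results,
    }
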