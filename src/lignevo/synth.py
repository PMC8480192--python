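"""Seeded generators for every input the pipeline consumes.

The generators emulate the statistical structure the analysis assumes: a
time-calibrated (Yule) species tree of ~52 tips with a ~192-My root,
lifestyles evolving as a symmetric 6-state Markov (Mk) jump process,
gene-family copy numbers evolving by an exact (Gillespie) linear
birth-death simulation whose per-gene gain rate can be biased by the
lifestyle in force on a branch — so counts, ancestral counts and ancestral
lifestyles stay jointly coherent ground truth — and toy POD alignments
whose catalytic columns deterministically encode planted enzyme types
while the remaining columns evolve under the reconstruction model.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coreio import LIFESTYLES, GeneCountMatrix, Msa, SiteMap, Tree
from .substmodels import get_model

__all__ = [
    "FamilySpec",
    "SimulationPreset",
    "simulate_tree",
    "simulate_lifestyles",
    "simulate_counts",
    "simulate_pod_alignment",
    "default_site_map",
    "agaricales_preset",
    "strong_signal_preset",
    "fast_family_preset",
    "POD_TEMPLATES",
]

#: hard cap on simulated copy numbers (guards supercritical branches;
#: real decay-enzyme families top out well below this)
COUNT_CAP = 150


@dataclass
class FamilySpec:
    """One simulated gene family.

    ``gain_bias`` maps lifestyles to multipliers on the per-gene birth
    rate (death stays at baseline) — this is how lifestyle signal enters.
    ``rate_mult`` scales both birth and death (a fast-evolving family).
    """

    name: str
    role: str = "focal"
    root_count: int = 5
    gain_bias: dict[str, float] = field(default_factory=dict)
    rate_mult: float = 1.0


@dataclass
class SimulationPreset:
    """Study conditions for one synthetic data set."""

    n_tips: int = 52
    root_age: float = 192.0
    mk_rate: float = 0.006          # lifestyle changes per My
    base_lambda: float = 0.002      # birth-death events per gene per My
    families: list[FamilySpec] = field(default_factory=list)
    burn_in_My: float = 0.0         # pre-root evolution under the root lifestyle
    require_presence: float | None = None   # min fraction of non-zero tips
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mk_rate < 0 or self.base_lambda < 0:
            raise ValueError("rates must be >= 0")


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def simulate_tree(n_tips: int, root_age_My: float, seed: int,
                  unit: str = "My") -> Tree:
    """Yule (pure-birth) tree rescaled so the root age is exactly
    ``root_age_My``; ultrametric by construction."""
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(seed)
    # grow lineages: each extant lineage splits at unit rate
    t = 0.0
    birth_time = {0: 0.0, 1: 0.0}   # lineage id -> time it was created
    children: dict[int, list[int]] = {0: [], 1: []}
    parent = {0: -1, 1: -1}
    extant = [0, 1]
    next_id = 2
    while len(extant) < n_tips:
        t += rng.exponential(1.0 / len(extant))
        i = extant[rng.integers(len(extant))]
        a, b = next_id, next_id + 1
        next_id += 2
        for c in (a, b):
            birth_time[c] = t
            children[c] = []
            parent[c] = i
        children[i] = [a, b]
        extant.remove(i)
        extant.extend([a, b])
    t += rng.exponential(1.0 / len(extant))  # stem below the last split
    end_time = {i: t for i in extant}
    for i in birth_time:
        if i not in end_time:
            end_time[i] = birth_time[children[i][0]]
    scale = root_age_My / t
    # assemble preorder arrays with a synthetic root joining lineages 0,1
    names, par, blen, chl = ["N0"], [-1], [0.0], [[]]
    tip_counter = [0]
    node_counter = [1]

    def build(i: int, parent_idx: int) -> None:
        me = len(names)
        if children[i]:
            names.append(f"N{node_counter[0]}")
            node_counter[0] += 1
        else:
            tip_counter[0] += 1
            names.append(f"sp{tip_counter[0]:02d}")
        par.append(parent_idx)
        blen.append((end_time[i] - birth_time[i]) * scale)
        chl.append([])
        chl[parent_idx].append(me)
        for c in children[i]:
            build(c, me)

    build(0, 0)
    build(1, 0)
    return Tree(names=names, parent=np.array(par), blen=np.array(blen),
                children=chl, unit=unit)


# ---------------------------------------------------------------------------
# Lifestyles (Mk jump process)
# ---------------------------------------------------------------------------

def simulate_lifestyles(tree: Tree, q: float, seed: int,
                        states: tuple[str, ...] = LIFESTYLES) -> pd.Series:
    """Symmetric Mk evolution of a lifestyle over the tree.

    The root state is uniform; along a branch of length t the number of
    jumps is Poisson(q t) and each jump moves to a uniformly chosen
    different state.  Returns the state of *every* node (ancestral truth
    retained).
    """
    if q < 0:
        raise ValueError("Mk rate must be >= 0")
    rng = np.random.default_rng(seed)
    k = len(states)
    out = np.zeros(tree.n_nodes, int)
    out[tree.root] = rng.integers(k)
    for i in tree.preorder()[1:]:
        s = out[tree.parent[i]]
        for _ in range(rng.poisson(q * tree.blen[i])):
            s = (s + 1 + rng.integers(k - 1)) % k
        out[i] = s
    return pd.Series([states[s] for s in out], index=tree.names,
                     name="lifestyle")


# ---------------------------------------------------------------------------
# Counts (exact Gillespie birth-death along branches)
# ---------------------------------------------------------------------------

def _gillespie_branch(n0: int, t: float, birth: float, death: float,
                      rng: np.random.Generator) -> int:
    n, clock = n0, 0.0
    if birth + death == 0 or t <= 0:
        return n
    while n > 0:
        rate = n * (birth + death)
        clock += rng.exponential(1.0 / rate)
        if clock >= t:
            break
        if rng.random() < birth / (birth + death):
            n = min(n + 1, COUNT_CAP)
        else:
            n -= 1
    return n


def simulate_counts(tree: Tree, lifestyles: pd.Series,
                    preset: SimulationPreset,
                    seed: int | None = None,
                    require_presence: float | None = None
                    ) -> tuple[GeneCountMatrix, pd.DataFrame]:
    """Forward-simulate every family's copy number over the tree.

    Along the branch into node v the birth rate per gene is
    ``base_lambda * rate_mult * gain_bias[lifestyle(v)]`` and the death
    rate ``base_lambda * rate_mult`` (the lifestyle at the child node is
    taken to rule the branch).  Returns the tip count matrix and the full
    ancestral-truth table (all nodes x families).

    ``require_presence`` conditions each family on being observable, as
    empirical family matrices are: if the family is non-zero in fewer than
    that fraction of tips it is redrawn (sequentially from the same RNG
    stream, so the output is still a pure function of the seed).
    """
    if not preset.families:
        raise ValueError("preset declares no families")
    if require_presence is None:
        require_presence = preset.require_presence
    rng = np.random.default_rng(preset.seed if seed is None else seed)
    ls = lifestyles.reindex(tree.names)
    tip_idx = tree.tip_indices
    truth = np.zeros((tree.n_nodes, len(preset.families)), int)
    for f, fam in enumerate(preset.families):
        lam = preset.base_lambda * fam.rate_mult
        for _attempt in range(1000):
            # burn-in: the root lineage has lived its lifestyle for a while,
            # so the root repertoire starts near that lifestyle's regime
            g_root = fam.gain_bias.get(ls.iloc[tree.root], 1.0)
            root_n = _gillespie_branch(fam.root_count, preset.burn_in_My,
                                       lam * g_root, lam, rng)
            truth[tree.root, f] = max(root_n, 1) if preset.burn_in_My else root_n
            for i in tree.preorder()[1:]:
                g = fam.gain_bias.get(ls.iloc[i], 1.0)
                truth[i, f] = _gillespie_branch(
                    truth[tree.parent[i], f], float(tree.blen[i]),
                    lam * g, lam, rng)
            if require_presence is None:
                break
            present = np.mean(truth[tip_idx, f] > 0)
            if present >= require_presence:
                break
        else:
            raise RuntimeError(f"family {fam.name} kept going extinct")
    names = [fam.name for fam in preset.families]
    truth_df = pd.DataFrame(truth, index=tree.names, columns=names)
    tips = tree.tip_names
    gcm = GeneCountMatrix(
        counts=truth_df.loc[tips],
        roles=pd.Series({fam.name: fam.role for fam in preset.families}))
    return gcm, truth_df


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

#: per-gene gain-rate multipliers of the seven fast-family analogues per
#: lifestyle (columns: white_rot, brown_rot, decayed_wood, grass_litter,
#: forest_litter, mycorrhiza) — ligninolytic families mark rotters,
#: cellulose-active families mark grass litter, and biotrophs shed nearly
#: everything, echoing the qualitative structure of real repertoires
_SIGNATURE = {
    "POD": (3.0, 0.2, 2.0, 0.6, 0.6, 0.1),
    "LAC": (2.0, 0.3, 0.8, 0.6, 3.0, 0.3),
    "AA9": (1.2, 0.3, 0.8, 3.0, 1.0, 0.2),
    "GMC": (1.5, 1.0, 2.5, 0.8, 2.0, 0.3),
    "UPO": (0.8, 0.6, 2.5, 1.0, 2.5, 0.4),
    "GH43": (0.8, 0.5, 1.0, 3.0, 1.5, 0.3),
    "CBM1": (2.0, 0.2, 1.0, 3.0, 1.0, 0.1),
}


def _signature_families(contrast: float = 1.0,
                        rate_mult: float = 1.0) -> list[FamilySpec]:
    """The seven marked families; ``contrast`` sharpens the multipliers
    (g -> g**contrast), 1.0 reproduces the table above."""
    fams = []
    for name, row in _SIGNATURE.items():
        bias = {l: float(g) ** contrast for l, g in zip(LIFESTYLES, row)}
        fams.append(FamilySpec(name=name, role="focal", root_count=5,
                               gain_bias=bias, rate_mult=rate_mult))
    return fams


def agaricales_preset(seed: int = 0) -> SimulationPreset:
    """Default realistic conditions: 52 tips, 192-My root, 62 focal
    families (7 of them lifestyle-marked) plus 24 background families."""
    fams = _signature_families()
    for i in range(55):
        fams.append(FamilySpec(name=f"PCWDE{i + 1:02d}", role="focal",
                               root_count=4))
    for i in range(24):
        fams.append(FamilySpec(name=f"BG{i + 1:02d}", role="background",
                               root_count=4))
    return SimulationPreset(n_tips=52, root_age=192.0, mk_rate=0.006,
                            base_lambda=0.002, families=fams, seed=seed)


#: marker family of each lifestyle in the strong-signal benchmark
_MARKERS = {"white_rot": "POD", "brown_rot": "UPO", "decayed_wood": "GMC",
            "grass_litter": "AA9", "forest_litter": "LAC",
            "mycorrhiza": "GH43"}


def strong_signal_preset(seed: int = 0) -> SimulationPreset:
    """High lifestyle signal for the ancestral-lifestyle benchmark.

    Each lifestyle marks one family (5x gain boost at home, 0.15x
    elsewhere) on a fast clock (8x the baseline rate) with a 150-My
    burn-in, so a node's repertoire tracks the lifestyle in force on the
    branches above it; Mk ancestral truth is retained for scoring.
    """
    fams = []
    for lifestyle, name in _MARKERS.items():
        bias = {l: (5.0 if l == lifestyle else 0.15) for l in LIFESTYLES}
        fams.append(FamilySpec(name=name, gain_bias=bias, rate_mult=8.0,
                               root_count=5))
    fams.append(FamilySpec(name="CBM1", rate_mult=8.0, root_count=5))
    return SimulationPreset(n_tips=52, root_age=192.0, mk_rate=0.005,
                            base_lambda=0.002, families=fams,
                            burn_in_My=150.0, require_presence=0.2,
                            seed=seed)


def fast_family_preset(seed: int = 0, n_fast: int = 7,
                       n_total: int = 62) -> SimulationPreset:
    """Planted-signal benchmark for fast-family detection: ``n_fast``
    families evolving at 10x the baseline rate among ``n_total``, all
    lifestyle-neutral, conditioned on presence in half the species."""
    fams = [FamilySpec(name=f"FAST{i}", rate_mult=10.0, root_count=5)
            for i in range(n_fast)]
    fams += [FamilySpec(name=f"SLOW{i}", root_count=5)
             for i in range(n_total - n_fast)]
    return SimulationPreset(n_tips=52, root_age=192.0, mk_rate=0.0,
                            base_lambda=0.002, families=fams,
                            require_presence=0.5, seed=seed)


# ---------------------------------------------------------------------------
# Toy POD alignments
# ---------------------------------------------------------------------------

#: catalytic-column residues per planted type:
#: (distal_his, distal_arg, proximal_his, mn1, mn2, mn3, trp, tyr, tail_len)
POD_TEMPLATES = {
    "MnP-s": ("H", "R", "H", "E", "E", "D", "F", "F", 8),
    "MnP-l": ("H", "R", "H", "E", "E", "D", "F", "F", 22),
    "LiP": ("H", "R", "H", "A", "A", "N", "W", "F", 10),
    "VP": ("H", "R", "H", "E", "E", "D", "W", "F", 10),
    "VP-a": ("H", "R", "H", "E", "S", "D", "W", "F", 10),
    "MnP-ESD": ("H", "R", "H", "E", "S", "D", "F", "F", 10),
    "MnP-DGD": ("H", "R", "H", "D", "G", "D", "F", "F", 10),
    "MnP-DED": ("H", "R", "H", "D", "E", "D", "F", "F", 10),
    "NPOD": ("H", "H", "H", "E", "A", "Y", "F", "Y", 10),
    "GP": ("H", "R", "H", "K", "A", "N", "F", "F", 10),
}


def default_site_map(length: int = 90) -> SiteMap:
    """A site map for generated alignments of the given length; the tail
    region is the last 30 columns."""
    if length < 40:
        raise ValueError("alignment too short for the default site map")
    return SiteMap(distal_his=5, distal_arg=9, proximal_his=20,
                   mn_site_1=28, mn_site_2=33, mn_site_3=40,
                   trp_lip=46, tyr_tc=52, tail_anchor=length - 30)


def simulate_pod_alignment(subst_tree: Tree, planted_types: dict[str, str],
                           site_map: SiteMap | None = None, seed: int = 0,
                           length: int = 90, model: str = "WAG"
                           ) -> tuple[Msa, SiteMap]:
    """Toy POD alignment: catalytic columns fixed by each tip's planted
    type, other columns evolved under the substitution model on the tree.

    The C-terminal tail (columns past ``tail_anchor``) is written as
    residues up to the template's tail length and gaps beyond, so
    extract_profile recovers the planted tail length exactly.
    """
    unknown = set(planted_types.values()) - set(POD_TEMPLATES)
    if unknown:
        raise ValueError(f"unknown planted POD types: {sorted(unknown)}")
    missing = set(subst_tree.tip_names) - set(planted_types)
    if missing:
        raise ValueError(f"no planted type for tips {sorted(missing)}")
    sm = site_map or default_site_map(length)
    rng = np.random.default_rng(seed)
    sub = get_model(model)
    n_states = len(sub.pi)
    cat_cols = {c for k, c in sm.columns().items() if k != "tail_anchor"}
    tail_start = sm.tail_anchor  # 0-based index of first tail column
    # evolve all columns, then overwrite catalytic + tail regions
    seqs = {}
    states = np.zeros((subst_tree.n_nodes, length), int)
    states[subst_tree.root] = rng.choice(n_states, size=length, p=sub.pi)
    Ps = [None] + [sub.transition(float(subst_tree.blen[i]))
                   for i in range(1, subst_tree.n_nodes)]
    for i in subst_tree.preorder()[1:]:
        prev = states[subst_tree.parent[i]]
        P = Ps[i]
        u = rng.random(length)
        cum = np.cumsum(P[prev], axis=1)
        states[i] = (u[:, None] > cum).sum(axis=1)
    for ti in subst_tree.tip_indices:
        name = subst_tree.names[ti]
        tpl = POD_TEMPLATES[planted_types[name]]
        row = [sub.alphabet[s] for s in states[ti]]
        for pos, key in zip(
                tpl, ("distal_his", "distal_arg", "proximal_his", "mn_site_1",
                      "mn_site_2", "mn_site_3", "trp_lip", "tyr_tc")):
            row[getattr(sm, key) - 1] = pos
        tail_len = tpl[8]
        for j in range(tail_start, length):
            row[j] = row[j] if (j - tail_start) < tail_len else "-"
        # ensure no catalytic column falls in the erased tail zone
        for c in cat_cols:
            if c - 1 >= tail_start:
                raise ValueError("site map places catalytic columns in the tail")
        seqs[name] = "".join(row)
    msa = Msa(ids=list(seqs), rows=list(seqs.values()))
    return msa, sm
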