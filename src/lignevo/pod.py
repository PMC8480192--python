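"""Class-II peroxidase (POD) typing and ancestral-residue reconstruction.

Ligninolytic class-II peroxidases are typed from a handful of catalytic
positions read off a curated alignment: the distal His/Arg pair involved
in activation by H2O2, the proximal His, the three residues of the
Mn(2+)-oxidation site, the surface Trp of LiP/VP (long-range electron
transfer from lignin), a surface Tyr position, and the C-terminal tail
length that separates long from short MnP.  The decision rules:

1. a His/His distal pair -> NPOD; any other non-His/Arg pair -> unclassified;
2. the Mn triad is looked up: Glu/Glu/Asp (canonical), Glu/Ser/Asp (ESD),
   Asp/Gly/Asp (DGD), Asp/Glu/Asp (DED), anything else counts as no site;
3. with the catalytic Trp: canonical triad -> VP, a partial (exactly two
   acidic residues) triad -> VP-a, no triad -> LiP;
4. without the Trp: canonical triad -> MnP-l or MnP-s by tail length,
   ESD/DGD/DED -> the matching new MnP subfamily, no triad -> GP.

Ancestral catalytic residues are reconstructed by marginal
(Felsenstein-pruning) posterior probabilities under the WAG model on the
fixed POD tree, ancestors are typed with the same rules, and the first
appearance of each type is dated on a time-calibrated tree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coreio import Msa, SiteMap, Tree
from .substmodels import SubstModel, get_model

__all__ = [
    "POD_TYPES",
    "PodSiteProfile",
    "extract_profile",
    "classify_pod",
    "marginal_asr",
    "classify_ancestors",
    "map_type_origins",
    "DEFAULT_TAIL_THRESHOLD",
]

POD_TYPES = ("LiP", "VP", "VP-a", "MnP-s", "MnP-l", "MnP-ESD", "MnP-DGD",
             "MnP-DED", "NPOD", "GP", "unclassified")

#: residues past the tail anchor that make a "long" C-terminal tail
DEFAULT_TAIL_THRESHOLD = 16

_ACIDIC = {"D", "E"}
_TRIADS = {("E", "E", "D"): "canonical",
           ("E", "S", "D"): "ESD",
           ("D", "G", "D"): "DGD",
           ("D", "E", "D"): "DED"}

#: catalytic columns whose residues decide the type (surface Tyr is an
#: annotation only; proximal His is conserved across all types)
DECISIVE_SITES = ("distal_his", "distal_arg", "mn_site_1", "mn_site_2",
                  "mn_site_3", "trp_lip")


@dataclass
class PodSiteProfile:
    """Residues at the catalytic positions of one POD sequence."""

    distal_his: str
    distal_arg: str
    proximal_his: str
    mn_site_1: str
    mn_site_2: str
    mn_site_3: str
    trp_lip: str
    tyr_tc: str
    c_tail_length: int

    def __post_init__(self) -> None:
        if self.c_tail_length < 0:
            raise ValueError("tail length must be >= 0")

    @property
    def mn_triad(self) -> tuple[str, str, str]:
        return (self.mn_site_1, self.mn_site_2, self.mn_site_3)

    @property
    def has_surface_tyr(self) -> bool:
        return self.tyr_tc == "Y"


def extract_profile(msa: Msa, site_map: SiteMap, seq_id: str) -> PodSiteProfile:
    """Read one sequence's catalytic residues and tail length.

    The tail length counts non-gap residues after the ``tail_anchor``
    column; gaps at catalytic columns are recorded as ``-``, not errors.
    """
    site_map.check_against(msa)
    row = msa.row(seq_id)
    res = {k: row[c - 1] for k, c in site_map.columns().items() if k != "tail_anchor"}
    tail = row[site_map.tail_anchor:]
    return PodSiteProfile(c_tail_length=sum(ch != "-" for ch in tail), **res)


def classify_pod(profile: PodSiteProfile,
                 tail_threshold: int = DEFAULT_TAIL_THRESHOLD) -> str:
    """Map a catalytic-site profile to a POD type (total function)."""
    distal = (profile.distal_his, profile.distal_arg)
    if distal == ("H", "H"):
        return "NPOD"
    if distal != ("H", "R"):
        return "unclassified"
    triad = _TRIADS.get(profile.mn_triad)
    n_acidic = sum(r in _ACIDIC for r in profile.mn_triad)
    if profile.trp_lip == "W":
        if triad == "canonical":
            return "VP"
        if n_acidic == 2:
            return "VP-a"
        if triad == "DED":
            return "VP"      # complete three-acidic Mn site retained
        return "LiP"
    if triad == "canonical":
        return "MnP-l" if profile.c_tail_length >= tail_threshold else "MnP-s"
    if triad == "ESD":
        return "MnP-ESD"
    if triad == "DGD":
        return "MnP-DGD"
    if triad == "DED":
        return "MnP-DED"
    return "GP"


# ---------------------------------------------------------------------------
# Marginal ancestral reconstruction of catalytic columns
# ---------------------------------------------------------------------------

def _column_partials(msa: Msa, tree: Tree, col: int, model: SubstModel) -> np.ndarray:
    """Tip partial likelihoods for one alignment column (gap/X = missing)."""
    n_states = len(model.pi)
    tips = tree.tip_indices
    L = np.ones((len(tips), n_states))
    for r, ti in enumerate(tips):
        ch = msa.row(tree.names[ti])[col - 1]
        pos = model.alphabet.find(ch)
        if pos >= 0:
            L[r] = 0.0
            L[r, pos] = 1.0
    return L


def marginal_asr(tree: Tree, msa: Msa, columns, model: str | SubstModel = "WAG"
                 ) -> dict[int, pd.DataFrame]:
    """Marginal posterior state probabilities at every internal node.

    ``tree`` must be in substitutions/site with tip names matching the
    alignment ids.  Returns, per 1-based column, an internal-node x state
    DataFrame of posteriors (each row sums to 1).  Root prior = stationary
    frequencies; gaps and X are treated as missing data.
    """
    if isinstance(model, str):
        model = get_model(model)
    Ps = [None] + [model.transition(float(tree.blen[i]))
                   for i in range(1, tree.n_nodes)]
    n_states = len(model.pi)
    tips = tree.tip_indices
    tip_row = {ti: r for r, ti in enumerate(tips)}
    out: dict[int, pd.DataFrame] = {}
    for col in np.atleast_1d(columns):
        col = int(col)
        tipL = _column_partials(msa, tree, col, model)
        down: list[np.ndarray | None] = [None] * tree.n_nodes
        for i in tree.postorder():
            if tree.is_tip(i):
                down[i] = tipL[tip_row[i]]
            else:
                L = np.ones(n_states)
                for ch in tree.children[i]:
                    L = L * (Ps[ch] @ down[ch])
                s = L.sum()
                down[i] = L / (s if s > 0 else 1.0)
        up: list[np.ndarray | None] = [None] * tree.n_nodes
        up[tree.root] = model.pi.copy()
        for i in tree.preorder():
            if tree.is_tip(i):
                continue
            for ch in tree.children[i]:
                sib = np.ones(n_states)
                for w in tree.children[i]:
                    if w != ch:
                        sib = sib * (Ps[w] @ down[w])
                above = up[i] * sib
                vec = Ps[ch].T @ above
                s = vec.sum()
                up[ch] = vec / (s if s > 0 else 1.0)
        rows = {}
        for i in tree.internal_indices:
            post = down[i] * up[i]
            post = post / post.sum()
            rows[tree.names[i]] = post
        out[col] = pd.DataFrame.from_dict(rows, orient="index",
                                          columns=list(model.alphabet))
    return out


def classify_ancestors(asr: dict[int, pd.DataFrame], site_map: SiteMap,
                       tail_policy="descendant_median",
                       tail_threshold: int = DEFAULT_TAIL_THRESHOLD,
                       tree: Tree | None = None,
                       tip_tail_lengths: pd.Series | None = None,
                       ambiguity_threshold: float = 0.7) -> pd.DataFrame:
    """Type each internal node from its modal catalytic residues.

    ``tail_policy`` fixes the C-terminal tail length an ancestor is assumed
    to carry: an integer, or ``"descendant_median"`` (median over
    descendant tips, requiring ``tree`` and ``tip_tail_lengths``).  When
    the modal posterior of any decisive column falls below
    ``ambiguity_threshold`` the runner-up type (profile with that column's
    second-best residue) is reported alongside.
    """
    cols = site_map.columns()
    needed = [cols[k] for k in DECISIVE_SITES] + [cols["proximal_his"], cols["tyr_tc"]]
    missing = [c for c in needed if c not in asr]
    if missing:
        raise ValueError(f"no posteriors for catalytic columns {missing}")
    nodes = asr[needed[0]].index
    records = []
    for node in nodes:
        modal, modal_p, runner = {}, {}, {}
        for key, c in cols.items():
            if key == "tail_anchor":
                continue
            post = asr[c].loc[node]
            srt = post.sort_values(ascending=False, kind="stable")
            modal[key] = srt.index[0]
            modal_p[key] = float(srt.iloc[0])
            runner[key] = srt.index[1]
        if isinstance(tail_policy, (int, np.integer)):
            tail = int(tail_policy)
        elif tail_policy == "descendant_median":
            if tree is None or tip_tail_lengths is None:
                raise ValueError("descendant_median tail policy needs the tree "
                                 "and tip tail lengths")
            below = [tree.names[t] for t in tree.subtree_tips(tree.index_of(node))]
            tail = int(np.median(tip_tail_lengths.reindex(below).dropna()))
        else:
            raise ValueError(f"unknown tail policy {tail_policy!r}")
        prof = PodSiteProfile(c_tail_length=tail, **modal)
        ptype = classify_pod(prof, tail_threshold)
        decisive_p = {k: modal_p[k] for k in DECISIVE_SITES}
        weakest = min(decisive_p, key=decisive_p.get)
        runner_type = ""
        if decisive_p[weakest] < ambiguity_threshold:
            alt = dict(modal)
            alt[weakest] = runner[weakest]
            runner_type = classify_pod(
                PodSiteProfile(c_tail_length=tail, **alt), tail_threshold)
        records.append({
            "node": node, "pod_type": ptype, "runner_up": runner_type,
            "min_decisive_prob": decisive_p[weakest],
            "weakest_site": weakest, "tail_length": tail,
            **{f"res_{k}": modal[k] for k in modal},
            **{f"p_{k}": modal_p[k] for k in DECISIVE_SITES},
        })
    return pd.DataFrame(records).set_index("node")


def map_type_origins(time_tree: Tree, node_types: pd.Series) -> pd.DataFrame:
    """First appearances of each POD type on a dated tree.

    A node is an origin of its type when its parent bears a different type
    (or it is the root).  All independent origins are reported, oldest
    first, with the node age (My) and the parent's type.
    """
    ages = time_tree.node_ages()
    types = node_types.reindex(time_tree.names)
    if types.isna().any():
        missing = sorted(types.index[types.isna()])
        raise ValueError(f"type missing for nodes {missing}")
    rows = []
    for i in time_tree.preorder():
        t = types.iloc[i]
        if i == time_tree.root:
            rows.append((t, time_tree.names[i], float(ages[i]), "none"))
        elif types.iloc[time_tree.parent[i]] != t:
            rows.append((t, time_tree.names[i], float(ages[i]),
                         types.iloc[time_tree.parent[i]]))
    df = pd.DataFrame(rows, columns=["pod_type", "origin_node", "age_My",
                                     "parent_type"])
    return df.sort_values(["pod_type", "age_My"],
                          ascending=[True, False]).reset_index(drop=True)
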