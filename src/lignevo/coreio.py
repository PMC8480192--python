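"""Shared domain types and readers/writers for the standard formats.

The package works with four kinds of input: a rooted, time-calibrated
species tree (Newick, branch lengths in million years), a species x
gene-family copy-number matrix (TSV of non-negative integers), a lifestyle
label per species drawn from the six lignocellulose-decay classes, and —
for the peroxidase stage — an amino-acid alignment (FASTA) with a site map
naming the catalytic columns plus a tree in substitutions/site.

Trees are stored in preorder arrays (:class:`Tree`); internal nodes keep
their Newick labels when present and are otherwise auto-named ``N<k>`` in
preorder so ancestral nodes can be reported deterministically.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import yaml
from Bio import AlignIO

__all__ = [
    "LIFESTYLES",
    "AA_ALPHABET",
    "Tree",
    "GeneCountMatrix",
    "Msa",
    "SiteMap",
    "read_newick",
    "write_newick",
    "read_counts",
    "write_counts",
    "read_labels",
    "write_labels",
    "read_msa",
    "write_msa",
    "read_site_map",
    "write_site_map",
    "validate_bundle",
]

#: The six lignocellulose-decay lifestyle classes (closed set).
LIFESTYLES = (
    "white_rot",
    "brown_rot",
    "decayed_wood",
    "grass_litter",
    "forest_litter",
    "mycorrhiza",
)

#: Amino-acid alphabet in the conventional (PAML) residue order.
AA_ALPHABET = "ARNDCQEGHILKMFPSTWYV"

_ULTRAMETRIC_RTOL = 1e-6


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

@dataclass
class Tree:
    """Rooted tree in preorder arrays.

    Node 0 is the root.  ``parent[i]`` is the preorder index of node *i*'s
    parent (-1 for the root) and ``blen[i]`` the length of the branch above
    node *i* (0 for the root unless the Newick source said otherwise).

    ``unit`` records what the branch lengths mean: ``"My"`` for a
    time-calibrated tree, ``"subs"`` for expected substitutions/site.
    """

    names: list[str]
    parent: np.ndarray
    blen: np.ndarray
    children: list[list[int]]
    unit: str = "My"

    # -- basic structure ----------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.names)

    @property
    def root(self) -> int:
        return 0

    def is_tip(self, i: int) -> bool:
        return not self.children[i]

    @property
    def tip_indices(self) -> list[int]:
        return [i for i in range(self.n_nodes) if not self.children[i]]

    @property
    def internal_indices(self) -> list[int]:
        return [i for i in range(self.n_nodes) if self.children[i]]

    @property
    def tip_names(self) -> list[str]:
        return [self.names[i] for i in self.tip_indices]

    @property
    def internal_names(self) -> list[str]:
        return [self.names[i] for i in self.internal_indices]

    def index_of(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"node {name!r} not in tree") from None

    def postorder(self) -> list[int]:
        """Node indices, children before parents."""
        return list(range(self.n_nodes))[::-1]

    def preorder(self) -> list[int]:
        return list(range(self.n_nodes))

    # -- depths and ages ----------------------------------------------------

    def depths(self) -> np.ndarray:
        """Root-to-node path lengths."""
        d = np.zeros(self.n_nodes)
        for i in range(1, self.n_nodes):
            d[i] = d[self.parent[i]] + self.blen[i]
        return d

    def is_ultrametric(self, rtol: float = _ULTRAMETRIC_RTOL) -> bool:
        d = self.depths()
        tip_d = d[self.tip_indices]
        h = tip_d.max()
        return bool(h == 0 or np.all(np.abs(tip_d - h) <= rtol * h))

    def node_ages(self, rtol: float = _ULTRAMETRIC_RTOL) -> np.ndarray:
        """Node ages (time before present); requires an ultrametric tree."""
        if not self.is_ultrametric(rtol):
            raise ValueError("node ages require an ultrametric tree")
        d = self.depths()
        h = d[self.tip_indices].max()
        ages = h - d
        ages[self.tip_indices] = 0.0
        return ages

    def mrca(self, i: int, j: int) -> int:
        anc_i = set()
        a = i
        while a != -1:
            anc_i.add(a)
            a = self.parent[a]
        a = j
        while a not in anc_i:
            a = self.parent[a]
        return a

    def subtree_tips(self, i: int) -> list[int]:
        """Tip indices below node *i* (inclusive if *i* is a tip)."""
        out, stack = [], [i]
        while stack:
            v = stack.pop()
            if self.is_tip(v):
                out.append(v)
            else:
                stack.extend(reversed(self.children[v]))
        return out


def read_newick(source: str | Path, unit: str = "My") -> Tree:
    """Parse a Newick tree (path or literal string) into a :class:`Tree`.

    Rejects negative branch lengths and duplicate tip labels.  Internal
    labels present in the source are preserved; missing ones are filled in
    as ``N<k>`` in preorder.
    """
    text = source if isinstance(source, str) and source.lstrip().startswith("(") \
        else Path(source).read_text()
    try:
        dt = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"malformed Newick: {exc}") from exc

    names: list[str] = []
    parent: list[int] = []
    blen: list[float] = []
    children: list[list[int]] = []
    index: dict[int, int] = {}
    k = 0
    for nd in dt.preorder_node_iter():
        i = len(names)
        index[id(nd)] = i
        if nd.taxon is not None:
            label = nd.taxon.label
        elif nd.label:
            label = nd.label
        else:
            label = f"N{k}"
        if nd.is_internal() and not nd.label and nd.taxon is None:
            k += 1
        names.append(label)
        bl = nd.edge.length
        bl = 0.0 if bl is None else float(bl)
        if bl < 0:
            raise ValueError(f"negative branch length at node {label!r}")
        blen.append(bl)
        parent.append(index[id(nd.parent_node)] if nd.parent_node is not None else -1)
        children.append([])
    for i, p in enumerate(parent):
        if p >= 0:
            children[p].append(i)

    tree = Tree(names=names, parent=np.array(parent), blen=np.array(blen, float),
                children=children, unit=unit)
    tips = tree.tip_names
    if len(set(tips)) != len(tips):
        dup = sorted({t for t in tips if tips.count(t) > 1})
        raise ValueError(f"duplicate tip labels: {dup}")
    return tree


def write_newick(tree: Tree, path: str | Path | None = None,
                 annotations: dict[str, str] | None = None) -> str:
    """Serialize a :class:`Tree` back to Newick, byte-deterministically.

    ``annotations`` maps node names to comment strings written as
    ``[&...]`` after the node, e.g. ancestral counts or lifestyle labels.
    """
    ann = annotations or {}

    def fmt(i: int) -> str:
        name = tree.names[i]
        note = f"[&{ann[name]}]" if name in ann else ""
        if tree.is_tip(i):
            return f"{name}{note}:{tree.blen[i]:.12g}"
        inner = ",".join(fmt(c) for c in tree.children[i])
        return f"({inner}){name}{note}:{tree.blen[i]:.12g}"

    text = fmt(tree.root) + ";\n"
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# Gene-count matrices and lifestyle labels
# ---------------------------------------------------------------------------

@dataclass
class GeneCountMatrix:
    """Species x gene-family copy numbers with a role tag per family.

    ``counts`` is an integer DataFrame (rows = species, columns = families);
    ``roles`` maps each family to ``"focal"`` (a cell-wall-degrading enzyme
    family under study) or ``"background"`` (a control family not expected
    to carry decay signal).
    """

    counts: pd.DataFrame
    roles: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not np.issubdtype(self.counts.values.dtype, np.integer):
            vals = self.counts.values
            if not np.allclose(vals, np.round(vals)):
                raise ValueError("gene counts must be integers")
            self.counts = self.counts.astype(int)
        if (self.counts.values < 0).any():
            raise ValueError("gene counts must be non-negative")
        if self.roles is None:
            self.roles = pd.Series("focal", index=self.counts.columns)
        self.roles = self.roles.reindex(self.counts.columns).fillna("focal")

    @property
    def species(self) -> list[str]:
        return list(self.counts.index)

    @property
    def families(self) -> list[str]:
        return list(self.counts.columns)

    def focal(self) -> pd.DataFrame:
        return self.counts.loc[:, self.roles == "focal"]

    def background(self) -> pd.DataFrame:
        return self.counts.loc[:, self.roles == "background"]


def read_counts(path: str | Path, roles: pd.Series | dict | None = None) -> GeneCountMatrix:
    """Read a species x family count TSV (header = family ids).

    An optional ``#role:`` comment line directly under the header, of the
    form ``#role<TAB>focal<TAB>background...``, carries the per-family role
    tags; a ``roles`` argument overrides it.
    """
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    role_line = None
    data_lines = []
    for ln in lines:
        if ln.startswith("#role"):
            role_line = ln
        elif ln.startswith("#"):
            continue
        else:
            data_lines.append(ln)
    df = pd.read_csv(_io.StringIO("\n".join(data_lines)), sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise ValueError("count table has no family columns")
    if df.isna().any().any():
        raise ValueError("ragged or non-numeric count table")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            raise ValueError(f"non-numeric cells in family column {col!r}")
    vals = df.values.astype(float)
    if not np.allclose(vals, np.round(vals)):
        raise ValueError("non-integer gene counts")
    if (vals < 0).any():
        raise ValueError("negative gene counts")
    role_series = None
    if role_line is not None:
        parts = role_line.split("\t")[1:]
        role_series = pd.Series(parts, index=df.columns[: len(parts)])
    if roles is not None:
        role_series = pd.Series(roles)
    return GeneCountMatrix(counts=df.astype(int), roles=role_series)


def write_counts(gcm: GeneCountMatrix, path: str | Path,
                 provenance: str | None = None) -> None:
    buf = _io.StringIO()
    if provenance:
        buf.write(f"# {provenance}\n")
    buf.write("species\t" + "\t".join(gcm.families) + "\n")
    buf.write("#role\t" + "\t".join(gcm.roles.astype(str)) + "\n")
    for sp in gcm.species:
        row = gcm.counts.loc[sp]
        buf.write(sp + "\t" + "\t".join(str(int(v)) for v in row) + "\n")
    Path(path).write_text(buf.getvalue())


def read_labels(path: str | Path, strict: bool = True) -> pd.Series:
    """Read a two-column TSV of node/species id -> lifestyle."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["id", "lifestyle"], dtype=str)
    ser = pd.Series(df["lifestyle"].values, index=df["id"].values, name="lifestyle")
    if strict:
        bad = sorted(set(ser) - set(LIFESTYLES))
        if bad:
            raise ValueError(f"labels outside the lifestyle set: {bad}")
    return ser


def write_labels(labels: pd.Series, path: str | Path,
                 provenance: str | None = None) -> None:
    lines = ([f"# {provenance}"] if provenance else []) + \
        [f"{k}\t{v}" for k, v in labels.items()]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Alignments and site maps
# ---------------------------------------------------------------------------

_MSA_OK = set(AA_ALPHABET) | {"-", "X"}


@dataclass
class Msa:
    """An amino-acid multiple alignment: parallel id and row lists."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("alignment rows have unequal lengths")
        bad = set("".join(self.rows).upper()) - _MSA_OK
        if bad:
            raise ValueError(f"alignment contains non-amino-acid symbols: {sorted(bad)}")
        self.rows = [r.upper() for r in self.rows]

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, seq_id: str) -> str:
        try:
            return self.rows[self.ids.index(seq_id)]
        except ValueError:
            raise KeyError(f"sequence {seq_id!r} not in alignment") from None

    def column(self, col_1based: int) -> str:
        if not 1 <= col_1based <= self.length:
            raise IndexError(f"column {col_1based} outside alignment of length {self.length}")
        return "".join(r[col_1based - 1] for r in self.rows)


def read_msa(path: str | Path) -> Msa:
    aln = AlignIO.read(str(path), "fasta")
    return Msa(ids=[rec.id for rec in aln], rows=[str(rec.seq) for rec in aln])


def write_msa(msa: Msa, path: str | Path) -> None:
    lines = []
    for sid, row in zip(msa.ids, msa.rows):
        lines.append(f">{sid}")
        lines.append(row)
    Path(path).write_text("\n".join(lines) + "\n")


_SITE_KEYS = ("distal_his", "distal_arg", "proximal_his",
              "mn_site_1", "mn_site_2", "mn_site_3",
              "trp_lip", "tyr_tc", "tail_anchor")


@dataclass
class SiteMap:
    """1-based alignment columns of the catalytic residues of a class-II
    peroxidase: the distal His/Arg pair (activation by H2O2), the proximal
    His, the three residues of the Mn(2+)-oxidation site, the surface
    Trp (LiP/VP) and Tyr positions, and the last conserved column before
    the C-terminal tail."""

    distal_his: int
    distal_arg: int
    proximal_his: int
    mn_site_1: int
    mn_site_2: int
    mn_site_3: int
    trp_lip: int
    tyr_tc: int
    tail_anchor: int

    def __post_init__(self) -> None:
        cols = [getattr(self, k) for k in _SITE_KEYS]
        if any(c < 1 for c in cols):
            raise ValueError("site-map columns are 1-based and must be >= 1")
        if len(set(cols)) != len(cols):
            raise ValueError("site-map columns must be distinct")

    def columns(self) -> dict[str, int]:
        return {k: getattr(self, k) for k in _SITE_KEYS}

    def check_against(self, msa: Msa) -> None:
        for k, c in self.columns().items():
            if c > msa.length:
                raise ValueError(f"site {k} column {c} outside alignment length {msa.length}")


def read_site_map(path: str | Path) -> SiteMap:
    data = yaml.safe_load(Path(path).read_text())
    return SiteMap(**{k: int(data[k]) for k in _SITE_KEYS})


def write_site_map(sm: SiteMap, path: str | Path) -> None:
    lines = [f"{k}: {getattr(sm, k)}" for k in _SITE_KEYS]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Cross-validation of a data bundle
# ---------------------------------------------------------------------------

def validate_bundle(tree: Tree | None = None,
                    counts: GeneCountMatrix | None = None,
                    labels: pd.Series | None = None,
                    msa: Msa | None = None,
                    site_map: SiteMap | None = None) -> list[str]:
    """Cross-check id sets between the supplied inputs.

    Returns a list of human-readable mismatch descriptions; an empty list
    means the bundle is internally consistent.
    """
    report: list[str] = []
    if tree is not None and counts is not None:
        tips, rows = set(tree.tip_names), set(counts.species)
        for sp in sorted(rows - tips):
            report.append(f"species {sp!r} in counts but not a tree tip")
        for sp in sorted(tips - rows):
            report.append(f"tree tip {sp!r} missing from counts")
    if labels is not None:
        for sp, lab in labels.items():
            if lab not in LIFESTYLES:
                report.append(f"label {lab!r} for {sp!r} outside the lifestyle set")
        if tree is not None:
            known = set(tree.names)
            for sp in sorted(set(labels.index) - known):
                report.append(f"labelled id {sp!r} not a tree node")
            for sp in sorted(set(tree.tip_names) - set(labels.index)):
                report.append(f"tree tip {sp!r} has no lifestyle label")
    if msa is not None and tree is not None and tree.unit == "subs":
        seqs, tips = set(msa.ids), set(tree.tip_names)
        for sid in sorted(tips - seqs):
            report.append(f"tree tip {sid!r} missing from alignment")
        for sid in sorted(seqs - tips):
            report.append(f"sequence {sid!r} not a tree tip")
    if msa is not None and site_map is not None:
        try:
            site_map.check_against(msa)
        except ValueError as exc:
            report.append(str(exc))
    return report
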