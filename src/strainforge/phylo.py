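"""Consensus-genome phylogenetics.

All consensus genomes are called against one shared reference, so they are
already positionally aligned; the "core" of the alignment is simply the set
of columns where every strain is callable (non-N), restricted to contiguous
blocks of at least ell_min bp (default 100) so that isolated callable
islands inside repeat deserts do not contribute.  Distances are p-distances
with a Jukes-Cantor correction, and the tree is inferred by neighbor
joining — on near-identical genomes the topology, which is the quantity of
interest (does the derived pathogenic strain branch inside the donor
clade?), is insensitive to the substitution model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from ._util import seq_to_array


@dataclass
class CoreAlignment:
    taxa: list[str]
    columns: np.ndarray          # reference positions retained
    matrix: np.ndarray           # (n_taxa, n_columns) uint8 base codes
    blocks: list[tuple[int, int]]

    @property
    def length(self) -> int:
        return int(self.matrix.shape[1])

    def row(self, taxon: str) -> str:
        return self.matrix[self.taxa.index(taxon)].tobytes().decode()


def extract_core(consensus: dict[str, str], ell_min: int = 100) -> CoreAlignment:
    """Columns where every consensus genome is non-N, kept only within
    maximal runs of length >= ell_min."""
    taxa = list(consensus)
    if not taxa:
        raise ValueError("no genomes given")
    lengths = {len(s) for s in consensus.values()}
    if len(lengths) != 1:
        raise ValueError("consensus genomes must share one reference coordinate "
                         f"frame (got lengths {sorted(lengths)})")
    arrs = np.stack([seq_to_array(consensus[t]) for t in taxa])
    callable_cols = (arrs != ord("N")).all(axis=0)
    blocks: list[tuple[int, int]] = []
    idx = np.nonzero(callable_cols)[0]
    if len(idx):
        start = prev = int(idx[0])
        for i in idx[1:]:
            i = int(i)
            if i != prev + 1:
                if prev + 1 - start >= ell_min:
                    blocks.append((start, prev + 1))
                start = i
            prev = i
        if prev + 1 - start >= ell_min:
            blocks.append((start, prev + 1))
    keep = np.concatenate([np.arange(s, e) for s, e in blocks]) if blocks \
        else np.array([], dtype=int)
    return CoreAlignment(taxa, keep, arrs[:, keep], blocks)


@dataclass
class StrainDistances:
    taxa: list[str]
    p: np.ndarray        # proportion of mismatching core columns
    jc69: np.ndarray     # -(3/4) ln(1 - 4p/3); NaN where p >= 0.75
    saturated: bool      # any pair beyond the JC69 domain

    def as_skbio(self, corrected: bool = True) -> DistanceMatrix:
        d = self.jc69 if corrected else self.p
        return DistanceMatrix(d, ids=self.taxa)


def distances(core: CoreAlignment) -> StrainDistances:
    n = len(core.taxa)
    if n < 2:
        raise ValueError("need at least two taxa")
    if core.length == 0:
        raise ValueError("empty core alignment")
    p = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p[i, j] = p[j, i] = np.count_nonzero(
                core.matrix[i] != core.matrix[j]) / core.length
    with np.errstate(invalid="ignore"):
        jc = np.where(p < 0.75, -0.75 * np.log1p(-4.0 * p / 3.0), np.nan)
    np.fill_diagonal(jc, 0.0)
    return StrainDistances(list(core.taxa), p, jc, saturated=bool(np.isnan(jc).any()))


def nj_tree(dist: StrainDistances | DistanceMatrix, corrected: bool = True) -> TreeNode:
    """Neighbor-joining tree; ties in the Q criterion resolve to the
    lowest-index pair (deterministic).  With fewer than three taxa a trivial
    star is returned with a warning."""
    dm = dist.as_skbio(corrected) if isinstance(dist, StrainDistances) else dist
    if dm.shape[0] < 3:
        import warnings

        warnings.warn("fewer than 3 taxa: returning trivial tree")
        tree = TreeNode(name=None)
        for t in dm.ids:
            tree.append(TreeNode(name=t, length=float(dm[dm.ids[0], t]) / 2))
        return tree
    tree = nj(dm)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0  # NJ can emit tiny negative branches; clamp
    return tree


def is_clade(tree: TreeNode, taxa_subset) -> bool:
    """True iff some edge bipartition of the (unrooted) tree isolates
    exactly this taxon set."""
    subset = frozenset(taxa_subset)
    leaves = frozenset(t.name for t in tree.tips())
    unknown = subset - leaves
    if unknown:
        raise KeyError(f"taxa not in tree: {sorted(unknown)}")
    if not subset:
        return False
    if subset == leaves or len(subset) == 1:
        return True
    for node in tree.non_tips(include_self=True):
        below = frozenset(t.name for t in node.tips())
        if below == subset or leaves - below == subset:
            return True
    return False


def write_newick(tree: TreeNode, path) -> None:
    with open(path, "w") as f:
        f.write(str(tree).strip() + "\n")


def write_phylip_distances(dist: StrainDistances, path, corrected: bool = True) -> None:
    d = dist.jc69 if corrected else dist.p
    with open(path, "w") as f:
        f.write(f"{len(dist.taxa)}\n")
        for i, t in enumerate(dist.taxa):
            row = " ".join(f"{d[i, j]:.8f}" for j in range(len(dist.taxa)))
            f.write(f"{t:<12s} {row}\n")
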