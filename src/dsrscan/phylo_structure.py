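"""Distance matrices, neighbor-joining phylogeny with locus bootstrap,
and the Evanno delta-K diagnostic for STRUCTURE-style output tables.

Distances: at the individual level the allele-sharing distance
d(i,j) = 1 - (1/(2 L_ij)) * sum_l (2 - |g_i - g_j|) over loci called in
both individuals; at the breed level the pairwise multi-locus
Weir-Cockerham theta (clamped at 0).  Trees are built by the classical
Saitou-Nei neighbor-joining agglomeration on the Q criterion with a
deterministic lexicographic tie-break, and internal-edge supports come
from resampling loci with replacement.

Evanno delta-K: for interior K, the mean over replicates of the
absolute second difference |L(K+1) - 2 L(K) + L(K-1)| of the log
probability of the data, divided by the replicate standard deviation
s(K); the argmax over interior K suggests the number of clusters.
"""

from __future__ import annotations

import dataclasses
import io
import logging
import math
from typing import Iterator, Sequence

import dendropy
import numpy as np
import pandas as pd

from .diffstat import Contrast, fst_scan, multilocus_theta
from .matrix import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


# ------------------------------------------------------------------ distances
@dataclasses.dataclass
class DistanceMatrix:
    """Symmetric non-negative distances with a zero diagonal."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("distance matrix diagonal is not zero")
        if (self.d < 0).any() or not np.isfinite(self.d).all():
            raise ValueError("distances must be finite and non-negative")

    def to_phylip(self) -> str:
        lines = [str(len(self.labels))]
        for lab, row in zip(self.labels, self.d):
            lines.append(lab + "  " + "  ".join(f"{x:.10g}" for x in row))
        return "\n".join(lines) + "\n"


def allele_sharing_distance(
    m: GenotypeMatrix, level: str = "individual"
) -> DistanceMatrix:
    """Pairwise distances between individuals or breeds.

    individual: 1 minus half the mean number of shared alleles
    (2 - |g_i - g_j| for genotype codes) over co-called loci — 0 for
    identical genotype vectors, 1 for opposite homozygotes everywhere.
    breed: pairwise multi-locus WC theta between single-breed groups,
    clamped at zero.
    """
    if level == "individual":
        labels = list(m.sample_ids)
        g = m.genotypes.astype(np.int16)
        called = g != MISSING
        n = len(labels)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                both = called[i] & called[j]
                L = int(both.sum())
                if L == 0:
                    raise ValueError(
                        f"samples {labels[i]} and {labels[j]} share no called loci"
                    )
                shared = (2 - np.abs(g[i, both] - g[j, both])).sum()
                d[i, j] = d[j, i] = 1.0 - shared / (2.0 * L)
        return DistanceMatrix(labels=labels, d=d)
    if level == "breed":
        labels = m.breeds
        if len(labels) < 2:
            raise ValueError("need at least two breeds")
        n = len(labels)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                contrast = Contrast(
                    f"{labels[i]}_vs_{labels[j]}", {labels[i]}, {labels[j]}
                )
                theta = multilocus_theta(fst_scan(m, contrast))
                if theta < 0:
                    logger.warning(
                        "negative multilocus theta %.3g for %s/%s clamped to 0",
                        theta, labels[i], labels[j],
                    )
                    theta = 0.0
                d[i, j] = d[j, i] = theta
        return DistanceMatrix(labels=labels, d=d)
    raise ValueError(f"unknown level {level!r} (expected 'individual' or 'breed')")


# ----------------------------------------------------------------------- tree
class TreeNode:
    """Minimal tree node: leaves carry names, edges carry lengths, and
    internal edges may carry a bootstrap support percentage."""

    __slots__ = ("name", "length", "support", "children")

    def __init__(
        self,
        name: str | None = None,
        length: float | None = None,
        support: float | None = None,
        children: list["TreeNode"] | None = None,
    ) -> None:
        self.name = name
        self.length = length
        self.support = support
        self.children = children if children is not None else []

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> Iterator["TreeNode"]:
        if self.is_leaf:
            yield self
        else:
            for c in self.children:
                yield from c.leaves()

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]


@dataclasses.dataclass
class PhyloTree:
    """Unrooted tree (stored rooted at a basal multifurcation) with
    branch lengths and optional internal-edge bootstrap supports."""

    root: TreeNode
    labels: list[str]

    # --------------------------------------------------------------- Newick
    def to_newick(self, decimals: int = 10) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                body = node.name
            else:
                inner = ",".join(fmt(c) for c in node.children)
                sup = "" if node.support is None else f"{node.support:g}"
                body = f"({inner}){sup}"
            if node.length is None:
                return body
            return f"{body}:{node.length:.{decimals}g}"

        return fmt(self.root) + ";"

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )

        def convert(nd: dendropy.Node) -> TreeNode:
            children = [convert(c) for c in nd.child_nodes()]
            name = nd.taxon.label if nd.taxon is not None else None
            support = None
            if children and nd.label is not None:
                try:
                    support = float(nd.label)
                except ValueError:
                    name = nd.label
            out = TreeNode(
                name=name, length=nd.edge.length, support=support, children=children
            )
            return out

        root = convert(tree.seed_node)
        return cls(root=root, labels=root.leaf_names())

    # --------------------------------------------------------- bipartitions
    def bipartitions(self) -> dict[frozenset[str], TreeNode]:
        """Internal-edge bipartitions keyed by the leaf set on the child
        side of the edge, canonicalised to the side not containing the
        first label (so keys are rooting-invariant)."""
        all_leaves = frozenset(self.labels)
        ref = self.labels[0]
        out: dict[frozenset[str], TreeNode] = {}

        def walk(node: TreeNode) -> frozenset[str]:
            if node.is_leaf:
                return frozenset([node.name])
            below = frozenset().union(*(walk(c) for c in node.children))
            if node is not self.root and 1 < len(below) < len(all_leaves) - 1:
                key = below if ref not in below else all_leaves - below
                out[key] = node
            return below

        walk(self.root)
        return out

    # ------------------------------------------------------------ distances
    def patristic_distances(self) -> DistanceMatrix:
        """Leaf-to-leaf path-length distances induced by the tree."""
        labels = sorted(self.labels)
        index = {lab: i for i, lab in enumerate(labels)}
        n = len(labels)
        d = np.zeros((n, n))

        def walk(node: TreeNode) -> dict[str, float]:
            if node.is_leaf:
                return {node.name: 0.0}
            child_maps = []
            for c in node.children:
                cm = walk(c)
                edge = c.length if c.length is not None else 0.0
                child_maps.append({k: v + edge for k, v in cm.items()})
            for a in range(len(child_maps)):
                for b in range(a + 1, len(child_maps)):
                    for la, va in child_maps[a].items():
                        for lb, vb in child_maps[b].items():
                            dist = va + vb
                            d[index[la], index[lb]] = dist
                            d[index[lb], index[la]] = dist
            merged: dict[str, float] = {}
            for cm in child_maps:
                merged.update(cm)
            return merged

        walk(self.root)
        return DistanceMatrix(labels=labels, d=d)


def neighbor_joining(dm: DistanceMatrix, clamp_negative: bool = False) -> PhyloTree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    At each step the pair (i, j) minimising
    Q(i,j) = (N-2) d(i,j) - sum_k d(i,k) - sum_k d(j,k)
    is joined, with ties broken by the lowest (i, j) pair in the current
    node order (creation order, so runs are reproducible).  Branch
    lengths use the standard closed forms; negative estimates are kept
    with a warning unless ``clamp_negative``.
    """
    n = len(dm.labels)
    if n < 2:
        raise ValueError("need at least two labels")
    nodes: list[TreeNode] = [TreeNode(name=lab) for lab in dm.labels]
    if n == 2:
        edge = float(dm.d[0, 1])
        nodes[1].length = edge
        root = TreeNode(children=[nodes[0], nodes[1]])
        return PhyloTree(root=root, labels=list(dm.labels))
    d = dm.d.astype(float).copy()
    active = list(range(n))

    def set_length(node: TreeNode, value: float) -> None:
        if value < 0:
            if clamp_negative:
                value = 0.0
            else:
                logger.warning("negative NJ branch length %.3g retained", value)
        node.length = float(value)

    while len(active) > 3:
        N = len(active)
        sub = d[np.ix_(active, active)]
        sums = sub.sum(axis=1)
        q = (N - 2) * sub - sums[:, None] - sums[None, :]
        np.fill_diagonal(q, np.inf)
        best = None
        for a in range(N):
            for b in range(a + 1, N):
                if best is None or q[a, b] < q[best] - 1e-12:
                    best = (a, b)
        a, b = best
        i, j = active[a], active[b]
        dij = d[i, j]
        vi = dij / 2 + (sums[a] - sums[b]) / (2 * (N - 2))
        vj = dij - vi
        parent = TreeNode(children=[nodes[i], nodes[j]])
        set_length(nodes[i], vi)
        set_length(nodes[j], vj)
        # distances from the new node to every remaining active node
        new_row = np.zeros(d.shape[0] + 1)
        for c in range(N):
            k = active[c]
            if k in (i, j):
                continue
            new_row[k] = (d[i, k] + d[j, k] - dij) / 2
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row[:-1]
        d[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]
    # final trifurcation closed forms
    i, j, k = active
    dij, dik, djk = d[i, j], d[i, k], d[j, k]
    root = TreeNode(children=[nodes[i], nodes[j], nodes[k]])
    set_length(nodes[i], (dij + dik - djk) / 2)
    set_length(nodes[j], (dij + djk - dik) / 2)
    set_length(nodes[k], (dik + djk - dij) / 2)
    return PhyloTree(root=root, labels=list(dm.labels))


def bootstrap_support(
    m: GenotypeMatrix,
    n_reps: int = 100,
    seed: int = 0,
    level: str = "individual",
    clamp_negative: bool = False,
) -> PhyloTree:
    """Point-estimate NJ tree with locus-bootstrap supports.

    Loci are resampled with replacement ``n_reps`` times; each internal
    bipartition of the point-estimate tree is scored by the percentage
    of replicate trees containing it.  Deterministic for a fixed seed.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    point = neighbor_joining(
        allele_sharing_distance(m, level=level), clamp_negative=clamp_negative
    )
    targets = point.bipartitions()
    counts = {key: 0 for key in targets}
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        idx = rng.integers(0, m.n_loci, size=m.n_loci)
        rep = neighbor_joining(
            allele_sharing_distance(m.take_loci(idx), level=level),
            clamp_negative=clamp_negative,
        )
        rep_bips = set(rep.bipartitions())
        for key in counts:
            if key in rep_bips:
                counts[key] += 1
    for key, node in targets.items():
        node.support = 100.0 * counts[key] / n_reps
    return point


# ------------------------------------------------------------------ Evanno dK
@dataclasses.dataclass
class DeltaKResult:
    """Per-K Evanno statistics and the suggested optimal K."""

    table: pd.DataFrame  # K, mean_lnP, sd_lnP, mean_abs_lppK (|L''|), delta_k
    optimal_k: int
    tied: bool = False


def read_lnp_table(path) -> pd.DataFrame:
    """Read a 3-column TSV (K, replicate, lnP)."""
    return pd.read_csv(
        path, sep="\t", header=None, names=["K", "replicate", "lnP"],
        comment="#",
    ).astype({"K": int, "replicate": int, "lnP": float})


def evanno_delta_k(table: pd.DataFrame) -> DeltaKResult:
    """Evanno delta-K from a (K, replicate, lnP) long table.

    Requires at least 3 contiguous K values and >= 2 replicates per K;
    second differences are taken per replicate and averaged in absolute
    value, then divided by the replicate standard deviation (ddof=1) of
    lnP at K.  Zero variance at an interior K is an error.  A flat
    (zero-curvature) profile yields all delta-K equal; the result is
    then reported as a tie with a warning.
    """
    df = table[["K", "replicate", "lnP"]].copy()
    ks = np.sort(df["K"].unique())
    if len(ks) < 3:
        raise ValueError("Evanno delta-K needs at least 3 distinct K values")
    if not np.array_equal(ks, np.arange(ks[0], ks[-1] + 1)):
        raise ValueError("K range must be contiguous")
    reps_per_k = df.groupby("K")["replicate"].nunique()
    if (reps_per_k < 2).any():
        raise ValueError("need >= 2 replicates per K")
    wide = df.pivot_table(index="replicate", columns="K", values="lnP")
    if wide.isna().any().any():
        raise ValueError("every replicate needs an lnP at every K")
    mean_lnp = wide.mean(axis=0)
    sd_lnp = wide.std(axis=0, ddof=1)
    rows = []
    for k in ks:
        row = {
            "K": int(k),
            "mean_lnP": float(mean_lnp[k]),
            "sd_lnP": float(sd_lnp[k]),
            "mean_abs_lppK": math.nan,
            "delta_k": math.nan,
        }
        if ks[0] < k < ks[-1]:
            lpp = wide[k + 1] - 2 * wide[k] + wide[k - 1]
            row["mean_abs_lppK"] = float(lpp.abs().mean())
            if sd_lnp[k] == 0:
                raise ValueError(f"zero variance of lnP at K={k}")
            row["delta_k"] = row["mean_abs_lppK"] / float(sd_lnp[k])
        rows.append(row)
    out = pd.DataFrame(rows)
    interior = out.dropna(subset=["delta_k"])
    best = interior["delta_k"].max()
    winners = interior.loc[np.isclose(interior["delta_k"], best), "K"].tolist()
    tied = len(winners) > 1
    if tied:
        logger.warning(
            "delta-K is tied across K=%s; optimal K is ill-defined", winners
        )
    return DeltaKResult(table=out, optimal_k=int(winners[0]), tied=tied)
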