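"""Nei D_A genetic distance, neighbor-joining trees, bootstrap supports.

D_A between populations X and Y over r loci with per-locus allele
frequencies x_ij, y_ij:

    D_A = 1 - (1/r) * sum_j sum_i sqrt(x_ij * y_ij)

(Nei, Tajima & Tateno 1983); a biallelic locus contributes
sqrt(p_x p_y) + sqrt(q_x q_y).  D_A is 0 for identical frequency profiles
and 1 for disjoint fixation, and is not additive — the NJ tree on it is the
standard population-level summary.

Neighbor joining is the Saitou–Nei agglomeration with the Q-criterion; ties
are broken deterministically by the lexicographically smallest pair of clade
names (a clade is named after its smallest leaf label), so results are exact
and reproducible.  Negative branch lengths can arise on non-additive inputs
and are retained in the data structure; the Newick writer clamps them to 0
only when asked.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .genio import GenotypeDataset
from .diversity import pop_allele_freq

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PopDistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0):
            raise ValueError("diagonal must be zero")
        if (d < -1e-12).any():
            raise ValueError("distances must be non-negative")
        object.__setattr__(self, "d", d)


@dataclass
class TreeNode:
    """Node of an (un)rooted tree; leaves carry population labels."""

    label: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: float | None = None  # percent of bootstrap replicates

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out


@dataclass
class PhyloTree:
    """Unrooted tree stored rooted at the final (trifurcating) NJ node."""

    root: TreeNode
    labels: list[str]

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial bipartitions, each as the frozenset not containing the
        first label (canonical side)."""
        all_labels = set(self.labels)
        first = self.labels[0]
        out = set()

        def walk(node):
            for child, _ in node.children:
                clade = set(child.leaves())
                if 1 < len(clade) < len(all_labels) - 1:
                    side = clade if first not in clade else all_labels - clade
                    out.add(frozenset(side))
                walk(child)

        walk(self.root)
        return out

    def internal_nodes(self) -> list[TreeNode]:
        out = []

        def walk(node):
            if not node.is_leaf:
                out.append(node)
                for child, _ in node.children:
                    walk(child)

        walk(self.root)
        return out

    def path_distance(self, a: str, b: str) -> float:
        """Sum of branch lengths on the path between two leaves."""
        pa = _path_to_leaf(self.root, a)
        pb = _path_to_leaf(self.root, b)
        if pa is None or pb is None:
            raise KeyError("leaf not found")
        # strip common prefix
        k = 0
        while k < min(len(pa), len(pb)) and pa[k][0] is pb[k][0]:
            k += 1
        return sum(bl for _, bl in pa[k:]) + sum(bl for _, bl in pb[k:])

    def newick(self, clamp_negative: bool = False) -> str:
        def fmt(node) -> str:
            if node.is_leaf:
                return node.label
            parts = []
            for child, bl in node.children:
                if clamp_negative:
                    bl = max(bl, 0.0)
                sup = ""
                if not child.is_leaf and child.support is not None:
                    sup = str(int(round(child.support)))
                parts.append(f"{fmt(child)}{sup if not child.is_leaf else ''}:{bl:.10g}")
            return "(" + ",".join(parts) + ")"

        return fmt(self.root) + ";"


def _path_to_leaf(node, target, acc=()):
    if node.is_leaf:
        return list(acc) if node.label == target else None
    for child, bl in node.children:
        hit = _path_to_leaf(child, target, acc + ((child, bl),))
        if hit is not None:
            return hit
    return None


def nei_da_pair(x: list[np.ndarray], y: list[np.ndarray]) -> float:
    """D_A from per-locus allele-frequency vectors (each summing to 1).

    Loci where either profile is undefined (NaN) are dropped from r.
    """
    if len(x) != len(y):
        raise ValueError("populations must share the same loci")
    total = 0.0
    r = 0
    for xv, yv in zip(x, y):
        xv = np.asarray(xv, dtype=float)
        yv = np.asarray(yv, dtype=float)
        if np.isnan(xv).any() or np.isnan(yv).any():
            continue
        total += float(np.sqrt(xv * yv).sum())
        r += 1
    if r == 0:
        raise ValueError("no locus defined in both populations")
    return 1.0 - total / r


def _freq_profiles(freq: np.ndarray) -> list[np.ndarray]:
    return [np.array([p, 1 - p]) for p in freq]


def da_matrix(ds: GenotypeDataset) -> PopDistanceMatrix:
    """Pairwise Nei D_A over all populations from per-population allele
    frequencies."""
    pops = ds.populations
    freqs = {p: pop_allele_freq(ds, p) for p in pops}
    K = len(pops)
    d = np.zeros((K, K))
    for i in range(K):
        for j in range(i + 1, K):
            fi, fj = freqs[pops[i]], freqs[pops[j]]
            ok = ~(np.isnan(fi) | np.isnan(fj))
            if not ok.any():
                raise ValueError(f"no shared defined loci for {pops[i]}, {pops[j]}")
            val = 1.0 - float(
                (np.sqrt(fi[ok] * fj[ok]) + np.sqrt((1 - fi[ok]) * (1 - fj[ok]))).mean()
            )
            d[i, j] = d[j, i] = max(val, 0.0)
    return PopDistanceMatrix(pops, d)


def neighbor_joining(dm: PopDistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    At each step the pair minimizing Q(i,j) = (n−2)·d(i,j) − r_i − r_j is
    joined; exact Q ties resolve to the lexicographically smallest pair of
    clade names.  The returned tree is unrooted (trifurcating root).
    """
    labels = list(dm.labels)
    n = len(labels)
    if n < 3:
        raise ValueError("need >= 3 taxa")
    d = dm.d.copy()
    nodes = [TreeNode(label=l) for l in labels]
    names = list(labels)  # canonical clade name: smallest leaf label

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                key = (q, *sorted((names[i], names[j])))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = d[i, j] / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        new = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        dnew = 0.5 * (d[i] + d[j] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d2 = np.zeros((m - 1, m - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = dnew[keep]
        d = d2
        nodes = [nodes[k] for k in keep] + [new]
        names = [names[k] for k in keep] + [min(names[i], names[j])]

    # three-point formulas for the final trifurcation
    (a, b, c) = nodes
    la = (d[0, 1] + d[0, 2] - d[1, 2]) / 2
    lb = (d[0, 1] + d[1, 2] - d[0, 2]) / 2
    lc = (d[0, 2] + d[1, 2] - d[0, 1]) / 2
    root = TreeNode(children=[(a, la), (b, lb), (c, lc)])
    return PhyloTree(root=root, labels=labels)


def bootstrap_tree(
    ds: GenotypeDataset, n_reps: int = 1000, seed: int = 0
) -> PhyloTree:
    """NJ tree on the full data with bootstrap supports over loci.

    Loci are resampled with replacement ``n_reps`` times; each internal node
    of the point-estimate tree gets the percentage of replicates whose NJ
    tree contains the same bipartition.  ``n_reps=0`` returns the point tree
    with supports absent.
    """
    tree = neighbor_joining(da_matrix(ds))
    if n_reps == 0:
        return tree
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {bp: 0 for bp in tree.bipartitions()}
    for _ in range(n_reps):
        idx = rng.integers(0, ds.n_snps, size=ds.n_snps)
        rep = ds.subset(snp_idx=np.sort(idx))
        rep_tree = neighbor_joining(da_matrix(rep))
        for bp in rep_tree.bipartitions():
            if bp in counts:
                counts[bp] += 1
    all_labels = set(tree.labels)
    first = tree.labels[0]
    for node in tree.internal_nodes():
        if node is tree.root:
            continue
        clade = set(node.leaves())
        if 1 < len(clade) < len(all_labels) - 1:
            side = clade if first not in clade else all_labels - clade
            bp = frozenset(side)
            if bp in counts:
                node.support = 100.0 * counts[bp] / n_reps
    return tree


def write_newick(tree: PhyloTree, path, clamp_negative: bool = False) -> None:
    """Write standard Newick with branch lengths and integer internal-node
    support labels."""
    with open(path, "w") as fh:
        fh.write(tree.newick(clamp_negative=clamp_negative) + "\n")
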