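"""Distance-based phylogeny of mtDNA haplotypes.

Pairwise distances (p-distance, Kimura 2-parameter, or HKY-corrected via
numerical maximum likelihood), Saitou–Nei neighbour joining with
deterministic tie-breaking, non-parametric bootstrap support, and clade
assignment of query haplotypes against labelled reference haplotypes.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize_scalar

from .errors import ValidationError
from .io_formats import SequenceSet

log = logging.getLogger(__name__)

SATURATION_CAP = 5.0  # distance assigned when the log correction diverges

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_PURINES = (0, 2)


def encode_sequences(sset: SequenceSet) -> np.ndarray:
    """(n, L) int8 matrix; A,C,G,T -> 0..3, anything else -> -1."""
    sset.require_alignment()
    arr = np.full((len(sset), len(sset.seqs[0]) if sset.seqs else 0), -1, dtype=np.int8)
    for i, seq in enumerate(sset.seqs):
        for j, ch in enumerate(seq):
            arr[i, j] = _CODE.get(ch, -1)
    return arr


def _pair_pq(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """Transition and transversion proportions over pairwise-complete sites."""
    valid = (x >= 0) & (y >= 0)
    n = int(valid.sum())
    if n == 0:
        return 0.0, 0.0, 0
    xa, ya = x[valid], y[valid]
    diff = xa != ya
    same_class = ((np.isin(xa, _PURINES)) == (np.isin(ya, _PURINES)))
    ts = int((diff & same_class).sum())
    tv = int((diff & ~same_class).sum())
    return ts / n, tv / n, n


def k2p_distance(p: float, q: float) -> float:
    """Kimura 2-parameter: d = -0.5 ln[(1-2P-Q) sqrt(1-2Q)]."""
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        log.warning("K2P saturation (P=%.3f, Q=%.3f); capping distance", p, q)
        return SATURATION_CAP
    return -0.5 * math.log(w1 * math.sqrt(w2))


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray
    model: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValidationError("distance matrix shape mismatch")
        if not np.allclose(self.values, self.values.T):
            raise ValidationError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValidationError("distance matrix diagonal not zero")
        if not np.isfinite(self.values).all():
            raise ValidationError("non-finite distances")


def _hky_rate_matrix(kappa: float, pi: np.ndarray) -> np.ndarray:
    q = np.empty((4, 4))
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            rate = pi[j]
            transition = (i in _PURINES) == (j in _PURINES)
            if transition:
                rate *= kappa
            q[i, j] = rate
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    scale = -np.sum(pi * np.diag(q))
    return q / scale


def _hky_ml_distance(counts: np.ndarray, kappa: float, pi: np.ndarray) -> float:
    """1-D ML branch-length fit under HKY for one sequence pair.

    ``counts`` is the 4x4 site-pattern count matrix (x in seq1, y in seq2).
    """
    qmat = _hky_rate_matrix(kappa, pi)
    n = counts.sum()
    if n == 0:
        return 0.0
    if np.trace(counts) == n:
        return 0.0

    def negll(t: float) -> float:
        p = expm(qmat * t)
        p = np.clip(p, 1e-300, None)
        return -float(np.sum(counts * np.log(pi[:, None] * p)))

    res = minimize_scalar(
        negll, bounds=(1e-9, SATURATION_CAP), method="bounded",
        options={"xatol": 1e-12},
    )
    return float(res.x)


def estimate_kappa(sset: SequenceSet) -> float:
    """Moment estimate of the transition/transversion rate ratio.

    Uses the K2P decomposition pooled over all pairs; capped to [1, 100]
    because the ratio is unidentifiable when transversions are absent.
    """
    enc = encode_sequences(sset)
    at, bt = 0.0, 0.0
    for i, j in itertools.combinations(range(len(enc)), 2):
        p, q, n = _pair_pq(enc[i], enc[j])
        w1, w2 = 1.0 - 2 * p - q, 1.0 - 2 * q
        if w1 <= 0 or w2 <= 0 or n == 0:
            continue
        at += -0.5 * math.log(w1) + 0.25 * math.log(w2)
        bt += -0.25 * math.log(w2)
    if bt <= 1e-12:
        return 100.0
    return float(min(max(at / bt, 1.0), 100.0))


def pairwise_distances(
    sset: SequenceSet,
    model: str = "K2P",
    kappa: Optional[float] = None,
    base_freqs: Optional[Sequence[float]] = None,
) -> DistanceMatrix:
    """All-pairs distances under ``p_distance``, ``K2P`` or ``HKY_ML``.

    Sites with gaps or ambiguity codes in either sequence are pairwise
    deleted.  For ``HKY_ML``, base frequencies default to the empirical
    frequencies of the alignment and κ to a pooled moment estimate.
    """
    enc = encode_sequences(sset)
    n = len(sset)
    d = np.zeros((n, n))
    if model == "HKY_ML":
        if base_freqs is None:
            flat = enc[enc >= 0]
            pi = np.bincount(flat, minlength=4).astype(float)
            pi = pi / pi.sum()
        else:
            pi = np.asarray(base_freqs, dtype=float)
            pi = pi / pi.sum()
        pi = np.clip(pi, 1e-6, None)
        pi = pi / pi.sum()
        k = kappa if kappa is not None else estimate_kappa(sset)
    for i, j in itertools.combinations(range(n), 2):
        if model == "p_distance":
            p, q, nn = _pair_pq(enc[i], enc[j])
            dij = p + q
        elif model == "K2P":
            p, q, nn = _pair_pq(enc[i], enc[j])
            dij = k2p_distance(p, q)
        elif model == "HKY_ML":
            valid = (enc[i] >= 0) & (enc[j] >= 0)
            counts = np.zeros((4, 4))
            np.add.at(counts, (enc[i][valid], enc[j][valid]), 1.0)
            counts = (counts + counts.T) / 2.0  # unrooted pair: symmetrise
            dij = _hky_ml_distance(counts, k, pi)
        else:
            raise ValidationError(f"unknown distance model {model!r}")
        d[i, j] = d[j, i] = dij
    return DistanceMatrix(list(sset.ids), d, model)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

@dataclass
class Node:
    name: Optional[str] = None
    children: list[tuple["Node", float]] = field(default_factory=list)
    support: Optional[float] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class Tree:
    """Unrooted tree represented with an arbitrary internal root node."""

    root: Node
    n_clamped_branches: int = 0

    def leaves(self) -> list[Node]:
        out = []

        def walk(node: Node) -> None:
            if node.is_leaf:
                out.append(node)
            for child, _ in node.children:
                walk(child)

        walk(self.root)
        return out

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def to_newick(self) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                return node.name or ""
            inner = ",".join(f"{fmt(c)}:{length:.10g}" for c, length in node.children)
            label = "" if node.support is None else f"{node.support:.4g}"
            return f"({inner}){label}"

        return fmt(self.root) + ";"

    def bipartitions(self) -> dict[frozenset, Node]:
        """Non-trivial splits (as frozensets of leaf names) -> child node."""
        all_leaves = frozenset(self.leaf_names())
        out: dict[frozenset, Node] = {}

        def walk(node: Node) -> frozenset:
            if node.is_leaf:
                return frozenset([node.name])
            below = frozenset()
            for child, _ in node.children:
                below |= walk(child)
            if 1 < len(below) < len(all_leaves) - 1:
                out[min(below, all_leaves - below, key=sorted)] = node
            return below

        for child, _ in self.root.children:
            walk(child)
        return out

    def patristic_distances(self) -> tuple[list[str], np.ndarray]:
        """Leaf labels plus the matrix of path-length distances."""
        # build adjacency
        adj: dict[int, list[tuple[int, float]]] = {}
        names: dict[int, str] = {}
        counter = itertools.count()
        index: dict[int, int] = {}

        def walk(node: Node) -> int:
            i = index.setdefault(id(node), next(counter))
            if node.is_leaf:
                names[i] = node.name
            for child, length in node.children:
                j = walk(child)
                adj.setdefault(i, []).append((j, length))
                adj.setdefault(j, []).append((i, length))
            return i

        walk(self.root)
        leaf_ids = sorted(names, key=lambda i: names[i])
        labels = [names[i] for i in leaf_ids]
        n_nodes = next(counter)
        dist = np.zeros((len(leaf_ids), len(leaf_ids)))
        for a, src in enumerate(leaf_ids):
            seen = {src: 0.0}
            stack = [src]
            while stack:
                u = stack.pop()
                for v, w in adj.get(u, []):
                    if v not in seen:
                        seen[v] = seen[u] + w
                        stack.append(v)
            for b, dst in enumerate(leaf_ids):
                dist[a, b] = seen[dst]
        return labels, dist


def neighbour_joining(dm: DistanceMatrix) -> Tree:
    """Saitou–Nei neighbour joining with deterministic tie-breaking.

    Exact on additive matrices; negative branch lengths are clamped to zero
    with a count kept on the tree.  Fewer than three labels produce a
    degenerate star tree.
    """
    labels = list(dm.labels)
    n = len(labels)
    nodes: list[Node] = [Node(name=lab) for lab in labels]
    clamped = 0
    if n == 0:
        raise ValidationError("empty distance matrix")
    if n == 1:
        return Tree(Node(children=[(nodes[0], 0.0)]))
    if n == 2:
        return Tree(Node(children=[(nodes[0], dm.values[0, 1] / 2), (nodes[1], dm.values[0, 1] / 2)]))
    d = dm.values.copy()
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # deterministic: first minimal entry in row-major order
        flat = np.argmin(q)
        i_loc, j_loc = divmod(int(flat), m)
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        i, j = active[i_loc], active[j_loc]
        dij = d[i, j]
        li = 0.5 * dij + (r[i_loc] - r[j_loc]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            clamped += 1
            li = 0.0
        if lj < 0:
            clamped += 1
            lj = 0.0
        new = Node(children=[(nodes[i], li), (nodes[j], lj)])
        # distances from the new node
        dnew = 0.5 * (d[i, :] + d[j, :] - dij)
        d = np.vstack([d, dnew])
        d = np.hstack([d, np.append(dnew, 0.0)[:, None]])
        nodes.append(new)
        new_idx = d.shape[0] - 1
        active = [a for a in active if a not in (i, j)] + [new_idx]
    # final trifurcation
    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    lens = []
    for val in (la, lb, lc):
        if val < 0:
            clamped += 1
            val = 0.0
        lens.append(val)
    root = Node(children=[(nodes[a], lens[0]), (nodes[b], lens[1]), (nodes[c], lens[2])])
    if clamped:
        log.info("clamped %d negative NJ branch lengths to 0", clamped)
    return Tree(root, n_clamped_branches=clamped)


def bootstrap_support(
    sset: SequenceSet,
    model: str = "K2P",
    n_boot: int = 1000,
    seed: int = 0,
    kappa: Optional[float] = None,
) -> Tree:
    """NJ tree with bootstrap percentages on internal nodes.

    Alignment columns are resampled with replacement ``n_boot`` times, a tree
    is rebuilt from each pseudo-alignment, and bipartition frequencies are
    mapped onto the full-data tree.
    """
    sset.require_alignment()
    tree = neighbour_joining(pairwise_distances(sset, model=model, kappa=kappa))
    splits = tree.bipartitions()
    counts = {s: 0 for s in splits}
    rng = np.random.default_rng(seed)
    length = len(sset.seqs[0])
    for _ in range(n_boot):
        cols = rng.integers(0, length, size=length)
        boot = SequenceSet(
            list(sset.ids), ["".join(seq[c] for c in cols) for seq in sset.seqs]
        )
        btree = neighbour_joining(pairwise_distances(boot, model=model, kappa=kappa))
        bsplits = set(btree.bipartitions())
        for s in counts:
            if s in bsplits:
                counts[s] += 1
    for s, node in splits.items():
        node.support = 100.0 * counts[s] / n_boot
    return tree


def assign_clades(
    tree: Tree, reference_clades: Mapping[str, str]
) -> dict[str, str]:
    """Assign each non-reference leaf the clade of its nearest reference.

    Nearness is patristic distance to the closest reference of each clade;
    exact ties between clades are reported as ``"tie:<c1>,<c2>"`` rather than
    silently resolved.  Without references an empty dict is returned with a
    warning.
    """
    if not reference_clades:
        log.warning("no reference haplotypes supplied; clade assignment skipped")
        return {}
    labels, dist = tree.patristic_distances()
    idx = {lab: i for i, lab in enumerate(labels)}
    missing = [r for r in reference_clades if r not in idx]
    if missing:
        raise ValidationError(f"reference labels absent from tree: {missing}")
    clades = sorted(set(reference_clades.values()))
    out: dict[str, str] = {}
    for leaf in labels:
        if leaf in reference_clades:
            continue
        best: dict[str, float] = {}
        for clade in clades:
            refs = [idx[r] for r, c in reference_clades.items() if c == clade]
            best[clade] = min(dist[idx[leaf], r] for r in refs)
        mn = min(best.values())
        winners = sorted(c for c, v in best.items() if abs(v - mn) <= 1e-12)
        out[leaf] = winners[0] if len(winners) == 1 else "tie:" + ",".join(winners)
    return out
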