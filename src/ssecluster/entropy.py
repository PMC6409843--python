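"""One- and two-dimensional structure entropy and its minimization.

A random walker on a weighted graph G visits node i with stationary
probability d_i / 2e (weighted degree over total volume).  The
one-dimensional structure entropy H1(G) is the Shannon entropy of that
distribution.  Given a partition P = {X_1..X_L} of the nodes into
communities, the two-dimensional structure entropy is

    H^P(G) = - sum_l (Vol_l / 2e) sum_{i in X_l} (d_i / Vol_l) log2(d_i / Vol_l)
             - sum_l (e_l / 2e) log2(Vol_l / 2e)

where Vol_l is the community volume (sum of member degrees) and e_l the
boundary weight (total weight of edges with exactly one endpoint in X_l).
The first ("intra") term encodes the walker's position inside its
community, the second ("boundary") term the community it enters when it
crosses a boundary edge.  Minimizing H^P over partitions recovers the
natural community structure without a preset cluster count; the minimizer
here is a deterministic greedy agglomeration from singletons with an
incremental merge-gain evaluation, plus an exhaustive enumeration oracle
for small graphs.

All logs are base 2 ("bits"); 0 * log 0 := 0 throughout.  Weighted degrees
(strengths) are used everywhere, which reduces to the plain-degree formula
on 0/1 weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import GraphError, InputError, SizeError
from .graph import CellGraph

__all__ = [
    "Partition",
    "EntropyReport",
    "shannon_entropy",
    "one_dimensional_entropy",
    "partition_entropy",
    "merge_delta",
    "minimize_entropy",
    "exhaustive_min_entropy",
    "MergeCache",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Partition:
    """Assignment of every node to one of L non-empty communities 0..L-1."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1 or self.labels.size == 0:
            raise InputError("labels must be a non-empty vector")
        uniq = np.unique(self.labels)
        if uniq[0] != 0 or uniq[-1] != uniq.size - 1:
            raise InputError(
                "labels must be consecutive integers 0..L-1 with every "
                "community non-empty"
            )

    @classmethod
    def from_raw(cls, labels) -> "Partition":
        """Relabel arbitrary hashable labels to 0..L-1 by first appearance."""
        seen: dict = {}
        out = []
        for lab in labels:
            if lab not in seen:
                seen[lab] = len(seen)
            out.append(seen[lab])
        return cls(np.asarray(out, dtype=int))

    @property
    def n(self) -> int:
        return self.labels.size

    @property
    def num_communities(self) -> int:
        return int(self.labels.max()) + 1

    @property
    def members(self) -> list[np.ndarray]:
        return [
            np.flatnonzero(self.labels == l) for l in range(self.num_communities)
        ]


@dataclass
class EntropyReport:
    """Two-dimensional structure entropy of one partition, decomposed."""

    total_bits: float
    intra_term_bits: float
    boundary_term_bits: float
    per_community: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "total_bits": self.total_bits,
            "intra_term_bits": self.intra_term_bits,
            "boundary_term_bits": self.boundary_term_bits,
            "per_community": self.per_community,
        }


# ---------------------------------------------------------------------------
# Entropy evaluation
# ---------------------------------------------------------------------------

def _xlog2x(p: np.ndarray) -> np.ndarray:
    """p * log2(p) with the 0 log 0 := 0 convention."""
    p = np.asarray(p, dtype=float)
    return np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)


def shannon_entropy(p) -> float:
    """Shannon entropy -sum p_i log2 p_i of a probability vector, in bits."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise InputError("probabilities must be nonnegative")
    if abs(p.sum() - 1.0) > 1e-8:
        raise InputError(f"probabilities sum to {p.sum():.10g}, not 1")
    return float(-_xlog2x(p).sum())


def one_dimensional_entropy(G: CellGraph) -> float:
    """Entropy of the degree-proportional stationary distribution, in bits."""
    if G.total_volume <= 0:
        raise GraphError("one-dimensional entropy needs at least one edge")
    return shannon_entropy(G.degrees / G.total_volume)


def partition_entropy(G: CellGraph, P: Partition) -> EntropyReport:
    """Two-dimensional structure entropy H^P(G) of partition P, in bits.

    Decomposed into the intra-community positional term and the
    boundary-crossing term; a zero-volume community contributes nothing.
    """
    if P.n != G.n_nodes:
        raise InputError(
            f"partition covers {P.n} nodes but graph has {G.n_nodes}"
        )
    if G.total_volume <= 0:
        raise GraphError("structure entropy needs at least one edge")
    two_e = G.total_volume
    d = G.degrees
    intra = 0.0
    boundary = 0.0
    per_community = []
    for l, idx in enumerate(P.members):
        vol = float(d[idx].sum())
        if vol <= 0:
            per_community.append(
                {"community": l, "size": int(idx.size), "volume": 0.0,
                 "boundary_weight": 0.0, "intra_bits": 0.0, "boundary_bits": 0.0}
            )
            continue
        internal_twice = float(G.W[np.ix_(idx, idx)].sum())
        e_l = vol - internal_twice  # edges with exactly one endpoint inside
        intra_l = float(-_xlog2x(d[idx] / vol).sum() * (vol / two_e))
        boundary_l = float(-(e_l / two_e) * np.log2(vol / two_e)) if e_l > 0 else 0.0
        intra += intra_l
        boundary += boundary_l
        per_community.append(
            {"community": l, "size": int(idx.size), "volume": vol,
             "boundary_weight": e_l, "intra_bits": intra_l,
             "boundary_bits": boundary_l}
        )
    return EntropyReport(
        total_bits=intra + boundary,
        intra_term_bits=intra,
        boundary_term_bits=boundary,
        per_community=per_community,
    )


# ---------------------------------------------------------------------------
# Incremental merge evaluation
# ---------------------------------------------------------------------------

class MergeCache:
    """Per-community sufficient statistics for O(1) merge-gain evaluation.

    A community's contribution to H^P(G) depends only on its volume, its
    sum of d_i log2 d_i over members (invariant under merging), and its
    boundary weight; the gain of merging (a, b) additionally needs only
    the cut weight between a and b and the global volume, so merges
    elsewhere never invalidate a cached pair gain.
    """

    def __init__(self, G: CellGraph, P: Partition):
        self.two_e = G.total_volume
        d = G.degrees
        L = P.num_communities
        self.vol = np.zeros(L)
        self.sum_dlogd = np.zeros(L)
        self.internal_twice = np.zeros(L)
        members = P.members
        for l, idx in enumerate(members):
            self.vol[l] = d[idx].sum()
            self.sum_dlogd[l] = _xlog2x(d[idx]).sum()  # sum d log2 d, d>=0
            self.internal_twice[l] = G.W[np.ix_(idx, idx)].sum()
        # community-level cut weights via one-hot aggregation
        ind = np.eye(L)[P.labels]
        agg = ind.T @ G.W @ ind
        np.fill_diagonal(agg, 0.0)
        self.cut = agg

    def boundary(self, l: int) -> float:
        return float(self.vol[l] - self.internal_twice[l])

    def community_bits(self, vol: float, sum_dlogd: float, e_l: float) -> float:
        """Contribution of one community to H^P(G)."""
        if vol <= 0:
            return 0.0
        two_e = self.two_e
        intra = (vol * np.log2(vol) - sum_dlogd) / two_e
        bound = (e_l / two_e) * (np.log2(two_e) - np.log2(vol)) if e_l > 0 else 0.0
        return float(intra + bound)

    def pair_delta(self, a: int, b: int) -> float:
        """H^P' - H^P where P' merges communities a and b."""
        cut = float(self.cut[a, b])
        va, vb = float(self.vol[a]), float(self.vol[b])
        sa, sb = float(self.sum_dlogd[a]), float(self.sum_dlogd[b])
        ea, eb = self.boundary(a), self.boundary(b)
        merged = self.community_bits(va + vb, sa + sb, ea + eb - 2.0 * cut)
        return merged - self.community_bits(va, sa, ea) - self.community_bits(vb, sb, eb)


def merge_delta(
    G: CellGraph, P: Partition, a: int, b: int, cache: MergeCache | None = None
) -> float:
    """Entropy change (bits) from merging communities a and b of P."""
    L = P.num_communities
    if a == b or not (0 <= a < L and 0 <= b < L):
        raise InputError(f"invalid community pair ({a}, {b}) for L={L}")
    if cache is None:
        cache = MergeCache(G, P)
    return cache.pair_delta(a, b)


# ---------------------------------------------------------------------------
# Minimization
# ---------------------------------------------------------------------------

def _community_bits(two_e: float, vol: float, sdl: float, e_l: float) -> float:
    """One community's contribution to H^P(G) from (Vol, sum d log2 d, e)."""
    if vol <= 0:
        return 0.0
    intra = (vol * np.log2(vol) - sdl) / two_e
    bound = (e_l / two_e) * (np.log2(two_e) - np.log2(vol)) if e_l > 0 else 0.0
    return float(intra + bound)


class _PartitionState:
    """Mutable partition with incremental community statistics.

    Community ids are arbitrary persistent ints; ``vol``, ``sdl`` (sum of
    d_i log2 d_i, invariant under moves) and ``internal`` (twice the
    internal edge weight) are kept per community so merge and single-node
    move gains cost O(neighbourhood).
    """

    def __init__(self, G: CellGraph, labels: np.ndarray):
        self.G = G
        self.two_e = G.total_volume
        self.d = G.degrees
        self.dlogd = _xlog2x(self.d)
        self.labels = labels.copy()
        self.members: dict[int, set[int]] = {}
        for node, lab in enumerate(self.labels):
            self.members.setdefault(int(lab), set()).add(node)
        self.vol = {}
        self.sdl = {}
        self.internal = {}
        for c, mem in self.members.items():
            idx = np.fromiter(mem, dtype=int)
            self.vol[c] = float(self.d[idx].sum())
            self.sdl[c] = float(self.dlogd[idx].sum())
            self.internal[c] = float(G.W[np.ix_(idx, idx)].sum())
        self.next_id = int(self.labels.max()) + 1

    def bits(self, c: int) -> float:
        return _community_bits(
            self.two_e, self.vol[c], self.sdl[c], self.vol[c] - self.internal[c]
        )

    def total_bits(self) -> float:
        return sum(self.bits(c) for c in self.members)

    def neighbour_weight(self, v: int) -> dict[int, float]:
        """Total edge weight from node v into each adjacent community."""
        wsum: dict[int, float] = {}
        row = self.G.W[v]
        for j in np.flatnonzero(row):
            lab = int(self.labels[j])
            wsum[lab] = wsum.get(lab, 0.0) + float(row[j])
        return wsum

    def move_delta(self, v: int, target: int | None, wsum: dict[int, float]) -> float:
        """Entropy change from moving v to ``target`` (None = new singleton)."""
        a = int(self.labels[v])
        dv, dlv = float(self.d[v]), float(self.dlogd[v])
        va, sa, ia = self.vol[a] - dv, self.sdl[a] - dlv, (
            self.internal[a] - 2.0 * wsum.get(a, 0.0)
        )
        new_a = _community_bits(self.two_e, va, sa, va - ia)
        if target is None:
            new_b = _community_bits(self.two_e, dv, dlv, dv)
            old_b = 0.0
        else:
            vb = self.vol[target] + dv
            sb = self.sdl[target] + dlv
            ib = self.internal[target] + 2.0 * wsum.get(target, 0.0)
            new_b = _community_bits(self.two_e, vb, sb, vb - ib)
            old_b = self.bits(target)
        return new_a + new_b - self.bits(a) - old_b

    def apply_move(self, v: int, target: int | None, wsum: dict[int, float]) -> int:
        a = int(self.labels[v])
        dv, dlv = float(self.d[v]), float(self.dlogd[v])
        self.members[a].discard(v)
        self.vol[a] -= dv
        self.sdl[a] -= dlv
        self.internal[a] -= 2.0 * wsum.get(a, 0.0)
        if not self.members[a]:
            del self.members[a], self.vol[a], self.sdl[a], self.internal[a]
        if target is None:
            target = self.next_id
            self.next_id += 1
            self.members[target] = set()
            self.vol[target] = 0.0
            self.sdl[target] = 0.0
            self.internal[target] = 0.0
        self.members[target].add(v)
        self.vol[target] += dv
        self.sdl[target] += dlv
        self.internal[target] += 2.0 * wsum.get(target, 0.0)
        self.labels[v] = target
        return target

    def canonical_labels(self) -> np.ndarray:
        """Labels renumbered 0..L-1 by smallest member node."""
        out = np.empty(self.labels.size, dtype=int)
        order = sorted(self.members.values(), key=min)
        for new_lab, mem in enumerate(order):
            out[list(mem)] = new_lab
        return out


def _merge_phase(state: _PartitionState, tol: float) -> float:
    """Greedy most-negative-delta merging of edge-joined communities.

    Ties break on the lexicographically smallest pair of community
    representatives (smallest member node).  Returns the total entropy
    change.  Pairs in different connected components share no edge and are
    never merged.
    """
    two_e = state.two_e
    # community-level cut weights
    cut: dict[int, dict[int, float]] = {c: {} for c in state.members}
    W = state.G.W
    rows, cols = np.nonzero(np.triu(W, k=1))
    for i, j in zip(rows, cols):
        a, b = int(state.labels[i]), int(state.labels[j])
        if a == b:
            continue
        w = float(W[i, j])
        cut[a][b] = cut[a].get(b, 0.0) + w
        cut[b][a] = cut[b].get(a, 0.0) + w

    def rep(c: int) -> int:
        return min(state.members[c])

    def pair_delta(a: int, b: int) -> float:
        merged = _community_bits(
            two_e,
            state.vol[a] + state.vol[b],
            state.sdl[a] + state.sdl[b],
            (state.vol[a] - state.internal[a])
            + (state.vol[b] - state.internal[b])
            - 2.0 * cut[a][b],
        )
        return merged - state.bits(a) - state.bits(b)

    deltas: dict[tuple[int, int], float] = {}
    for a in cut:
        for b in cut[a]:
            if a < b:
                deltas[(a, b)] = pair_delta(a, b)

    total = 0.0
    while deltas:
        (a, b) = min(deltas, key=lambda p: (deltas[p], rep(p[0]), rep(p[1])))
        if deltas[(a, b)] >= -tol:
            break
        total += deltas[(a, b)]
        keep = a if rep(a) < rep(b) else b
        gone = b if keep == a else a
        state.members[keep] |= state.members[gone]
        state.labels[list(state.members[gone])] = keep
        state.vol[keep] += state.vol[gone]
        state.sdl[keep] += state.sdl[gone]
        state.internal[keep] += state.internal[gone] + 2.0 * cut[keep][gone]
        del state.members[gone], state.vol[gone], state.sdl[gone]
        del state.internal[gone], cut[keep][gone]
        for nb, wgt in cut[gone].items():
            if nb == keep:
                continue
            cut[keep][nb] = cut[keep].get(nb, 0.0) + wgt
            del cut[nb][gone]
            cut[nb][keep] = cut[keep][nb]
        del cut[gone]
        deltas = {
            p: g for p, g in deltas.items() if keep not in p and gone not in p
        }
        for nb in cut[keep]:
            pair = (keep, nb) if keep < nb else (nb, keep)
            deltas[pair] = pair_delta(*pair)
    return total


def _refine_phase(state: _PartitionState, tol: float) -> float:
    """One Kernighan-Lin-style relocation round.

    Repeatedly applies the best single-node move (to an edge-adjacent
    community or out into a new singleton), each node at most once, even
    when the move raises the entropy; the cumulative-gain prefix that is
    lowest is kept and the tail rolled back.  This escapes merge-phase
    local minima (e.g. a bridge pair that swallowed the cheapest merge)
    while staying deterministic.  Returns the accepted entropy change.
    """
    start_labels = state.labels.copy()
    locked: set[int] = set()
    cumulative = 0.0
    best_cum = 0.0
    best_labels = start_labels
    n = state.labels.size
    for _ in range(n):
        best_move = None
        for v in range(n):
            if v in locked:
                continue
            wsum = state.neighbour_weight(v)
            cur = int(state.labels[v])
            targets: list[int | None] = sorted(
                (c for c in wsum if c != cur), key=lambda c: min(state.members[c])
            )
            if len(state.members[cur]) > 1:
                targets.append(None)  # split off into a fresh singleton
            for tgt in targets:
                delta = state.move_delta(v, tgt, wsum)
                rep = np.inf if tgt is None else min(state.members[tgt])
                key = (delta, v, rep)
                if best_move is None or key < best_move[0]:
                    best_move = (key, v, tgt, wsum)
        if best_move is None:
            break
        (delta, _, _), v, tgt, wsum = best_move
        state.apply_move(v, tgt, wsum)
        locked.add(v)
        cumulative += delta
        if cumulative < best_cum - 1e-15:
            best_cum = cumulative
            best_labels = state.labels.copy()
    # roll back to the best prefix
    if not np.array_equal(state.labels, best_labels):
        state.__init__(state.G, best_labels)
    return best_cum if best_cum < -tol else 0.0


def minimize_entropy(
    G: CellGraph, tol: float = 1e-12
) -> tuple[Partition, EntropyReport]:
    """Structure-entropy minimization by greedy merging plus refinement.

    Starts from all-singleton communities and alternates (a) greedy
    agglomeration, applying the most negative merge gain among pairs of
    communities joined by at least one edge (ties to the lexicographically
    smallest representative pair), with (b) a Kernighan-Lin-style
    single-node relocation round that can traverse bounded uphill
    sequences.  Stops when neither phase lowers the entropy by more than
    ``tol``.  Disconnected components are never merged (no joining edge,
    and relocations only target edge-adjacent communities).  The result is
    deterministic; labels are renumbered 0..L-1 by smallest member node.
    """
    if G.total_volume <= 0:
        raise GraphError("cannot cluster a graph with no edges")
    n = G.n_nodes
    state = _PartitionState(G, np.arange(n))
    _merge_phase(state, tol)
    for _ in range(100):  # each accepted round strictly lowers H; cap is a guard
        gain = _refine_phase(state, tol)
        if gain >= -tol:
            break
        _merge_phase(state, tol)
    part = Partition(state.canonical_labels())
    return part, partition_entropy(G, part)


def _set_partitions(n: int):
    """Yield all set partitions of range(n) as restricted-growth labels."""
    labels = [0] * n

    def rec(i: int, max_used: int):
        if i == n:
            yield tuple(labels)
            return
        for lab in range(max_used + 2):
            labels[i] = lab
            yield from rec(i + 1, max(max_used, lab))

    yield from rec(1, 0)  # labels[0] is fixed at 0


def exhaustive_min_entropy(G: CellGraph) -> tuple[Partition, float]:
    """Exact structure-entropy minimum by Bell-number enumeration (n <= 10).

    Ties are broken toward fewer communities, then the lexicographically
    smallest restricted-growth label sequence.
    """
    n = G.n_nodes
    if n > 10:
        raise SizeError(f"exhaustive enumeration limited to n <= 10, got {n}")
    if G.total_volume <= 0:
        raise GraphError("cannot cluster a graph with no edges")
    best_labels: tuple[int, ...] | None = None
    best = (np.inf, np.inf)
    for labels in _set_partitions(n):
        H = partition_entropy(G, Partition(np.array(labels))).total_bits
        L = max(labels) + 1
        if best_labels is None or H < best[0] - 1e-12:
            take = True
        elif H <= best[0] + 1e-12:
            take = (L, labels) < (best[1], best_labels)
        else:
            take = False
        if take:
            best = (H, L)
            best_labels = labels
    assert best_labels is not None
    return Partition(np.array(best_labels)), float(best[0])
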