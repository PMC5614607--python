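"""Greedy seed-based subnetwork detection.

Every scored node of a network is tried as a seed. From each seed the
neighborhood is explored breadth-first, layer by layer: every frontier
node is tested *independently* for whether adding it alone would raise
the subnetwork's mean score by strictly more than the improvement
threshold ``th``. All nodes that pass are added simultaneously, the score
is recomputed, and the next layer is the set of yet-unseen neighbors of
the newly added nodes. A rejected node closes its path: it is never
retested for that seed, even if reachable through another kept branch.
The layer-simultaneous update makes the result independent of neighbor
iteration order.

Redundant results (two distant seeds converging on the same high-scoring
gene pool) are pruned by a pairwise mutual-overlap filter.
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Set

from .core import BioNetwork, GeneScoreTable, Subnetwork

__all__ = ["expand_seed", "detect_subnetworks", "filter_redundant"]


def expand_seed(
    net: BioNetwork,
    scores: GeneScoreTable,
    seed: str,
    th: float = 0.05,
    score_mode: str = "mean",
) -> Subnetwork:
    """Grow one subnetwork from ``seed`` under improvement threshold ``th``.

    A frontier node v is kept iff score(members + {v}) - score(members) > th
    (strict: a node improving by exactly th is rejected). Kept nodes of a
    layer are added together before the next layer is formed.
    """
    if seed not in scores:
        raise KeyError(f"seed {seed!r} has no score")
    if th < 0:
        raise ValueError("th must be >= 0")

    members: Set[str] = {seed}
    rejected: Set[str] = set()
    total = scores[seed]
    size = 1
    frontier = net.neighbors(seed) - members

    while frontier:
        kept: List[str] = []
        if score_mode == "sum":
            current = total
        else:
            current = total / size
        for v in sorted(frontier):
            z = scores[v]
            if score_mode == "sum":
                delta = z
            else:
                # algebraically (total+z)/(size+1) - current, in the form
                # that keeps the Δ == th boundary numerically exact
                delta = (z - current) / (size + 1)
            if delta > th:
                kept.append(v)
            else:
                rejected.add(v)
        if not kept:
            break
        for v in kept:
            members.add(v)
            total += scores[v]
            size += 1
        new_frontier: Set[str] = set()
        for v in kept:
            new_frontier |= net.neighbors(v)
        frontier = new_frontier - members - rejected

    score = total if score_mode == "sum" else total / size
    return Subnetwork(
        id=f"{net.kind[:3]}-snw-{seed}",
        seed=seed,
        members=members,
        network_kind=net.kind,
        score=score,
    )


def detect_subnetworks(
    net: BioNetwork,
    scores: GeneScoreTable,
    th: float = 0.05,
    min_size: int = 2,
    score_mode: str = "mean",
) -> List[Subnetwork]:
    """Run :func:`expand_seed` from every node; drop trivial size-1 results.

    The network must already be induced on scored genes. Output is sorted
    by descending score, ties broken by seed id.
    """
    subs: List[Subnetwork] = []
    for seed in net.graph.nodes:
        sn = expand_seed(net, scores, seed, th=th, score_mode=score_mode)
        if sn.size >= min_size:
            subs.append(sn)
    subs.sort(key=lambda s: (-s.score, s.seed))
    return subs


def _overlaps(a: Subnetwork, b: Subnetwork) -> tuple:
    inter = len(a.members & b.members)
    return inter / len(a.members), inter / len(b.members)


def filter_redundant(
    subs: Sequence[Subnetwork], rate: float = 0.8
) -> List[Subnetwork]:
    """Discard near-duplicate subnetworks by pairwise mutual overlap.

    For each pair, the two directed overlaps |A∩B|/|A| and |A∩B|/|B| are
    computed. If both reach ``rate``, the lower-scoring subnetwork is
    dropped. If exactly one reaches it, the smaller subnetwork is dropped
    only when it also scores lower — a smaller but better-scoring
    subnetwork survives alongside the larger one, so that large subnetworks
    are not lost. Pairs are processed over the pool sorted by descending
    score; a discarded subnetwork leaves the pool immediately.
    """
    if not 0 < rate <= 1:
        raise ValueError("rate must be in (0, 1]")
    # deterministic order: score desc, then size desc, then seed id
    pool = sorted(subs, key=lambda s: (-s.score, -s.size, s.seed))
    alive = [True] * len(pool)
    for i in range(len(pool)):
        if not alive[i]:
            continue
        for j in range(i + 1, len(pool)):
            if not alive[j]:
                continue
            a, b = pool[i], pool[j]
            ov_a, ov_b = _overlaps(a, b)
            hit_a, hit_b = ov_a >= rate, ov_b >= rate
            if hit_a and hit_b:
                # drop the lower-scoring one; ties -> keep lexicographically
                # smaller seed id for determinism
                if a.score > b.score:
                    alive[j] = False
                elif b.score > a.score:
                    alive[i] = False
                else:
                    if a.seed <= b.seed:
                        alive[j] = False
                    else:
                        alive[i] = False
            elif hit_a or hit_b:
                small, idx_small = (a, i) if a.size < b.size else (b, j)
                big = b if small is a else a
                if small.score < big.score:
                    alive[idx_small] = False
            if not alive[i]:
                break
    return [sn for sn, ok in zip(pool, alive) if ok]
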