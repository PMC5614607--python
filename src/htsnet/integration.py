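"""Merge validated interactome and regulome subnetworks into
meta-subnetworks.

An interactome subnetwork and a regulome subnetwork are linked when they
share at least ``n`` genes. Each connected component of the resulting
bipartite link graph that contains at least one link becomes a
meta-subnetwork; subnetworks that link to nothing are reported separately.
The meta score is the mean z-score over the union of member genes (the
maximum member score is carried as an alternative column).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Set, Tuple

import networkx as nx

from .core import GeneScoreTable, Subnetwork, subnetwork_score

__all__ = ["MetaSubnetwork", "build_meta_subnetworks", "meta_threshold_profile"]


@dataclass
class MetaSubnetwork:
    id: str
    member_ids: Set[str]
    union_genes: Set[str]
    score: float
    max_member_score: float
    n_interactome: int = 0
    n_regulome: int = 0

    @property
    def n_members(self) -> int:
        return len(self.member_ids)


def build_meta_subnetworks(
    int_subs: Sequence[Subnetwork],
    reg_subs: Sequence[Subnetwork],
    n: int,
    scores: GeneScoreTable,
) -> Tuple[List[MetaSubnetwork], List[Subnetwork]]:
    """Bundle subnetworks sharing >= ``n`` genes across network kinds.

    Returns (meta-subnetworks, unlinked subnetworks). Links are only ever
    interactome <-> regulome; same-kind subnetworks are never compared.
    Meta ids are deterministic: derived from the seed of the
    highest-scoring member.
    """
    if n < 1:
        raise ValueError("common-node threshold n must be >= 1")
    by_id: Dict[str, Subnetwork] = {}
    link = nx.Graph()
    for sn in list(int_subs) + list(reg_subs):
        by_id[sn.id] = sn
        link.add_node(sn.id)
    for a in int_subs:
        for b in reg_subs:
            if len(a.members & b.members) >= n:
                link.add_edge(a.id, b.id)

    metas: List[MetaSubnetwork] = []
    unlinked: List[Subnetwork] = []
    for comp in nx.connected_components(link):
        members = [by_id[i] for i in comp]
        if len(members) == 1:
            unlinked.append(members[0])
            continue
        union: Set[str] = set()
        for sn in members:
            union |= sn.members
        best = max(members, key=lambda s: (s.score, s.seed))
        metas.append(
            MetaSubnetwork(
                id=f"meta-snw-{best.seed}",
                member_ids=set(comp),
                union_genes=union,
                score=subnetwork_score(union, scores),
                max_member_score=best.score,
                n_interactome=sum(1 for s in members if s.network_kind == "interactome"),
                n_regulome=sum(1 for s in members if s.network_kind == "regulome"),
            )
        )
    metas.sort(key=lambda m: (-m.score, m.id))
    unlinked.sort(key=lambda s: (-s.score, s.id))
    return metas, unlinked


def meta_threshold_profile(
    int_subs: Sequence[Subnetwork],
    reg_subs: Sequence[Subnetwork],
    n_range: Iterable[int],
    scores: GeneScoreTable,
) -> List[Tuple[int, int]]:
    """Meta-subnetwork count as a function of the common-gene threshold.

    The count is non-increasing in n: raising the threshold can only
    remove links from the bipartite graph.
    """
    profile = []
    for n in sorted(set(int(v) for v in n_range)):
        metas, _ = build_meta_subnetworks(int_subs, reg_subs, n, scores)
        profile.append((n, len(metas)))
    return profile
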