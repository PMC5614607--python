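"""Core domain types shared by every pipeline stage.

The per-gene input to the whole analysis is a single screening z-score.
Scores may be transformed once on ingestion (identity, negate, abs)
depending on the screening convention: screens scored so that strong hits
are very negative use ``negate``; ratio screens where both directions are
interesting use ``abs``.

A subnetwork's score is the arithmetic mean of its members' z-scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Mapping, Optional, Set, Tuple

import networkx as nx

__all__ = [
    "GeneScoreTable",
    "BioNetwork",
    "Subnetwork",
    "transform_scores",
    "subnetwork_score",
    "induce_scored_subgraph",
    "TRANSFORMS",
]

TRANSFORMS = ("identity", "negate", "abs")


class InputError(ValueError):
    """Raised on malformed or inconsistent user input."""


@dataclass(frozen=True)
class GeneScoreTable:
    """Gene-id -> z-score mapping with the applied transform recorded.

    Stored scores are post-transform; the transform is applied exactly once,
    by :func:`transform_scores`.
    """

    entries: Mapping[str, float]
    transform: str = "identity"
    source_label: str = ""

    def __post_init__(self) -> None:
        if self.transform not in TRANSFORMS:
            raise InputError(f"unknown transform {self.transform!r}")

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, gene: str) -> bool:
        return gene in self.entries

    def __getitem__(self, gene: str) -> float:
        return self.entries[gene]

    def genes(self) -> Set[str]:
        return set(self.entries)


@dataclass
class BioNetwork:
    """One of the two gene networks: interactome (undirected PPI plus
    TF-TF edges) or regulome (directed TF -> target edges).

    Adjacency queries are symmetric for both kinds: during subnetwork
    expansion a regulated gene may recruit its transcription factor and
    vice versa. Edge orientation for the regulome is retained only for
    reporting, in ``directed_edges``.
    """

    kind: str  # "interactome" | "regulome"
    graph: nx.Graph = field(default_factory=nx.Graph)
    tf_genes: Set[str] = field(default_factory=set)
    directed_edges: Set[Tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.kind not in ("interactome", "regulome"):
            raise InputError(f"unknown network kind {self.kind!r}")

    @property
    def directed(self) -> bool:
        return self.kind == "regulome"

    @property
    def nodes(self) -> Set[str]:
        return set(self.graph.nodes)

    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def is_tf(self, gene: str) -> bool:
        return gene in self.tf_genes

    def add_edge(self, u: str, v: str, directed: bool = False) -> None:
        if u == v:
            raise InputError(f"self-loop {u!r} not allowed")
        self.graph.add_edge(u, v)
        if directed:
            self.directed_edges.add((u, v))

    def neighbors(self, gene: str) -> Set[str]:
        return set(self.graph.neighbors(gene))

    def copy(self) -> "BioNetwork":
        return BioNetwork(
            kind=self.kind,
            graph=self.graph.copy(),
            tf_genes=set(self.tf_genes),
            directed_edges=set(self.directed_edges),
        )


@dataclass
class Subnetwork:
    """A connected gene set grown from one seed, with its mean z-score and
    the three empirical p-values attached by validation."""

    id: str
    seed: str
    members: Set[str]
    network_kind: str
    score: float
    p1: Optional[float] = None
    p2: Optional[float] = None
    p3: Optional[float] = None
    retained: bool = False

    def __post_init__(self) -> None:
        if self.seed not in self.members:
            raise ValueError(f"seed {self.seed!r} not among members")

    @property
    def size(self) -> int:
        return len(self.members)

    def with_pvalues(self, p1: float, p2: float, p3: float, retained: bool) -> "Subnetwork":
        return replace(self, p1=p1, p2=p2, p3=p3, retained=retained)


def transform_scores(
    raw: Mapping[str, float], mode: str = "identity", source_label: str = ""
) -> GeneScoreTable:
    """Apply the screening-convention transform to raw z-scores.

    ``identity`` keeps the values, ``negate`` flips the sign (screens where
    hits are highly negative), ``abs`` takes magnitudes (bidirectional ratio
    screens). Non-finite scores and empty tables are rejected.
    """
    if not raw:
        raise InputError("empty score table")
    if mode not in TRANSFORMS:
        raise InputError(f"unknown transform {mode!r}")
    out: Dict[str, float] = {}
    for gene, z in raw.items():
        z = float(z)
        if not math.isfinite(z):
            raise InputError(f"non-finite score for gene {gene!r}: {z}")
        if mode == "negate":
            z = -z
        elif mode == "abs":
            z = abs(z)
        out[gene] = z
    return GeneScoreTable(entries=out, transform=mode, source_label=source_label)


def subnetwork_score(
    members: Iterable[str], scores: GeneScoreTable, mode: str = "mean"
) -> float:
    """Score of a gene set: the mean z-score over its members.

    ``mode='sum'`` is available for users who prefer a plain additive score,
    but the mean is the default — it is the only reading under which a small
    improvement threshold (th ~ 0.05) is a meaningful acceptance criterion.
    """
    members = list(members)
    if not members:
        raise ValueError("empty member set")
    total = 0.0
    for g in members:
        if g not in scores:
            raise KeyError(f"gene {g!r} has no score; unscored genes must be removed upstream")
        total += scores[g]
    if mode == "sum":
        return total
    return total / len(members)


def induce_scored_subgraph(
    net: BioNetwork, scores: GeneScoreTable
) -> Tuple[BioNetwork, int]:
    """Restrict a network to the nodes that carry a screening score.

    Returns the induced network plus the mapped-gene count. Genes with
    scores but no network node are simply not part of that network's
    analysis; nodes without scores cannot contribute a score term and are
    dropped before detection.
    """
    keep = net.nodes & scores.genes()
    if not keep:
        raise InputError(
            f"no scored gene maps onto the {net.kind}; "
            "check the identifier mapping between score file and edge lists"
        )
    sub = net.graph.subgraph(keep).copy()
    directed = {(u, v) for (u, v) in net.directed_edges if u in keep and v in keep}
    induced = BioNetwork(
        kind=net.kind,
        graph=sub,
        tf_genes=net.tf_genes & keep,
        directed_edges=directed,
    )
    return induced, len(keep)
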