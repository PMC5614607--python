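"""Statistical validation of detected subnetworks.

Three empirical null distributions of subnetwork scores are built:

* type I  — shuffle the score-to-gene assignment, re-run detection;
  tests the link between the screening z-scores and the subnetworks.
* type II — rewire the network with degree-preserving double-edge swaps,
  re-run detection on the true scores; tests the link between the
  subnetworks and the network topology.
* type III — mean scores of uniformly drawn gene sets of the same size,
  ignoring both scores' placement and topology; one null per size.

Each null sample is fitted with a Gaussian mixture (components chosen by
BIC) and a subnetwork's p-value is the mixture's upper tail probability
at the subnetwork's score. A subnetwork is retained when all three
(optionally Bonferroni-corrected) p-values pass the per-network alpha.

Because the variance of a mean score shrinks with subnetwork size, the
type-I and type-II nulls are size-matched by default: a subnetwork of
size k is compared against null subnetworks of (approximately) the same
size, the size window widening adaptively when a bin is sparse. Pooling
all sizes into one null (``ValidationConfig(size_matched=False)``) is
also available, but it lets small high-scoring null pairs dominate the
tail and drains power for larger modules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set

import numpy as np
from scipy.stats import norm
from sklearn.mixture import GaussianMixture

from .core import BioNetwork, GeneScoreTable, Subnetwork
from .detection import detect_subnetworks, filter_redundant

__all__ = [
    "MixtureNull",
    "EmpiricalNull",
    "ValidationConfig",
    "null_type1",
    "null_type2",
    "null_type3",
    "rewire_preserving_degrees",
    "fit_gaussian_mixture",
    "mixture_tail_p",
    "validate_subnetworks",
]

_VAR_FLOOR_FACTOR = 1e-6
_ABS_VAR_FLOOR = 1e-12


@dataclass
class MixtureNull:
    """An empirical null score sample plus its fitted Gaussian mixture."""

    kind: str  # "type1" | "type2" | "type3"
    size_key: object  # int for type3, "pooled" otherwise
    samples: np.ndarray
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if np.any(self.sds <= 0):
            raise ValueError("mixture sds must be positive")

    @property
    def n_components(self) -> int:
        return len(self.weights)

    def tail_p(self, x: float) -> float:
        return mixture_tail_p(self, x)


@dataclass
class EmpiricalNull:
    """Null subnetwork scores with their sizes, for type-I/II p-values.

    ``tail_p(x, k)`` fits (and caches) a Gaussian mixture on the null
    scores whose sizes fall in a window around k; the window widens one
    size at a time until at least ``min_bin`` samples are covered (or the
    whole pool is). With ``size_matched=False`` every query uses the full
    pooled sample.
    """

    kind: str
    sizes: np.ndarray
    scores: np.ndarray
    max_components: int = 3
    min_bin: int = 50
    size_matched: bool = True
    fit_seed: int = 0

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=int)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.sizes.shape != self.scores.shape:
            raise ValueError("sizes and scores must align")
        if self.scores.size == 0:
            raise ValueError("empty null sample")
        self._cache: Dict[object, MixtureNull] = {}

    def _bin_samples(self, k: int) -> np.ndarray:
        if not self.size_matched:
            return self.scores
        for w in range(0, int(self.sizes.max()) + 1):
            mask = np.abs(self.sizes - k) <= w
            if mask.sum() >= min(self.min_bin, self.scores.size):
                return self.scores[mask]
        return self.scores

    def mixture_for(self, k: int) -> MixtureNull:
        key = int(k) if self.size_matched else "pooled"
        if key not in self._cache:
            samples = self._bin_samples(int(k))
            rng = np.random.default_rng(self.fit_seed)
            self._cache[key] = fit_gaussian_mixture(
                samples, self.max_components, rng, self.kind, key
            )
        return self._cache[key]

    def tail_p(self, x: float, k: int) -> float:
        return mixture_tail_p(self.mixture_for(k), x)


@dataclass
class ValidationConfig:
    """Knobs for the validation stage.

    ``n_reps`` detection re-runs feed the type-I and type-II pools and
    ``m_samples`` random gene sets per size feed the type-III null.
    ``alpha_int`` / ``alpha_reg`` are the per-network significance
    thresholds applied to all three p-values after optional Bonferroni
    correction by the number of candidate subnetworks in that network.
    """

    n_reps: int = 20
    m_samples: int = 10_000
    alpha_int: float = 5e-3
    alpha_reg: float = 1e-2
    bonferroni: bool = True
    max_components: int = 3
    n_swaps_factor: int = 10
    th: float = 0.05
    overlap_rate: float = 0.8
    min_size: int = 2
    score_mode: str = "mean"
    size_matched: bool = True
    min_bin: int = 50

    def alpha_for(self, kind: str) -> float:
        return self.alpha_int if kind == "interactome" else self.alpha_reg


def fit_gaussian_mixture(
    samples: Sequence[float],
    max_components: int = 3,
    rng: Optional[np.random.Generator] = None,
    kind: str = "type1",
    size_key: object = "pooled",
) -> MixtureNull:
    """Fit a 1-D Gaussian mixture to null scores, choosing k by BIC.

    Fewer than 10 samples fall back to a single normal from the sample
    mean/sd; zero-variance samples get a single component with a floored
    variance so that tail probabilities stay defined.
    """
    rng = rng or np.random.default_rng()
    x = np.asarray(list(samples), dtype=float)
    if x.size == 0:
        raise ValueError("cannot fit a mixture to zero samples")
    var = float(np.var(x))
    floor = max(_VAR_FLOOR_FACTOR * var, _ABS_VAR_FLOOR)
    if var <= _ABS_VAR_FLOOR:
        warnings.warn("zero-variance null sample; using degenerate component")
        return MixtureNull(kind, size_key, x, np.array([1.0]),
                           np.array([float(np.mean(x))]),
                           np.array([np.sqrt(floor)]))
    if x.size < 10:
        sd = float(np.std(x, ddof=1)) if x.size > 1 else np.sqrt(floor)
        sd = max(sd, np.sqrt(floor))
        return MixtureNull(kind, size_key, x, np.array([1.0]),
                           np.array([float(np.mean(x))]), np.array([sd]))
    X = x.reshape(-1, 1)
    best = None
    best_bic = np.inf
    seed = int(rng.integers(0, 2**31 - 1))
    for k in range(1, max(1, max_components) + 1):
        if k > x.size:
            break
        gm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            n_init=3,
            reg_covar=floor,
            random_state=seed,
        )
        try:
            gm.fit(X)
        except Exception:
            continue
        bic = gm.bic(X)
        if bic < best_bic:
            best_bic = bic
            best = gm
    if best is None:  # pragma: no cover - defensive
        return MixtureNull(kind, size_key, x, np.array([1.0]),
                           np.array([float(np.mean(x))]),
                           np.array([max(float(np.std(x)), np.sqrt(floor))]))
    w = best.weights_.ravel()
    mu = best.means_.ravel()
    sd = np.sqrt(best.covariances_.ravel())
    sd = np.maximum(sd, np.sqrt(floor))
    return MixtureNull(kind, size_key, x, w / w.sum(), mu, sd)


def mixture_tail_p(null: MixtureNull, x: float) -> float:
    """Upper-tail probability P(S >= x) under the fitted mixture."""
    p = float(np.sum(null.weights * norm.sf((x - null.means) / null.sds)))
    return min(max(p, np.nextafter(0.0, 1.0)), 1.0)


def _shuffled_scores(scores: GeneScoreTable, rng: np.random.Generator) -> GeneScoreTable:
    genes = sorted(scores.entries)
    vals = np.array([scores.entries[g] for g in genes])
    perm = rng.permutation(len(genes))
    return GeneScoreTable(
        entries={g: float(vals[p]) for g, p in zip(genes, perm)},
        transform=scores.transform,
        source_label=scores.source_label + " [shuffled]",
    )


def _detect_pool(
    net: BioNetwork, scores: GeneScoreTable, cfg: ValidationConfig
) -> List[tuple]:
    subs = detect_subnetworks(net, scores, th=cfg.th, min_size=cfg.min_size,
                              score_mode=cfg.score_mode)
    subs = filter_redundant(subs, rate=cfg.overlap_rate)
    return [(s.size, s.score) for s in subs]


def _fallback_null(
    kind: str, scores: GeneScoreTable, cfg: ValidationConfig,
    rng: np.random.Generator,
) -> EmpiricalNull:
    """Random gene-set means standing in when a detection null is empty
    (degenerate score fields)."""
    m = max(cfg.m_samples, 100)
    means = _random_set_means(scores, size=min(2, len(scores)), m=m, rng=rng)
    return EmpiricalNull(
        kind=kind, sizes=np.full(m, 2), scores=means,
        max_components=cfg.max_components, min_bin=cfg.min_bin,
        size_matched=cfg.size_matched,
        fit_seed=int(rng.integers(0, 2**31 - 1)),
    )


def _empirical_null(
    kind: str, pool: List[tuple], cfg: ValidationConfig,
    rng: np.random.Generator,
) -> EmpiricalNull:
    sizes = np.array([k for k, _ in pool], dtype=int)
    vals = np.array([s for _, s in pool], dtype=float)
    return EmpiricalNull(
        kind=kind, sizes=sizes, scores=vals,
        max_components=cfg.max_components, min_bin=cfg.min_bin,
        size_matched=cfg.size_matched,
        fit_seed=int(rng.integers(0, 2**31 - 1)),
    )


def null_type1(
    net: BioNetwork,
    scores: GeneScoreTable,
    cfg: ValidationConfig,
    rng: np.random.Generator,
) -> EmpiricalNull:
    """Score-shuffle null: permute the score-to-gene assignment before each
    detection run and pool the resulting subnetwork scores (with sizes)."""
    pool: List[tuple] = []
    for _ in range(cfg.n_reps):
        shuffled = _shuffled_scores(scores, rng)
        pool.extend(_detect_pool(net, shuffled, cfg))
    if not pool:
        warnings.warn(
            "score-shuffle null produced no subnetworks; "
            "falling back to random gene-set sampling"
        )
        return _fallback_null("type1", scores, cfg, rng)
    return _empirical_null("type1", pool, cfg, rng)


def rewire_preserving_degrees(
    net: BioNetwork,
    n_swaps: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    max_tries_factor: int = 50,
) -> BioNetwork:
    """Randomize edges with double-edge swaps, keeping every node degree.

    Swaps producing self-loops or duplicate edges are rejected. Graphs too
    constrained to admit any swap (e.g. stars, complete graphs) come back
    unchanged with a warning after a bounded number of attempts.
    """
    rng = rng or np.random.default_rng()
    g = net.graph.copy()
    m = g.number_of_edges()
    if m < 2:
        warnings.warn("graph has < 2 edges; cannot rewire")
        return net.copy()
    if n_swaps is None:
        n_swaps = 10 * m
    edges = [tuple(e) for e in g.edges()]
    done = 0
    tries = 0
    max_tries = max_tries_factor * n_swaps
    while done < n_swaps and tries < max_tries:
        tries += 1
        i, j = rng.integers(0, m, size=2)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        # swap to (a, d), (c, b)
        if len({a, b, c, d}) < 4:
            continue
        if g.has_edge(a, d) or g.has_edge(c, b):
            continue
        g.remove_edge(a, b)
        g.remove_edge(c, d)
        g.add_edge(a, d)
        g.add_edge(c, b)
        edges[i] = (a, d)
        edges[j] = (c, b)
        done += 1
    if done == 0:
        warnings.warn("graph too constrained to rewire; returning input unchanged")
        return net.copy()
    directed = set()
    if net.directed_edges:
        tf = {u for (u, _) in net.directed_edges}
        for u, v in g.edges():
            # orient rewired regulome edges TF -> target where possible
            if u in tf:
                directed.add((u, v))
            elif v in tf:
                directed.add((v, u))
    return BioNetwork(kind=net.kind, graph=g, tf_genes=set(net.tf_genes),
                      directed_edges=directed)


def null_type2(
    net: BioNetwork,
    scores: GeneScoreTable,
    cfg: ValidationConfig,
    rng: np.random.Generator,
) -> EmpiricalNull:
    """Rewired-network null: degree-preserving randomization of the network
    before each detection run on the true scores; scores pooled over reps."""
    pool: List[tuple] = []
    for _ in range(cfg.n_reps):
        rnet = rewire_preserving_degrees(
            net, n_swaps=cfg.n_swaps_factor * net.n_edges(), rng=rng
        )
        pool.extend(_detect_pool(rnet, scores, cfg))
    if not pool:
        warnings.warn(
            "rewired-network null produced no subnetworks; "
            "falling back to random gene-set sampling"
        )
        return _fallback_null("type2", scores, cfg, rng)
    return _empirical_null("type2", pool, cfg, rng)


def _random_set_means(
    scores: GeneScoreTable, size: int, m: int, rng: np.random.Generator
) -> np.ndarray:
    vals = np.array([scores.entries[g] for g in sorted(scores.entries)])
    n = vals.size
    if size > n:
        raise ValueError(f"set size {size} exceeds number of scored genes {n}")
    if size == n:
        return np.full(m, float(vals.mean()))
    # uniform k-subsets: smallest-k entries of iid uniforms per row
    r = rng.random((m, n))
    idx = np.argpartition(r, size, axis=1)[:, :size]
    return vals[idx].mean(axis=1)


def null_type3(
    scores: GeneScoreTable,
    sizes: Iterable[int],
    cfg: ValidationConfig,
    rng: np.random.Generator,
) -> Dict[int, MixtureNull]:
    """Size-matched random gene-set null: for each observed subnetwork size
    k, mean scores of uniformly drawn k-subsets of scored genes, with no
    connectivity constraint."""
    out: Dict[int, MixtureNull] = {}
    for k in sorted(set(int(s) for s in sizes)):
        means = _random_set_means(scores, k, cfg.m_samples, rng)
        out[k] = fit_gaussian_mixture(means, cfg.max_components, rng, "type3", k)
    return out


def validate_subnetworks(
    subs: Sequence[Subnetwork],
    null1: EmpiricalNull,
    null2: EmpiricalNull,
    null3: Dict[int, MixtureNull],
    cfg: ValidationConfig,
    scores: Optional[GeneScoreTable] = None,
    rng: Optional[np.random.Generator] = None,
) -> List[Subnetwork]:
    """Attach p-values I/II/III to each subnetwork and flag retention.

    With Bonferroni on, each raw p is multiplied by the number of candidate
    subnetworks of that network (capped at 1) before thresholding; a
    subnetwork is retained iff all three corrected p-values are <= the
    network's alpha. A missing size-specific type-III null is computed on
    demand when the score table and rng are supplied.
    """
    m = len(subs)
    out: List[Subnetwork] = []
    for sn in subs:
        if sn.size not in null3:
            if scores is None or rng is None:
                raise KeyError(f"no type-III null for size {sn.size}")
            null3.update(null_type3(scores, [sn.size], cfg, rng))
        p1 = null1.tail_p(sn.score, sn.size)
        p2 = null2.tail_p(sn.score, sn.size)
        p3 = mixture_tail_p(null3[sn.size], sn.score)
        if cfg.bonferroni and m > 0:
            p1, p2, p3 = (min(1.0, p * m) for p in (p1, p2, p3))
        alpha = cfg.alpha_for(sn.network_kind)
        retained = p1 <= alpha and p2 <= alpha and p3 <= alpha
        out.append(sn.with_pvalues(p1, p2, p3, retained))
    return out
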