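"""Readers and writers for every on-disk format the pipeline touches.

Inputs are plain tab-delimited text: a 2-column score file
(gene, z-score; optional header auto-detected), edge lists
(source, target[, class]) where the class token is one of ``ppi``,
``tf-tf`` (interactome) or ``tf-target`` (regulome), an optional
alias -> canonical identifier mapping, and an optional gene/term
annotation table. Gene identifiers are opaque strings throughout.

Outputs: per-subnetwork GraphViz DOT files, one NNF (nested network
format) file encoding the meta-subnetwork -> subnetwork -> gene nesting
in the Cytoscape dialect (one line per nesting ``parent<TAB>child`` and
per leaf edge ``network<TAB>source<TAB>target``), TSV result tables, and
a JSON run summary.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from .core import BioNetwork, GeneScoreTable, InputError, Subnetwork
from .enrichment import AnnotationTable, EnrichmentResult
from .integration import MetaSubnetwork

__all__ = [
    "EdgeRecord",
    "read_score_file",
    "read_edge_list",
    "read_id_mapping",
    "read_annotations",
    "apply_id_mapping",
    "build_networks",
    "write_outputs",
    "subnetwork_dot",
]

EDGE_CLASSES = ("ppi", "tf-tf", "tf-target")


@dataclass(frozen=True)
class EdgeRecord:
    source: str
    target: str
    edge_class: str  # ppi | tf-tf | tf-target

    def __post_init__(self) -> None:
        if self.edge_class not in EDGE_CLASSES:
            raise InputError(f"unknown edge class {self.edge_class!r}")


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def read_score_file(path, average_duplicates: bool = False) -> Dict[str, float]:
    """Parse a 2-column gene/z-score TSV into a raw score dict.

    A header line is skipped when its second field is non-numeric.
    Duplicate genes are an error unless ``average_duplicates`` — replicate
    scores must be averaged to a single value per gene.
    """
    path = Path(path)
    raw: Dict[str, List[float]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise InputError(f"{path}:{lineno}: expected 2 tab-delimited columns")
            gene, val = parts[0].strip(), parts[1].strip()
            if lineno == 1 and not _is_number(val):
                continue  # header
            if not _is_number(val):
                raise InputError(f"{path}:{lineno}: non-numeric score {val!r} for gene {gene!r}")
            raw.setdefault(gene, []).append(float(val))
    if not raw:
        raise InputError(f"{path}: empty score file")
    out: Dict[str, float] = {}
    for gene, vals in raw.items():
        if len(vals) > 1 and not average_duplicates:
            raise InputError(
                f"{path}: duplicate gene {gene!r} ({len(vals)} entries); "
                "replicates must be averaged (pass average_duplicates=True)"
            )
        out[gene] = sum(vals) / len(vals)
    return out


def read_edge_list(path, default_class: str = "ppi") -> List[EdgeRecord]:
    """Parse an edge TSV; column 3, when present, is the edge-class token.

    Self-loops are dropped with a warning; duplicates collapse; undirected
    (ppi / tf-tf) pairs are canonicalized to sorted order.
    """
    if default_class not in EDGE_CLASSES:
        raise InputError(f"unknown edge class {default_class!r}")
    path = Path(path)
    records: List[EdgeRecord] = []
    seen: Set[Tuple[str, str, str]] = set()
    n_self_loops = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.split("\t")]
            if len(parts) < 2 or not parts[0] or not parts[1]:
                raise InputError(f"{path}:{lineno}: malformed edge line {line!r}")
            cls = parts[2] if len(parts) >= 3 and parts[2] else default_class
            if cls not in EDGE_CLASSES:
                raise InputError(f"{path}:{lineno}: unknown edge class {cls!r}")
            u, v = parts[0], parts[1]
            if u == v:
                n_self_loops += 1
                continue
            if cls != "tf-target":
                u, v = sorted((u, v))
            key = (u, v, cls)
            if key in seen:
                continue
            seen.add(key)
            records.append(EdgeRecord(u, v, cls))
    if n_self_loops:
        warnings.warn(f"{path}: dropped {n_self_loops} self-loop(s)")
    return records


def read_id_mapping(path) -> Dict[str, str]:
    """Parse an alias -> canonical-id TSV. An alias mapping to several
    distinct targets is an error."""
    path = Path(path)
    mapping: Dict[str, str] = {}
    offenders: Set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.split("\t")]
            if len(parts) < 2:
                raise InputError(f"{path}:{lineno}: expected 2 columns")
            alias, canon = parts[0], parts[1]
            if alias in mapping and mapping[alias] != canon:
                offenders.add(alias)
            mapping[alias] = canon
    if offenders:
        raise InputError(f"{path}: aliases with multiple targets: {sorted(offenders)}")
    return mapping


def read_annotations(path) -> AnnotationTable:
    """Parse a gene / term [/ term-name] TSV into an annotation table."""
    path = Path(path)
    gene_terms: Dict[str, Set[str]] = {}
    term_names: Dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.split("\t")]
            if len(parts) < 2:
                raise InputError(f"{path}:{lineno}: expected >= 2 columns")
            gene, term = parts[0], parts[1]
            gene_terms.setdefault(gene, set()).add(term)
            if len(parts) >= 3 and parts[2]:
                term_names[term] = parts[2]
    return AnnotationTable(gene_terms=gene_terms, term_names=term_names)


def apply_id_mapping(
    records: Sequence[EdgeRecord], mapping: Mapping[str, str]
) -> Tuple[List[EdgeRecord], int]:
    """Replace aliases by canonical ids; unmapped identifiers pass through.

    Substitution can merge identifiers: resulting self-loops are dropped
    with a warning and duplicates collapse. Returns (records, unmapped
    identifier count).
    """
    out: List[EdgeRecord] = []
    seen: Set[Tuple[str, str, str]] = set()
    unmapped: Set[str] = set()
    n_self = 0
    for rec in records:
        u = mapping.get(rec.source, rec.source)
        v = mapping.get(rec.target, rec.target)
        if rec.source not in mapping:
            unmapped.add(rec.source)
        if rec.target not in mapping:
            unmapped.add(rec.target)
        if u == v:
            n_self += 1
            continue
        if rec.edge_class != "tf-target":
            u, v = sorted((u, v))
        key = (u, v, rec.edge_class)
        if key in seen:
            continue
        seen.add(key)
        out.append(EdgeRecord(u, v, rec.edge_class))
    if n_self:
        warnings.warn(f"id mapping merged {n_self} edge(s) into self-loops; dropped")
    return out, len(unmapped)


def build_networks(
    records: Sequence[EdgeRecord], tf_set: Optional[Set[str]] = None
) -> Tuple[BioNetwork, BioNetwork]:
    """Route classed edges into the two networks.

    ppi and tf-tf edges build the undirected interactome; tf-target edges
    build the regulome, whose sources are flagged as TFs (in both
    networks) together with any gene in ``tf_set``.
    """
    tfs: Set[str] = set(tf_set or ())
    for rec in records:
        if rec.edge_class == "tf-target":
            tfs.add(rec.source)
        elif rec.edge_class == "tf-tf":
            tfs.add(rec.source)
            tfs.add(rec.target)
    interactome = BioNetwork(kind="interactome", tf_genes=tfs)
    regulome = BioNetwork(kind="regulome", tf_genes=tfs)
    for rec in records:
        if rec.edge_class == "tf-target":
            regulome.add_edge(rec.source, rec.target, directed=True)
        else:
            interactome.add_edge(rec.source, rec.target)
    if interactome.n_edges() == 0:
        raise InputError("interactome is empty after construction")
    if regulome.n_edges() == 0:
        raise InputError("regulome is empty after construction")
    return interactome, regulome


# ---------------------------------------------------------------------------
# output writers


def _z_color(z: float, zmax: float) -> str:
    """Signed two-color fill: green for positive scores, red for negative,
    darker shades for larger magnitudes."""
    if zmax <= 0:
        zmax = 1.0
    frac = min(abs(z) / zmax, 1.0)
    level = int(0xF0 - frac * 0x90)  # 0xF0 (pale) .. 0x60 (dark)
    if z >= 0:
        return f"#{level:02x}f0{level:02x}"
    return f"#f0{level:02x}{level:02x}"


def subnetwork_dot(
    sn: Subnetwork,
    net: BioNetwork,
    scores: GeneScoreTable,
    zmax: Optional[float] = None,
) -> str:
    """GraphViz DOT source for one subnetwork.

    TF nodes are squares; regulome edges are directed; node fill encodes
    z-score sign and magnitude.
    """
    if zmax is None:
        zmax = max((abs(scores[g]) for g in sn.members), default=1.0)
    lines = [f'graph "{sn.id}" {{'] if not net.directed_edges else [f'digraph "{sn.id}" {{']
    sep = "->" if net.directed_edges else "--"
    for g in sorted(sn.members):
        shape = "box" if net.is_tf(g) else "ellipse"
        color = _z_color(scores[g], zmax)
        lines.append(
            f'  "{g}" [shape={shape}, style=filled, fillcolor="{color}", '
            f'label="{g}\\n{scores[g]:.2f}"];'
        )
    sub = net.graph.subgraph(sn.members)
    emitted: Set[Tuple[str, str]] = set()
    for u, v in sorted(tuple(sorted(e)) for e in sub.edges()):
        if net.directed_edges:
            if (u, v) in net.directed_edges:
                a, b = u, v
            elif (v, u) in net.directed_edges:
                a, b = v, u
            else:
                a, b = u, v
        else:
            a, b = u, v
        if (a, b) in emitted:
            continue
        emitted.add((a, b))
        lines.append(f'  "{a}" {sep} "{b}";')
    lines.append("}")
    return "\n".join(lines) + "\n"


def _write_subnetwork_tsv(path: Path, subs: Sequence[Subnetwork]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["id", "network", "seed", "size", "score",
                    "p1", "p2", "p3", "retained", "members"])
        for sn in subs:
            w.writerow([
                sn.id, sn.network_kind, sn.seed, sn.size, f"{sn.score:.6f}",
                "" if sn.p1 is None else f"{sn.p1:.6g}",
                "" if sn.p2 is None else f"{sn.p2:.6g}",
                "" if sn.p3 is None else f"{sn.p3:.6g}",
                int(sn.retained),
                ",".join(sorted(sn.members)),
            ])


def read_subnetwork_tsv(path) -> List[Subnetwork]:
    """Re-read a subnetwork table written by :func:`write_outputs`."""
    subs: List[Subnetwork] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            subs.append(
                Subnetwork(
                    id=row["id"],
                    seed=row["seed"],
                    members=set(row["members"].split(",")),
                    network_kind=row["network"],
                    score=float(row["score"]),
                    p1=float(row["p1"]) if row["p1"] else None,
                    p2=float(row["p2"]) if row["p2"] else None,
                    p3=float(row["p3"]) if row["p3"] else None,
                    retained=bool(int(row["retained"])),
                )
            )
    return subs


def write_outputs(
    out_dir,
    subnetworks: Sequence[Subnetwork],
    metas: Sequence[MetaSubnetwork],
    networks: Mapping[str, BioNetwork],
    scores: GeneScoreTable,
    enrichment: Optional[Mapping[str, Sequence[EnrichmentResult]]] = None,
    summary: Optional[dict] = None,
) -> List[str]:
    """Write DOT files, the NNF nesting file, TSV tables and a JSON run
    summary; returns the manifest of relative file paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: List[str] = []

    retained = [sn for sn in subnetworks if sn.retained]
    dot_dir = out_dir / "dot"
    if retained:
        dot_dir.mkdir(exist_ok=True)
    zmax = max((abs(z) for z in scores.entries.values()), default=1.0)
    for sn in retained:
        net = networks[sn.network_kind]
        p = dot_dir / f"{sn.id}.dot"
        p.write_text(subnetwork_dot(sn, net, scores, zmax=zmax))
        manifest.append(str(p.relative_to(out_dir)))

    _write_subnetwork_tsv(out_dir / "subnetworks.tsv", subnetworks)
    manifest.append("subnetworks.tsv")

    with open(out_dir / "genes.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene", "zscore", "subnetworks"])
        gene2subs: Dict[str, List[str]] = {}
        for sn in retained:
            for g in sn.members:
                gene2subs.setdefault(g, []).append(sn.id)
        for g in sorted(gene2subs):
            w.writerow([g, f"{scores[g]:.6f}", ",".join(sorted(gene2subs[g]))])
    manifest.append("genes.tsv")

    with open(out_dir / "meta_subnetworks.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["id", "n_members", "n_interactome", "n_regulome",
                    "n_genes", "score", "max_member_score", "members"])
        for m in metas:
            w.writerow([m.id, m.n_members, m.n_interactome, m.n_regulome,
                        len(m.union_genes), f"{m.score:.6f}",
                        f"{m.max_member_score:.6f}",
                        ",".join(sorted(m.member_ids))])
    manifest.append("meta_subnetworks.tsv")

    # NNF: meta -> subnetwork nesting lines, then subnetwork -> gene-edge lines
    by_id = {sn.id: sn for sn in subnetworks}
    with open(out_dir / "subnetworks.nnf", "w") as fh:
        for m in metas:
            for sid in sorted(m.member_ids):
                fh.write(f"{m.id}\t{sid}\n")
        for sn in retained:
            net = networks[sn.network_kind]
            sub = net.graph.subgraph(sn.members)
            for u, v in sorted(tuple(sorted(e)) for e in sub.edges()):
                fh.write(f"{sn.id}\t{u}\t{v}\n")
    manifest.append("subnetworks.nnf")

    with open(out_dir / "enrichment.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["set_id", "term", "name", "k", "K", "n", "N",
                    "p", "q", "significant"])
        for set_id in sorted(enrichment or {}):
            for r in enrichment[set_id]:
                w.writerow([set_id, r.term_id, r.term_name, r.k, r.K,
                            r.n, r.N, f"{r.p:.6g}", f"{r.q:.6g}",
                            int(r.significant)])
    manifest.append("enrichment.tsv")

    with open(out_dir / "run_summary.json", "w") as fh:
        json.dump(summary or {}, fh, indent=2, sort_keys=True)
        fh.write("\n")
    manifest.append("run_summary.json")

    with open(out_dir / "MANIFEST.txt", "w") as fh:
        for item in sorted(manifest):
            fh.write(item + "\n")
    return sorted(manifest)
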