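"""Static HTML report: index, per-subnetwork and per-meta pages, gene index.

The report is a pure function of the results and configuration (apart from
one timestamp line), needs no server, and degrades gracefully when no
GraphViz layout engine is installed — DOT sources are always emitted and
linked, rendered SVG images are added when the ``dot`` executable is
found on PATH.
"""

from __future__ import annotations

import html
import shutil
import subprocess
from datetime import datetime, timezone
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

from .core import BioNetwork, GeneScoreTable, Subnetwork
from .enrichment import EnrichmentResult
from .integration import MetaSubnetwork
from .io import subnetwork_dot

__all__ = ["render_report"]

_CSS = """
body { font-family: sans-serif; margin: 2em; max-width: 70em; }
table { border-collapse: collapse; }
td, th { border: 1px solid #999; padding: 0.3em 0.6em; }
th { background: #eee; }
.footer { margin-top: 3em; color: #666; font-size: 0.85em; }
"""


def _page(title: str, body: str, timestamp: str) -> str:
    return (
        "<!DOCTYPE html>\n<html><head><meta charset='utf-8'>"
        f"<title>{html.escape(title)}</title><style>{_CSS}</style></head>\n"
        f"<body><h1>{html.escape(title)}</h1>\n{body}\n"
        "<div class='footer'>Node fill encodes z-score: green positive, red "
        "negative, darker for larger magnitude; transcription factors are "
        "drawn as squares; regulome edges are directed TF &rarr; target.<br>"
        f"Generated {timestamp}</div></body></html>\n"
    )


def _gene_link(gene: str) -> str:
    # NCBI gene link only for all-numeric identifiers (Entrez convention)
    if gene.isdigit():
        return (f"<a href='https://www.ncbi.nlm.nih.gov/gene/{gene}'>"
                f"{html.escape(gene)}</a>")
    return html.escape(gene)


def _enrichment_table(results: Sequence[EnrichmentResult], top: int = 10) -> str:
    if not results:
        return "<p>No enriched terms tested.</p>"
    rows = "".join(
        f"<tr><td>{html.escape(r.term_id)}</td><td>{html.escape(r.term_name)}</td>"
        f"<td>{r.k}/{r.K}</td><td>{r.p:.3g}</td><td>{r.q:.3g}</td>"
        f"<td>{'yes' if r.significant else 'no'}</td></tr>"
        for r in results[:top]
    )
    return ("<table><tr><th>term</th><th>name</th><th>k/K</th><th>p</th>"
            f"<th>q</th><th>significant</th></tr>{rows}</table>")


def render_report(
    out_dir,
    subnetworks: Sequence[Subnetwork],
    metas: Sequence[MetaSubnetwork],
    networks: Mapping[str, BioNetwork],
    scores: GeneScoreTable,
    enrichment: Optional[Mapping[str, Sequence[EnrichmentResult]]] = None,
    config_echo: Optional[dict] = None,
    timestamp: Optional[str] = None,
) -> List[str]:
    """Write the static HTML bundle under ``out_dir/report``; returns the
    manifest of written files (relative to out_dir)."""
    out_dir = Path(out_dir)
    rep = out_dir / "report"
    rep.mkdir(parents=True, exist_ok=True)
    if timestamp is None:
        timestamp = datetime.now(timezone.utc).isoformat(timespec="seconds")
    manifest: List[str] = []
    enrichment = enrichment or {}
    retained = [sn for sn in subnetworks if sn.retained]
    have_dot = shutil.which("dot") is not None
    zmax = max((abs(z) for z in scores.entries.values()), default=1.0)

    # per-subnetwork pages
    for sn in retained:
        net = networks[sn.network_kind]
        dot_src = subnetwork_dot(sn, net, scores, zmax=zmax)
        dot_path = rep / f"{sn.id}.dot"
        dot_path.write_text(dot_src)
        manifest.append(str(dot_path.relative_to(out_dir)))
        img = ""
        if have_dot:
            svg_path = rep / f"{sn.id}.svg"
            try:
                subprocess.run(
                    ["dot", "-Tsvg", "-o", str(svg_path)],
                    input=dot_src.encode(), check=True, timeout=30,
                )
                img = f"<p><img src='{sn.id}.svg' alt='{html.escape(sn.id)}'></p>"
                manifest.append(str(svg_path.relative_to(out_dir)))
            except Exception:
                img = ""
        member_rows = "".join(
            f"<tr><td>{_gene_link(g)}</td><td>{scores[g]:.3f}</td>"
            f"<td>{'TF' if net.is_tf(g) else ''}</td></tr>"
            for g in sorted(sn.members)
        )
        body = (
            f"<p>Network: {sn.network_kind}; seed {html.escape(sn.seed)}; "
            f"{sn.size} genes; score {sn.score:.4f}; "
            f"p-values I/II/III = {sn.p1:.3g} / {sn.p2:.3g} / {sn.p3:.3g}</p>"
            f"{img}"
            f"<p><a href='{sn.id}.dot'>DOT source</a></p>"
            f"<table><tr><th>gene</th><th>z</th><th></th></tr>{member_rows}</table>"
            f"<h2>Enrichment</h2>{_enrichment_table(enrichment.get(sn.id, []))}"
            "<p><a href='index.html'>back to index</a></p>"
        )
        (rep / f"{sn.id}.html").write_text(_page(f"Subnetwork {sn.id}", body, timestamp))
        manifest.append(str((rep / f"{sn.id}.html").relative_to(out_dir)))

    # per-meta pages
    for m in metas:
        links = "".join(
            f"<li><a href='{sid}.html'>{html.escape(sid)}</a></li>"
            for sid in sorted(m.member_ids)
        )
        body = (
            f"<p>{m.n_members} member subnetworks "
            f"({m.n_interactome} interactome, {m.n_regulome} regulome); "
            f"{len(m.union_genes)} genes; score {m.score:.4f} "
            f"(best member {m.max_member_score:.4f})</p>"
            f"<ul>{links}</ul>"
            f"<h2>Enrichment</h2>{_enrichment_table(enrichment.get(m.id, []))}"
            "<p><a href='index.html'>back to index</a></p>"
        )
        (rep / f"{m.id}.html").write_text(_page(f"Meta-subnetwork {m.id}", body, timestamp))
        manifest.append(str((rep / f"{m.id}.html").relative_to(out_dir)))

    # gene index
    gene2subs: Dict[str, List[str]] = {}
    for sn in retained:
        for g in sn.members:
            gene2subs.setdefault(g, []).append(sn.id)
    rows = "".join(
        f"<tr><td>{_gene_link(g)}</td><td>{scores[g]:.3f}</td><td>"
        + ", ".join(f"<a href='{sid}.html'>{html.escape(sid)}</a>"
                    for sid in sorted(gene2subs[g]))
        + "</td></tr>"
        for g in sorted(gene2subs)
    )
    body = (f"<table><tr><th>gene</th><th>z</th><th>subnetworks</th></tr>{rows}"
            "</table><p><a href='index.html'>back to index</a></p>")
    (rep / "genes.html").write_text(_page("Gene index", body, timestamp))
    manifest.append(str((rep / "genes.html").relative_to(out_dir)))

    # index
    if retained:
        sn_rows = "".join(
            f"<tr><td><a href='{sn.id}.html'>{html.escape(sn.id)}</a></td>"
            f"<td>{sn.network_kind}</td><td>{sn.size}</td><td>{sn.score:.4f}</td>"
            f"<td>{sn.p1:.3g}</td><td>{sn.p2:.3g}</td><td>{sn.p3:.3g}</td></tr>"
            for sn in retained
        )
        sn_table = ("<table><tr><th>id</th><th>network</th><th>size</th>"
                    f"<th>score</th><th>pI</th><th>pII</th><th>pIII</th></tr>{sn_rows}</table>")
    else:
        sn_table = "<p>Zero significant subnetworks were retained.</p>"
    meta_rows = "".join(
        f"<tr><td><a href='{m.id}.html'>{html.escape(m.id)}</a></td>"
        f"<td>{m.n_members}</td><td>{len(m.union_genes)}</td><td>{m.score:.4f}</td></tr>"
        for m in metas
    )
    meta_table = (
        ("<table><tr><th>id</th><th>members</th><th>genes</th><th>score</th></tr>"
         f"{meta_rows}</table>") if metas else "<p>No meta-subnetworks.</p>"
    )
    cfg_rows = "".join(
        f"<tr><td>{html.escape(str(k))}</td><td>{html.escape(str(v))}</td></tr>"
        for k, v in sorted((config_echo or {}).items())
    )
    body = (
        f"<h2>Retained subnetworks ({len(retained)})</h2>{sn_table}"
        f"<h2>Meta-subnetworks ({len(metas)})</h2>{meta_table}"
        "<h2>Genes</h2><p><a href='genes.html'>gene index</a></p>"
        f"<h2>Run configuration</h2><table>{cfg_rows}</table>"
    )
    (rep / "index.html").write_text(_page("Screen analysis report", body, timestamp))
    manifest.append(str((rep / "index.html").relative_to(out_dir)))
    return sorted(manifest)
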