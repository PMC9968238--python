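"""ceRNA network assembly and export.

Tripartite graph: circRNA -> miRNA sponge edges (weight = number of sites,
``bsj`` flag for junction-spanning sites), miRNA -> category edges
(weight = number of the miRNA's kept targets in the category) and
category -- category edges (weight = shared target genes).
"""

from __future__ import annotations

import networkx as nx
import pandas as pd

from .targets import SpongeCall


def build_network(
    sponges: list[SpongeCall],
    targets: pd.DataFrame,
    enriched: pd.DataFrame,
    categories: pd.DataFrame,
) -> nx.Graph:
    g = nx.Graph()
    active = [s for s in sponges if s.is_sponge]
    mirnas = {s.mirna for s in active}
    cat_genes = {
        cat: set(group["gene"]) for cat, group in categories.groupby("category")
    }
    enriched_cats = list(enriched["category"]) if len(enriched) else []
    targets_by_mirna = {
        m: set(grp["gene"]) for m, grp in targets.groupby("mirna") if m in mirnas
    }
    kept_genes = set().union(*targets_by_mirna.values()) if targets_by_mirna else set()

    for s in active:
        g.add_node(s.circ_id, kind="circRNA")
        g.add_node(s.mirna, kind="miRNA")
        g.add_edge(s.circ_id, s.mirna, kind="sponge", weight=s.n_sites, bsj=s.has_bsj_site)
    for cat in enriched_cats:
        members = cat_genes.get(cat, set())
        g.add_node(cat, kind="category")
        for mirna, tgenes in sorted(targets_by_mirna.items()):
            shared = tgenes & members
            if shared:
                g.add_edge(mirna, cat, kind="target", weight=len(shared))
    for i, a in enumerate(enriched_cats):
        for b in enriched_cats[i + 1 :]:
            shared = cat_genes.get(a, set()) & cat_genes.get(b, set()) & kept_genes
            if shared:
                g.add_edge(a, b, kind="shared", weight=len(shared))
    return g


def to_sif(g: nx.Graph) -> str:
    lines = []
    for u, v, data in sorted(g.edges(data=True)):
        lines.append(f"{u}\t{data.get('kind', 'edge')}\t{v}")
    return "\n".join(lines) + ("\n" if lines else "")


def write_graphml(g: nx.Graph, path: str) -> None:
    nx.write_graphml(g, path)
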