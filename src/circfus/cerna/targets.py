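"""Sponge calling, target filtering and over-representation analysis."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .sites import BindingSite

SOURCE_FLAGS = ["targetscan", "mirdb", "mirtarbase", "tarbase"]


@dataclass
class SpongeCall:
    circ_id: str
    mirna: str
    n_sites: int
    has_bsj_site: bool

    @property
    def is_sponge(self) -> bool:
        return self.n_sites >= 2 or self.has_bsj_site


def _dedup(sites: list[BindingSite]) -> list[BindingSite]:
    """Sites overlapping by > 50% of the shorter site count once (keep the
    higher-scoring one)."""
    kept: list[BindingSite] = []
    for s in sorted(sites, key=lambda s: -s.score):
        dup = False
        for k in kept:
            ov = min(s.end, k.end) - max(s.start, k.start)
            if ov > 0.5 * min(s.end - s.start, k.end - k.start):
                dup = True
                break
        if not dup:
            kept.append(s)
    return kept


def call_sponges(sites: list[BindingSite]) -> list[SpongeCall]:
    groups: dict[tuple[str, str], list[BindingSite]] = {}
    for s in sites:
        groups.setdefault((s.circ_id, s.mirna), []).append(s)
    out = []
    for (circ_id, mirna), group in sorted(groups.items()):
        group = _dedup(group)
        out.append(
            SpongeCall(circ_id, mirna, len(group), any(s.spans_bsj for s in group))
        )
    return out


def filter_targets(
    sponges: list[SpongeCall],
    interactions: pd.DataFrame,
    mrna_fc: pd.DataFrame,
    protein_fc: pd.DataFrame,
    min_score: float = 0.95,
) -> pd.DataFrame:
    """Targets of sponged miRNAs passing score / corroboration /
    downregulation filters.

    Keep (miRNA, gene) iff score >= min_score AND >= 1 source flag set AND
    the gene is downregulated at the mRNA and/or protein level; rows with a
    validated-interaction flag (tarbase) bypass the score threshold.
    """
    sponged = {s.mirna for s in sponges if s.is_sponge}
    df = interactions[interactions["mirna"].isin(sponged)].copy()
    flags = [f for f in SOURCE_FLAGS if f in df.columns]
    corroborated = df[flags].sum(axis=1) > 0 if flags else False
    validated = df["tarbase"] > 0 if "tarbase" in df.columns else False
    score_ok = df["score"] >= min_score
    df = df[(score_ok & corroborated) | validated]
    mlfc = mrna_fc.set_index("gene")["log2fc"]
    plfc = protein_fc.set_index("gene")["log2fc"]
    df["mrna_log2fc"] = df["gene"].map(mlfc)
    df["protein_log2fc"] = df["gene"].map(plfc)
    down = (df["mrna_log2fc"] < 0) | (df["protein_log2fc"] < 0)
    return df[down.fillna(False)].reset_index(drop=True)


def ora_enrichment(
    target_genes: set[str],
    categories: pd.DataFrame,
    background: set[str],
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Hypergeometric over-representation of the target set in each
    category; returns categories with p < alpha."""
    if not target_genes <= background:
        raise ValueError("background must contain all target genes")
    rows = []
    N = len(background)
    n = len(target_genes)
    for cat, group in categories.groupby("category"):
        members = set(group["gene"]) & background
        K = len(members)
        k = len(members & target_genes)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((cat, k, K, p))
    df = pd.DataFrame(rows, columns=["category", "overlap", "size", "p_value"])
    return df[df["p_value"] < alpha].sort_values("p_value").reset_index(drop=True)
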