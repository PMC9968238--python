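"""Faux-circRNA null model and localization preference test.

Faux circRNAs are runs of consecutive internal exons drawn from the
circ-hosting transcripts, with run lengths sampled from the empirical
exon-count distribution of the real circRNAs.  Preferential localization is
assessed with a chi-squared test on the real-vs-faux contingency table over
the observed region-flag combinations.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy import stats

from ..models import Gene, Transcript
from .regions import RegionProfile, region_profile


def exon_count(gene: Gene, start: int, end: int) -> int:
    """Number of exons included between a junction pair.

    Per-isoform counts (exons overlapping [start, end)) are averaged over
    the isoforms that overlap the circ and rounded half up.
    """
    counts = []
    for tx in gene.transcripts:
        n = sum(1 for s, e in tx.exons if s < end and start < e)
        if n:
            counts.append(n)
    if not counts:
        raise ValueError("circ overlaps no exon of any isoform")
    return int(np.floor(np.mean(counts) + 0.5))


def exon_count_distribution(circ_spans, genes: dict[str, Gene]) -> dict[int, float]:
    """``circ_spans``: iterable of (gene_id, start, end) for circRNAs whose
    junctions fall in exons (intronic/intergenic ones are excluded
    upstream).  Returns the empirical distribution of exon counts."""
    counter = Counter(exon_count(genes[gid], s, e) for gid, s, e in circ_spans)
    total = sum(counter.values())
    return {k: v / total for k, v in sorted(counter.items())}


@dataclass
class FauxCircSet:
    draws: list[tuple[str, int, int]]  # (transcript_id, first internal exon idx, n_exons)
    exon_count_dist: dict[int, float]


def sample_faux_circs(
    hosts: list[Transcript],
    dist: dict[int, float],
    n: int = 5000,
    seed: int = 0,
) -> FauxCircSet:
    """Draw ``n`` runs of consecutive internal exons (first/last excluded)."""
    rng = np.random.default_rng(seed)
    ks = np.array(sorted(dist))
    ps = np.array([dist[k] for k in ks], dtype=float)
    ps = ps / ps.sum()
    if not any(len(t.exons) >= k + 2 for t in hosts for k in ks):
        raise ValueError("no host transcript can fit any drawn exon count")
    draws = []
    while len(draws) < n:
        k = int(rng.choice(ks, p=ps))
        valid = [t for t in hosts if len(t.exons) >= k + 2]
        if not valid:  # impossible draw: redraw to preserve support
            continue
        t = valid[int(rng.integers(0, len(valid)))]
        i = int(rng.integers(1, len(t.exons) - k))  # internal start index
        draws.append((t.transcript_id, i, k))
    return FauxCircSet(draws, dict(dist))


def faux_profiles(faux: FauxCircSet, transcripts: dict[str, Transcript]) -> list[RegionProfile]:
    out = []
    for idx, (tid, i, k) in enumerate(faux.draws):
        tx = transcripts[tid]
        start = tx.exons[i][0]
        end = tx.exons[i + k - 1][1]
        out.append(RegionProfile(f"faux_{idx}", region_profile(tx, start, end)))
    return out


def localization_test(real: list[RegionProfile], faux: list[RegionProfile]):
    """Chi-squared test over the observed region-combination categories.

    Returns (statistic, df, p_value).
    """
    if not real or not faux:
        raise ValueError("both profile sets must be non-empty")
    combos = sorted(
        {p.overlaps for p in real} | {p.overlaps for p in faux},
        key=lambda f: sorted(f),
    )
    idx = {c: i for i, c in enumerate(combos)}
    table = np.zeros((2, len(combos)))
    for p in real:
        table[0, idx[p.overlaps]] += 1
    for p in faux:
        table[1, idx[p.overlaps]] += 1
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row * col / table.sum()
    stat = float(((table - expected) ** 2 / expected).sum())
    df = len(combos) - 1
    p = float(stats.chi2.sf(stat, df)) if df > 0 else 1.0
    if stat == 0.0:
        p = 1.0
    return stat, df, p
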