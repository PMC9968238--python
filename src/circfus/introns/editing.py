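"""Alu editing index: pooled weighted A-to-G mismatch level over expressed
Alu elements.

For plus-strand Alus every reference-A position contributes; reads showing
G there are counted as edited (coverage = A + G reads).  Minus-strand Alus
are measured on the reverse complement: reference-T positions, C reads as
edited.  Site totals are pooled before division (weighted-average
semantics) and reported as a percentage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..detect.aligner import GenomeIndex
from ..gio import revcomp


@dataclass
class EditingIndex:
    sample: str
    scope: str  # "global" | "flanks"
    a_coverage: int
    g_mismatches: int
    index: float | None  # percentage, None when coverage is zero
    n_expressed_alus: int


def place_reads(index: GenomeIndex, pairs, max_mm: int = 2, exclude_positions=None):
    """Uniquely placed full-length mates as (pos, forward-strand seq).

    ``exclude_positions`` (a set) exempts candidate editing sites from the
    mismatch budget so edited reads are not lost.
    """
    exclude = None
    if exclude_positions:
        exclude = exclude_positions.__contains__
    out = []
    for _, s1, s2 in pairs:
        for seq in (s1, s2):
            hits = index.map_full(seq, max_mm, exclude=exclude)
            if len(hits) == 1:
                h = hits[0]
                out.append((h.pos, seq if h.strand == "+" else revcomp(seq)))
    return out


def _alu_records(alus) -> list[tuple[str, int, int, str]]:
    if isinstance(alus, pd.DataFrame):
        return [
            (r["chrom"], int(r["start"]), int(r["end"]), r["strand"])
            for _, r in alus.iterrows()
        ]
    return [(a.chrom, a.start, a.end, a.strand) for a in alus]


def alu_editing_index(
    placements,
    genome: str,
    alus,
    sample: str = "",
    scope_regions=None,
    min_cov: int = 10,
) -> EditingIndex:
    """Compute the pooled editing index for one sample.

    ``placements``: (pos, forward-strand read sequence) tuples;
    ``scope_regions``: optional genomic intervals restricting the Alu set
    (e.g. circRNA flanks); an Alu is "expressed" when at least ``min_cov``
    of its A positions are covered.
    """
    records = _alu_records(alus)
    if scope_regions is not None:
        records = [
            (c, s, e, st)
            for c, s, e, st in records
            if any(s < hi and lo < e for lo, hi in scope_regions)
        ]

    # per-Alu site tallies
    site_pos: list[int] = []
    site_strand: list[str] = []
    site_alu: list[int] = []
    for ai, (_, s, e, strand) in enumerate(records):
        base = "A" if strand == "+" else "T"
        for p in range(s, e):
            if genome[p] == base:
                site_pos.append(p)
                site_strand.append(strand)
                site_alu.append(ai)
    order = np.argsort(site_pos, kind="stable") if site_pos else []
    pos_arr = np.asarray(site_pos)[order] if site_pos else np.array([], dtype=int)
    strand_arr = np.asarray(site_strand)[order] if site_pos else np.array([])
    alu_arr = np.asarray(site_alu)[order] if site_pos else np.array([], dtype=int)

    cov = np.zeros(len(pos_arr), dtype=int)
    mis = np.zeros(len(pos_arr), dtype=int)
    for pos, seq in placements:
        lo = np.searchsorted(pos_arr, pos)
        hi = np.searchsorted(pos_arr, pos + len(seq))
        for k in range(lo, hi):
            base = seq[pos_arr[k] - pos]
            if strand_arr[k] == "+":
                if base == "A":
                    cov[k] += 1
                elif base == "G":
                    cov[k] += 1
                    mis[k] += 1
            else:
                if base == "T":
                    cov[k] += 1
                elif base == "C":
                    cov[k] += 1
                    mis[k] += 1

    total_cov = 0
    total_mis = 0
    n_expressed = 0
    for ai in range(len(records)):
        mask = alu_arr == ai
        covered_sites = int((cov[mask] > 0).sum())
        if covered_sites < min_cov:
            continue
        n_expressed += 1
        total_cov += int(cov[mask].sum())
        total_mis += int(mis[mask].sum())

    index = 100.0 * total_mis / total_cov if total_cov else None
    scope = "flanks" if scope_regions is not None else "global"
    return EditingIndex(sample, scope, total_cov, total_mis, index, n_expressed)
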