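"""1-kb flanking intronic regions: extraction, FUS-binding marks, inverted
Alu detection."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

FLANK_WIDTH = 1000


@dataclass
class FlankRegion:
    circ_id: str
    chrom: str
    strand: str
    upstream: tuple[int, int]  # 1 kb ending at the circ start (clipped)
    downstream: tuple[int, int]  # 1 kb starting at the circ end (clipped)
    de_status: str = "unaffected"  # up | down | unaffected
    fus_bound: bool = False
    inverted_alu: bool = False
    bound_flanks: set = field(default_factory=set)


def extract_flanks(
    circs,
    concordance: pd.DataFrame | None = None,
    chrom_len: int | None = None,
    width: int = FLANK_WIDTH,
) -> list[FlankRegion]:
    """Flanks for circRNAs tested for differential expression.

    ``circs``: iterable of (circ_id, chrom, start, end, strand, de_status).
    Concordantly deregulated circRNAs (class "both-concordant" in the
    concordance table) are excluded — a direct effect on their biogenesis is
    less likely.  Flanks are genomic-coordinate windows regardless of
    strand, clipped at position 0 / chromosome end.
    """
    excluded = set()
    if concordance is not None:
        excluded = set(concordance.index[concordance["class"] == "both-concordant"])
    out = []
    for circ_id, chrom, start, end, strand, status in circs:
        if circ_id in excluded:
            continue
        up = (max(0, start - width), start)
        down = (end, min(chrom_len, end + width) if chrom_len else end + width)
        out.append(FlankRegion(circ_id, chrom, strand, up, down, status))
    return out


def _overlaps(lo: int, hi: int, s: int, e: int) -> bool:
    return lo < e and s < hi


def mark_fus_bound(flanks: list[FlankRegion], transitions: pd.DataFrame) -> list[FlankRegion]:
    """Set ``fus_bound`` where >= 1 T-to-C transition overlaps either flank
    (half-open interval overlap)."""
    by_chrom: dict[str, list[int]] = {}
    for _, row in transitions.iterrows():
        by_chrom.setdefault(row["chrom"], []).append(int(row["start"]))
    for chrom in by_chrom:
        by_chrom[chrom].sort()
    import bisect

    for f in flanks:
        positions = by_chrom.get(f.chrom, [])
        f.bound_flanks = set()
        for side, (lo, hi) in (("up", f.upstream), ("down", f.downstream)):
            i = bisect.bisect_left(positions, lo)
            if i < len(positions) and positions[i] < hi:
                f.bound_flanks.add(side)
        f.fus_bound = bool(f.bound_flanks)
    return flanks


def detect_inverted_alus(flanks: list[FlankRegion], alus: pd.DataFrame) -> list[FlankRegion]:
    """Set ``inverted_alu`` where an upstream-flank Alu and a downstream-
    flank Alu have opposite orientation (partial flank overlap counts)."""
    records = [
        (row["chrom"], int(row["start"]), int(row["end"]), row["strand"])
        for _, row in alus.iterrows()
    ]
    for f in flanks:
        up_strands = {
            strand
            for chrom, s, e, strand in records
            if chrom == f.chrom and _overlaps(f.upstream[0], f.upstream[1], s, e)
        }
        down_strands = {
            strand
            for chrom, s, e, strand in records
            if chrom == f.chrom and _overlaps(f.downstream[0], f.downstream[1], s, e)
        }
        f.inverted_alu = bool(
            ("+" in up_strands and "-" in down_strands)
            or ("-" in up_strands and "+" in down_strands)
        )
    return flanks
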