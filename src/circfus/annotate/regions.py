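"""Localization of circRNAs within host-transcript regions.

Regions are 5UTR / CDS / 3UTR (exonic split at the coding span) plus
INTRON.  A circRNA's profile is the set of region types its body overlaps
by at least 1 bp; by default the body is the host transcript's exonic
sequence clipped to the circ span, but an explicit body (e.g. with a
retained intron) can be supplied.
"""

from __future__ import annotations

from dataclasses import dataclass

from ..models import Transcript

REGION_TYPES = ("5UTR", "CDS", "3UTR", "INTRON")

Interval = tuple[int, int]


@dataclass
class RegionProfile:
    circ_id: str
    overlaps: frozenset[str]


def transcript_regions(tx: Transcript) -> dict[str, list[Interval]]:
    """Genomic intervals of each region type for one transcript."""
    regions: dict[str, list[Interval]] = {r: [] for r in REGION_TYPES}
    regions["INTRON"] = list(tx.introns)
    if tx.cds is None:
        return regions
    cs, ce = tx.cds
    left_utr = "5UTR" if tx.strand == "+" else "3UTR"
    right_utr = "3UTR" if tx.strand == "+" else "5UTR"
    for s, e in tx.exons:
        if s < cs:
            regions[left_utr].append((s, min(e, cs)))
        if max(s, cs) < min(e, ce):
            regions["CDS"].append((max(s, cs), min(e, ce)))
        if e > ce:
            regions[right_utr].append((max(s, ce), e))
    return regions


def _overlaps(a: Interval, b: Interval) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def circ_body_intervals(tx: Transcript, start: int, end: int) -> list[Interval]:
    """Exonic intervals of the host transcript clipped to the circ span."""
    out = []
    for s, e in tx.exons:
        lo, hi = max(s, start), min(e, end)
        if lo < hi:
            out.append((lo, hi))
    return out


def region_profile(
    tx: Transcript,
    start: int,
    end: int,
    body: list[Interval] | None = None,
) -> frozenset[str]:
    if body is None:
        body = circ_body_intervals(tx, start, end)
    regions = transcript_regions(tx)
    flags = {
        rtype
        for rtype, ivs in regions.items()
        if any(_overlaps(b, iv) for b in body for iv in ivs)
    }
    return frozenset(flags)


def classify_regions(assignments, transcripts: dict[str, Transcript]) -> list[RegionProfile]:
    """``assignments``: iterable of (circ_id, transcript_id, start, end).

    Order-independent and idempotent; output follows input order.
    """
    out = []
    for circ_id, tid, start, end in assignments:
        tx = transcripts[tid]
        out.append(RegionProfile(circ_id, region_profile(tx, start, end)))
    return out
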