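"""Read preprocessing: adapter clipping, duplicate removal, contaminant
filtering."""

from __future__ import annotations

from ..gio import revcomp

MIN_LEN_AFTER_TRIM = 18


class InputError(ValueError):
    pass


def trim_read(seq: str, adapter: str, min_len: int = MIN_LEN_AFTER_TRIM) -> str | None:
    """Clip an exact adapter suffix.

    The read is scanned for the leftmost position ``i`` such that
    ``seq[i:]`` is a prefix of the adapter; everything from ``i`` on is
    removed.  Returns ``None`` when fewer than ``min_len`` bases remain.
    """
    if not adapter:
        return seq
    probe = adapter[: min(8, len(adapter))]
    i = seq.find(probe)
    while i != -1:
        if seq[i:] == adapter[: len(seq) - i]:
            clipped = seq[:i]
            return clipped if len(clipped) >= min_len else None
        i = seq.find(probe, i + 1)
    # adapter may start within the last probe-length bases
    for i in range(max(0, len(seq) - len(probe) + 1), len(seq)):
        if seq[i:] == adapter[: len(seq) - i]:
            clipped = seq[:i]
            return clipped if len(clipped) >= min_len else None
    return seq


def trim_pairs(pairs, adapter: str, min_len: int = MIN_LEN_AFTER_TRIM):
    """Trim both mates; drop pairs where either mate falls below min_len."""
    out = []
    for name, s1, s2 in pairs:
        t1 = trim_read(s1, adapter, min_len)
        t2 = trim_read(s2, adapter, min_len)
        if t1 is not None and t2 is not None:
            out.append((name, t1, t2))
    return out


def dedup_reads(r1: list[tuple[str, str]], r2: list[tuple[str, str]]):
    """Remove exact duplicates and reverse-complement exact duplicates.

    A pair is removed iff its (seq1, seq2) equals, or is the mate-swapped
    reverse complement of, an already retained pair; the first occurrence
    wins.
    """
    if len(r1) != len(r2):
        raise InputError(f"r1/r2 length mismatch: {len(r1)} vs {len(r2)}")
    seen: set[tuple[str, str]] = set()
    out1, out2 = [], []
    for (n1, s1), (n2, s2) in zip(r1, r2):
        fwd = (s1, s2)
        rc = (revcomp(s2), revcomp(s1))
        key = min(fwd, rc)
        if key in seen:
            continue
        seen.add(key)
        out1.append((n1, s1))
        out2.append((n2, s2))
    return out1, out2


def filter_contaminants(pairs, contam_db: dict[str, str], max_mm: int = 1):
    """Drop pairs where either mate aligns end-to-end to a contaminant with
    at most ``max_mm`` mismatches (both orientations)."""
    if not contam_db:
        return list(pairs)
    from .aligner import GenomeIndex

    index = GenomeIndex(("N" * 25).join(contam_db.values()))
    out = []
    for name, s1, s2 in pairs:
        if index.map_full(s1, max_mm) or index.map_full(s2, max_mm):
            continue
        out.append((name, s1, s2))
    return out
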