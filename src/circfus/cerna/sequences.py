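"""circRNA sequence reconstruction across the back-splice junction.

For every transcript overlapping a circRNA, the exonic subsequence spanned
by the circ is extracted and its 3' end extended with the first 125 nt of
its own 5' end; BSJ read pairs are aligned to each candidate and the
transcript with the most supporting pairs (both mates aligned, at least one
crossing the original 3' end) wins.  The final sequence retains only the
first 25 nt of the extension.
"""

from __future__ import annotations

from dataclasses import dataclass

from ..gio import revcomp
from ..models import Gene, Transcript

EXT_SEARCH = 125
EXT_KEEP = 25


@dataclass
class CircSequence:
    circ_id: str
    transcript_id: str
    seq: str  # body + first EXT_KEEP nt of the body
    bsj_offset: int  # = body length; seq[bsj_offset:] == seq[:EXT_KEEP]
    support: int


def candidate_body(tx: Transcript, genome: str, start: int, end: int) -> str:
    """Exonic subsequence of ``tx`` clipped to [start, end), in transcript
    orientation (starting at the acceptor)."""
    parts = []
    for s, e in tx.exons:
        lo, hi = max(s, start), min(e, end)
        if lo < hi:
            parts.append(genome[lo:hi])
    body = "".join(parts)
    return body if tx.strand == "+" else revcomp(body)


def _occurrences(needle: str, haystack: str) -> list[int]:
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def _pair_support(extended: str, body_len: int, s1: str, s2: str) -> bool:
    """True when both mates align to the candidate and at least one of them
    crosses the original 3' end (offset ``body_len``)."""
    hits = []
    for seq in (s1, s2):
        occ = []
        for oriented in (seq, revcomp(seq)):
            occ += [(p, p + len(oriented)) for p in _occurrences(oriented, extended)]
        if not occ:
            return False
        hits.append(occ)
    return any(a < body_len < b for occ in hits for a, b in occ)


def reconstruct_sequences(
    circs,
    genes: list[Gene],
    genome: str,
    bsj_pairs: dict[str, list[tuple[str, str]]],
    expressed_transcripts: set[str] | None = None,
    ext_keep: int = EXT_KEEP,
) -> tuple[list[CircSequence], dict[str, str]]:
    """``circs``: iterable of (circ_id, chrom, start, end, strand).

    Returns (sequences, dropped) where ``dropped`` maps circ ids without
    any supported candidate to a reason string.
    """
    sequences: list[CircSequence] = []
    dropped: dict[str, str] = {}
    for circ_id, chrom, start, end, strand in circs:
        candidates: list[tuple[Transcript, str]] = []
        for g in genes:
            if g.chrom != chrom or g.strand != strand:
                continue
            for tx in g.transcripts:
                if expressed_transcripts is not None and tx.transcript_id not in expressed_transcripts:
                    continue
                if any(s < end and start < e for s, e in tx.exons):
                    body = candidate_body(tx, genome, start, end)
                    if body:
                        candidates.append((tx, body))
        if not candidates:
            dropped[circ_id] = "no overlapping expressed transcript"
            continue
        pairs = bsj_pairs.get(circ_id, [])
        best: tuple[int, Transcript, str] | None = None
        for tx, body in candidates:
            extended = body + body[:EXT_SEARCH]
            support = sum(_pair_support(extended, len(body), s1, s2) for s1, s2 in pairs)
            if best is None or support > best[0]:
                best = (support, tx, body)
        support, tx, body = best
        if support < 1:
            dropped[circ_id] = "no BSJ read pair supports any candidate"
            continue
        sequences.append(
            CircSequence(circ_id, tx.transcript_id, body + body[:ext_keep], len(body), support)
        )
    return sequences, dropped
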