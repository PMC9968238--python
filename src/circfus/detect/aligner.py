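"""Exact k-mer seed index with mismatch-tolerant full-length verification.

Stands in for a general-purpose short-read aligner on desk-scale synthetic
genomes.  The contract consumed downstream is only: does a read have a
full-length contiguous placement (with at most ``max_mm`` mismatches), and
is an exact 20-nt anchor placement unique or multiple.
"""

from __future__ import annotations

from dataclasses import dataclass

from ..gio import revcomp

ANCHOR_LEN = 20


@dataclass(frozen=True)
class Placement:
    pos: int  # 0-based offset of the leftmost base on the forward strand
    strand: str  # orientation of the read relative to the forward strand
    mismatches: int


class GenomeIndex:
    """Exact k-mer index over the forward strand of one sequence."""

    def __init__(self, genome: str, k: int = ANCHOR_LEN):
        self.genome = genome
        self.k = k
        index: dict[str, list[int]] = {}
        for i in range(len(genome) - k + 1):
            index.setdefault(genome[i : i + k], []).append(i)
        self._index = index

    def __len__(self) -> int:
        return len(self.genome)

    def seed_positions(self, kmer: str) -> list[int]:
        return self._index.get(kmer, [])

    # ------------------------------------------------------------------
    def _mismatches(self, seq: str, pos: int, budget: int,
                    exclude=None) -> int | None:
        g = self.genome
        mm = 0
        for i, c in enumerate(seq):
            if g[pos + i] != c:
                if exclude is not None and exclude(pos + i):
                    continue
                mm += 1
                if mm > budget:
                    return None
        return mm

    def map_full(self, read: str, max_mm: int = 2, exclude=None) -> list[Placement]:
        """All full-length contiguous placements of the read (both
        orientations) with at most ``max_mm`` mismatches.

        ``exclude(pos)`` may exempt genomic positions from the mismatch
        budget (used by the editing index so edited sites do not bias
        coverage).
        """
        k = self.k
        out: list[Placement] = []
        n = len(self.genome)
        L = len(read)
        if L < k:
            return out
        for strand, seq in (("+", read), ("-", revcomp(read))):
            # pigeonhole seeding: with max_mm mismatches, at least one of
            # max_mm+1 disjoint seeds is exact (when L >= (max_mm+1)*k)
            offsets = list(range(0, L - k + 1, k))
            if offsets[-1] != L - k:
                offsets.append(L - k)
            candidates: set[int] = set()
            for off in offsets:
                for p in self.seed_positions(seq[off : off + k]):
                    candidates.add(p - off)
            for p in sorted(candidates):
                if p < 0 or p + L > n:
                    continue
                mm = self._mismatches(seq, p, max_mm, exclude)
                if mm is not None:
                    out.append(Placement(p, strand, mm))
        return out

    def map_anchor(self, anchor: str) -> list[int]:
        """Exact placements of a 20-nt anchor on the forward strand."""
        return self.seed_positions(anchor)
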