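"""Shared domain types.

All coordinates are 0-based half-open on the forward genomic strand unless
noted otherwise.  Exon lists are kept in genomic order regardless of gene
strand; transcript order is derived from the strand when needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class Transcript:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]  # genomic order
    cds: tuple[int, int] | None = None  # genomic span of the coding region

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]

    def exons_in_transcript_order(self) -> list[tuple[int, int]]:
        return self.exons if self.strand == "+" else list(reversed(self.exons))

    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass
class Gene:
    gene_id: str
    chrom: str
    strand: str
    biotype: str = "protein_coding"
    transcripts: list[Transcript] = field(default_factory=list)

    @property
    def start(self) -> int:
        return min(t.start for t in self.transcripts)

    @property
    def end(self) -> int:
        return max(t.end for t in self.transcripts)

    def overlaps(self, other: "Gene") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


@dataclass
class CircJunction:
    """A head-to-tail (back-splice) junction.

    ``start`` is the 0-based acceptor boundary (first base of the circRNA),
    ``end`` the end-exclusive donor boundary.
    """

    chrom: str
    start: int
    end: int
    strand: str
    n_reads: int = 0
    n_unique_reads: int = 0
    best_anchor_quality: int = 0
    splice_signal: str = ""
    host_genes: list[str] = field(default_factory=list)
    host_biotype: str = ""

    @property
    def span(self) -> int:
        return self.end - self.start

    @property
    def circ_id(self) -> str:
        # 1-based closed rendering, e.g. "16:8858350-8859335_-"
        return f"{self.chrom}:{self.start + 1}-{self.end}_{self.strand}"

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.start, self.end, self.strand)


def circ_id_to_coords(circ_id: str) -> tuple[str, int, int, str]:
    """Invert :attr:`CircJunction.circ_id` back to 0-based half-open coords."""
    loc, strand = circ_id.rsplit("_", 1)
    chrom, rng = loc.rsplit(":", 1)
    start, end = rng.split("-")
    return chrom, int(start) - 1, int(end), strand


def genes_from_gtf(records) -> list[Gene]:
    """Assemble :class:`Gene` models from parsed GTF records (exon + CDS)."""
    genes: dict[str, Gene] = {}
    transcripts: dict[str, Transcript] = {}
    cds_bounds: dict[str, list[int]] = {}
    for rec in records:
        gid = rec.attributes.get("gene_id", "")
        tid = rec.attributes.get("transcript_id", "")
        if rec.feature == "exon":
            if gid not in genes:
                genes[gid] = Gene(
                    gid,
                    rec.chrom,
                    rec.strand,
                    rec.attributes.get("gene_biotype", "protein_coding"),
                )
            if tid not in transcripts:
                transcripts[tid] = Transcript(tid, gid, rec.chrom, rec.strand, [])
                genes[gid].transcripts.append(transcripts[tid])
            transcripts[tid].exons.append((rec.start, rec.end))
        elif rec.feature == "CDS":
            cds_bounds.setdefault(tid, []).extend([rec.start, rec.end])
    for tid, t in transcripts.items():
        t.exons.sort()
        if tid in cds_bounds:
            t.cds = (min(cds_bounds[tid]), max(cds_bounds[tid]))
    return list(genes.values())
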