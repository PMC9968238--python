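"""Planted ground truth carried alongside the synthetic data.

Every downstream stage's expected output is computable from
:class:`GroundTruth` alone; tests use it as the oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ..models import Gene, Transcript
from ..gio import revcomp


@dataclass
class PlantedCirc:
    index: int
    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    start: int  # acceptor boundary, 0-based
    end: int  # donor boundary, end-exclusive
    exon_range: tuple[int, int]  # inclusive indices into host exons, genomic order
    lfc: float
    counts: dict[str, int] = field(default_factory=dict)  # sample -> BSJ pairs
    has_inverted_alu: bool = False
    localization: str = "cyt"

    @property
    def circ_id(self) -> str:
        return f"{self.chrom}:{self.start + 1}-{self.end}_{self.strand}"


@dataclass
class DecoyJunction:
    """A planted head-to-tail junction flanked by an AT..AC signal; the
    detector must reject it."""

    chrom: str
    start: int
    end: int
    gene_id: str
    pairs_per_sample: int


@dataclass
class AluElement:
    chrom: str
    start: int
    end: int
    strand: str
    editing_rate: float
    circ_index: int | None = None  # flank membership, None for background
    side: str | None = None  # "up" | "down"
    # genomic positions whose base on the Alu strand is A (editable sites)
    sites: list[int] = field(default_factory=list)

    @property
    def name(self) -> str:
        tag = "bg" if self.circ_index is None else f"circ{self.circ_index}_{self.side}"
        return f"alu_{tag}_{self.start}"


@dataclass
class PlantedSite:
    circ_index: int
    mirna: str
    offsets: list[int]  # site starts on the circ body (transcript orientation)
    bsj_spanning: bool


@dataclass
class TargetPlan:
    mirna: str
    gene: str
    mode: str  # "mrna" | "protein" | "both"
    validated: bool = False  # TarBase-like flag bypassing the score threshold


@dataclass
class GroundTruth:
    chrom: str
    chrom_len: int
    genes: list[Gene]
    circs: list[PlantedCirc]
    decoys: list[DecoyJunction]
    alus: list[AluElement]
    mirnas: dict[str, str]
    mirna_expressed: dict[str, bool]
    planted_sites: list[PlantedSite]
    targets: list[TargetPlan]
    gene_abundance: dict[str, float]
    batch_factor: dict[str, float]  # sample -> depth multiplier
    contaminant: str
    transitions: list[tuple[str, int, str]] = field(default_factory=list)

    # ------------------------------------------------------------------
    def gene_by_id(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def transcript_by_id(self, tid: str) -> Transcript:
        for g in self.genes:
            for t in g.transcripts:
                if t.transcript_id == tid:
                    return t
        raise KeyError(tid)

    def circ_exons(self, circ: PlantedCirc) -> list[tuple[int, int]]:
        t = self.transcript_by_id(circ.transcript_id)
        i, j = circ.exon_range
        return t.exons[i : j + 1]

    def circ_body(self, circ: PlantedCirc, genome: str) -> str:
        """Spliced circRNA sequence in transcript orientation, starting at
        the acceptor (the base immediately after the BSJ)."""
        parts = [genome[s:e] for s, e in self.circ_exons(circ)]
        body = "".join(parts)
        return body if circ.strand == "+" else revcomp(body)

    def junction_window(self, circ: PlantedCirc, genome: str, read_len: int,
                        margin: int = 1) -> str:
        """Sequence window such that every read crossing the BSJ by at least
        ``margin`` nt on both sides is one of its substrings (or of its
        reverse complement)."""
        body = self.circ_body(circ, genome)
        return body[-(read_len - margin):] + body[: read_len - margin]

    def flanks(self, circ: PlantedCirc, width: int = 1000) -> tuple[tuple[int, int], tuple[int, int]]:
        up = (max(0, circ.start - width), circ.start)
        down = (circ.end, min(self.chrom_len, circ.end + width))
        return up, down
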