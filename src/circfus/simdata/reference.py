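"""Synthetic genome, annotation and repeat generation with planted truth.

Layout: a single chromosome carrying ``n_genes`` multi-exon genes separated
by intergenic spacers.  Canonical splice signals are stamped on the genomic
strand appropriate to each gene's strand (GT..AG for plus genes, CT..AC on
the forward strand for minus genes, i.e. GT..AG on the template).  A chosen
subset of genes hosts planted circRNAs over runs of internal exons; their
flanking introns may carry inverted Alu pairs within 1 kb of the
circularized exons.  miRNA binding sites (including one spanning the BSJ)
are written into circ exons so the ceRNA stage has recoverable truth.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..gio import revcomp, write_fasta, write_gtf, write_bed6, GtfRecord
from ..models import Gene, Transcript
from .config import SimConfig, ConfigError
from .truth import (
    AluElement,
    DecoyJunction,
    GroundTruth,
    PlantedCirc,
    PlantedSite,
    TargetPlan,
)

_BASES = np.array(list("ACGT"))
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

SPACER = 1200
FLANK_WIDTH = 1000
ALU_OFFSET = 60  # distance between a flank Alu and the circ boundary


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def _body_positions(exons: list[tuple[int, int]], strand: str) -> list[int]:
    """Genomic position of every body base, in transcript orientation."""
    pos: list[int] = []
    if strand == "+":
        for s, e in exons:
            pos.extend(range(s, e))
    else:
        for s, e in reversed(exons):
            pos.extend(range(e - 1, s - 1, -1))
    return pos


def nb_draw(rng: np.random.Generator, mean, dispersion: float, size=None):
    """NB counts via a gamma-Poisson mixture; dispersion 0 gives Poisson."""
    if dispersion <= 0:
        return rng.poisson(mean, size)
    lam = rng.gamma(1.0 / dispersion, np.asarray(mean) * dispersion, size)
    return rng.poisson(lam)


def generate_reference(config: SimConfig):
    """Build genome FASTA text, GTF text, Alu BED6 text and GroundTruth."""
    config.validate()
    rng = np.random.default_rng([1, config.seed])
    chrom = "chr1"

    # ------------------------------------------------------------- genes
    genes: list[Gene] = []
    cursor = SPACER
    for gi in range(config.n_genes):
        strand = "+" if rng.random() < 0.5 else "-"
        n_ex = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        exon_lens = rng.integers(config.exon_len[0], config.exon_len[1] + 1, n_ex)
        intron_lens = rng.integers(config.intron_len[0], config.intron_len[1] + 1, n_ex - 1)
        exons = []
        pos = cursor
        for k in range(n_ex):
            exons.append((pos, pos + int(exon_lens[k])))
            pos += int(exon_lens[k])
            if k < n_ex - 1:
                pos += int(intron_lens[k])
        cursor = pos + SPACER
        biotype = "lincRNA" if gi == config.n_genes - 1 else "protein_coding"
        gid = f"G{gi:03d}"
        tx = Transcript(f"T{gi:03d}.1", gid, chrom, strand, exons)
        if biotype == "protein_coding":
            u5 = int(rng.integers(40, 91))
            u3 = int(rng.integers(40, 91))
            # long UTRs reach into the second / penultimate exon for some
            # genes, so internal exons are not uniformly coding
            k5 = int(rng.random() < 0.5)
            k3 = int(rng.random() < 0.5)
            if strand == "+":
                tx.cds = (exons[k5][0] + u5, exons[-1 - k3][1] - u3)
            else:
                tx.cds = (exons[k3][0] + u3, exons[-1 - k5][1] - u5)
        genes.append(Gene(gid, chrom, strand, biotype, [tx]))
    chrom_len = cursor + SPACER

    seq = rng.choice(_BASES, size=chrom_len)

    # --------------------------------------------- splice signal stamping
    for g in genes:
        for tx in g.transcripts:
            for istart, iend in tx.introns:
                if g.strand == "+":
                    seq[istart : istart + 2] = list("GT")
                    seq[iend - 2 : iend] = list("AG")
                else:
                    seq[istart : istart + 2] = list("CT")
                    seq[iend - 2 : iend] = list("AC")

    # ------------------------------------------------------------- circs
    lfcs = config.effective_lfc()
    circs: list[PlantedCirc] = []
    for ci in range(config.n_circ):
        g = genes[ci]
        tx = g.transcripts[0]
        n_ex = len(tx.exons)
        run = None
        for span in (2, 3, 2, 3, 4):
            if n_ex - 2 < span:
                continue
            i = int(rng.integers(1, n_ex - span))  # internal start index
            cand = tx.exons[i : i + span]
            body_len = sum(e - s for s, e in cand)
            if body_len >= config.frag_len:
                run = (i, i + span - 1)
                break
        if run is None:  # fall back: all internal exons
            run = (1, n_ex - 2)
        start = tx.exons[run[0]][0]
        end = tx.exons[run[1]][1]
        circs.append(
            PlantedCirc(
                index=ci,
                gene_id=g.gene_id,
                transcript_id=tx.transcript_id,
                chrom=chrom,
                strand=g.strand,
                start=start,
                end=end,
                exon_range=run,
                lfc=lfcs[ci],
            )
        )
    if len(circs) > 2:
        circs[2].localization = "nuc"

    # ----------------------------------------------------------- miRNAs
    mirnas = {f"mir-sim-{i + 1}": _rand_seq(rng, config.mirna_len) for i in range(config.n_mirnas)}
    mirna_expressed = {name: True for name in mirnas}
    if config.n_mirnas >= 8:
        mirna_expressed[f"mir-sim-{config.n_mirnas}"] = False

    planted_sites: list[PlantedSite] = []

    def _plant_site(circ: PlantedCirc, site_seq: str, body_offset: int) -> None:
        exons = [
            (s, e)
            for s, e in genes[circ.index].transcripts[0].exons[
                circ.exon_range[0] : circ.exon_range[1] + 1
            ]
        ]
        pos = _body_positions(exons, circ.strand)
        body_len = len(pos)
        for k, base in enumerate(site_seq):
            p = pos[(body_offset + k) % body_len]
            seq[p] = base if circ.strand == "+" else _COMP[base]

    def _exon_interior_offsets(circ: PlantedCirc, n_sites: int, m: int,
                               used: list[tuple[int, int]]) -> list[int]:
        exons = genes[circ.index].transcripts[0].exons[
            circ.exon_range[0] : circ.exon_range[1] + 1
        ]
        lens = [e - s for s, e in exons]
        if circ.strand == "-":
            lens = lens[::-1]
        cum = np.cumsum([0] + lens)
        offsets = []
        for _ in range(200):
            if len(offsets) == n_sites:
                break
            k = int(rng.integers(0, len(lens)))
            lo, hi = cum[k] + 4, cum[k + 1] - 4 - m
            if hi <= lo:
                continue
            o = int(rng.integers(lo, hi))
            if all(o + m <= a or o >= b for a, b in used):
                offsets.append(o)
                used.append((o, o + m))
        return sorted(offsets)

    if config.n_circ >= 2 and config.n_mirnas >= 3:
        m = config.mirna_len
        # circ0: two sites each for mir-sim-1 and mir-sim-2
        used: list[tuple[int, int]] = []
        for name in ("mir-sim-1", "mir-sim-2"):
            offs = _exon_interior_offsets(circs[0], 2, m, used)
            for o in offs:
                _plant_site(circs[0], revcomp(mirnas[name]), o)
            planted_sites.append(PlantedSite(0, name, offs, False))
        # circ1: two sites for mir-sim-1 (shared-miRNA motif) and one
        # BSJ-spanning site for mir-sim-3
        used = []
        offs = _exon_interior_offsets(circs[1], 2, m, used)
        for o in offs:
            _plant_site(circs[1], revcomp(mirnas["mir-sim-1"]), o)
        planted_sites.append(PlantedSite(1, "mir-sim-1", offs, False))
        body_len1 = sum(e - s for s, e in genes[1].transcripts[0].exons[
            circs[1].exon_range[0] : circs[1].exon_range[1] + 1
        ])
        bsj_off = body_len1 - 10  # 10 nt before the junction, wraps around
        _plant_site(circs[1], revcomp(mirnas["mir-sim-3"]), bsj_off)
        planted_sites.append(PlantedSite(1, "mir-sim-3", [bsj_off], True))

    # --------------------------------------------------------------- Alus
    alu_consensus = _rand_seq(rng, config.alu_len)
    alus: list[AluElement] = []

    def _place_alu(start: int, strand: str, rate: float,
                   circ_index: int | None, side: str | None) -> None:
        alu_seq = alu_consensus if strand == "+" else revcomp(alu_consensus)
        seq[start : start + config.alu_len] = list(alu_seq)
        base = "A" if strand == "+" else "T"
        sites = [start + k for k, b in enumerate(alu_seq) if b == base]
        alus.append(
            AluElement(chrom, start, start + config.alu_len, strand, rate,
                       circ_index, side, sites)
        )

    for ci in config.effective_inverted_alu_circs():
        if ci >= len(circs):
            raise ConfigError(f"inverted_alu_circs index {ci} out of range")
        circ = circs[ci]
        tx = genes[ci].transcripts[0]
        up_intron = tx.introns[circ.exon_range[0] - 1]
        down_intron = tx.introns[circ.exon_range[1]]
        up_start = circ.start - ALU_OFFSET - config.alu_len
        down_start = circ.end + ALU_OFFSET
        if up_start < up_intron[0] + 2 or down_start + config.alu_len > down_intron[1] - 2:
            raise ConfigError("intron too short for flank Alu placement")
        _place_alu(up_start, "+", config.editing_rate, ci, "up")
        _place_alu(down_start, "-", config.editing_rate, ci, "down")

    bg_genes = [g for gi, g in enumerate(genes) if gi >= config.n_circ + config.n_decoys]
    placed = 0
    attempts = 0
    while placed < config.n_background_alus and bg_genes and attempts < 500:
        attempts += 1
        g = bg_genes[int(rng.integers(0, len(bg_genes)))]
        tx = g.transcripts[0]
        introns = tx.introns
        istart, iend = introns[int(rng.integers(0, len(introns)))]
        if iend - istart < config.alu_len + 40:
            continue
        start = int(rng.integers(istart + 20, iend - 20 - config.alu_len))
        if any(a.chrom == chrom and start < a.end + 10 and a.start - 10 < start + config.alu_len
               for a in alus):
            continue
        _place_alu(start, "+" if rng.random() < 0.5 else "-", config.editing_rate, None, None)
        placed += 1

    # -------------------------------------------------------------- decoys
    decoys: list[DecoyJunction] = []
    for di in range(config.n_decoys):
        g = genes[config.n_circ + di]
        tx = g.transcripts[0]
        introns = tx.introns
        if len(introns) < 2:
            continue
        a_int = introns[0]
        d_int = introns[-1]
        da = a_int[0] + (a_int[1] - a_int[0]) // 2
        dd = d_int[0] + (d_int[1] - d_int[0]) // 2
        seq[dd : dd + 2] = list("AT")
        seq[da - 2 : da] = list("AC")
        decoys.append(DecoyJunction(chrom, da, dd, g.gene_id, config.decoy_pairs))

    # ---------------------------------------------------- per-sample counts
    batch_factor = {
        s: float(np.exp(rng.normal(0.0, config.batch_effect_sd)))
        for s in config.samples
    }
    design = config.design
    for circ in circs:
        for s in config.samples:
            cond = design[s][0]
            mean = config.circ_abundance * batch_factor[s]
            if cond == config.conditions[1]:
                mean *= 2.0 ** circ.lfc
            circ.counts[s] = int(nb_draw(rng, mean, config.nb_dispersion))

    gene_abundance = {
        g.gene_id: float(rng.lognormal(np.log(config.gene_abundance), 0.3))
        for g in genes
    }

    # ------------------------------------------------------------- tables
    target_modes = ["mrna", "protein", "both"]
    targets: list[TargetPlan] = []
    tg = 0
    for site in planted_sites:
        if any(t.mirna == site.mirna for t in targets):
            continue
        for k in range(4):
            validated = k == 3
            targets.append(
                TargetPlan(site.mirna, f"TG{tg:03d}", target_modes[k % 3], validated)
            )
            tg += 1

    contaminant = _rand_seq(rng, 1500)

    genome = "".join(seq)
    truth = GroundTruth(
        chrom=chrom,
        chrom_len=chrom_len,
        genes=genes,
        circs=circs,
        decoys=decoys,
        alus=alus,
        mirnas=mirnas,
        mirna_expressed=mirna_expressed,
        planted_sites=planted_sites,
        targets=targets,
        gene_abundance=gene_abundance,
        batch_factor=batch_factor,
        contaminant=contaminant,
    )

    fasta = write_fasta([(chrom, genome)])
    gtf = write_gtf(_gtf_records(genes))
    bed = write_bed6(
        pd.DataFrame(
            [(a.chrom, a.start, a.end, a.name, 0, a.strand) for a in alus],
            columns=["chrom", "start", "end", "name", "score", "strand"],
        )
    )
    return fasta, gtf, bed, truth


def _gtf_records(genes: list[Gene]) -> list[GtfRecord]:
    records = []
    for g in genes:
        for tx in g.transcripts:
            attrs = {
                "gene_id": g.gene_id,
                "transcript_id": tx.transcript_id,
                "gene_biotype": g.biotype,
            }
            for s, e in tx.exons:
                records.append(GtfRecord(g.chrom, "sim", "exon", s, e, g.strand, dict(attrs)))
            if tx.cds is not None:
                cs, ce = tx.cds
                for s, e in tx.exons:
                    os_, oe = max(s, cs), min(e, ce)
                    if os_ < oe:
                        records.append(
                            GtfRecord(g.chrom, "sim", "CDS", os_, oe, g.strand, dict(attrs))
                        )
    return records
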