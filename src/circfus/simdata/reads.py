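"""Paired-end read simulation from the synthetic reference.

Per sample the generator emits, in order: linear (mature and pre-mRNA)
fragments per gene, BSJ-spanning pairs for each planted circRNA (exactly the
planted count), decoy-junction pairs, rRNA-like contaminant pairs, and a
tail of exact / reverse-complement duplicate pairs drawn from the linear
reads.  Mates are emitted unstranded (random mate swap).  A-to-I editing is
applied in genomic space at per-Alu rates before orientation, so edited
pre-mRNA reads carry G (plus-strand Alus) or C (minus) at planted sites.
"""

from __future__ import annotations

import numpy as np

from ..gio import read_fasta, revcomp, write_fastq
from .config import SimConfig
from .truth import GroundTruth
from .reference import nb_draw


class SimulationError(RuntimeError):
    pass


def _spliced(genome: str, tx) -> str:
    s = "".join(genome[a:b] for a, b in tx.exons)
    return s if tx.strand == "+" else revcomp(s)


def _pair_from_fragment(frag: str, read_len: int, rng) -> tuple[str, str]:
    r1 = frag[:read_len]
    r2 = revcomp(frag[-read_len:])
    if rng.random() < 0.5:  # unstranded library
        r1, r2 = r2, r1
    return r1, r2


def simulate_reads(genome, truth: GroundTruth, config: SimConfig) -> dict[str, tuple[str, str]]:
    """Return ``{sample: (r1_fastq_text, r2_fastq_text)}``."""
    if isinstance(genome, str) and genome.startswith(">"):
        genome = read_fasta(genome)[truth.chrom]
    rng = np.random.default_rng([2, config.seed])
    read_len, frag_len = config.read_len, config.frag_len

    # editing site lookup arrays
    site_pos, site_rate, site_sub = [], [], []
    for alu in truth.alus:
        for p in alu.sites:
            site_pos.append(p)
            site_rate.append(alu.editing_rate)
            site_sub.append("G" if alu.strand == "+" else "C")
    order = np.argsort(site_pos) if site_pos else []
    site_pos = np.asarray(site_pos)[order] if len(site_pos) else np.array([], dtype=int)
    site_rate = np.asarray(site_rate)[order] if len(site_rate) else np.array([])
    site_sub = np.asarray(site_sub)[order] if len(site_sub) else np.array([])

    def _edited_slice(start: int) -> str:
        raw = genome[start : start + frag_len]
        lo = np.searchsorted(site_pos, start)
        hi = np.searchsorted(site_pos, start + frag_len)
        if lo == hi:
            return raw
        chars = list(raw)
        for k in range(lo, hi):
            if rng.random() < site_rate[k]:
                chars[site_pos[k] - start] = site_sub[k]
        return "".join(chars)

    out: dict[str, tuple[str, str]] = {}
    for sample in config.samples:
        pairs: list[tuple[str, str, str]] = []
        linear_idx: list[int] = []
        serial = 0

        def _emit(tag: str, r1: str, r2: str, linear: bool = False) -> None:
            nonlocal serial
            pairs.append((f"{sample}:{serial}:{tag}", r1, r2))
            if linear:
                linear_idx.append(len(pairs) - 1)
            serial += 1

        # ----------------------------------------------------- linear reads
        for g in truth.genes:
            tx = g.transcripts[0]
            mean = truth.gene_abundance[g.gene_id] * truth.batch_factor[sample]
            n = int(nb_draw(rng, mean, config.nb_dispersion))
            n_pre = int(rng.binomial(n, config.premrna_frac))
            mature = _spliced(genome, tx)
            for _ in range(n - n_pre):
                if len(mature) <= frag_len:
                    frag = mature
                else:
                    st = int(rng.integers(0, len(mature) - frag_len + 1))
                    frag = mature[st : st + frag_len]
                _emit(f"lin:{g.gene_id}", *_pair_from_fragment(frag, read_len, rng), linear=True)
            gstart, gend = tx.start, tx.end
            for _ in range(n_pre):
                st = int(rng.integers(gstart, max(gstart + 1, gend - frag_len + 1)))
                frag = _edited_slice(st)
                if tx.strand == "-":
                    frag = revcomp(frag)
                _emit(f"pre:{g.gene_id}", *_pair_from_fragment(frag, read_len, rng), linear=True)

        # -------------------------------------------------------- BSJ reads
        for circ in truth.circs:
            body = truth.circ_body(circ, genome)
            if read_len > len(body) or frag_len > len(body):
                raise SimulationError(
                    f"{circ.circ_id}: reads/fragments longer than the circRNA "
                    "would wrap more than once"
                )
            doubled = body + body
            for _ in range(circ.counts.get(sample, 0)):
                # junction offset inside the crossing mate; >= 8 nt on both
                # sides so a BSJ read is never a 1-2 nt coincidence away
                # from a linear substring
                u = int(rng.integers(8, read_len - 7))
                fstart = len(body) - u
                frag = doubled[fstart : fstart + frag_len]
                _emit(f"bsj:{circ.circ_id}", *_pair_from_fragment(frag, read_len, rng))

        # ----------------------------------------------------- decoy reads
        for di, decoy in enumerate(truth.decoys):
            for _ in range(decoy.pairs_per_sample):
                u = int(rng.integers(30, read_len - 29))
                frag = genome[decoy.end - u : decoy.end] + genome[
                    decoy.start : decoy.start + frag_len - u
                ]
                _emit(f"decoy:{di}", *_pair_from_fragment(frag, read_len, rng))

        # ---------------------------------------------------- contaminants
        n_lin = len(linear_idx)
        for _ in range(int(round(config.contam_frac * n_lin))):
            st = int(rng.integers(0, len(truth.contaminant) - frag_len + 1))
            frag = truth.contaminant[st : st + frag_len]
            _emit("contam", *_pair_from_fragment(frag, read_len, rng))

        # --------------------------------------------- adapter read-through
        n_adapter = int(round(config.adapter_frac * n_lin))
        if n_adapter and n_lin:
            chosen = rng.choice(np.asarray(linear_idx), size=n_adapter, replace=False)
            alen = min(20, len(config.adapter))
            for idx in chosen:
                name, r1, r2 = pairs[idx]
                pairs[idx] = (name, r1[: read_len - alen] + config.adapter[:alen], r2)

        # ------------------------------------------------------- duplicates
        n_dup = int(round(config.dup_frac * n_lin))
        if n_dup and n_lin:
            chosen = rng.choice(np.asarray(linear_idx), size=n_dup, replace=True)
            for idx in chosen:
                _, r1, r2 = pairs[idx]
                if rng.random() < 0.5:  # reverse-complement exact duplicate
                    r1, r2 = revcomp(r2), revcomp(r1)
                _emit("dup", r1, r2)

        r1_txt = write_fastq((f"{name}/1", s1) for name, s1, _ in pairs)
        r2_txt = write_fastq((f"{name}/2", s2) for name, _, s2 in pairs)
        out[sample] = (r1_txt, r2_txt)
    return out
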