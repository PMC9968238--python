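"""Shared fixtures: the default seeded simulation and its pipeline outputs."""

from __future__ import annotations

import pytest

from circfus import pipeline
from circfus.gio import read_fasta, read_fastq
from circfus.simdata import (
    SimConfig,
    generate_reference,
    simulate_parclip,
    simulate_reads,
    simulate_tables,
)

DEFAULT_SEED = 1


@pytest.fixture(scope="session")
def sim():
    """Default desk-scale simulation (seed 1): reference + reads + tables."""
    cfg = SimConfig(seed=DEFAULT_SEED)
    fasta, gtf, alus_bed, truth = generate_reference(cfg)
    genome = read_fasta(fasta)[truth.chrom]
    reads = simulate_reads(genome, truth, cfg)
    parclip = simulate_parclip(genome, truth, cfg)
    tables = simulate_tables(truth, cfg)
    return {
        "cfg": cfg,
        "fasta": fasta,
        "gtf": gtf,
        "alus_bed": alus_bed,
        "truth": truth,
        "genome": genome,
        "reads": reads,
        "parclip": parclip,
        "tables": tables,
    }


@pytest.fixture(scope="session")
def detected(sim):
    """Full multi-sample detection on the default simulation."""
    cfg = sim["cfg"]
    truth = sim["truth"]
    sample_reads = {
        s: (read_fastq(r1), read_fastq(r2)) for s, (r1, r2) in sim["reads"].items()
    }
    junctions, tables, results = pipeline.run_detection(
        sim["genome"],
        sample_reads,
        truth.genes,
        chrom=truth.chrom,
        adapter=cfg.adapter,
        contam_db={"rRNA": truth.contaminant},
    )
    return {"junctions": junctions, "tables": tables, "results": results}


@pytest.fixture(scope="session")
def de_results(sim, detected):
    cfg = sim["cfg"]
    return pipeline.run_de(detected["tables"], cfg.design, cfg.conditions)


@pytest.fixture(scope="session")
def minisim():
    """Tiny genome (< 10 kb) without Alus/decoys, for oracle comparisons."""
    cfg = SimConfig(
        seed=11,
        n_genes=2,
        n_circ=2,
        n_decoys=0,
        exons_per_gene=(5, 5),
        exon_len=(110, 160),
        intron_len=(300, 500),
        inverted_alu_circs=(),
        n_background_alus=0,
        background_transition_density=0.0,
        gene_abundance=120.0,
        circ_abundance=15.0,
        contam_frac=0.0,
        adapter_frac=0.0,
        premrna_frac=0.1,
    )
    fasta, gtf, alus_bed, truth = generate_reference(cfg)
    genome = read_fasta(fasta)[truth.chrom]
    reads = simulate_reads(genome, truth, cfg)
    return {"cfg": cfg, "truth": truth, "genome": genome, "reads": reads, "gtf": gtf}
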