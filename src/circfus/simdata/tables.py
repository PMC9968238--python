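"""Expression / interaction table simulation.

Emulates the external resources consumed by the ceRNA stage: a miRNA-gene
interaction table (prediction score plus four source flags), mRNA and
protein log2 fold-change tables with planted concordant downregulation of
true sponge targets, a miRNA expression table and a gene-category map.

Background interaction rows are engineered to fail the target filters
(score < 0.95, or no corroborating source), so the expected target set is
exactly the planted one — tests rely on this.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import SimConfig
from .truth import GroundTruth

SOURCE_FLAGS = ["targetscan", "mirdb", "mirtarbase", "tarbase"]


def simulate_tables(truth: GroundTruth, config: SimConfig) -> dict[str, pd.DataFrame]:
    rng = np.random.default_rng([4, config.seed])
    bg_genes = [f"BG{i:03d}" for i in range(150)]
    target_genes = sorted({t.gene for t in truth.targets})
    host_genes = [g.gene_id for g in truth.genes]
    all_genes = host_genes + target_genes + bg_genes

    # ------------------------------------------------------ fold changes
    mrna_rows, prot_rows = [], []
    modes = {t.gene: t.mode for t in truth.targets}
    for gene in all_genes:
        mode = modes.get(gene)
        mlfc = rng.normal(0.0, 0.25)
        plfc = rng.normal(0.0, 0.25)
        if mode in ("mrna", "both"):
            mlfc = -abs(rng.normal(1.2, 0.3))
        elif mode == "protein":
            mlfc = rng.normal(0.0, 0.05)
        if mode in ("protein", "both"):
            plfc = -abs(rng.normal(1.2, 0.3))
        elif mode == "mrna":
            plfc = rng.normal(0.0, 0.05)
        mrna_rows.append((gene, round(float(mlfc), 4)))
        prot_rows.append((gene, round(float(plfc), 4)))
    mrna_fc = pd.DataFrame(mrna_rows, columns=["gene", "log2fc"])
    protein_fc = pd.DataFrame(prot_rows, columns=["gene", "log2fc"])

    # ------------------------------------------------------ interactions
    rows = []
    for t in truth.targets:
        flags = {f: 0 for f in SOURCE_FLAGS}
        if t.validated:
            score = round(float(rng.uniform(0.5, 0.9)), 4)  # bypasses threshold
            flags["tarbase"] = 1
        else:
            score = round(float(rng.uniform(0.95, 1.0)), 4)
            flags[SOURCE_FLAGS[int(rng.integers(0, 3))]] = 1
        rows.append({"mirna": t.mirna, "gene": t.gene, "score": score, **flags})
    mirna_names = list(truth.mirnas)
    for _ in range(300):
        mirna = mirna_names[int(rng.integers(0, len(mirna_names)))]
        gene = bg_genes[int(rng.integers(0, len(bg_genes)))]
        flags = {f: 0 for f in SOURCE_FLAGS}
        if rng.random() < 0.5:
            # corroborated but sub-threshold score
            score = round(float(rng.uniform(0.0, 0.94)), 4)
            flags[SOURCE_FLAGS[int(rng.integers(0, 3))]] = 1
        else:
            # high score but no corroborating source
            score = round(float(rng.uniform(0.95, 1.0)), 4)
        rows.append({"mirna": mirna, "gene": gene, "score": score, **flags})
    interactions = pd.DataFrame(rows).drop_duplicates(["mirna", "gene"])

    # -------------------------------------------------- miRNA expression
    mirna_expression = pd.DataFrame(
        [
            (name, round(float(rng.uniform(5, 50)), 2) if truth.mirna_expressed[name] else 0.1)
            for name in truth.mirnas
        ],
        columns=["mirna", "cpm"],
    )

    # --------------------------------------------------------- categories
    cat_rows = []
    by_mirna: dict[str, list[str]] = {}
    for t in truth.targets:
        by_mirna.setdefault(t.mirna, []).append(t.gene)
    cat_names = ["CAT_axon_transport", "CAT_signaling", "CAT_synapse"]
    for ci, (mirna, members) in enumerate(sorted(by_mirna.items())):
        cat = cat_names[ci % len(cat_names)]
        for gene in members:
            cat_rows.append((cat, gene))
        cat_rows.append((cat, bg_genes[ci]))  # one background member each
    for k in range(5):
        members = rng.choice(bg_genes, size=8, replace=False)
        cat_rows.extend((f"CAT_bg{k}", g) for g in members)
    categories = pd.DataFrame(sorted(set(cat_rows)), columns=["category", "gene"])

    # ------------------------------------------------------- localization
    localization = pd.DataFrame(
        [(c.circ_id, c.localization) for c in truth.circs],
        columns=["circ_id", "compartment"],
    )

    return {
        "mrna_fc": mrna_fc,
        "protein_fc": protein_fc,
        "interactions": interactions,
        "mirna_expression": mirna_expression,
        "categories": categories,
        "localization": localization,
    }
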