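"""High-level orchestration shared by the CLI, the tests and the
acceptance script."""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import detect, diffexp
from .models import Gene


def run_detection(
    genome: str,
    sample_reads: dict[str, tuple[list, list]],
    genes: list[Gene] | None = None,
    cfg: detect.DetectConfig | None = None,
    chrom: str = "chr1",
    adapter: str = "",
    contam_db: dict[str, str] | None = None,
):
    """Detect and merge junctions across samples; annotate host genes.

    ``sample_reads``: sample -> (r1 records, r2 records) with records as
    (read_id, sequence).  Returns (junctions, tables, results).
    """
    cfg = cfg or detect.DetectConfig()
    index = detect.GenomeIndex(genome)
    results = {}
    for sample, (r1, r2) in sample_reads.items():
        results[sample] = detect.detect_sample(
            index, r1, r2, cfg, chrom=chrom, adapter=adapter, contam_db=contam_db
        )
    merged, tables = detect.merge_samples(results, cfg)
    if genes is not None:
        merged = detect.annotate_junctions(merged, genes)
        kept = {j.circ_id for j in merged}
        tables = {
            s: {cid: row for cid, row in t.items() if cid in kept}
            for s, t in tables.items()
        }
    return merged, tables, results


def run_de(
    tables: dict[str, dict],
    design: dict[str, tuple],
    conditions: tuple[str, str],
    alpha_circ: float = 0.05,
    alpha_lin: float = 0.1,
):
    """Count matrix -> expression calling -> NB LRT -> concordance."""
    matrix = diffexp.build_matrix(tables, design)
    lib = diffexp.library_sizes(matrix)
    cpm_m = diffexp.cpm(matrix, lib)
    expressed = diffexp.expressed_sets(cpm_m, design)
    test_m = diffexp.testing_filter(matrix, design, conditions)
    res = diffexp.nb_glm_lrt(test_m, design, conditions, lib_sizes=lib, alpha=alpha_circ)

    circ_rows = res.index.str.endswith(diffexp.CIRC_SUFFIX)
    de_circ = res[circ_rows].copy()
    de_circ.index = de_circ.index.str.removesuffix(diffexp.CIRC_SUFFIX)
    de_lin = res[~circ_rows].copy()
    de_lin.index = de_lin.index.str.removesuffix(diffexp.LINEAR_SUFFIX)
    de_lin["status"] = np.where(
        (de_lin["p_value"] < alpha_lin) & (de_lin["log2FC"] > 0),
        "up",
        np.where(
            (de_lin["p_value"] < alpha_lin) & (de_lin["log2FC"] < 0),
            "down",
            "unaffected",
        ),
    )
    concordance = diffexp.classify_concordance(de_circ, de_lin, alpha_circ, alpha_lin)
    summary = diffexp.concordance_summary(concordance)
    return {
        "matrix": matrix,
        "cpm": cpm_m,
        "expressed": expressed,
        "tested": test_m,
        "de_circular": de_circ,
        "de_linear": de_lin,
        "concordance": concordance,
        "summary": summary,
    }


def tables_to_long(tables: dict[str, dict]) -> pd.DataFrame:
    rows = []
    for sample, t in tables.items():
        for cid, (circ, lin_a, lin_d) in t.items():
            rows.append((cid, sample, circ, lin_a, lin_d))
    return pd.DataFrame(
        rows, columns=["junction_id", "sample", "circular", "linear_acceptor", "linear_donor"]
    )


def tables_from_long(df: pd.DataFrame) -> dict[str, dict]:
    out: dict[str, dict] = {}
    for _, r in df.iterrows():
        out.setdefault(r["sample"], {})[r["junction_id"]] = (
            int(r["circular"]),
            int(r["linear_acceptor"]),
            int(r["linear_donor"]),
        )
    return out
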