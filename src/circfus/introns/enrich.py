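"""Enrichment statistics for flanking-intron features."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .flanks import FlankRegion


def fisher_binding_enrichment(flanks: list[FlankRegion]) -> dict[str, dict]:
    """One-sided Fisher's exact tests comparing the proportion of bound
    flanking regions among up- and downregulated circRNAs to the proportion
    among unaffected circRNAs (alternative: greater binding in the
    deregulated group)."""
    out = {}
    unaff = [f for f in flanks if f.de_status == "unaffected"]
    for direction in ("down", "up"):
        group = [f for f in flanks if f.de_status == direction]
        table = [
            [sum(f.fus_bound for f in group), sum(not f.fus_bound for f in group)],
            [sum(f.fus_bound for f in unaff), sum(not f.fus_bound for f in unaff)],
        ]
        _, p = stats.fisher_exact(table, alternative="greater")
        out[direction] = {
            "table": table,
            "p_value": float(p),
            "n_deregulated": len(group),
            "n_unaffected": len(unaff),
        }
    return out


def hypergeom_overlap(bound_set: set, inverted_set: set, universe: set) -> dict:
    """P(X >= observed overlap), X ~ Hypergeom(|U|, |bound|, |inverted|)."""
    if not bound_set <= universe or not inverted_set <= universe:
        raise ValueError("sets must be subsets of the universe")
    N = len(universe)
    K = len(bound_set)
    n = len(inverted_set)
    k = len(bound_set & inverted_set)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return {"overlap": k, "universe": N, "bound": K, "inverted": n, "p_value": p}


def compare_editing(pairs: list[tuple[float, float]]) -> dict:
    """Two-sided paired t-test on per-sample editing-index pairs
    (e.g. deregulated-flank scope vs unaffected-flank scope).

    Identical pairs give t = 0 and p = 1 by convention.
    """
    a = np.array([x for x, _ in pairs], dtype=float)
    b = np.array([y for _, y in pairs], dtype=float)
    diff = a - b
    if np.allclose(diff.std(ddof=1) if len(diff) > 1 else 0.0, 0.0):
        return {"t": 0.0 if np.allclose(diff, 0.0) else float("inf"), "p_value": 1.0 if np.allclose(diff, 0.0) else 0.0, "n": len(pairs)}
    t, p = stats.ttest_rel(a, b)
    return {"t": float(t), "p_value": float(p), "n": len(pairs)}


def expression_passthrough(expression: pd.DataFrame, genes: list[str],
                           gene_col: str = "gene") -> pd.DataFrame:
    """Report expression rows for user-designated genes (e.g. editing
    enzymes) unchanged from the supplied table — an identity contract."""
    return expression[expression[gene_col].isin(genes)].reset_index(drop=True)
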