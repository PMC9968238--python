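"""Concordance of circular events with their cognate linear RNAs."""

from __future__ import annotations

import numpy as np
import pandas as pd

CLASSES = ("circ-only", "linear-only", "both-concordant", "both-discordant", "neither")


def classify_concordance(
    circ: pd.DataFrame,
    linear: pd.DataFrame,
    alpha_circ: float = 0.05,
    alpha_lin: float = 0.1,
) -> pd.DataFrame:
    """Classify each matched circ/linear event pair.

    Both inputs are indexed by a shared junction id and carry ``log2FC`` and
    ``p_value`` columns.  "Concordant" means both members significant at
    their thresholds with the same fold-change sign.
    """
    common = circ.index.intersection(linear.index)
    c = circ.loc[common]
    l = linear.loc[common]
    c_sig = c["p_value"] < alpha_circ
    l_sig = l["p_value"] < alpha_lin
    same_sign = np.sign(c["log2FC"]) == np.sign(l["log2FC"])
    cls = np.select(
        [
            c_sig & l_sig & same_sign,
            c_sig & l_sig & ~same_sign,
            c_sig & ~l_sig,
            ~c_sig & l_sig,
        ],
        ["both-concordant", "both-discordant", "circ-only", "linear-only"],
        default="neither",
    )
    return pd.DataFrame(
        {
            "class": cls,
            "circ_log2FC": c["log2FC"],
            "circ_p": c["p_value"],
            "linear_log2FC": l["log2FC"],
            "linear_p": l["p_value"],
        },
        index=common,
    )


def concordance_summary(classes: pd.DataFrame) -> dict:
    """Summary over deregulated circRNAs (circ significant): how many vary
    concordantly with their linear counterpart, as a rounded percentage."""
    dereg = classes["class"].isin(["circ-only", "both-concordant", "both-discordant"])
    down = dereg & (classes["circ_log2FC"] < 0)
    up = dereg & (classes["circ_log2FC"] > 0)
    conc = classes["class"] == "both-concordant"
    n_dereg = int(dereg.sum())
    n_conc = int((dereg & conc).sum())
    percent = int(np.floor(100.0 * n_conc / n_dereg + 0.5)) if n_dereg else 0
    return {
        "n_deregulated": n_dereg,
        "n_down": int(down.sum()),
        "n_up": int(up.sum()),
        "n_down_concordant": int((down & conc).sum()),
        "n_up_concordant": int((up & conc).sum()),
        "n_concordant": n_conc,
        "percent_concordant": percent,
    }
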