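"""PAR-CLIP T-to-C transition simulation.

Transition events are placed at ``transition_density`` per kb inside the
1-kb flanks of the designated bound circRNAs and at a low background density
in other intronic space.  Every emitted position carries a T on the
annotated strand (an A on the forward strand for minus-strand genes).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..gio import read_fasta, write_bed6
from .config import SimConfig
from .truth import GroundTruth
from .reference import FLANK_WIDTH


def _t_positions(genome: str, start: int, end: int, strand: str) -> list[int]:
    base = "T" if strand == "+" else "A"
    return [p for p in range(start, end) if genome[p] == base]


def simulate_parclip(
    genome,
    truth: GroundTruth,
    config: SimConfig,
    bound_circ_ids: set | None = None,
) -> pd.DataFrame:
    """Return transition events as a BED6 dataframe (also stored on truth)."""
    if isinstance(genome, str) and genome.startswith(">"):
        genome = read_fasta(genome)[truth.chrom]
    rng = np.random.default_rng([3, config.seed])
    if bound_circ_ids is None:
        bound_circ_ids = {c.index for c in truth.circs if c.lfc < 0}
    bound = {
        c.index for c in truth.circs
        if c.index in bound_circ_ids or c.circ_id in bound_circ_ids
    }

    records: list[tuple[str, int, str]] = []
    flank_windows: list[tuple[int, int]] = []
    for circ in truth.circs:
        up, down = truth.flanks(circ, FLANK_WIDTH)
        flank_windows.extend([up, down])
        if circ.index not in bound:
            continue
        strand = circ.strand
        for lo, hi in (up, down):
            density = config.transition_density * (hi - lo) / 1000.0
            n = max(1, int(rng.poisson(density)))
            cand = _t_positions(genome, lo, hi, strand)
            if not cand:
                continue
            take = rng.choice(len(cand), size=min(n, len(cand)), replace=False)
            records.extend((truth.chrom, cand[i], strand) for i in sorted(take))

    if config.background_transition_density > 0:
        for g in truth.genes:
            for istart, iend in g.transcripts[0].introns:
                n = int(rng.poisson(
                    config.background_transition_density * (iend - istart) / 1000.0
                ))
                if n == 0:
                    continue
                cand = [
                    p
                    for p in _t_positions(genome, istart, iend, g.strand)
                    if not any(lo <= p < hi for lo, hi in flank_windows)
                ]
                if not cand:
                    continue
                take = rng.choice(len(cand), size=min(n, len(cand)), replace=False)
                records.extend((truth.chrom, cand[i], g.strand) for i in sorted(take))

    records.sort(key=lambda r: r[1])
    truth.transitions = records
    df = pd.DataFrame(
        [(chrom, p, p + 1, "tc", 0, strand) for chrom, p, strand in records],
        columns=["chrom", "start", "end", "name", "score", "strand"],
    )
    return df


def parclip_bed_text(df: pd.DataFrame) -> str:
    return write_bed6(df)
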