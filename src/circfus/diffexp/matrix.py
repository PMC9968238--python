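"""Count matrix assembly, expression calling and set intersections.

The matrix holds two rows per junction — ``<id>|circular`` (BSJ read pairs)
and ``<id>|linear`` (reads supporting linear splicing at either junction
boundary, summed).  CPM uses raw column sums of the full event matrix as
library sizes (no between-sample normalization).
"""

from __future__ import annotations

import itertools

import pandas as pd

CIRC_SUFFIX = "|circular"
LINEAR_SUFFIX = "|linear"


def build_matrix(junction_tables: dict[str, dict[str, tuple]], design: dict[str, tuple]) -> pd.DataFrame:
    """``junction_tables``: sample -> {junction_id: (circ, lin_acceptor,
    lin_donor)}.  Junctions absent from a sample get zero counts."""
    samples = [s for s in design if s in junction_tables]
    all_junc = sorted({j for t in junction_tables.values() for j in t})
    rows = {}
    for j in all_junc:
        circ_row, lin_row = [], []
        for s in samples:
            circ, lin_a, lin_d = junction_tables[s].get(j, (0, 0, 0))
            circ_row.append(circ)
            lin_row.append(lin_a + lin_d)
        rows[j + CIRC_SUFFIX] = circ_row
        rows[j + LINEAR_SUFFIX] = lin_row
    return pd.DataFrame.from_dict(rows, orient="index", columns=samples)


def filter_events(matrix: pd.DataFrame, min_reads: int = 2, min_samples: int = 2) -> pd.DataFrame:
    """Keep events having >= min_reads reads in >= min_samples samples."""
    keep = (matrix >= min_reads).sum(axis=1) >= min_samples
    return matrix.loc[keep]


def library_sizes(matrix: pd.DataFrame) -> pd.Series:
    return matrix.sum(axis=0)


def cpm(matrix: pd.DataFrame, lib_sizes: pd.Series | None = None) -> pd.DataFrame:
    """Counts per million; library sizes default to the column sums of the
    supplied (full) matrix."""
    if lib_sizes is None:
        lib_sizes = library_sizes(matrix)
    return matrix.div(lib_sizes, axis=1) * 1e6


def expressed_sets(
    cpm_matrix: pd.DataFrame,
    design: dict[str, tuple],
    threshold: float = 1.0,
    circular_only: bool = True,
) -> dict[str, set[str]]:
    """Per condition, events with average CPM >= threshold."""
    rows = cpm_matrix
    if circular_only:
        rows = rows.loc[rows.index.str.endswith(CIRC_SUFFIX)]
    conditions = sorted({design[s][0] for s in rows.columns})
    out = {}
    for cond in conditions:
        cols = [s for s in rows.columns if design[s][0] == cond]
        mean = rows[cols].mean(axis=1)
        ids = {i.removesuffix(CIRC_SUFFIX) for i in mean.index[mean >= threshold]}
        out[cond] = ids
    return out


def intersect_expressed(sets: dict[str, set[str]]) -> dict[tuple[str, ...], int]:
    """Exclusive intersection cells (UpSet semantics): for every non-empty
    subset of conditions, the number of items in all of them and none of
    the others."""
    if len(sets) < 2:
        raise ValueError("need at least two sets")
    names = sorted(sets)
    out: dict[tuple[str, ...], int] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(sets[c] for c in combo))
            for other in names:
                if other not in combo:
                    inside -= sets[other]
            out[combo] = len(inside)
    return out


def testing_filter(
    matrix: pd.DataFrame,
    design: dict[str, tuple],
    conditions: tuple[str, str],
    min_reads: int = 2,
) -> pd.DataFrame:
    """Pre-test filter: events supported by >= min_reads reads in at least
    as many samples as the minimum replicate count across the two tested
    conditions."""
    n_rep = min(
        sum(1 for s in matrix.columns if design[s][0] == cond) for cond in conditions
    )
    return filter_events(matrix, min_reads=min_reads, min_samples=n_rep)
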