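"""miRNA binding-site prediction on reconstructed circRNA sequences.

A local-alignment scanner in the spirit of seed-weighted miRNA target
finders: the miRNA (3'->5') is aligned against the target with
Watson-Crick match, G:U wobble, mismatch and gap weights, and positions
2-8 of the miRNA (the seed) are double-weighted.  Scores are on a scale
where a perfect ~21-nt duplex reaches ~140, so the default threshold of
140 reports only near-complete complementarity; the pairing-energy proxy
is a weighted pair count on a kcal/mol-like scale, not a thermodynamics
model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_PAIR = {"A": "T", "C": "G", "G": "C", "T": "A"}
_GU = {("G", "T"), ("T", "G")}  # target base, miRNA base


@dataclass
class SiteParams:
    min_score: float = 140.0
    max_energy: float = -1.0
    match: float = 5.0
    gu: float = 1.0
    mismatch: float = -4.0
    gap: float = -9.0
    seed_start: int = 2  # 1-based miRNA positions, inclusive
    seed_end: int = 8
    seed_weight: float = 2.0


@dataclass
class BindingSite:
    circ_id: str
    mirna: str
    start: int  # on the extended circ sequence
    end: int
    score: float
    energy: float
    spans_bsj: bool


def _pair_score(t: str, m: str, weight: float, params: SiteParams) -> tuple[float, str]:
    if _PAIR.get(m) == t:
        return params.match * weight, "wc"
    if (t, m) in _GU:
        return params.gu * weight, "gu"
    return params.mismatch * weight, "mm"


def scan_target(target: str, mirna_seq: str, params: SiteParams) -> list[tuple[int, int, float, int, int]]:
    """All non-overlapping local alignments with score >= min_score.

    Returns (start, end, score, n_wc, n_gu) tuples on the target.
    """
    query = mirna_seq.upper().replace("U", "T")[::-1]  # 3'->5'
    mlen = len(query)
    # miRNA position (1-based, from the 5' end) for each query index
    weights = [
        params.seed_weight
        if params.seed_start <= (mlen - j) <= params.seed_end
        else 1.0
        for j in range(mlen)
    ]
    n = len(target)
    H = np.zeros((n + 1, mlen + 1))
    for i in range(1, n + 1):
        t = target[i - 1]
        row = H[i]
        prev = H[i - 1]
        for j in range(1, mlen + 1):
            s, _ = _pair_score(t, query[j - 1], weights[j - 1], params)
            row[j] = max(0.0, prev[j - 1] + s, prev[j] + params.gap, row[j - 1] + params.gap)

    sites: list[tuple[int, int, float, int, int]] = []
    taken: list[tuple[int, int]] = []
    order = np.dstack(np.unravel_index(np.argsort(H, axis=None)[::-1], H.shape))[0]
    for i, j in order:
        score = H[i, j]
        if score < params.min_score:
            break
        start, end, wc, gu = _traceback(H, target, query, weights, params, int(i), int(j))
        if any(start < b and a < end for a, b in taken):
            continue
        sites.append((start, end, float(score), wc, gu))
        taken.append((start, end))
    sites.sort()
    return sites


def _traceback(H, target, query, weights, params, i, j):
    wc = gu = 0
    end = i
    while i > 0 and j > 0 and H[i, j] > 0:
        s, kind = _pair_score(target[i - 1], query[j - 1], weights[j - 1], params)
        if np.isclose(H[i, j], H[i - 1, j - 1] + s):
            if kind == "wc":
                wc += 1
            elif kind == "gu":
                gu += 1
            i, j = i - 1, j - 1
        elif np.isclose(H[i, j], H[i - 1, j] + params.gap):
            i -= 1
        elif np.isclose(H[i, j], H[i, j - 1] + params.gap):
            j -= 1
        else:
            break
    return i, end, wc, gu


def predict_sites(
    circ_seqs,
    mirnas: dict[str, str],
    params: SiteParams | None = None,
    expressed: set[str] | None = None,
) -> list[BindingSite]:
    """Scan every (circ, miRNA) combination; miRNAs can be restricted to an
    expressed subset.  Sites that start inside the duplicated extension are
    rotations of their 5' copies and are dropped."""
    params = params or SiteParams()
    out: list[BindingSite] = []
    for cs in circ_seqs:
        for name, seq in mirnas.items():
            if expressed is not None and name not in expressed:
                continue
            for start, end, score, wc, gu in scan_target(cs.seq, seq, params):
                energy = -(0.6 * wc + 0.2 * gu)
                if energy > params.max_energy:
                    continue
                if start >= cs.bsj_offset:
                    continue  # duplicate of the 5' copy
                out.append(
                    BindingSite(
                        cs.circ_id,
                        name,
                        start,
                        end,
                        score,
                        energy,
                        start < cs.bsj_offset < end,
                    )
                )
    return out
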