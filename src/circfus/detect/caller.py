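"""Anchor-based back-splice and linear splice-junction calling.

For every unmappable mate, 20-nt anchors from both read ends are placed on
the genome; anchor placements are extended toward each other until the full
read is explained by a donor suffix followed by an acceptor prefix.  A
head-to-tail (circular) event is called when the 3'-end anchor lands
upstream of the 5'-end anchor; the ordinary geometry yields a linear splice
event.  Breakpoints require the canonical splice signal: GT..AG flanking the
event on the forward strand for '+' events, CT..AC (the reverse complement
read on the template) for '-' events.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from ..gio import revcomp
from ..models import CircJunction
from .aligner import GenomeIndex, ANCHOR_LEN
from .preprocess import dedup_reads, filter_contaminants, trim_pairs

MIN_INTRON = 30
MIN_CIRC_SPAN = 30


@dataclass
class DetectConfig:
    max_mm: int = 2
    max_hits: int = 10
    min_unique: int = 2
    max_span: int = 100_000
    min_quality: int = 35
    unique_quality: int = 40  # surrogate MAPQ for uniquely placed anchors
    multi_quality: int = 3


@dataclass
class MateCall:
    kind: str  # "circ" | "linear"
    chrom: str
    left: int  # circ: acceptor start; linear: donor end
    right: int  # circ: donor end; linear: acceptor start
    strand: str
    unique: bool


@dataclass
class SampleResult:
    chrom: str
    junctions: dict = field(default_factory=dict)  # key -> CircJunction
    linear_events: Counter = field(default_factory=Counter)  # (donor, acceptor, strand) -> reads
    linear_placements: list = field(default_factory=list)  # (pos, forward-strand seq)
    bsj_pairs: dict = field(default_factory=dict)  # key -> [(seq1, seq2), ...]
    n_bsj_pairs: int = 0
    n_pairs_in: int = 0


def _extensions(genome: str, seq: str, pa: int, pb: int) -> tuple[int, int]:
    """Longest matching prefix of ``seq`` at ``pa`` and longest matching
    suffix ending at ``pb + ANCHOR_LEN``."""
    n = len(genome)
    L = len(seq)
    e_don = 0
    while e_don < L and pa + e_don < n and genome[pa + e_don] == seq[e_don]:
        e_don += 1
    end = pb + ANCHOR_LEN
    e_acc = 0
    while e_acc < L and end - e_acc - 1 >= 0 and genome[end - e_acc - 1] == seq[L - e_acc - 1]:
        e_acc += 1
    return e_don, e_acc


def _signal_strand(genome: str, left: int, right: int, circ: bool) -> str | None:
    """Strand implied by the splice signal at a candidate breakpoint.

    For a circular event the intronic dinucleotides flank the interval
    (acceptor side at ``left``, donor side at ``right``); for a linear event
    they sit inside the intron (donor at ``left``, acceptor at ``right``).
    """
    if circ:
        acc = genome[left - 2 : left]
        don = genome[right : right + 2]
    else:
        don = genome[left : left + 2]
        acc = genome[right - 2 : right]
    if don == "GT" and acc == "AG":
        return "+"
    if don == "CT" and acc == "AC":
        return "-"
    return None


def scan_mate(index: GenomeIndex, seq: str, cfg: DetectConfig, chrom: str) -> list[MateCall]:
    """Anchor-split one unmapped mate into at most one circular call and any
    number of linear splice-junction calls."""
    genome = index.genome
    k = ANCHOR_LEN
    L = len(seq)
    if L < 2 * k:
        return []
    circ_calls: list[MateCall] = []
    linear_calls: list[MateCall] = []
    for oriented in (seq, revcomp(seq)):
        pa_list = index.map_anchor(oriented[:k])
        pb_list = index.map_anchor(oriented[-k:])
        if not pa_list or not pb_list:
            continue
        unique = len(pa_list) == 1 and len(pb_list) == 1
        for pa in pa_list[: cfg.max_hits]:
            for pb in pb_list[: cfg.max_hits]:
                e_don, e_acc = _extensions(genome, oriented, pa, pb)
                x_lo = max(k, L - e_acc)
                x_hi = min(e_don, L - k)
                best = None
                for x in range(x_lo, x_hi + 1):
                    e = pa + x  # end of the 5'-part alignment
                    s = pb + k - (L - x)  # start of the 3'-part alignment
                    if s - e >= MIN_INTRON:
                        strand = _signal_strand(genome, e, s, circ=False)
                        if strand is not None:
                            linear_calls.append(
                                MateCall("linear", chrom, e, s, strand, unique)
                            )
                            break  # one linear breakpoint per placement pair
                    elif e - s >= MIN_CIRC_SPAN and s >= 2:
                        strand = _signal_strand(genome, s, e, circ=True)
                        if strand is not None:
                            # smallest x maximizes the acceptor-side match
                            if best is None or (x, s) < best[:2]:
                                best = (x, s, e, strand)
                            break
                if best is not None:
                    _, s, e, strand = best
                    circ_calls.append(MateCall("circ", chrom, s, e, strand, unique))
    # a mate voting for more than one distinct circular junction is ambiguous
    keys = {(c.left, c.right, c.strand) for c in circ_calls}
    if len(keys) > 1:
        circ_calls = []
    elif len(circ_calls) > 1:
        circ_calls = [max(circ_calls, key=lambda c: c.unique)]
    return circ_calls + linear_calls


def align_and_split(pairs, index: GenomeIndex, cfg: DetectConfig):
    """Split pairs into linearly-placed mates and anchoring candidates.

    Returns (linear_placements, candidate_mates) where candidate mates are
    (pair_id, seq) for every mate without a full-length placement, and
    linear placements are (pos, forward-strand sequence) for uniquely
    placed mates.
    """
    placements = []
    candidates = []
    for name, s1, s2 in pairs:
        for seq in (s1, s2):
            hits = index.map_full(seq, cfg.max_mm)
            if hits:
                if len(hits) == 1:
                    h = hits[0]
                    placements.append((h.pos, seq if h.strand == "+" else revcomp(seq)))
            else:
                candidates.append((name, seq))
    return placements, candidates


def call_backsplice(candidates, index: GenomeIndex, cfg: DetectConfig, chrom: str):
    """Aggregate per-mate calls into junction-level circular support (by
    read pair) and linear splice-event read counts."""
    junctions: dict[tuple, CircJunction] = {}
    linear_events: Counter = Counter()
    by_pair: dict[str, list[MateCall]] = {}
    for name, seq in candidates:
        calls = scan_mate(index, seq, cfg, chrom)
        for call in calls:
            if call.kind == "linear":
                linear_events[(call.left, call.right, call.strand)] += 1
            else:
                by_pair.setdefault(name, []).append(call)
    n_pairs = 0
    assignments: dict[str, tuple] = {}
    for name, calls in by_pair.items():
        keys = {(c.left, c.right, c.strand) for c in calls}
        if len(keys) != 1:  # mates disagree: mapping error
            continue
        left, right, strand = keys.pop()
        assignments[name] = (chrom, left, right, strand)
        unique = any(c.unique for c in calls)
        key = (chrom, left, right, strand)
        j = junctions.get(key)
        if j is None:
            j = CircJunction(
                chrom,
                left,
                right,
                strand,
                splice_signal=(
                    index.genome[right : right + 2] + ".." + index.genome[left - 2 : left]
                ),
            )
            junctions[key] = j
        j.n_reads += 1
        if unique:
            j.n_unique_reads += 1
            j.best_anchor_quality = cfg.unique_quality
        elif j.best_anchor_quality == 0:
            j.best_anchor_quality = cfg.multi_quality
        n_pairs += 1
    return junctions, linear_events, n_pairs, assignments


def filter_junctions(junctions, cfg: DetectConfig | None = None):
    """Support / span / anchor-quality filter."""
    cfg = cfg or DetectConfig()
    return [
        j
        for j in junctions
        if j.n_unique_reads >= cfg.min_unique
        and j.span < cfg.max_span
        and j.best_anchor_quality >= cfg.min_quality
    ]


def count_linear_support(junctions, linear_events: Counter):
    """Per junction, reads supporting linear splicing at each of its two
    boundaries; the per-junction linear count is their sum."""
    acceptor: Counter = Counter()
    donor: Counter = Counter()
    for (d, a, strand), n in linear_events.items():
        donor[(d, strand)] += n
        acceptor[(a, strand)] += n
    out = {}
    for j in junctions:
        lin_acc = acceptor[(j.start, j.strand)]
        lin_don = donor[(j.end, j.strand)]
        out[j.key] = (lin_acc, lin_don)
    return out


# ---------------------------------------------------------------------------
# per-sample driver

def detect_sample(
    index: GenomeIndex,
    r1: list[tuple[str, str]],
    r2: list[tuple[str, str]],
    cfg: DetectConfig | None = None,
    chrom: str = "chr1",
    adapter: str = "",
    contam_db: dict[str, str] | None = None,
) -> SampleResult:
    """Run preprocessing and junction calling for one sample."""
    cfg = cfg or DetectConfig()
    r1, r2 = dedup_reads(r1, r2)
    pairs = [(n1.removesuffix("/1"), s1, s2) for (n1, s1), (_, s2) in zip(r1, r2)]
    if adapter:
        pairs = trim_pairs(pairs, adapter)
    if contam_db:
        pairs = filter_contaminants(pairs, contam_db)
    placements, candidates = align_and_split(pairs, index, cfg)
    junctions, linear_events, n_bsj, assignments = call_backsplice(candidates, index, cfg, chrom)
    seqs = {name: (s1, s2) for name, s1, s2 in pairs}
    bsj_pairs: dict[tuple, list] = {}
    for name, key in assignments.items():
        bsj_pairs.setdefault(key, []).append(seqs[name])
    return SampleResult(
        chrom=chrom,
        junctions=junctions,
        linear_events=linear_events,
        linear_placements=placements,
        bsj_pairs=bsj_pairs,
        n_bsj_pairs=n_bsj,
        n_pairs_in=len(pairs),
    )


def merge_samples(results: dict[str, SampleResult], cfg: DetectConfig | None = None):
    """Merge per-sample filtered junctions into one junction set, then count
    circular and linear support for every sample over the merged set."""
    cfg = cfg or DetectConfig()
    merged: dict[tuple, CircJunction] = {}
    for res in results.values():
        for j in filter_junctions(res.junctions.values(), cfg):
            m = merged.get(j.key)
            if m is None:
                m = CircJunction(j.chrom, j.start, j.end, j.strand,
                                 splice_signal=j.splice_signal)
                merged[j.key] = m
            m.n_reads += j.n_reads
            m.n_unique_reads += j.n_unique_reads
            m.best_anchor_quality = max(m.best_anchor_quality, j.best_anchor_quality)
    tables = {}
    merged_list = sorted(merged.values(), key=lambda j: (j.chrom, j.start, j.end))
    for sample, res in results.items():
        lin = count_linear_support(merged_list, res.linear_events)
        rows = {}
        for j in merged_list:
            circ_n = res.junctions[j.key].n_reads if j.key in res.junctions else 0
            lin_acc, lin_don = lin[j.key]
            rows[j.circ_id] = (circ_n, lin_acc, lin_don)
        tables[sample] = rows
    return merged_list, tables
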