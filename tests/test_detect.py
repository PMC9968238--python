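import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circfus import detect
from circfus.gio import read_fastq, revcomp
from circfus.models import CircJunction, Gene, Transcript


def _rand_seq(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


# ---------------------------------------------------------------------------
# preprocessing

def test_dedup_identical_pairs():
    r1 = [("a/1", "ACGT" * 10), ("b/1", "ACGT" * 10)]
    r2 = [("a/2", "TTTT" * 10), ("b/2", "TTTT" * 10)]
    o1, o2 = detect.dedup_reads(r1, r2)
    assert len(o1) == 1 and o1[0][0] == "a/1"


def test_dedup_revcomp_swapped_pair():
    s1, s2 = "ACGTACGTAC", "GGGTTTCCCA"
    r1 = [("a/1", s1), ("b/1", revcomp(s2))]
    r2 = [("a/2", s2), ("b/2", revcomp(s1))]
    o1, _ = detect.dedup_reads(r1, r2)
    assert [n for n, _ in o1] == ["a/1"]


def test_dedup_mismatched_lengths_raises():
    with pytest.raises(detect.InputError):
        detect.dedup_reads([("a", "ACGT")], [])


def test_dedup_planted_duplicates_brute_force():
    rng = random.Random(0)
    base = [(_rand_seq(rng, 50), _rand_seq(rng, 50)) for _ in range(90)]
    pairs = list(base)
    for i in rng.sample(range(90), 10):  # 10 duplicates (mixed kinds)
        s1, s2 = base[i]
        pairs.append((s1, s2) if i % 2 else (revcomp(s2), revcomp(s1)))
    rng.shuffle(pairs)
    # independent oracle: canonical-form set
    expected = len({min((a, b), (revcomp(b), revcomp(a))) for a, b in pairs})
    r1 = [(f"p{i}/1", a) for i, (a, b) in enumerate(pairs)]
    r2 = [(f"p{i}/2", b) for i, (a, b) in enumerate(pairs)]
    o1, _ = detect.dedup_reads(r1, r2)
    assert len(o1) == expected == 90


@given(st.lists(st.tuples(st.text("ACGT", min_size=30, max_size=30),
                          st.text("ACGT", min_size=30, max_size=30)),
                min_size=0, max_size=30))
@settings(max_examples=50, deadline=None)
def test_dedup_idempotent_and_canonical(pairs):
    r1 = [(f"p{i}/1", a) for i, (a, b) in enumerate(pairs)]
    r2 = [(f"p{i}/2", b) for i, (a, b) in enumerate(pairs)]
    o1, o2 = detect.dedup_reads(r1, r2)
    oo1, oo2 = detect.dedup_reads(o1, o2)
    assert o1 == oo1 and o2 == oo2
    keys = {min((a, b), (revcomp(b), revcomp(a)))
            for (_, a), (_, b) in zip(o1, o2)}
    assert len(keys) == len(o1)


def test_trim_adapter_suffix():
    adapter = "AGATCGGAAGAGC"
    read = "ACGT" * 10 + adapter[:8]
    assert detect.trim_read(read, adapter) == "ACGT" * 10
    assert detect.trim_read("ACGT" * 10, adapter) == "ACGT" * 10


def test_trim_below_min_len_drops():
    adapter = "AGATCGGAAGAGC"
    read = "ACGTACGTAC" + adapter  # 10 nt remain < 18
    assert detect.trim_read(read, adapter) is None


def test_filter_contaminants_empty_db_identity():
    pairs = [("a", "ACGT" * 25, "TTTT" * 25)]
    assert detect.filter_contaminants(pairs, {}) == pairs


def test_filter_contaminants_removes_planted_fraction():
    rng = random.Random(1)
    contam = _rand_seq(rng, 600)
    clean = [("c%d" % i, _rand_seq(rng, 100), _rand_seq(rng, 100)) for i in range(95)]
    dirty = []
    for i in range(5):
        st_ = rng.randrange(0, 500)
        dirty.append(("d%d" % i, contam[st_ : st_ + 100], _rand_seq(rng, 100)))
    kept = detect.filter_contaminants(clean + dirty, {"rRNA": contam})
    assert len(kept) == 95
    assert all(n.startswith("c") for n, _, _ in kept)


# ---------------------------------------------------------------------------
# alignment / anchoring on the default simulation

def test_exonic_read_is_discarded_bsj_read_is_kept(sim):
    truth, genome = sim["truth"], sim["genome"]
    index = detect.GenomeIndex(genome)
    cfg = detect.DetectConfig()
    tx = truth.genes[0].transcripts[0]
    exon_read = genome[tx.exons[0][0] : tx.exons[0][0] + 100]
    circ = truth.circs[0]
    body = truth.circ_body(circ, genome)
    bsj_read = body[-50:] + body[:50]
    placements, candidates = detect.align_and_split(
        [("p1", exon_read, bsj_read)], index, cfg
    )
    assert len(placements) == 1  # the exonic mate maps
    assert [seq for _, seq in candidates] == [bsj_read]


def test_linear_splice_read_yields_no_circ_call(sim):
    truth, genome = sim["truth"], sim["genome"]
    index = detect.GenomeIndex(genome)
    cfg = detect.DetectConfig()
    tx = truth.genes[0].transcripts[0]
    (s1, e1), (s2, e2) = tx.exons[0], tx.exons[1]
    read = genome[e1 - 50 : e1] + genome[s2 : s2 + 50]
    calls = detect.scan_mate(index, read, cfg, truth.chrom)
    assert calls and all(c.kind == "linear" for c in calls)
    assert calls[0].left == e1 and calls[0].right == s2


def test_backsplice_call_exact_coordinates(sim):
    truth, genome = sim["truth"], sim["genome"]
    index = detect.GenomeIndex(genome)
    cfg = detect.DetectConfig()
    for circ in truth.circs[:4]:
        body = truth.circ_body(circ, genome)
        read = body[-50:] + body[:50]
        calls = [c for c in detect.scan_mate(index, read, cfg, truth.chrom) if c.kind == "circ"]
        assert len(calls) == 1
        call = calls[0]
        assert (call.left, call.right, call.strand) == (circ.start, circ.end, circ.strand)


def test_exon_internal_read_gives_no_call(sim):
    truth, genome = sim["truth"], sim["genome"]
    index = detect.GenomeIndex(genome)
    tx = truth.genes[0].transcripts[0]
    read = genome[tx.exons[1][0] : tx.exons[1][0] + 100]
    assert detect.scan_mate(index, read, detect.DetectConfig(), truth.chrom) == []


def test_decoy_atac_junction_rejected(sim):
    truth, genome = sim["truth"], sim["genome"]
    index = detect.GenomeIndex(genome)
    cfg = detect.DetectConfig()
    for decoy in truth.decoys:
        read = genome[decoy.end - 50 : decoy.end] + genome[decoy.start : decoy.start + 50]
        calls = detect.scan_mate(index, read, cfg, truth.chrom)
        assert all(c.kind != "circ" for c in calls)


# ---------------------------------------------------------------------------
# junction filtering

def _junction(n_unique=2, span=500, quality=40, n_reads=None):
    j = CircJunction("chr1", 1000, 1000 + span, "+")
    j.n_unique_reads = n_unique
    j.n_reads = n_reads if n_reads is not None else n_unique
    j.best_anchor_quality = quality
    return j


def test_filter_requires_two_unique_reads():
    assert detect.filter_junctions([_junction(n_unique=1)]) == []
    assert len(detect.filter_junctions([_junction(n_unique=2)])) == 1


def test_filter_span_strictly_below_100kb():
    assert detect.filter_junctions([_junction(span=100_000)]) == []
    assert len(detect.filter_junctions([_junction(span=99_999)])) == 1


def test_filter_anchor_quality():
    assert detect.filter_junctions([_junction(quality=3)]) == []
    assert len(detect.filter_junctions([_junction(quality=35)])) == 1


def test_filter_engineered_low_support(sim, detected):
    """Junctions below the support threshold in every sample vanish."""
    res = next(iter(detected["results"].values()))
    weak = _junction(n_unique=1)
    strong = list(res.junctions.values())[0]
    kept = detect.filter_junctions([weak, strong])
    assert weak not in kept and strong in kept


# ---------------------------------------------------------------------------
# linear support

def test_count_linear_support_sums_boundaries():
    from collections import Counter

    j = CircJunction("chr1", 5000, 7000, "+")
    events = Counter({(7000, 9000, "+"): 12, (3000, 5000, "+"): 9, (100, 300, "+"): 4})
    out = detect.count_linear_support([j], events)
    lin_acc, lin_don = out[j.key]
    assert lin_acc == 9 and lin_don == 12 and lin_acc + lin_don == 21


def test_no_linear_reads_means_zero_support():
    from collections import Counter

    j = CircJunction("chr1", 5000, 7000, "+")
    assert detect.count_linear_support([j], Counter())[j.key] == (0, 0)


def test_bsj_read_contributes_nothing_to_linear(sim):
    truth, genome = sim["truth"], sim["genome"]
    index = detect.GenomeIndex(genome)
    cfg = detect.DetectConfig()
    circ = truth.circs[0]
    body = truth.circ_body(circ, genome)
    read = body[-50:] + body[:50]
    _, events, _, _ = detect.call_backsplice([("p", read)], index, cfg, truth.chrom)
    assert sum(events.values()) == 0


# ---------------------------------------------------------------------------
# host annotation

def _gene(gid, start, end, strand="+", biotype="protein_coding"):
    tx = Transcript(gid + ".1", gid, "chr1", strand, [(start, end)])
    return Gene(gid, "chr1", strand, biotype, [tx])


def test_annotate_single_host():
    g = _gene("G1", 1000, 9000)
    j = CircJunction("chr1", 2000, 5000, "+")
    out = detect.annotate_junctions([j], [g])
    assert out[0].host_genes == ["G1"]
    assert out[0].host_biotype == "protein-coding"


def test_annotate_two_nonoverlapping_genes_removed():
    ga = _gene("GA", 1000, 3000)
    gb = _gene("GB", 6000, 9000)
    j = CircJunction("chr1", 2000, 7000, "+")
    assert detect.annotate_junctions([j], [ga, gb]) == []


def test_annotate_intergenic_kept_as_no_gene():
    g = _gene("G1", 1000, 3000)
    j = CircJunction("chr1", 5000, 6000, "+")
    out = detect.annotate_junctions([j], [g])
    assert out[0].host_biotype == "no gene"


# ---------------------------------------------------------------------------
# planted-truth recovery and invariants

def test_planted_truth_recovery_and_precision(sim, detected):
    truth = sim["truth"]
    called = {j.key for j in detected["junctions"]}
    expected = {(c.chrom, c.start, c.end, c.strand) for c in truth.circs}
    assert called == expected  # exact coordinates, no false junctions


def test_counting_conservation_per_sample(detected):
    for res in detected["results"].values():
        assert sum(j.n_reads for j in res.junctions.values()) == res.n_bsj_pairs


def test_monotonicity_more_reads_never_remove_junction(minisim):
    cfg = minisim["cfg"]
    truth, genome = minisim["truth"], minisim["genome"]
    index = detect.GenomeIndex(genome)
    sample = cfg.samples[0]
    r1 = read_fastq(minisim["reads"][sample][0])
    r2 = read_fastq(minisim["reads"][sample][1])
    base = detect.detect_sample(index, r1, r2, chrom=truth.chrom)
    circ = truth.circs[0]
    body = truth.circ_body(circ, genome)
    extra = [(f"x{i}/1", body[-40 - i :] + body[: 60 + i]) for i in range(4)]
    extra2 = [(f"x{i}/2", revcomp(body[: 100])) for i in range(4)]
    more = detect.detect_sample(index, r1 + extra, r2 + extra2, chrom=truth.chrom)
    assert set(base.junctions) <= set(more.junctions)
    for key in base.junctions:
        assert more.junctions[key].n_reads >= base.junctions[key].n_reads


def test_tighter_mismatch_budget_never_adds_junctions(minisim):
    truth, genome = minisim["truth"], minisim["genome"]
    index = detect.GenomeIndex(genome)
    sample = minisim["cfg"].samples[0]
    r1 = read_fastq(minisim["reads"][sample][0])
    r2 = read_fastq(minisim["reads"][sample][1])
    loose = detect.detect_sample(index, r1, r2, detect.DetectConfig(max_mm=2), chrom=truth.chrom)
    tight = detect.detect_sample(index, r1, r2, detect.DetectConfig(max_mm=0), chrom=truth.chrom)
    assert set(tight.junctions) <= set(loose.junctions)


# ---------------------------------------------------------------------------
# brute-force oracle on the mini genome

def brute_force_junctions(truth, genome, pairs, read_len, min_unique=2):
    """Try every exon-boundary pair; count post-dedup read pairs by string
    search of the junction window with >= 20 nt on both sides."""
    expected = {}
    for g in truth.genes:
        tx = g.transcripts[0]
        n = len(tx.exons)
        for i in range(n):
            for j in range(i, n):
                a, d = tx.exons[i][0], tx.exons[j][1]
                if g.strand == "+":
                    ok = genome[d : d + 2] == "GT" and genome[a - 2 : a] == "AG"
                else:
                    ok = genome[d : d + 2] == "CT" and genome[a - 2 : a] == "AC"
                if not ok or d - a >= 100_000:
                    continue
                body = "".join(genome[s:e] for s, e in tx.exons[i : j + 1])
                if g.strand == "-":
                    body = revcomp(body)
                w = body[-(read_len - 20) :] + body[: read_len - 20]
                n_pairs = 0
                for s1, s2 in pairs:
                    if any(q in w or revcomp(q) in w for q in (s1, s2)):
                        n_pairs += 1
                if n_pairs >= min_unique:
                    expected[(truth.chrom, a, d, g.strand)] = n_pairs
    return expected


def test_detector_equals_brute_force_oracle(minisim):
    cfg = minisim["cfg"]
    truth, genome = minisim["truth"], minisim["genome"]
    assert truth.chrom_len <= 10_000
    index = detect.GenomeIndex(genome)
    for sample in cfg.samples[:2]:
        r1 = read_fastq(minisim["reads"][sample][0])
        r2 = read_fastq(minisim["reads"][sample][1])
        d1, d2 = detect.dedup_reads(r1, r2)
        pairs = [(a, b) for (_, a), (_, b) in zip(d1, d2)]
        res = detect.detect_sample(index, r1, r2, chrom=truth.chrom)
        called = detect.filter_junctions(res.junctions.values())
        expected = brute_force_junctions(truth, genome, pairs, cfg.read_len)
        assert {j.key for j in called} == set(expected)
        for j in called:
            assert j.n_reads == expected[j.key]
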