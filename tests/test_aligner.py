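"""Exhaustive and hash-indexed aligners: examples, oracles, skip rules."""

import pytest

from lrdalign import (
    AlignmentParams,
    LrdParams,
    Sequence,
    align_exhaustive,
    align_hash,
    align_with_strands,
    build_read_index,
    delta_one_sided,
    nearest_occurrence,
    shared_kmer_counts,
)
from lrdalign.aligner import ReadProfile, ReferenceIndex, delta_at_window
from lrdalign.rankdist import revcomp

from conftest import mutated_copy, random_dna


def exact_params(**kw) -> AlignmentParams:
    """Hash aligner with every approximation disabled."""
    kw.setdefault("S", 0.0)
    kw.setdefault("use_rule2", False)
    kw.setdefault("use_abort", False)
    return AlignmentParams(**kw)


def sampled_read(rng, ref: Sequence, length: int, error: float) -> Sequence:
    s = int(rng.integers(0, len(ref) - length + 1))
    return Sequence("read", mutated_copy(rng, ref.bases[s : s + length], error))


def test_build_read_index_examples():
    idx = build_read_index("ACAC", 2)
    assert idx.table == {"AC": [0, 2], "CA": [1]}
    assert build_read_index("AAAA", 1).table == {"A": [0, 1, 2, 3]}
    assert build_read_index("ACGT", 4).table == {"ACGT": [0]}
    with pytest.raises(ValueError):
        build_read_index("AC", 3)


def test_index_invariants(rng):
    for _ in range(20):
        k = int(rng.integers(1, 5))
        read = random_dna(rng, int(rng.integers(k, 40)))
        idx = build_read_index(read, k)
        assert sum(len(v) for v in idx.table.values()) == len(read) - k + 1
        for v in idx.table.values():
            assert v == sorted(v)
        assert idx.positions("N" * k) == []


@pytest.mark.parametrize(
    "positions, q, expected",
    [([1, 5, 9], 6, 5), ([1, 5, 9], 7, 5), ([], 3, None), ([4], 0, 4)],
)
def test_nearest_occurrence(positions, q, expected):
    assert nearest_occurrence(positions, q) == expected


def test_nearest_occurrence_equals_linear_scan(rng):
    for _ in range(200):
        pos = sorted(set(rng.integers(0, 50, size=rng.integers(1, 10)).tolist()))
        q = int(rng.integers(-5, 55))
        best = min(pos, key=lambda p: (abs(p - q), p))
        assert nearest_occurrence(pos, q) == best


def test_shared_kmer_counts_example():
    idx = build_read_index("ACG", 2)
    state = shared_kmer_counts(idx, Sequence("ref", "ACGT"))
    assert state.presence.tolist() == [True, True, False]
    assert state.counts.tolist() == [2, 1]
    assert state.max_count == 2


def test_shared_kmer_counts_disjoint_and_errors():
    idx = build_read_index("AAA", 2)
    state = shared_kmer_counts(idx, Sequence("ref", "CCCCCC"))
    assert state.counts.max() == 0
    with pytest.raises(ValueError):
        shared_kmer_counts(build_read_index("ACGTA", 2), Sequence("r", "ACG"))


def test_shared_kmer_counts_matches_naive_recount(rng):
    for _ in range(100):
        read = random_dna(rng, 20)
        ref = Sequence("ref", random_dna(rng, 100))
        idx = build_read_index(read, 3)
        state = shared_kmer_counts(idx, ref)
        kmers = set(idx.table)
        for i, c in enumerate(state.counts):
            naive = sum(
                ref.bases[j : j + 3] in kmers for j in range(i, i + len(read) - 2)
            )
            assert naive == c


def test_delta_at_window(rng):
    params = AlignmentParams(k=3, m=10)
    ref = Sequence("ref", "TTTTACGTACGTTTT")
    read = Sequence("r", "ACGTACGT")
    idx = build_read_index(read, 3)
    assert delta_at_window(read, ref, 4, idx, params) == 0
    # abort_above=0 aborts any window with a missing k-mer
    assert delta_at_window(read, ref, 0, idx, params, abort_above=0) is None
    with pytest.raises(ValueError):
        delta_at_window(read, ref, 8, idx, params)
    # equals the one-sided LRD of (window, read) with abort disabled
    for _ in range(100):
        read = Sequence("r", random_dna(rng, 30))
        ref = Sequence("ref", random_dna(rng, 80))
        idx = build_read_index(read.bases, 3)
        i = int(rng.integers(0, len(ref) - len(read) + 1))
        got = delta_at_window(read, ref, i, idx, params)
        window = ref.bases[i : i + len(read)]
        assert got == delta_one_sided(window, read.bases, LrdParams(3, 10))


def test_align_exhaustive_toy(toy_reference):
    params = exact_params(k=2, m=4, D=1000.0)
    res = align_exhaustive(Sequence("r", "ACGTACGT"), toy_reference, params)
    assert (res.position, res.distance, res.aligned) == (4, 0, True)


def test_align_unalignable_read():
    params = exact_params(k=2, m=4, D=10.0)
    res = align_exhaustive(Sequence("r", "AAAA"), Sequence("ref", "CCCCCCCC"), params)
    assert not res.aligned and res.distance == 3 * 4


def test_align_exhaustive_matches_bruteforce(rng):
    params = exact_params(k=3, m=10)
    for _ in range(30):
        ref = Sequence("ref", random_dna(rng, 150))
        read = sampled_read(rng, ref, 30, 0.1)
        res = align_exhaustive(read, ref, params)
        deltas = [
            delta_one_sided(ref.bases[i : i + 30], read.bases, LrdParams(3, 10))
            for i in range(len(ref) - 29)
        ]
        assert res.distance == min(deltas)
        assert res.position == deltas.index(min(deltas))


def test_align_read_to_window_side_matches_bruteforce(rng):
    params = exact_params(k=3, m=10, partial_sum_side="read_to_window")
    for _ in range(10):
        ref = Sequence("ref", random_dna(rng, 100))
        read = sampled_read(rng, ref, 25, 0.1)
        res = align_exhaustive(read, ref, params)
        deltas = [
            delta_one_sided(read.bases, ref.bases[i : i + 25], LrdParams(3, 10))
            for i in range(len(ref) - 24)
        ]
        assert res.distance == min(deltas)
        assert res.position == deltas.index(min(deltas))


def test_hash_equals_exhaustive_when_exact(rng):
    params = exact_params(k=3, m=10)
    for _ in range(30):
        ref = Sequence("ref", random_dna(rng, 300))
        read = sampled_read(rng, ref, 40, float(rng.choice([0.0, 0.05, 0.3])))
        a = align_exhaustive(read, ref, params)
        b = align_hash(read, ref, params)
        assert (a.position, a.distance) == (b.position, b.distance)


def test_hash_exact_substring_any_skip_fraction(rng):
    for S in (0.0, 0.5, 1.0):
        params = AlignmentParams(k=3, m=10, S=S)
        ref = Sequence("ref", random_dna(rng, 200))
        s = int(rng.integers(0, 161))
        read = Sequence("r", ref.bases[s : s + 40])
        res = align_hash(read, ref, params)
        assert res.distance == 0 and res.aligned


def test_hash_s1_visits_only_max_count_windows(rng):
    ref = Sequence("ref", random_dna(rng, 300))
    read = sampled_read(rng, ref, 40, 0.1)
    params = AlignmentParams(k=3, m=10, S=1.0, use_rule2=False, use_abort=False)
    idx = build_read_index(read.bases, 3)
    state = shared_kmer_counts(idx, ref)
    n_max = int((state.counts == state.max_count).sum())
    res = align_hash(read, ref, params)
    assert res.windows_visited == n_max


def test_rule2_admissibility(rng):
    """(missing k-mers) * m never exceeds the true window distance."""
    params = AlignmentParams(k=3, m=10)
    for _ in range(10):
        ref = Sequence("ref", random_dna(rng, 120))
        read = sampled_read(rng, ref, 30, 0.2)
        idx = build_read_index(read.bases, 3)
        state = shared_kmer_counts(idx, ref)
        for i, c in enumerate(state.counts):
            bound = (idx.n_kmers - int(c)) * params.m
            true = delta_one_sided(
                ref.bases[i : i + 30], read.bases, LrdParams(3, 10)
            )
            assert bound <= true


def test_abort_and_rule2_never_change_the_minimum(rng):
    for _ in range(25):
        ref = Sequence("ref", random_dna(rng, 300))
        read = sampled_read(rng, ref, 40, 0.1)
        base = align_hash(read, ref, exact_params(k=3, m=10))
        pruned = align_hash(
            read, ref, AlignmentParams(k=3, m=10, S=0.0, use_rule2=True,
                                       use_abort=True)
        )
        assert (base.position, base.distance) == (pruned.position, pruned.distance)
        assert pruned.windows_visited <= base.windows_visited


def test_skip_fraction_monotone_in_visited_windows(rng):
    for _ in range(10):
        ref = Sequence("ref", random_dna(rng, 400))
        read = sampled_read(rng, ref, 40, 0.15)
        visited = [
            align_hash(read, ref, AlignmentParams(k=3, m=10, S=S)).windows_visited
            for S in (0.0, 0.9)
        ]
        assert visited[1] <= visited[0]


def test_slack_skip_mode(rng):
    ref = Sequence("ref", random_dna(rng, 200))
    read = sampled_read(rng, ref, 30, 0.1)
    idx = build_read_index(read.bases, 3)
    state = shared_kmer_counts(idx, ref)
    res = align_hash(
        read, ref,
        AlignmentParams(k=3, m=10, skip_mode="slack", slack=2,
                        use_rule2=False, use_abort=False),
    )
    assert res.windows_visited == int(
        (state.counts >= state.max_count - 2).sum()
    )


def test_align_with_strands_forward(rng):
    ref = Sequence("ref", random_dna(rng, 200))
    read = Sequence("r", ref.bases[50:90])
    res = align_with_strands(read, ref, AlignmentParams(k=3, m=10))
    assert res.strand == "+" and res.distance == 0 and res.position == 50


def test_align_with_strands_reverse(rng):
    ref = Sequence("ref", random_dna(rng, 200))
    read = Sequence("r", revcomp(ref.bases[50:90]))
    res = align_with_strands(read, ref, AlignmentParams(k=3, m=24))
    assert res.strand == "-" and res.distance == 0 and res.position == 50


def test_align_with_strands_picks_better_strand(rng):
    """With rc_factor=1 the forward result is kept unless reverse is
    strictly better; cross-check against aligning both strands fully."""
    params = AlignmentParams(k=3, m=10, rc_factor=1.0, S=0.0,
                             use_rule2=False, use_abort=False)
    for _ in range(10):
        ref = Sequence("ref", random_dna(rng, 150))
        read = Sequence("r", random_dna(rng, 30))
        res = align_with_strands(read, ref, params)
        fwd = align_hash(read, ref, params)
        rev = align_hash(Sequence("r", revcomp(read.bases)), ref, params)
        if fwd.distance <= params.rc_threshold(30):
            assert (res.strand, res.distance) == ("+", fwd.distance)
        else:
            best = min(fwd.distance, rev.distance)
            assert res.distance == best
            assert res.strand == ("+" if fwd.distance <= rev.distance else "-")


def test_determinism(rng):
    ref = Sequence("ref", random_dna(rng, 300))
    read = sampled_read(rng, ref, 40, 0.1)
    params = AlignmentParams(k=3, m=10)
    r1 = align_with_strands(read, ref, params)
    r2 = align_with_strands(read, ref, params)
    assert (r1.position, r1.strand, r1.distance) == (r2.position, r2.strand, r2.distance)


def test_hard_errors():
    params = AlignmentParams(k=3, m=10)
    with pytest.raises(ValueError):
        align_hash(Sequence("r", "AC"), Sequence("ref", "ACGTACGT"), params)
    with pytest.raises(ValueError):
        align_hash(Sequence("r", "ACGTACGTACGT"), Sequence("ref", "ACGT"), params)
    with pytest.raises(ValueError):  # ReferenceIndex k must match params.k
        align_hash(
            Sequence("r", "ACGT"),
            ReferenceIndex(Sequence("ref", "ACGTACGT"), 2),
            params,
        )


def test_profile_reuse_matches_fresh(rng):
    ref = ReferenceIndex(Sequence("ref", random_dna(rng, 300)), 3)
    params = AlignmentParams(k=3, m=10)
    read = sampled_read(rng, ref.sequence, 40, 0.05)
    profile = ReadProfile(read, params)
    a = align_with_strands(read, ref, params, profile=profile)
    b = align_with_strands(read, ref.sequence, params)
    assert (a.position, a.strand, a.distance) == (b.position, b.strand, b.distance)
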