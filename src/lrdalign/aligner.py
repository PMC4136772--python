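"""Read alignment by Local Rank Distance minimisation.

A read is placed at the reference window whose one-sided LRD partial sum
(window k-mers scanned against the read, by default) is minimal; the
read counts as *aligned* only when that minimum is at or below a
distance threshold ``D``.

Two aligners are provided:

``align_exhaustive``
    evaluates every window start and returns the leftmost minimum.

``align_hash``
    the approximate hash-indexed aligner.  The read's k-mer positions go
    into a positional inverted index; a boolean presence array over the
    reference k-mer starts and a sliding-window count array ``C`` rank
    candidate windows by how many of their k-mers occur in the read.
    Windows are skipped when their count is too far below the maximum
    (rule 1, skip fraction ``S``) or when the missing-k-mer lower bound
    ``(read_kmers - C[i]) * m`` already exceeds the best distance so far
    (rule 2, admissible).  Window evaluation aborts as soon as its
    running sum exceeds the current best.  With ``S=0`` and rule 2 and
    the abort disabled, the result is identical to ``align_exhaustive``.

The reverse complement of a read is only aligned when the forward
minimum exceeds an internal threshold ``T = rc_factor * (|r|-k+1) * m``
(see ``align_with_strands``).

Positions are 0-based throughout; k-mer equality treats any k-mer
containing ``N`` as matching nothing.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field

import numpy as np

from .rankdist import (
    LrdParams,
    Sequence,
    nearest_position,
    reverse_complement,
)

#: default D as a fraction of the per-read maximum (|r|-k+1)*m
DEFAULT_D_FRACTION = 0.3

# k-mer integer encoding: A,C,G,T -> 0..3; anything else poisons the code
_BASE_LUT = np.full(256, -1, dtype=np.int64)
for _i, _c in enumerate("ACGT"):
    _BASE_LUT[ord(_c)] = _i

# table-based alignment only while 4**k fits comfortably in memory
_MAX_TABLE_CODES = 4**10


@dataclass(frozen=True)
class AlignmentParams:
    """Aligner configuration.

    Parameters
    ----------
    k, m:
        k-mer length and maximal offset of the underlying LRD.
    D:
        maximum distance accepted for an aligned read; ``None`` resolves
        per read to ``DEFAULT_D_FRACTION * (|r|-k+1) * m``.
    S:
        skip fraction in [0, 1] of rule 1: window ``i`` is visited only
        when ``C[i] >= S * max(C)``.  ``S=0`` visits everything, ``S=1``
        only windows attaining the maximal shared-k-mer count.
    rc_factor:
        fraction in (0, 1] defining the internal threshold
        ``T = rc_factor * (|r|-k+1) * m`` below which the forward
        alignment is accepted without trying the reverse complement.
    use_hash:
        choose the hash aligner (default) or the exhaustive one in
        strand-aware entry points.
    use_rule2, use_abort:
        enable the admissible missing-k-mer bound and the early abort.
    partial_sum_side:
        ``"window_to_read"`` (default) scans window k-mers against the
        read index; ``"read_to_window"`` scans read k-mers against the
        window.  Both aligners use the same side so their results are
        directly comparable.
    skip_mode, slack:
        ``"fraction"`` applies rule 1 as above; ``"slack"`` instead
        visits windows with ``C[i] >= max(C) - slack``.
    """

    k: int = 3
    m: int = 24
    D: float | None = None
    S: float = 1.0
    rc_factor: float = 0.2
    use_hash: bool = True
    use_rule2: bool = True
    use_abort: bool = True
    partial_sum_side: str = "window_to_read"
    skip_mode: str = "fraction"
    slack: int = 0

    def __post_init__(self) -> None:
        if self.k < 1 or self.m < 1:
            raise ValueError("k and m must be >= 1")
        if self.D is not None and self.D < 0:
            raise ValueError("D must be >= 0")
        if not 0.0 <= self.S <= 1.0:
            raise ValueError("S must lie in [0, 1]")
        if not 0.0 < self.rc_factor <= 1.0:
            raise ValueError("rc_factor must lie in (0, 1]")
        if self.partial_sum_side not in ("window_to_read", "read_to_window"):
            raise ValueError(f"unknown partial_sum_side {self.partial_sum_side!r}")
        if self.skip_mode not in ("fraction", "slack"):
            raise ValueError(f"unknown skip_mode {self.skip_mode!r}")

    @property
    def lrd(self) -> LrdParams:
        return LrdParams(self.k, self.m)

    def resolve_threshold(self, read_length: int) -> float:
        if self.D is not None:
            return self.D
        return DEFAULT_D_FRACTION * (read_length - self.k + 1) * self.m

    def rc_threshold(self, read_length: int) -> float:
        return self.rc_factor * (read_length - self.k + 1) * self.m


@dataclass
class KmerIndex:
    """Positional inverted index of a read: k-mer -> ascending positions.

    Every k-mer of the read is stored (``n_kmers == read_length-k+1``
    positions in total); k-mers containing ``N`` are stored but excluded
    from matching.
    """

    k: int
    read_length: int
    table: dict[str, list[int]]
    _code_positions: dict[int, np.ndarray] = field(repr=False, default_factory=dict)
    _code_array: np.ndarray = field(
        repr=False, default_factory=lambda: np.empty(0, dtype=np.int64)
    )

    @property
    def n_kmers(self) -> int:
        return self.read_length - self.k + 1

    def positions(self, kmer: str) -> list[int]:
        if "N" in kmer:
            return []
        return self.table.get(kmer, [])


@dataclass
class AlignState:
    """Candidate bookkeeping of the hash aligner.

    ``presence[j]`` flags reference k-mer starts whose k-mer occurs in
    the read; ``counts[i]`` is the number of flagged starts inside the
    window beginning at ``i``.
    """

    presence: np.ndarray
    counts: np.ndarray
    max_count: int
    best_pos: int | None = None
    best_dist: float = float("inf")


@dataclass
class AlignmentResult:
    read_id: str
    reference_id: str
    position: int | None
    strand: str
    distance: float
    aligned: bool
    windows_visited: int = 0


def encode_kmers(bases: str, k: int) -> np.ndarray:
    """Integer codes of all k-mers; k-mers containing N map to ``4**k``.

    Valid codes lie in ``[0, 4**k)``; the sentinel row ``4**k`` marks
    unmatched/invalid k-mers.
    """
    if len(bases) < k:
        raise ValueError(f"string shorter than k={k}")
    vals = _BASE_LUT[np.frombuffer(bases.encode("ascii"), dtype=np.uint8)].copy()
    sentinel = 4**k
    vals[vals < 0] = -sentinel * k  # any window containing it goes negative
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    codes = np.lib.stride_tricks.sliding_window_view(vals, k) @ powers
    codes = codes.copy()
    codes[codes < 0] = sentinel
    return codes


def build_read_index(read: Sequence | str, k: int) -> KmerIndex:
    """Build the positional inverted index of a read."""
    bases = read.bases if isinstance(read, Sequence) else read
    if len(bases) < k:
        raise ValueError(f"read shorter than k={k}")
    table: dict[str, list[int]] = {}
    for p in range(len(bases) - k + 1):
        table.setdefault(bases[p : p + k], []).append(p)
    codes = encode_kmers(bases, k)
    code_positions = {
        int(c): np.flatnonzero(codes == c).astype(np.int64)
        for c in np.unique(codes)
        if c < 4**k
    }
    code_array = np.fromiter(code_positions, dtype=np.int64, count=len(code_positions))
    return KmerIndex(k, len(bases), table, code_positions, code_array)


def nearest_occurrence(positions: list[int], q: int) -> int | None:
    """Occurrence list element nearest to ``q``; ties to the smaller one."""
    return nearest_position(positions, q)


class ReferenceIndex:
    """Precomputed k-mer codes of a reference, reusable across reads."""

    def __init__(self, sequence: Sequence, k: int):
        self.sequence = sequence
        self.k = k
        self.codes = encode_kmers(sequence.bases, k)
        self._pos_by_code: dict[int, np.ndarray] | None = None

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def id(self) -> str:
        return self.sequence.id

    def positions_by_code(self) -> dict[int, np.ndarray]:
        # only needed for the read->window partial-sum side
        if self._pos_by_code is None:
            sentinel = 4**self.k
            self._pos_by_code = {
                int(c): np.flatnonzero(self.codes == c).astype(np.int64)
                for c in np.unique(self.codes)
                if c < sentinel
            }
        return self._pos_by_code


def _as_ref_index(reference: Sequence | ReferenceIndex, k: int) -> ReferenceIndex:
    if isinstance(reference, ReferenceIndex):
        if reference.k != k:
            raise ValueError(
                f"ReferenceIndex built with k={reference.k}, aligner uses k={k}"
            )
        return reference
    return ReferenceIndex(reference, k)


def _contribution_table(index: KmerIndex, m: int) -> np.ndarray:
    """Table ``C[code, t]`` = capped offset of a window k-mer at in-window
    position ``t`` whose integer code is ``code``.

    Rows of codes absent from the read (including the N sentinel) are
    the flat penalty ``m``; for present codes the nearest read
    occurrence is found for every ``t`` at once.
    """
    n_codes = 4**index.k
    if n_codes > _MAX_TABLE_CODES:
        raise ValueError(f"k={index.k} too large for table-based alignment")
    T = index.n_kmers
    table = np.full((n_codes + 1, T), m, dtype=np.int64)
    t = np.arange(T, dtype=np.int64)
    for code, pos in index._code_positions.items():
        i = np.searchsorted(pos, t)
        right = np.where(i < len(pos), pos[np.minimum(i, len(pos) - 1)] - t, np.iinfo(np.int64).max)
        left = np.where(i > 0, t - pos[np.maximum(i - 1, 0)], np.iinfo(np.int64).max)
        table[code] = np.minimum(np.minimum(left, right), m)
    return table


class ReadProfile:
    """Per-read precomputation (index + contribution table) reusable
    across many references; the reverse-complement profile is built
    lazily on first use."""

    def __init__(self, read: Sequence, params: AlignmentParams):
        if len(read) < params.k:
            raise ValueError(f"read {read.id!r} shorter than k={params.k}")
        self.read = read
        self.params = params
        self.index = build_read_index(read, params.k)
        self.ctab = _contribution_table(self.index, params.m)
        self._rc: ReadProfile | None = None

    def rc(self) -> "ReadProfile":
        if self._rc is None:
            self._rc = ReadProfile(reverse_complement(self.read), self.params)
        return self._rc


def shared_kmer_counts(
    index: KmerIndex, reference: Sequence | ReferenceIndex
) -> AlignState:
    """Presence flags and sliding-window shared-k-mer counts.

    ``counts[i]`` sums the presence flags over the window of
    ``read_length - k + 1`` k-mer starts beginning at ``i``; computed by
    a cumulative sum so total work is linear in the reference length.
    """
    ref = _as_ref_index(reference, index.k)
    if len(ref) < index.read_length:
        raise ValueError("reference shorter than read")
    presence = np.isin(ref.codes, index._code_array)
    T = index.n_kmers
    cs = np.concatenate(([0], np.cumsum(presence, dtype=np.int64)))
    counts = cs[T:] - cs[: len(cs) - T]
    return AlignState(presence, counts, int(counts.max()))


def delta_at_window(
    read: Sequence,
    reference: Sequence | ReferenceIndex,
    i: int,
    index: KmerIndex,
    params: AlignmentParams,
    abort_above: float | None = None,
) -> int | None:
    """One-sided LRD of reference window ``[i, i+|read|)`` vs the read.

    Window k-mers are looked up in the read index; the nearest read
    occurrence to the in-window position contributes ``min(offset, m)``,
    an absent k-mer contributes ``m``.  Returns ``None`` (aborted) as
    soon as the running sum exceeds ``abort_above``; otherwise equals
    ``delta_one_sided(window, read)`` exactly.
    """
    ref_seq = reference.sequence if isinstance(reference, ReferenceIndex) else reference
    L = index.read_length
    if i < 0 or i + L > len(ref_seq):
        raise ValueError(f"window [{i}, {i + L}) outside reference of length {len(ref_seq)}")
    m = params.m
    total = 0
    for t in range(index.n_kmers):
        kmer = ref_seq.bases[i + t : i + t + index.k]
        q = nearest_occurrence(index.positions(kmer), t)
        total += m if q is None else min(abs(t - q), m)
        if abort_above is not None and total > abort_above:
            return None
    return total


def _delta_read_to_window(
    ref: ReferenceIndex, profile: ReadProfile, i: int
) -> int:
    """One-sided LRD scanning read k-mers against the reference window."""
    m = profile.params.m
    T = profile.index.n_kmers
    pos_by_code = ref.positions_by_code()
    total = 0
    for code, read_positions in profile.index._code_positions.items():
        ref_pos = pos_by_code.get(code)
        for q in read_positions:
            if ref_pos is None:
                total += m
                continue
            lo = bisect_left(ref_pos, i)
            hi = bisect_right(ref_pos, i + T - 1)
            if lo == hi:
                total += m
                continue
            window_pos = ref_pos[lo:hi]
            j = nearest_position(list(window_pos), i + q)
            total += min(abs(int(j) - i - q), m)
    # k-mers containing N never match: they are not in _code_positions
    n_valid = sum(len(p) for p in profile.index._code_positions.values())
    total += (T - n_valid) * m
    return total


def _window_delta_table(
    ctab: np.ndarray, ref_codes: np.ndarray, i: int, T: int
) -> int:
    idx = np.arange(T, dtype=np.int64)
    return int(ctab[ref_codes[i : i + T], idx].sum())


def _all_window_deltas(profile: ReadProfile, ref: ReferenceIndex) -> np.ndarray:
    """Vector of one-sided LRD values at every window start (diagonal sums
    of the contribution table gathered over the reference codes)."""
    T = profile.index.n_kmers
    n_windows = len(ref) - profile.index.read_length + 1
    deltas = np.zeros(n_windows, dtype=np.int64)
    for t in range(T):
        deltas += profile.ctab[ref.codes[t : t + n_windows], t]
    return deltas


def _check_align_pre(
    read: Sequence,
    ref: ReferenceIndex,
    params: AlignmentParams,
    profile: ReadProfile | None = None,
) -> None:
    if len(read) < params.k:
        raise ValueError(f"read {read.id!r} shorter than k={params.k}")
    if profile is not None and (
        profile.params.k != params.k or profile.params.m != params.m
    ):
        raise ValueError("ReadProfile was built with different k/m parameters")
    if len(ref) < len(read):
        raise ValueError(
            f"reference {ref.id!r} ({len(ref)} bp) shorter than read "
            f"{read.id!r} ({len(read)} bp)"
        )


def align_exhaustive(
    read: Sequence,
    reference: Sequence | ReferenceIndex,
    params: AlignmentParams,
    profile: ReadProfile | None = None,
) -> AlignmentResult:
    """Evaluate the one-sided LRD at every window start; leftmost minimum."""
    ref = _as_ref_index(reference, params.k)
    _check_align_pre(read, ref, params, profile)
    n_windows = len(ref) - len(read) + 1
    if params.partial_sum_side == "read_to_window":
        if profile is None:
            profile = ReadProfile(read, params)
        deltas = np.array(
            [_delta_read_to_window(ref, profile, i) for i in range(n_windows)],
            dtype=np.int64,
        )
    else:
        if profile is None:
            profile = ReadProfile(read, params)
        deltas = _all_window_deltas(profile, ref)
    best_pos = int(np.argmin(deltas))  # argmin is leftmost on ties
    best = int(deltas[best_pos])
    D = params.resolve_threshold(len(read))
    return AlignmentResult(
        read.id, ref.id, best_pos, "+", best, best <= D, n_windows
    )


def align_hash(
    read: Sequence,
    reference: Sequence | ReferenceIndex,
    params: AlignmentParams,
    profile: ReadProfile | None = None,
) -> AlignmentResult:
    """The approximate hash-indexed LRD aligner.

    Builds the read's positional inverted index and the shared-k-mer
    counts, then visits candidate windows left to right applying skip
    rule 1 (fraction/slack of the maximal count), skip rule 2 (the
    admissible missing-k-mer bound, ``window_to_read`` side only) and
    the early abort at the running best distance.
    """
    ref = _as_ref_index(reference, params.k)
    _check_align_pre(read, ref, params, profile)
    if profile is None:
        profile = ReadProfile(read, params)
    index = profile.index
    state = shared_kmer_counts(index, ref)
    T = index.n_kmers
    n_windows = len(ref) - len(read) + 1

    if params.skip_mode == "slack":
        min_count = state.max_count - params.slack
    else:
        min_count = params.S * state.max_count
    read_to_window = params.partial_sum_side == "read_to_window"
    use_rule2 = params.use_rule2 and not read_to_window

    candidates = np.flatnonzero(state.counts >= min_count)
    t_idx = np.arange(T, dtype=np.int64)
    visited = 0
    for i in candidates:
        if use_rule2 and (T - int(state.counts[i])) * params.m > state.best_dist:
            continue
        visited += 1
        if read_to_window:
            dist = _delta_read_to_window(ref, profile, int(i))
            if params.use_abort and dist > state.best_dist:
                continue
        else:
            dist = int(profile.ctab[ref.codes[i : i + T], t_idx].sum())
            if params.use_abort and dist > state.best_dist:
                # the running sum would have been aborted mid-window;
                # the outcome (window discarded) is identical
                continue
        if dist < state.best_dist:
            state.best_dist = dist
            state.best_pos = int(i)
    D = params.resolve_threshold(len(read))
    aligned = state.best_pos is not None and state.best_dist <= D
    return AlignmentResult(
        read.id, ref.id, state.best_pos, "+", state.best_dist, aligned, visited
    )


def _align_one_strand(
    read: Sequence,
    ref: ReferenceIndex,
    params: AlignmentParams,
    profile: ReadProfile | None,
) -> AlignmentResult:
    if params.use_hash:
        return align_hash(read, ref, params, profile)
    return align_exhaustive(read, ref, params, profile)


def align_with_strands(
    read: Sequence,
    reference: Sequence | ReferenceIndex,
    params: AlignmentParams,
    profile: ReadProfile | None = None,
) -> AlignmentResult:
    """Forward-first strand policy.

    The forward read is aligned; only if its minimum distance exceeds
    the internal threshold ``T = rc_factor * (|r|-k+1) * m`` is the
    reverse complement aligned as well, and the strand with the smaller
    minimum returned (ties -> forward).  A reverse-strand result keeps
    the original read id; its position is the 0-based window start on
    the forward reference.
    """
    ref = _as_ref_index(reference, params.k)
    if profile is None:
        profile = ReadProfile(read, params)
    fwd = _align_one_strand(read, ref, params, profile)
    if fwd.distance <= params.rc_threshold(len(read)):
        return fwd
    rev = _align_one_strand(profile.rc().read, ref, params, profile.rc())
    if rev.distance < fwd.distance:
        D = params.resolve_threshold(len(read))
        return AlignmentResult(
            read.id,
            ref.id,
            rev.position,
            "-",
            rev.distance,
            rev.distance <= D,
            fwd.windows_visited + rev.windows_visited,
        )
    return fwd


def align_read(
    read: Sequence,
    references: list[Sequence | ReferenceIndex],
    params: AlignmentParams,
    profile: ReadProfile | None = None,
) -> AlignmentResult:
    """Align one read against several reference sequences independently
    and report the best (reference, position); ties keep the first
    reference in input order.  Reads never span a sequence boundary."""
    if not references:
        raise ValueError("no reference sequences given")
    if profile is None:
        profile = ReadProfile(read, params)
    best: AlignmentResult | None = None
    for reference in references:
        res = align_with_strands(read, reference, params, profile)
        if best is None or res.distance < best.distance:
            best = res
    assert best is not None
    return best
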