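"""Rank-based distances on DNA strings.

Local Rank Distance (LRD) measures the dissimilarity of two strings by
pairing every k-mer of one string with the *nearest* identical k-mer of
the other and summing the positional offsets.  Each contribution is
capped at a maximal offset ``m``, which doubles as the penalty for a
k-mer with no identical partner anywhere in the other string.  The full
distance is the symmetric sum of the two one-sided partial sums

    LRD(x, y) = Delta(x -> y) + Delta(y -> x),

where ``Delta(x -> y)`` scans the k-mers of ``x`` against ``y``.  LRD is
zero exactly on identical strings (for the one-sided sum, whenever every
k-mer of ``x`` occurs at the same position in ``y``) and grows with the
amount of local rearrangement, substitution and indel noise between the
strings, which is what makes it usable both as an alignment objective
and as a whole-sequence similarity for phylogenetic comparison.

The module also provides the older character-level rank distance, the
reverse complement, and the Hamming / edit distances used when auditing
simulated reads against their ground-truth substrings.
"""

from __future__ import annotations

from bisect import bisect_left
from collections import defaultdict
from dataclasses import dataclass

import edlib

DNA_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class Sequence:
    """An identified DNA string over {A, C, G, T, N}.

    Lowercase input is uppercased on construction; any other character
    raises ``ValueError``.
    """

    id: str
    bases: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "bases", self.bases.upper())
        bad = set(self.bases) - DNA_ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains invalid characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class LrdParams:
    """LRD parameters: k-mer length ``k`` and maximal offset ``m``.

    ``m`` caps the contribution of any single k-mer and is the penalty
    for an unmatched one; it defines the radius of the window in which a
    matching k-mer is worth looking for.
    """

    k: int = 3
    m: int = 24

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if self.m < 1:
            raise ValueError(f"m must be >= 1, got {self.m}")


def _bases(x: Sequence | str) -> str:
    return x.bases if isinstance(x, Sequence) else str(x)


def _check_alphabet(s: str) -> None:
    bad = set(s) - DNA_ALPHABET
    if bad:
        raise ValueError(f"invalid characters: {sorted(bad)}")


def kmer_positions(s: Sequence | str, k: int) -> dict[str, list[int]]:
    """Ascending start positions of every matchable k-mer of ``s``.

    K-mers containing ``N`` are omitted: they never match anything.
    """
    b = _bases(s)
    table: dict[str, list[int]] = defaultdict(list)
    for p in range(len(b) - k + 1):
        kmer = b[p : p + k]
        if "N" not in kmer:
            table[kmer].append(p)
    return dict(table)


def nearest_position(positions: list[int], q: int) -> int | None:
    """Element of an ascending list nearest to ``q``; ties -> smaller element.

    Returns ``None`` on an empty list.
    """
    if not positions:
        return None
    i = bisect_left(positions, q)
    if i == 0:
        return positions[0]
    if i == len(positions):
        return positions[-1]
    left, right = positions[i - 1], positions[i]
    # tie |q-left| == |right-q| broken toward the smaller position
    return left if q - left <= right - q else right


def delta_one_sided(
    x: Sequence | str, y: Sequence | str, params: LrdParams
) -> int:
    """One-sided LRD partial sum Delta(x -> y).

    For every k-mer start position ``p`` in ``x`` (all ``|x|-k+1`` of
    them), the contribution is ``min(|p - q|, m)`` where ``q`` is the
    position of the nearest identical k-mer in ``y``, or ``m`` when no
    identical k-mer exists.  K-mers containing ``N`` never match.
    """
    bx, by = _bases(x), _bases(y)
    _check_alphabet(bx)
    _check_alphabet(by)
    k, m = params.k, params.m
    if len(bx) < k or len(by) < k:
        raise ValueError(
            f"both strings must be at least k={k} long "
            f"(got {len(bx)} and {len(by)})"
        )
    index = kmer_positions(by, k)
    total = 0
    for p in range(len(bx) - k + 1):
        kmer = bx[p : p + k]
        if "N" in kmer:
            total += m
            continue
        q = nearest_position(index.get(kmer, []), p)
        total += m if q is None else min(abs(p - q), m)
    return total


def local_rank_distance(
    x: Sequence | str, y: Sequence | str, params: LrdParams
) -> int:
    """Symmetric Local Rank Distance Delta(x -> y) + Delta(y -> x)."""
    return delta_one_sided(x, y, params) + delta_one_sided(y, x, params)


def rank_distance(
    x: Sequence | str,
    y: Sequence | str,
    unmatched_penalty: float | str = "length_mean",
) -> float:
    """Character-level rank distance with occurrence-indexed pairing.

    Each character is annotated with its occurrence ordinal (the i-th A,
    the i-th C, ...).  Annotated characters present in both strings add
    the absolute difference of their positions; each occurrence present
    in only one string adds ``unmatched_penalty``.  The default policy
    ``"length_mean"`` charges ``(|x| + |y|) / 2`` per unmatched
    occurrence; a number may be passed to override it.
    """
    bx, by = _bases(x), _bases(y)
    if not bx or not by:
        raise ValueError("rank_distance requires non-empty strings")
    if unmatched_penalty == "length_mean":
        penalty = (len(bx) + len(by)) / 2
    else:
        penalty = float(unmatched_penalty)

    def annotate(b: str) -> dict[tuple[str, int], int]:
        seen: dict[str, int] = defaultdict(int)
        out: dict[tuple[str, int], int] = {}
        for pos, c in enumerate(b):
            out[(c, seen[c])] = pos
            seen[c] += 1
        return out

    ax, ay = annotate(bx), annotate(by)
    total = 0.0
    for key, px in ax.items():
        if key in ay:
            total += abs(px - ay[key])
        else:
            total += penalty
    total += penalty * len(set(ay) - set(ax))
    return total


def reverse_complement(x: Sequence) -> Sequence:
    """Reverse complement; id is preserved. A<->T, C<->G, N->N."""
    return Sequence(x.id, revcomp(x.bases))


def revcomp(bases: str) -> str:
    """Reverse complement of a plain string."""
    _check_alphabet(bases.upper())
    return bases.upper().translate(_COMPLEMENT)[::-1]


def hamming_distance(a: Sequence | str, b: Sequence | str) -> int:
    """Number of mismatching positions of two equal-length strings."""
    ba, bb = _bases(a), _bases(b)
    if len(ba) != len(bb):
        raise ValueError(
            f"hamming_distance requires equal lengths ({len(ba)} != {len(bb)})"
        )
    return sum(ca != cb for ca, cb in zip(ba, bb))


def edit_distance(a: Sequence | str, b: Sequence | str) -> int:
    """Levenshtein distance (unit-cost substitutions, insertions, deletions)."""
    ba, bb = _bases(a), _bases(b)
    if not ba or not bb:
        return max(len(ba), len(bb))
    return edlib.align(ba, bb, task="distance")["editDistance"]
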