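"""wgsim-style read simulation and synthetic genome collections.

Ground truth for every experiment comes from here: a genome mutator
(SNPs plus geometrically extended indels), a uniform read sampler with
per-base substitution sequencing error and an exact fraction of
reverse-complement reads, a random phylogeny of "orders" generated by
divergence from a common root, and a contamination mixer that labels
reads by their genome of origin.

All randomness flows through a single :class:`numpy.random.Generator`,
so every output is bit-reproducible from one seed.  Defaults follow the
published wgsim defaults (error rate 0.02, mutation rate 0.001, indel
fraction 0.15, indel extension 0.30, 100 bp reads) and are stand-ins to
be overridden freely.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np

from .rankdist import Sequence, revcomp

_BASES = "ACGT"
_OTHER = {b: _BASES.replace(b, "") for b in _BASES}


@dataclass(frozen=True)
class SimParams:
    """Simulation settings.

    error_rate:
        per-base sequencing substitution probability on reads.
    mutation_rate:
        per-base genome mutation probability.
    indel_fraction:
        fraction of mutations that are indels (the rest are SNPs).
    indel_extend:
        probability of extending an indel by one more base.
    read_length, n_reads:
        read geometry and count.
    rc_fraction:
        exact fraction of reads emitted as reverse complements.
    """

    error_rate: float = 0.02
    mutation_rate: float = 0.001
    indel_fraction: float = 0.15
    indel_extend: float = 0.30
    read_length: int = 100
    n_reads: int = 100
    rc_fraction: float = 0.5

    def __post_init__(self) -> None:
        for name in ("error_rate", "mutation_rate", "indel_fraction",
                     "indel_extend", "rc_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")


class Variant(NamedTuple):
    position: int  # 0-based position in the input genome
    kind: str  # "snp" | "ins" | "del"
    ref: str
    alt: str


@dataclass(frozen=True)
class SimulatedRead:
    """A read with its ground truth.

    ``truth_substring`` is the error-free substring of the source genome
    the read was sampled from (always on the forward strand); for a
    reverse-complement read, ``revcomp(read.bases)`` is comparable to it
    position by position.
    """

    read: Sequence
    source_genome_id: str
    source_start: int
    strand: str
    truth_substring: str


@dataclass(frozen=True)
class GenomeRecord:
    """Manifest entry of a genome collection."""

    genome_id: str
    order: str
    sequence: Sequence
    group_id: str = ""

    def __post_init__(self) -> None:
        if not self.group_id:
            object.__setattr__(self, "group_id", self.genome_id)


def random_genome(genome_id: str, length: int, rng: np.random.Generator) -> Sequence:
    """Uniform random genome over {A, C, G, T}."""
    return Sequence(genome_id, "".join(rng.choice(list(_BASES), size=length)))


def _indel_length(params: SimParams, rng: np.random.Generator) -> int:
    length = 1
    while rng.random() < params.indel_extend:
        length += 1
    return length


def mutate_genome(
    genome: Sequence,
    params: SimParams,
    rng: np.random.Generator,
    new_id: str | None = None,
) -> tuple[Sequence, list[Variant]]:
    """Mutate a genome base by base at ``mutation_rate``.

    A mutation is an indel with probability ``indel_fraction`` (insert
    or delete with equal odds, length geometric with continuation
    probability ``indel_extend``) and otherwise a SNP to a uniformly
    chosen different base.  ``N`` bases are passed through unmutated.
    Returns the mutated genome and a log of variants in input-genome
    coordinates.
    """
    r = params.mutation_rate
    out: list[str] = []
    log: list[Variant] = []
    bases = genome.bases
    i = 0
    while i < len(bases):
        b = bases[i]
        if b != "N" and rng.random() < r:
            if rng.random() < params.indel_fraction:
                length = _indel_length(params, rng)
                if rng.random() < 0.5:  # deletion of this and following bases
                    del_len = min(length, len(bases) - i)
                    log.append(Variant(i, "del", bases[i : i + del_len], ""))
                    i += del_len
                    continue
                ins = "".join(rng.choice(list(_BASES), size=length))
                out.append(b)
                out.append(ins)
                log.append(Variant(i, "ins", b, b + ins))
                i += 1
                continue
            alt = _OTHER[b][rng.integers(3)]
            out.append(alt)
            log.append(Variant(i, "snp", b, alt))
            i += 1
            continue
        out.append(b)
        i += 1
    mutated = Sequence(new_id or genome.id, "".join(out))
    return mutated, log


def _apply_errors(bases: str, e: float, rng: np.random.Generator) -> str:
    if e <= 0.0:
        return bases
    arr = list(bases)
    err = np.flatnonzero(rng.random(len(arr)) < e)
    for j in err:
        b = arr[j]
        arr[j] = _OTHER.get(b, _BASES)[rng.integers(3 if b in _OTHER else 4)]
    return "".join(arr)


def simulate_reads(
    genome: Sequence,
    params: SimParams,
    rng: np.random.Generator,
    read_prefix: str | None = None,
) -> list[SimulatedRead]:
    """Sample ``n_reads`` uniform reads with sequencing error.

    An exact ``round(rc_fraction * n_reads)`` of the reads (chosen at
    random) are emitted as reverse complements with strand ``-``; the
    substitution error is applied to the sequenced strand.
    """
    L, n = params.read_length, params.n_reads
    if len(genome) < L:
        raise ValueError(
            f"genome {genome.id!r} ({len(genome)} bp) shorter than read length {L}"
        )
    prefix = read_prefix or genome.id
    starts = rng.integers(0, len(genome) - L + 1, size=n)
    n_rc = int(round(params.rc_fraction * n))
    rc_set = set(rng.choice(n, size=n_rc, replace=False).tolist()) if n_rc else set()
    reads = []
    for idx in range(n):
        s = int(starts[idx])
        truth = genome.bases[s : s + L]
        strand = "-" if idx in rc_set else "+"
        seq = revcomp(truth) if strand == "-" else truth
        seq = _apply_errors(seq, params.error_rate, rng)
        reads.append(
            SimulatedRead(
                Sequence(f"{prefix}_r{idx}", seq), genome.id, s, strand, truth
            )
        )
    return reads


def synth_phylogeny(
    n_orders: int,
    genomes_per_order: int,
    genome_length: int,
    within_divergence: float,
    between_divergence: float,
    rng: np.random.Generator,
    params: SimParams | None = None,
) -> list[GenomeRecord]:
    """Random genome collection with order structure.

    One ancestral genome per order is derived from a common root at
    ``between_divergence``; order members are derived from their
    ancestor at ``within_divergence``.  Mutation uses
    :func:`mutate_genome` with the indel settings of ``params``.
    """
    if not 0.0 <= within_divergence < between_divergence <= 1.0:
        raise ValueError(
            "require 0 <= within_divergence < between_divergence <= 1, got "
            f"({within_divergence}, {between_divergence})"
        )
    base = params or SimParams()
    root = random_genome("root", genome_length, rng)
    records: list[GenomeRecord] = []
    for o in range(n_orders):
        order = f"order{o}"
        ancestor, _ = mutate_genome(
            root, replace(base, mutation_rate=between_divergence), rng, order
        )
        for g in range(genomes_per_order):
            gid = f"{order}_g{g}"
            member, _ = mutate_genome(
                ancestor, replace(base, mutation_rate=within_divergence), rng, gid
            )
            records.append(GenomeRecord(gid, order, member))
    return records


def contamination_mix(
    target_genome: Sequence,
    contaminant_genomes: list[Sequence],
    n_target: int,
    n_contaminant: int,
    params: SimParams,
    rng: np.random.Generator,
) -> list[tuple[SimulatedRead, str]]:
    """Shuffled read set of target ("positive") and contaminant
    ("negative") reads; contaminant reads are split as evenly as
    possible across the contaminant genomes (earlier genomes take the
    remainder)."""
    mix: list[tuple[SimulatedRead, str]] = []
    for r in simulate_reads(target_genome, replace(params, n_reads=n_target), rng):
        mix.append((r, "positive"))
    if contaminant_genomes:
        share = n_contaminant // len(contaminant_genomes)
        rem = n_contaminant % len(contaminant_genomes)
        for ci, cg in enumerate(contaminant_genomes):
            n_c = share + (1 if ci < rem else 0)
            for r in simulate_reads(
                cg, replace(params, n_reads=n_c), rng, read_prefix=f"{cg.id}_c{ci}"
            ):
                mix.append((r, "negative"))
    elif n_contaminant:
        raise ValueError("n_contaminant > 0 but no contaminant genomes given")
    order = rng.permutation(len(mix))
    return [mix[i] for i in order]
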