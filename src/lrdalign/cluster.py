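"""Clustering an unknown organism by genome scores.

A set of reads representing an unknown organism is aligned against
every genome in a collection.  For each genome, only the subset ``A``
of reads whose minimum distance passes the aligner threshold counts;
the genome score is

    score = (sum of minimum distances over A) / |A|**2

i.e. the average minimum distance further divided by the number of
aligned reads, so a genome that aligns more reads scores as more
similar.  The genome with the lowest score is the nearest; the unknown
organism is predicted to belong to that genome's order.  A genome (or
group of chromosomes) that aligns no reads at all has an undefined
score and ranks strictly after every genome with a defined one.

Multi-chromosome organisms are handled through manifest *groups*:
distances and aligned-read counts are pooled over a group's sequences
before the final division, and each read contributes its best
chromosome placement.

``leave_one_out`` wraps the full protocol: each genome in turn is the
unknown, represented by reads simulated from it, and scored against all
remaining genomes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .aligner import (
    AlignmentParams,
    AlignmentResult,
    ReadProfile,
    ReferenceIndex,
    align_with_strands,
)
from .rankdist import Sequence
from .simulate import GenomeRecord, SimParams, simulate_reads


@dataclass
class GenomeScore:
    """Aligned-read count, pooled minimum distances and the final score
    (``None`` when no read aligned)."""

    genome_id: str
    n_aligned: int
    sum_min_dist: float
    score: float | None


@dataclass
class ClusterPrediction:
    query_genome_id: str | None
    nearest_genome_id: str | None
    predicted_order: str | None
    correct: bool | None
    scores: dict[str, GenomeScore]


def score_genome(
    genome_id: str,
    results: list[AlignmentResult],
    mode: str = "squared",
) -> GenomeScore:
    """Score one genome from the alignment results of a read set.

    ``mode="squared"`` is the default ``sum / |A|**2``; ``mode="mean"``
    is the plain average minimum distance ``sum / |A|``.
    """
    if mode not in ("squared", "mean"):
        raise ValueError(f"unknown score mode {mode!r}")
    aligned = [r for r in results if r.aligned]
    n = len(aligned)
    total = float(sum(r.distance for r in aligned))
    if n == 0:
        return GenomeScore(genome_id, 0, 0.0, None)
    score = total / (n * n) if mode == "squared" else total / n
    return GenomeScore(genome_id, n, total, score)


def _group_score(members: list[GenomeScore], group_id: str, mode: str) -> GenomeScore:
    n = sum(s.n_aligned for s in members)
    total = sum(s.sum_min_dist for s in members)
    if n == 0:
        return GenomeScore(group_id, 0, 0.0, None)
    score = total / (n * n) if mode == "squared" else total / n
    return GenomeScore(group_id, n, total, score)


def nearest_genome(
    reads: list[Sequence],
    genomes: list[GenomeRecord],
    params: AlignmentParams,
    score_mode: str = "squared",
    query_genome_id: str | None = None,
    true_order: str | None = None,
) -> ClusterPrediction:
    """Align every read to every genome and return the lowest-scoring
    group; ties break to the lexicographically smaller group id.

    When no group aligns any read, the prediction is the explicit "no
    similar genome" outcome (``nearest_genome_id is None``).
    """
    if not genomes:
        raise ValueError("empty genome collection")
    profiles = [ReadProfile(r, params) for r in reads]
    refs = [ReferenceIndex(g.sequence, params.k) for g in genomes]
    per_genome: dict[str, GenomeScore] = {}
    for rec, ref in zip(genomes, refs):
        results = [
            align_with_strands(p.read, ref, params, profile=p) for p in profiles
        ]
        per_genome[rec.genome_id] = score_genome(rec.genome_id, results, score_mode)
    groups: dict[str, list[GenomeScore]] = {}
    group_order: dict[str, str] = {}
    for rec in genomes:
        groups.setdefault(rec.group_id, []).append(per_genome[rec.genome_id])
        group_order[rec.group_id] = rec.order
    group_scores = {
        gid: _group_score(members, gid, score_mode)
        for gid, members in groups.items()
    }
    defined = [
        (s.score, gid) for gid, s in group_scores.items() if s.score is not None
    ]
    if not defined:
        return ClusterPrediction(query_genome_id, None, None, None, per_genome)
    _, best_gid = min(defined)
    predicted = group_order[best_gid]
    correct = None if true_order is None else predicted == true_order
    return ClusterPrediction(query_genome_id, best_gid, predicted, correct, per_genome)


def leave_one_out(
    genomes: list[GenomeRecord],
    sim: SimParams,
    params: AlignmentParams,
    rng: np.random.Generator,
    score_mode: str = "squared",
) -> tuple[list[ClusterPrediction], int, int]:
    """Leave-one-out order recovery.

    Each genome in turn is the unknown organism, represented by reads
    simulated from it; its order is predicted from the nearest remaining
    genome.  Returns the predictions plus (correct, total), to be
    reported as the accuracy fraction ``correct/total``.
    """
    if len(genomes) < 2:
        raise ValueError("leave-one-out needs at least two genomes")
    if len({g.order for g in genomes}) < 2:
        raise ValueError("leave-one-out needs at least two orders")
    predictions: list[ClusterPrediction] = []
    correct = 0
    for held in genomes:
        reads = [
            r.read for r in simulate_reads(held.sequence, sim, rng)
        ]
        rest = [g for g in genomes if g.genome_id != held.genome_id]
        pred = nearest_genome(
            reads,
            rest,
            params,
            score_mode,
            query_genome_id=held.genome_id,
            true_order=held.order,
        )
        predictions.append(pred)
        correct += bool(pred.correct)
    return predictions, correct, len(genomes)
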