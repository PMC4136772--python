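# Methods

## Local Rank Distance

For strings over {A, C, G, T, N}, a k-mer size `k` and a maximal offset
`m`, the one-sided partial sum Δ(x→y) pairs each of the `|x|-k+1`
k-mers of `x` with the nearest identical k-mer of `y` and adds the
positional offset, capped at `m`; a k-mer with no identical partner —
and any k-mer containing `N`, which by definition matches nothing —
adds `m`. LRD is the symmetric sum Δ(x→y)+Δ(y→x). Capping at `m` is
equivalent to restricting the nearest-match search to a window of
radius `m` around the k-mer's own position, which is how the
implementation can bound the search; the equivalence is asserted by a
test. LRD is returned as an exact integer. It is a similarity measure,
not a metric: the triangle inequality is neither claimed nor used.

Positions are 0-based everywhere in the library. Offsets are
differences of positions, so results match a 1-based convention
exactly; only SAM output converts to 1-based coordinates. When a k-mer
has two nearest occurrences at equal offset, the smaller position is
chosen — the contribution is unaffected, but the choice keeps traces
deterministic.

The character-level rank distance is included for completeness: each
character is annotated with its occurrence ordinal, matched ordinals
add their position difference, and each unmatched occurrence adds a
penalty. The penalty policy is configurable; the default charges
`(|x|+|y|)/2` per unmatched occurrence, a neutral mid-scale value —
there is no single canonical choice, so it is a keyword argument.

## Aligners

Alignment minimises the *one-sided* sum only: symmetry is irrelevant
when placing a read, and one partial sum halves the work. Both aligners
default to the same side — window k-mers looked up in the read's index
(Δ(w→r)) — so that the exhaustive and hash aligners are exactly
comparable; the opposite side (read k-mers searched within the window)
is available via `partial_sum_side="read_to_window"`. The admissible
pruning bound below is only valid for the window→read side, so rule 2
is disabled on the other side.

The exhaustive aligner evaluates every window start and returns the
leftmost minimum (ties across strands resolve to forward). Internally
it precomputes, for every k-mer code and every in-window offset `t`,
the capped distance to the nearest read occurrence (a `(4^k+1) × T`
table including an all-`m` row for absent/N k-mers), after which each
window's distance is a gather-and-sum; this is algebraically identical
to evaluating Δ(w→r) per window and is tested against the quadratic
definition directly. Table-based evaluation requires `4^k` to stay
small; `k ≤ 10` is enforced, far above the useful range for 100 bp
reads.

The hash aligner adds three prunings:

1. **Skip fraction** `S`: windows with shared-k-mer count
   `C[i] < S·max(C)` are skipped. `S=0` disables the rule, `S=1`
   visits only count-maximal windows. This is the approximate step: a
   true optimum at a low-count window can be lost, though a window
   attaining `max(C)` is never skipped. An alternative absolute
   reading (`C[i] ≥ max(C) − slack`) is available via
   `skip_mode="slack"`.
2. **Missing-k-mer bound** (rule 2): every window k-mer absent from the
   read contributes exactly `m`, and present ones contribute ≥ 0, so
   `(T − C[i])·m ≤ Δ(w_i→r)`. Windows whose bound exceeds the current
   best are skipped without loss.
3. **Early abort**: contributions are non-negative, so a window whose
   running sum exceeds the running best cannot win. The reference
   `delta_at_window` implements the literal running-sum abort; the
   vectorised path computes the window sum and discards it on the same
   condition — the kept/discarded outcome is identical, which is what
   the abort-soundness test asserts.

Strand policy: the forward read is aligned first and accepted outright
when its minimum is ≤ `T = rc_factor·(|r|−k+1)·m`; only otherwise is
the reverse complement aligned and the smaller minimum returned (ties
to forward). This saves a factor of ~2 on same-organism data and
degrades to both-strand evaluation on diverged data, where forward
minima are rarely below `T`.

### Parameter defaults

| parameter | default | meaning |
|---|---|---|
| `k` | 3 | k-mer length; 3–5-mers suit 100 bp reads — long k-mers almost never repeat within a short read |
| `m` | 24 | maximal offset / unmatched penalty, in positions; scales with read length and alphabet (4^3 = 64 ≫ 24 keeps accidental matches rare inside the window) |
| `D` | `0.3·(L−k+1)·m` | acceptance threshold: 30 % of a read's worst possible score |
| `S` | 1.0 | visit only count-maximal windows; empirically indistinguishable from exhaustive placement on reads with a true home |
| `rc_factor` | 0.2 | forward-acceptance threshold factor |

These defaults are the package's own working values, chosen for 100 bp
reads, and every one is overridable per call and on the CLI.

## Read simulator

The simulator emulates the wgsim model. Genome mutation walks the
sequence once: each base mutates with probability `r`; a mutation is an
indel with probability `f` (insert/delete with equal odds, length 1 plus
a geometric extension with continuation probability `p`) and otherwise
a SNP to a uniformly chosen different base. Reads are sampled uniformly
(never across the origin — circular genomes such as mtDNA are treated
as linear, a documented simplification), an exact
`round(rc_fraction·n)` of them emitted as reverse complements, and
per-base substitution errors applied to the sequenced strand at rate
`e`. Sequencing errors are substitutions only, as in wgsim; indels
enter through genome mutation. Defaults are wgsim's published defaults
(`e=0.02, r=0.001, f=0.15, p=0.30, L=100`).

Every read records its source genome, 0-based start, strand and the
error-free forward-strand substring it came from, so Hamming and edit
distances between a read and its ground truth are always well defined
(reverse-complement reads are re-complemented before comparison).

The synthetic phylogeny generator draws one random root genome, derives
one ancestor per "order" at a between-order divergence and order
members at a smaller within-order divergence. It emulates the
hierarchical, ultrametric part of real taxonomy only: no rate
variation across lineages, no conserved/variable site structure, no
compositional bias, no repeats beyond chance. Passing tests on these
collections demonstrates that the scoring machinery recovers known
hierarchical structure under the stated noise model — not that it will
resolve any particular real clade.

## Genome scoring and leave-one-out

Reads are aligned to each genome under the threshold `D`; with `A` the
aligned subset and `d_a` each read's minimum distance, the genome score
is `(Σ d_a)/|A|²` — the average minimum distance divided once more by
the number of aligned reads. The sentence defining the score admits a
second reading (the plain average, without the extra division);
the squared form is the default here because it encodes "a genome that
aligns more reads is more similar" — duplicating every aligned read
halves the score, a behaviour asserted by a test — and the plain
average remains available as `score_mode="mean"`. A genome aligning no
reads has an *undefined* score and ranks strictly after all defined
scores; if no genome aligns anything the outcome is an explicit "no
similar genome" prediction rather than an arbitrary pick. Score ties
break to the lexicographically smaller genome id. Multi-chromosome
organisms are manifest *groups*: counts and distance sums are pooled
across the group's sequences before the final division.

Leave-one-out treats each genome in turn as unknown, simulates a read
set from it, scores the remaining genomes and predicts the order of the
nearest; accuracy is reported as correct/total.

## Evaluation

A read counts as aligned at threshold `t` iff its distance is finite
and ≤ `t`; reads the aligner never produced a distance for are +∞ and
never align. A `direction="higher"` flag serves score-like measures
where larger is better. Curve thresholds are the distinct observed
distances plus a sentinel below all of them — a fixed grid can only
coarsen this sweep. Precision is 0 by convention when nothing aligns.
ROC AUC is computed by scikit-learn's trapezoidal rule on the negated
distances (ties contribute diagonal segments) and is tested against
independent Mann–Whitney pair counting; F-beta is the standard
`(1+β²)PR/(β²P+R)` with 0 at P=R=0, reported for β ∈ {1, 2}. The TP/FN
audit partitions *positive* reads at a threshold into mapped/unmapped
and reports each side's count and mean Hamming/edit distance to ground
truth; an empty side's means are absent rather than zero.

## Problem sizes and numerical choices

The test suite and the acceptance script run on synthetic instances
sized so the full pipeline stays exact and quick: 5 kb references for
aligner-equivalence checks (100 instances), 20 kb genomes for the
leave-one-out (3 orders × 3 genomes, 100×100 bp reads) and
contamination (500+500 reads) protocols. These sizes give every stage
thousands-to-millions of elementary comparisons, ample to expose
off-by-one or tie-breaking defects, while each protocol's outcome
(order recovery, AUC ≈ 0.99) is already saturated and would not change
qualitatively at larger scale.

All distances are exact integer arithmetic end to end; no floating
point enters until scores and rates are formed. All randomness flows
through a single `numpy.random.Generator`, so every simulated dataset,
read and result is bit-reproducible from one seed.

## Known limitations

- The aligner reports a placement position and a distance, not a
  base-level CIGAR alignment; indel reads get a position and an `<L>M`
  CIGAR in SAM output.
- No paired-end support, no quality-aware scoring; FASTQ qualities are
  read and discarded.
- The skip-fraction rule makes the default aligner approximate by
  design; exactness is available (`S=0`, rule 2 and abort off) at the
  cost of visiting every window.
- Circularity of small genomes is ignored by the simulator and the
  aligner alike.
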