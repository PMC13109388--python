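# Methods

## Read classification and the retention statistic

Reads are represented by their maximal gapless aligned segments
("blocks"), taken from the alignment CIGAR: match/mismatch operations
extend a block, reference skips (`N`) always open a gap, and deletions
are absorbed into the surrounding block when shorter than
`max_deletion_as_gap` (default 20 nt — below this a deletion is an indel,
not a junction) and open a gap otherwise. Secondary, supplementary and
unmapped alignments are ignored; duplicates are kept, and each mate of a
pair is classified independently.

Overlap with an intron is computed on the read's full genomic span (first
block start to last block end), so an exact-junction read "overlaps" the
intron it skips — necessary for junction reads to be countable as
spliced. A minimum span overlap of 3 bases is required; below it the
(read, intron) pair is ignored entirely. Classification of an
overlapping pair is exhaustive and mutually exclusive:

| blocks | condition | class |
|---|---|---|
| 1 | fully inside the intron | intronic |
| 1 | crosses a boundary | unspliced |
| >1 | some gap equals the intron at both ends, no tolerance | spliced |
| >1 | no gap matches | alternatively spliced |

A read with several gaps can be spliced for each intron its gaps match; a
read may increment counts for multiple overlapping introns. The
retention fraction is `IR = u/(u + 2s)` with `u` the unspliced and `s`
the spliced count; it is undefined (missing, never 0/0-coerced) when the
denominator is zero. Intronic reads are counted and reported but kept
out of the statistic by default: boundary-crossing reads measure the
boundary directly, whereas fully-intronic coverage also reflects intron
length and degradation. `include_intronic_in_numerator` adds them to
both numerator and denominator for sensitivity analyses.

Strand handling follows dUTP-type libraries: under the default
`second`-mate protocol a second-mate read reports its aligned strand and
a first-mate read the opposite; the `first` protocol mirrors this and
`unstranded` matches both strands. The reporting mate is switchable
because both conventions occur in practice and the choice silently flips
which antisense features absorb reads.

## Coverage and significance rules

Inclusion tables are long-format: one row per (event, condition,
replicate) with an inclusion level (PSI) and a supporting read count —
for retention events the informative count `u + s`, for rMATS events the
per-replicate inclusion + skipping junction count (IJC + SJC). An event
is adequately covered when the median count across replicates reaches 50
in at least one condition; cross-condition comparisons additionally
require the rule in every condition (`all_conditions`). The
all-conditions variant takes the minimum over conditions the event was
measured in; a condition entirely absent surfaces later as an undefined
delta rather than as silent removal, and a zero cutoff is exactly the
identity.

Retention significance uses the two-sample pooled-variance Student
t-test on replicate IR fractions (Welch available via `equal_var=False`),
two-tailed, requiring p < 0.01 and |ΔPSI| ≥ 0.05 with Δ = mean(test) −
mean(reference). Boundary semantics are ≥ for the delta and strict <
for p/FDR. Degenerate events (both groups constant) get p = 1 on equal
means and p = 0 otherwise; events with fewer than two replicates in a
group are skipped and logged. rMATS events use the upstream FDR when
present, else Benjamini–Hochberg within each event type (rMATS reports
per-type output files), at FDR < 0.01 and |ΔPSI| ≥ 0.1. Retained-intron
events quantified with an enlarged maximum-exon-length setting are
post-filtered to flanking exons ≤ 500 nt, restoring typical exon
architecture while keeping long introns representable; RI events without
flank geometry are dropped and logged. Missing inclusion values are
ignored, never imputed.

## Additive decomposition

The combined-perturbation inclusion difference is modelled per event as
`(1−w)·ID_A + w·ID_B`. The sweep evaluates Pearson correlation between
prediction and observation at weights k/N (default N = 100); weights are
kept as integer fractions so that swapping the two inputs mirrors the
correlation profile bitwise, and the argmax takes the smallest weight on
ties. Grid points with zero prediction variance are undefined and
excluded. Profiles are computed pooled and per event type (≥ 3 complete
events), because a pooled optimum can mask heterogeneous per-type
weights; both are always emitted. Correlation is Pearson on raw
inclusion differences — inclusion differences are already on a common
bounded scale, so rank methods would only discard magnitude information.
The event universe is everything passing the all-conditions coverage
filter, not only significant events; restricting to significant events is
possible upstream but conflates effect-size selection with the mixture
question. An OLS summary (slope, intercept, r, r², pointwise 95% CI
band) of observed on predicted effects accompanies the sweep for
plotting.

## Binding isotherm

The anisotropy model solves the 1:1 mass balance exactly — the bound
complex is the smaller root of `[PR]² − (P+R+K_d)[PR] + P·R = 0` — and
mixes free and bound anisotropies by bound fraction; no free-ligand
approximation, which matters when K_d is within an order of magnitude of
the RNA concentration. A discriminant pushed slightly negative by
rounding is clamped to zero (exact stoichiometric saturation).
Fitting is unweighted nonlinear least squares (no error model is assumed
for the spectrometer) on (K_d, A_R, A_PR), with the RNA concentration a
fixed known assay constant (default 20 nM labelled oligo). Deterministic
initialisation: A_R from the lowest-protein point, A_PR from the highest,
K_d from linear interpolation of the half-signal concentration. K_d is
bounded below at 10⁻¹⁵ M; hitting that bound, fewer than 5 distinct
concentrations, K_d beyond the titrated range, or A_PR < A_R are
surfaced as warnings on the fit object, and constant anisotropy raises an
unidentifiability error rather than returning arbitrary parameters.

## Synthetic data: what it emulates, and what it does not

The generator mirrors a two-factor perturbation study: four conditions
(control, knockout A, knockdown B, combined) × 3 replicates, 50 nt
paired-end reads from a dUTP-type stranded library. Genes are laid out
non-overlapping on one chromosome, alternating strands, exons 80–300 nt
and introns 100–1500 nt — ranges chosen so that every read emitted for an
intron stays within its flanking exons and can never touch a neighbouring
intron, which makes the recorded truth table an *exact* oracle for the
classifier rather than an approximate one.

Per intron and sample with true retention ψ and target informative depth
d (default 80), spliced counts are Poisson(d·(1−ψ)/(1+ψ)) and unspliced
counts Poisson(d·2ψ/(1+ψ)), so the expected value of the retention
statistic equals ψ and the expected informative depth equals d — this
makes estimator recovery a well-posed test of the exact 2× statistic.
Nuisance intronic and non-matching split reads are added at 5% of depth
each; intronic reads are suppressed (with a warning) for introns shorter
than the read length. Baseline retention is uniform on 0.02–0.30 with
30% of introns responding to the perturbations (+0.10 for A, +0.04 for
B, the mixture for the combined condition).

Inclusion tables draw baseline PSI uniform on 0.15–0.85 (kept off the
boundaries so clipping does not distort the additive structure), with
condition-A effects enriched among retained-intron events and
condition-B effects among alternative-3′SS events (N(0.12, 0.08²) for
half of the targeted type, N(0, 0.02²) background) — mirroring a design
where one factor shifts retention and the other 3′ splice-site choice.
The combined effect is the weighted mean (default w = 0.6) plus
N(0, 0.02²) event noise; replicates add N(0, 0.05²) and clip to [0, 1];
read counts are negative binomial (dispersion 10) around per-event means
log-uniform on 20–300 so the coverage filter is genuinely exercised.
Titrations evaluate the isotherm at 12 points over 0–10 µM protein with
20 nM RNA and 1% multiplicative Gaussian noise.

Not modelled: sequencing errors, GC or positional bias, fragment-length
distributions, overlapping genes, multi-isoform structure, novel
junctions, and correlated replicate noise. Passing tests therefore
demonstrate correctness of the computations under the stated statistical
model, not robustness to alignment artefacts or annotation errors in
real data.

Determinism: every stage draws from `numpy` PCG64 generators seeded as
(seed, stage-tag[, sample-index]) in a documented order; coordinates are
integer arithmetic throughout; reads are emitted coordinate-sorted with
deterministic tie-breaking on read name. Rerunning any stage with one
seed reproduces outputs byte for byte.

## Verification scales and numerical choices

The classifier is checked exhaustively against an independently coded
rule-table oracle over a 2 kb window around a fixed intron: every
single-block read at 10-base resolution, every 2-block read at 25-base
and every 3-block read at 100-base resolution (≈1.7 million reads,
agreement required at 100%). The coarser multi-block grids keep the
enumeration complete at each stated resolution while the per-read check
stays a plain function call; the gap-match rule is coordinate-exact, so
grid spacing does not interact with the decision boundaries, which all
lie on multiples of the tested offsets. Estimator recovery uses 200
introns at ψ ∈ {0.02, 0.05, 0.1, 0.25, 0.5} and ~400 informative reads;
the null calibration 2000 events at 3 vs 3 replicates; weight recovery
5000 events at replicate noise 0.05; determinism a 15-gene, 500-event
pipeline run twice. These sizes are the package's verification
conditions and are regenerated, never stored.

## Known limitations

- Introns are derived from one transcript per gene (the longest), so the
  intron universe ignores minor isoforms; introns shared by overlapping
  genes are emitted once with all parent gene ids.
- The IR t-test treats replicate IR fractions as approximately normal;
  at very low informative depth a count-based test would be better
  calibrated. The coverage filter is the guard.
- The weighted-mean model is descriptive, not causal: it cannot
  distinguish additivity from shared upstream regulation, and it is not
  generalised beyond two perturbations.
- rMATS PSI estimation and its likelihood test are consumed, not
  reimplemented; the package's own p-values for rMATS-format tables are
  only produced when the upstream file carries none.
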