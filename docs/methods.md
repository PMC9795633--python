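# Methods

## The accumulation model

The central quantity is the summed mutation frequency of a sample,
M_s = Σ_i p_i,s over all retained mutations i, with p_i,s estimated as
mutant reads over total reads. Under neutral accumulation at a constant
per-generation rate and no initial mutations, M_s grows linearly through
the origin. For a population containing hypermutator lineages the model
decomposes by lineage:

    M_s = Σ_k r_k · f_k,s · g_s

where r_k is lineage k's accumulation rate (mutations/generation),
f_k,s its fraction of the population at sample s (estimated from the
frequency of the lineage's defining marker allele, e.g. a mutS variant),
and g_s the elapsed generations. The model assumes each mutator lineage
arose near the start of the experiment and kept one constant rate, and
that lineage fractions enter only at the sampled time points (no
integration of the fraction history between samples). Every mutation
inside a lineage is treated as a neutral hitchhiker whose population
frequency equals the lineage fraction.

Fits are ordinary (unweighted) least squares with a zero intercept:
design columns X_{s,k} = f_k,s·g_s, estimates (XᵀX)⁻¹Xᵀy, covariance
(RSS/(n−p))·(XᵀX)⁻¹ with p = number of rates (no intercept degree of
freedom). Marker fractions that sum slightly above 1 (independent
per-site estimates) are proportionally renormalized and the ancestral
fraction is the remainder. Rate equality is tested by an F-test against
the model with the two lineages' design columns merged; an exactly
zero full-model residual (noise-free data) is reported as a degenerate
comparison (infinite F, p clamped to 0) with a warning.

Weighted fits are deliberately not the default. A consequence,
quantified on synthetic data: with binomial read noise the variance of
M_s grows with the number of accumulated mutations, and under the
strongly heteroskedastic mouse-host design the nominal 95% interval
r̂ ± 1.96·SE covers the true rate in only ~81% of replicates. On designs
with near-constant sampling variance coverage is ~93%, consistent with
the nominal level minus the 1.96-versus-t(n−p) deficit at 15 points.
Interval users on heteroskedastic designs should treat the OLS standard
errors as optimistic.

`generation_time(t1, t2, X1, X2) = log 2 · (t2−t1)/(log X2 − log X1)`
converts two abundance measurements (e.g. CFU/mL) into a doubling time
in the units of t; declining abundance returns a negative value with a
warning.

## Filtering cascade

Stages run in a fixed order; the report telescopes counts exactly.

1. **Poisson LRT + BH.** Mutant read counts m_i across samples are
   Poisson with the total count t_i as offset. Null: one common rate
   (MLE Σm/Σt); alternative: one rate per sample — with one observation
   per sample this saturated model is exactly "sample as a fixed
   factor". Deviance 2·Σ m_i ln(m_i/(λ̂t_i)) (0·ln 0 = 0) on S_eff−1
   degrees of freedom, where S_eff counts samples with nonzero coverage;
   a single usable sample gives p = 1. p-values are floored at the
   smallest positive double. BH runs pooled over all candidates at
   q = 0.01 (per-treatment correction is available as an option).
2. **Ubiquity.** Removal iff frequency ≥ 0.05 in at least
   ceil(S_total/2) samples pooled over all treatments in the run — so
   with an even sample count, exactly half triggers removal. This
   targets mapping artifacts, which show a roughly constant frequency
   everywhere.
3. **Persistence.** Within a treatment, keep iff the unmasked frequency
   range exceeds 0.20, or the peak exceeds 0.10 while the mutation
   appears in at most floor(S_treat/2) samples. "Appears" defaults to
   any nonzero frequency (exposed as `presence_thr`). A mutation passing
   in any targeted treatment is kept.

Boundary conventions (≥ vs >, ceil vs floor) follow the wording "at
least half" / "less than or equal to half" and are fixed in code rather
than configurable. One consequence worth knowing: in a two-sample
treatment, a mutation fixed at 100% in both samples fails persistence
(zero range, present everywhere) — the filter deliberately discards
signals indistinguishable from reference errors.

## Lineage assignment and spectra

A mutation's trajectory is compared with each marker trajectory by the
total Manhattan distance Σ_s |a_s − b_s| over samples where both are
observed (masked samples are dropped pairwise, not imputed). The
mutation joins the nearest lineage if that distance is below the cutoff
(default 0.4); exact ties below the cutoff stay unassigned with a tie
flag. Two caveats are inherent to the method and visible in the
synthetic runs: mutations arising after their lineage was already at
substantial frequency carry a distance penalty equal to the summed
pre-arrival marker frequencies and end up unassigned; and with many
mid-frequency samples, read noise alone contributes ≈0.03–0.04 per
sample to the distance, so long sampling series push even perfect
trackers toward the cutoff.

Spectra fold SNVs into the six strand-symmetric classes (A:T→G:C,
A:T→C:G, A:T→T:A, C:G→T:A, C:G→A:T, C:G→G:C); indels are excluded and
tallied. Counts are unweighted (each mutation once).

## Muller reconstruction

Under asexual reproduction a new mutation arises inside an existing
genotype, so its frequency trajectory must fit within its parent's.
Mutations reaching ≥10% frequency (plus a user exclusion list) are
processed in order of first detected appearance (detection threshold
0.05 so stray error reads do not scramble the order; ties broken by
descending peak, then identifier). Each mutation is placed against the
existing forest:

* trajectory B is *contained* in A when B ≤ A + tol at every common
  sample, with tol = eps (default 0.02) plus, when a read depth is
  supplied, z = 5 binomial standard deviations of the difference of the
  two estimates at that depth;
* if the deepest containing genotype also fits inside B (mutual
  containment), the trajectories are statistically indistinguishable —
  the signature of mutations in one genetic background — and B joins
  that genotype, whose trajectory becomes the running mean of its
  members';
* otherwise B becomes a child of the deepest containing genotype, or a
  new root-level genotype if none contains it.

An optional rule forbids nesting two mutations of the same gene; it
presumes the population kept the low ancestral mutation rate and should
be disabled for hypermutator treatments, where multiple hits per gene
are routine.

Corrections then run top-down: each genotype is capped at its parent's
corrected frequency, and sibling groups whose per-sample total exceeds
the parent (1.0 at the root) are rescaled proportionally. This makes
child ≤ parent and the conservation identity (exclusive frequencies plus
ancestor remainder sum to exactly 1) hold exactly, and is idempotent.
All adjustments are reported; any at ≥0.10 raises a flag. On the
bundled mouse scenario at depth 150 the maximum adjustment is ~0.03.
The export produces the `ggmuller` tables: edges (Parent, Identity) and
populations (Generation, Identity, Population), where Population is the
exclusive frequency (a genotype's corrected frequency minus its
children's).

Design choices made where the design was genuinely open: placement is
greedy and deterministic, so unorderable trajectories become root-level
siblings rather than guesses; merging updates a genotype's mean
trajectory but already-placed children are not revisited; and across
concurrently segregating (disjoint) lineages the containment heuristic
cannot tell a late low-frequency mutation of one lineage from a
sub-clone of the other — reconstruction is only expected to be exact
within a lineage's nesting chain.

## Synthetic-experiment generator

Each treatment specifies sample times (generations), lineages (rate,
fraction schedule, optional marker allele, six-class spectrum weights),
a negative-binomial depth model (mean 150 by default, within the
study's reported 124–193 coverage range; dispersion 0 means constant
depth), a per-base sequencing error rate (0.001), and false positives
(count, mean frequency 0.04 — drawn per site from a Beta with
concentration 300 and held constant across all samples of the run,
exactly the signature the ubiquity filter removes). Mutations arrive
per inter-sample interval as Poisson(r_k·Δg) and thereafter track their
lineage's fraction; markers are emitted as ordinary rows whose true
frequency is the lineage fraction. Genome coordinates are synthetic
integers on one circular contig (3.3 Mb, 1.5 kb gene bins); no real
genome content is used.

Two exactness switches support the noise-free identities: deterministic
counts replace Poisson arrivals by their expectation, carrying the
fractional part as one partial-weight hitchhiker per interval so the
summed true frequency equals r_k·f_k,s·g_s exactly; and exact
observation encodes each true frequency as the reduced integer
read-count ratio, so observed frequencies equal true frequencies to
machine precision while counts stay integral. Together they make
generator → tables → rate fit an exact identity, which the
parameter-recovery checks exercise.

What the generator does not emulate — and hence what passing tests do
not show about real data: no read-level artifacts (mapping errors,
strand bias, indel realignment), no sub-lineage structure within a
mutator lineage (every hitchhiker sits exactly at the lineage fraction),
no linkage between false positives, and no reference-genome content.
The bundled mouse study preset uses a 15-point generation schedule
(30–286 generations across five mouse generations), two mutator
fraction schedules with clonal interference (one lineage peaking at 90%
before collapsing, the other sweeping to fixation), generating rates of
2.453, 0.310 and 0.0076 mutations per generation, and a 0.9-weight
A:T→G:C mutator spectrum; the fly preset uses four samples at 176–1760
generations with rates 0.00177 and 0.00150.

## Problem sizes and numerical conventions

The test suite's stochastic checks use 1000 constant-frequency sites for
type-I control, 500 replicates for interval coverage, and 300 for the
F-test null calibration; all run in seconds. Zero-coverage cells are
masked and contribute zero to sums (the treatment of such cells is a
convention, not data). Frequencies are never stored in files — only
integer counts, from which frequencies are always re-derived. All
randomness flows through one seeded NumPy generator per simulated
experiment; identical configurations reproduce byte-identical tables.
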