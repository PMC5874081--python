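# Methods

## The overlap model

All overlap statistics condition on a finite gene universe of size N. The
universe is the set of genes that *could* have appeared in either list; the
default of N = 27,416 is a stand-in at the scale of the TAIR10
protein-coding gene count, and is deliberately a configuration input rather
than a constant, because the choice of N is the single largest lever on any
hypergeometric overlap p-value. Users joining real lists should restrict
every list and track to an explicit, shared universe first
(`restrict_to_universe`), which is also what `overlap_test` does
internally.

Given sets A and B with |A| = n_a, |B| = n_b and |A ∩ B| = k, the
enrichment p-value is the hypergeometric upper tail P[X ≥ k] with X the
overlap of a fixed n_a-set with a uniformly random n_b-set. The sum is
evaluated on log-gamma terms combined with log-sum-exp; results are exact
to ~1e-12 relative error over small universes (verified against integer
arithmetic) and remain finite and positive down to ~1e-300. Two numerical
conventions: a queried overlap at the support minimum returns exactly 1.0
(the event is certain, and roundoff from the log-space path would
otherwise report 1 − 1e-16), and no p-value is ever reported as 0 — the
floor is the smallest positive normal double. The test is one-sided for
enrichment; a depletion (lower-tail) variant exists behind the `lower`
flag but is never a default, because the analyses this package supports
report enrichment or "not significant" only.

### Directional partition

When both lists carry per-gene directions, the k overlapping genes are
partitioned into concordant up/up, concordant down/down, and the two
discordant classes. Each class is tested with the same upper-tail statistic
using the per-direction sublist sizes as margins — e.g. the up/up class
count against (|A up|, |B up|, N). This conditions on the observed
direction composition of each list, which we consider the honest margin
choice: the class counts are then comparable across panels even when lists
are heavily skewed toward one direction. The class tests are not
independent of one another (the classes compete for the same genes); a
class count below its margin-forced minimum — possible precisely because of
that competition — is reported with p = 1. Removing direction information
never changes k or the overall p.

### Percent reporting

Overlaps are reported as percentages of either list at one decimal and at
nearest-integer precision; the nearest-integer form matches the convention
of prose statements like "1068 (26%) of the 4081 track genes".

## DEG lists and merging

Gene IDs are normalized to uppercase locus codes with any `.n`
transcript-model suffix stripped, since meta-analysis across labs is only
well-defined at locus level. The DEG filter keeps genes with padj strictly
below alpha (default 0.05) and assigns direction = sign(log2FC); a
filter survivor with log2FC exactly 0 has no direction and is an error
rather than a silent guess.

Cross-dataset compilation uses union-minus-conflicts semantics: a gene
present in any input list survives with its direction unless two lists
disagree on the direction, in which case it is excluded. Genes absent from
a dataset are treated as not measured, never as disagreement. An
intersection mode (`how="intersection"`) is available for the stricter
reading — genes present consistently in *all* datasets — but union is the
default: compiled lists are meant to pool evidence across labs, and
requiring presence everywhere would punish datasets with lower power.

## Monte-Carlo null calibration

The simulated null draws K independent pairs of gene lists from the
universe and records the hypergeometric upper-tail p of each pair's chance
overlap. Defaults: K = 100,000 pairs, with each list's size drawn
independently and uniformly from [500, 2000] (two independent sizes per
pair; the protocol we reimplement states only that sizes were comparable
to the analyzed lists). Valid p-values are super-uniform under this null —
mildly so here, because the overlap distribution is discrete — so the
empirical CDF at alpha sits at or just below alpha; the package's test
suite checks this at K = 10,000 as a scaled-down run, where the full
K = 100,000 would only shrink the Monte-Carlo error without changing the
conclusion.

An observed p-value is located in the null by its plug-in percentile
(#null ≤ p_obs)/K and by the add-one estimate (#+1)/(K+1), which is the
recommended empirical p because it can never be exactly zero. Observations
below the simulated minimum are flagged "outside simulated distribution".
Reproducibility: one PCG64 generator seeded from the run seed, consumed in
the documented order size_a, list_a, size_b, list_b per replicate; the
generator name is recorded in the serialized output. The CLI's `--threads`
option chunks K across SeedSequence-spawned child streams, so parallel
results are a pure function of (seed, threads).

## Enrichment and FDR

Enrichment of a query list against flat annotation tracks uses the
one-sided Fisher exact test, which for fixed margins is identically the
hypergeometric upper tail under the mapping a → k, a+b → n_a, a+c → n_b,
a+b+c+d → N (asserted exactly in tests). Multiple tracks are corrected
with Benjamini–Yekutieli, the FDR procedure valid under arbitrary
dependence — appropriate because annotation tracks overlap and the tests
are positively dependent. The step-up adjustment multiplies by the
harmonic factor c(m) = Σ 1/i, so BY-adjusted values dominate
Benjamini–Hochberg, which dominates the raw p-values. No GO-graph
handling: tracks are flat gene sets, and term propagation is out of scope.

## Phenotype interaction tests

`two_way_anova_interaction` fits the cell-means model by least squares and
computes the interaction sum of squares as SSE(additive) − SSE(full), i.e.
Type II model comparison, which reduces to the classical balanced
partition when cell counts are equal (tested both ways: against a
normal-equations oracle and against an independent Type II ANOVA
implementation on unbalanced data). F = (SS_int/df_int)/(SS_res/df_res)
with p from the F distribution. Degenerate designs fail loudly: an empty
cell is an error naming the cell, and zero residual degrees of freedom is
an error rather than an infinite F. The t-test is Student's pooled-variance
test by default — matching the naming convention of the reports this
mirrors — with Welch behind a flag; two groups with zero variance and equal
means return (t=0, p=1) by convention. `reaction_norm_summary` emits cell
means ± standard errors, with the SE of a single-observation cell reported
as missing rather than zero.

No multiple-testing correction is applied across phenotype panels; panel
p-values are raw by design.

## The synthetic-data generator

The generator exists so every stage is testable end-to-end with known
ground truth; its defaults are the package's reference study conditions.

- **Universe**: N = 27,416 synthetic AGI-style locus IDs.
- **Tracks**: sampled without replacement at configured sizes (defaults
  4,081 for the high gene-body H2A.Z track and 1,984 for the H3K9ac
  track). A track can force an exact intersection with an earlier track
  (e.g. 850 genes shared with the 4,081-track), giving exact pairwise
  dependence by construction; infeasible requests are errors.
- **DEG lists**: exact-size weighted sampling without replacement, where
  membership odds are multiplied by θ inside the target track. θ = 1 is
  the uniform null; θ = ∞ nests the list in the track. Sampling uses
  exponential race keys (keep the `size` smallest of Exp(w_i) draws),
  which is distributionally identical to sequential draw-and-remove but
  vectorizes. Exact sizes — rather than independent Bernoulli inclusion —
  were chosen because real DEG lists have fixed observed sizes and the
  overlap test conditions on them.
- **Directions**: a latent per-gene sign is drawn once per universe. The
  first generated list is the reference and carries the latent signs
  exactly; later lists copy the latent sign with probability ρ and flip
  it otherwise, so agreement with the reference on a shared gene is
  exactly ρ. (Making every list flip independently would give pairwise
  agreement ρ² + (1−ρ)², which is ≥ ½ for every ρ and cannot represent
  anti-concordant datasets; the reference-anchored model can, with ρ < ½
  planting discordant-dominant overlaps.)
- **Phenotypes**: balanced two-factor tables, mm scale, cell mean =
  grand mean + main effects + β_int in the corner cell, Gaussian noise.
  Defaults emulate a warm-temperature elongation experiment: baseline
  2 mm, +4 mm temperature effect, −3 mm interaction (the mutant's
  attenuated response), σ = 0.5 mm, n = 15 per cell.

What the generator does **not** emulate: expression-level or count-level
structure (DEG lists are drawn directly, so DE-calling noise, fold-change
correlation and mean-variance effects are absent), gene-property-matched
nulls (no matching on expression, GC or chromatin state — the calibration
null is unmatched random sampling by design), and correlated annotation
tracks beyond pairwise forced intersections. Passing tests therefore
demonstrate the statistical machinery is correct and calibrated under the
assumed sampling model, not that any particular biological overlap is
real.

## Problem sizes in the checked runs

The test suite runs the null calibration at K = 10,000 (of the 100,000
default), the planted-enrichment recovery at 100 replicates for the θ = 3
arm and 1,000 for the θ = 1 null arm (the null rate estimate needs the
smaller Monte-Carlo error: at 100 replicates its binomial SE of ~2.2
percentage points is comparable to the margin being checked), and the
ANOVA size study at 2,000 replicates with power at 200. These sizes keep
the whole suite under a minute while leaving every Monte-Carlo standard
error small relative to the band it is checked against.

## Known limitations

- Overlap p-values treat gene inclusions as exchangeable within the
  universe; biological clustering (co-regulation, tandem duplicates)
  makes real lists over-dispersed relative to this null — which is
  exactly why the Monte-Carlo calibration reports where an observed value
  falls rather than trusting the nominal tail alone, and why a matched
  null (out of scope) would be stricter still.
- The directional class tests share genes across classes and are not
  mutually independent; they should be read as per-class descriptions,
  not as four independent hypotheses.
- Type II sums of squares are the only ANOVA flavor offered; with heavily
  unbalanced data and a true interaction, Type II main-effect tests are
  conservative, but the interaction test itself is the same under Type II
  and Type III for the two-factor model.
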