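# Methods

## Event coding of promoter alignments

Input is a multiple alignment of orthologous promoter regions over
{A,C,G,T,N,−} with one designated reference species. Three binary
per-column channels are produced:

- **base_changes**: 1 where at least one non-reference record carries a
  non-gap, non-N base differing from the reference's non-gap, non-N base.
  Columns where the reference or the differing record has a gap or N score
  0 here; N is treated as missing data and never creates an event.
- **indels**: each maximal gap run in each record — including runs in the
  reference, which represent insertions in other species — registers one
  event at its 5′-most column. The channel is the binary OR over records,
  so coincident starts collapse to a single 1. A run touching column 0
  registers at column 0.
- **all_changes**: position-wise OR of the two.

Divergence is measured against the reference record (the
*D. melanogaster* role). Coordinates are 0-based, half-open. Each column
carries its reference (ungapped) coordinate; columns that are gaps in the
reference share the preceding reference position, and leading reference
gaps map to position 0 (no preceding base exists; the synthetic generator
keeps insertions interior so this corner never carries planted events).
TSS offsets are signed reference-coordinate distances from an explicitly
supplied TSS column, negative upstream, with the sign flipped for −-strand
genes (upstream = larger genome coordinates). How the TSS column is
located inside a cross-species alignment is left to the caller — it is an
input, not an inference.

When channels are placed on a TSS-offset grid, alignment columns sharing
an offset (insertions relative to the reference) are OR-collapsed.

## Sliding event scores and the d statistic

`Se[i]` is the sum of events over positions `[i−5, i+5]` (11-nt window;
half-width configurable). Edge windows are truncated sums rather than
dropped, so a profile over offsets [−1000, 1000) always yields the full
350 promoter-window values. The TATA-distal promoter window is the
half-open interval **[−380, −30)** — exactly 350 positions, with −30 the
approximate TATA location.

`Se^C` is the flat arithmetic mean of all control-group Se values across
genes and window positions. The divergence score of a cohort pools its
window positions across genes (350 per gene) and computes
`d = 100 · #{Se > Se^C} / N`; the comparison is strict, ties count as
not-above. A per-gene-then-average alternative exists in the literature
sense but the pooled form matches group-level quantification; callers can
compute per-gene d values directly from `d_statistic` if wanted.

Group-vs-control significance is a Pearson 1-df goodness-of-fit of the
(above, not-above) counts against expectations `N·d_C/100` and
`N·(1−d_C/100)`; p-values are Bonferroni-corrected with m defaulting to
the number of non-control groups in the contrast (exposed as a parameter).
A degenerate control rate of exactly 0% or 100% raises rather than
dividing by zero.

## The G-function cluster test

For `n` sorted event columns `x_1 < … < x_n` (0-based) in an alignment of
`L` columns, with 1-based sites `s_j = x_j + 1`:

    G_j = j/n − s_j/L,   ΔG_j = G_j − G_{j−1},   G_0 = 0.

Uniformly spread events give G ≡ 0; a cluster produces a run of positive
ΔG. The global statistic is the maximal increase of G over any event
interval, `max_{0 ≤ j < k ≤ n} (G_k − G_j)`, clamped at zero — a one-sided
scan statistic that dominates any single-gap ΔG and directly yields the
interval to report. G_0 = 0 at a virtual site 0 makes a leading cluster
detectable.

The null resamples `n` distinct sites uniformly without replacement from
the `L` columns (default B = 100,000 replicates, vectorised in chunks);
`p = (1 + #{null ≥ observed}) / (1 + B)` (add-one estimator, never zero).
For tiny problems the complete enumeration of all C(L, n) site subsets
replaces sampling and gives the exact permutation p.

**Stretches**: when the global test rejects at 0.05, the maximal-excess
interval `[x_j, x_{k−1}]` (reported half-open) is flagged; further
non-overlapping intervals are added greedily while their G-excess exceeds
the null 95th percentile. The greedy rule is a declared design choice —
the stretch-flagging convention in the figure tradition this follows is
not fully specified. Per-increment ΔG p-values are also computed against
the pooled null increment distribution (spacings of uniform order
statistics are exchangeable, so pooling across ranks is valid).

## McDonald–Kreitman machinery

Per gene, the 2×2 table [[Pn, Ps], [Dn, Ds]] is tested with a two-sided
Fisher exact test (direction reported separately via the odds ratio);
across genes, Benjamini–Hochberg step-up q-values implement the FDR
correction. `α = 1 − (Ds·Pn)/(Dn·Ps)` is undefined (NaN-flagged, never a
crash) when Dn = 0 or Ps = 0; pooled α sums counts first. The bootstrap
contrast draws k = 30 genes with replacement B = 100 times per group,
takes each draw's pooled α, and compares the two α samples with an
unpaired Student t test (Welch selectable). Draws with undefined α are
redrawn with bounded retries and counted. Both groups consume an
identically seeded stream, so a group compared against itself gives
identical draws and exactly t = 0, p = 1.

## Conservation profiles and d^P

Per-base conservation scores are read from bedGraph (half-open intervals)
or fixed-step wiggle (1-based starts per the wiggle convention). Each
gene's vector covers offsets −1000..+299 (1300 positions) relative to its
transcription strand; offset o maps to genome coordinate tss + o on +
strand and tss − o on −. Genes missing any position are omitted and
logged, never imputed. Group profiles are per-offset means. Promoter
conservation is compared by an unpaired t test on per-gene means over
[−380, −30), and by `d^P = 100 · #{p < p^C} / N` with `p^C` the control
group's flat promoter-window mean (strict comparison; ties not-below),
tested against the control group's own below-proportion with the same
1-df chi-squared construction as d.

## Synthetic data: what it emulates and what it does not

The generator provides inputs shaped like the real study data (5-species
promoter alignments, 1300-nt conservation vectors, polymorphism/divergence
count tables) with known ground truth.

**Alignments.** An ungapped reference of 2000 nt is drawn uniformly over
ACGT; each of the other species (default 5 total) derives from it
independently — a star phylogeny, not the true species topology, because
every downstream statistic uses only per-column difference from the
reference. Defaults: substitution probability 0.02/site/species, indel
rate 2 events/kb/species, geometric indel lengths with p = 0.5 (mean 2 nt,
minimum 1; the empirical indel length spectrum of real promoters is not
modelled — the geometric is a standard stand-in), insertions and deletions
equiprobable. An optional hotspot triple (start, end, multiplier) scales
the indel rate inside a reference-coordinate window; event positions are
drawn proportional to the resulting weights, so the expected in-hotspot
fraction is the analytic ratio of weighted masses. Placement re-draws
collisions: within a species, footprints keep a 1-base guard so its own
gap runs never merge; across species only the genuinely ambiguous
coincidences are excluded (two insertions at one point, or an insertion at
another species' deletion start) — everything else is allowed, keeping the
planted rate essentially unbiased while making ground-truth recovery by
the event caller exact. Insertions are realised as gap columns in all
other records (standard MSA semantics) and restricted to interior
positions so no alignment starts with a reference gap.

Not emulated: realistic base composition, rate heterogeneity along the
sequence, back-substitutions on a shared tree, alignment error. Passing
tests therefore demonstrate the statistics' correctness and power under
clean planted signal, not robustness to alignment artefacts.

**Conservation vectors.** Gaussian noise (sd 0.1) around a base mean
(1.0), minus a configurable drop on [−380, −30). Real PhyloP tracks are
heavy-tailed and autocorrelated; the Gaussian emulation is adequate for
mean/threshold statistics, which is all d^P and the t test use.

**MKT tables.** Ps ~ Poisson(mean_Ps), Pn ~ Poisson(r·mean_Ps),
Ds ~ Poisson(mean_Ds), Dn ~ Poisson(mean_Ds·r/(1−α)) with r the
neutral Pn/Ps ratio (default 0.3, means 20): inflating non-synonymous
divergence by 1/(1−α) is exactly the excess that pooled α recovers, so
the pooled estimate converges to the target as the cohort grows.

## Numerical and design choices

- Strict inequalities everywhere the statistics say "greater"/"less"
  (Se > Se^C, p < p^C); ties favour the null.
- The Monte Carlo scan statistic is clamped at 0; the clamping matters
  only for degenerate all-decreasing trajectories (e.g. n = 1 with an
  early site) and keeps the statistic one-sided.
- Fisher p for a table with an all-zero margin is 1 by convention.
- All randomness flows through numpy Generators; the pipeline fans a
  single global seed into independent per-stage streams via
  `SeedSequence.spawn`, so outputs are byte-reproducible and changing one
  stage's stream leaves the others untouched.
- Simulation sizes in the test suite and acceptance script (hundreds of
  alignments, B in the low thousands for calibration runs, cohorts of
  200–5000 genes) are chosen to give standard errors several times smaller
  than the effects being asserted; the full B = 100,000 default is used
  when a single gene is analysed, not in calibration sweeps.

## Known limitations

- The comparison mode is reference-anchored; a true any-pair mode would
  need per-pair channels and is not implemented beyond the reference
  semantics (every species pair containing the reference is covered).
- No analytic p-value approximation for the G test; Monte Carlo only.
- bigWig tracks are not read directly; convert to bedGraph/wiggle text.
- The per-population polymorphism sources and genome-wide gene lists that
  a real analysis would use are consumed as user-supplied tables; nothing
  here fetches them.
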