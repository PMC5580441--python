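# Methods

## Demographic model

Three demes — *chilensis* (C), *pallatangae* (P), *albiceps* (A) — under
the structured coalescent with the fixed topology ((C,P),A): backward in
time, P folds into C at `T_CP` and C into A at `T_A`, with `T_CP < T_A`
enforced on every prior draw. Deme sizes are constant; an ancestral deme
inherits the size of the deme that absorbs it (the C+P ancestor has size
`N_C`, the root `N_A`). Migration is symmetric per edge: a per-lineage
backward probability of migration per generation, constant while the edge
is active. After `T_CP` the C+P ancestor exchanges no migrants with A
under any model — the minimal reading of migration arrows drawn between
terminal taxa only. Model G deactivates both of model F's edges for the
most recent `T_iso` generations; `T_iso` defaults to 20,000, identifying
"the last 20 kyr" with generations at a one-year generation time, and is a
configuration knob rather than a free parameter.

Priors are independent uniforms: deme sizes 10–100,000 diploid
individuals, `T_CP` 10⁴–2×10⁶ and `T_A` 10⁶–7×10⁶ generations, migration
probabilities 10⁻⁸–10⁻⁴ per generation. Ordering constraints
(`T_CP < T_A`; `m_CP > m_CA` for models F and G) are enforced by redrawing
the violating subset. The asymmetry in F/G is implemented as a hard
ordering constraint; an independent-priors variant is available by
dropping the constraint from the model object. For mitochondrial analyses
the size prior's upper bound is quartered (25,000 — maternal, haploid
inheritance) while time and migration priors are unchanged; models F and G
are defined for the nuclear track only and requesting them with the
mitochondrial marker set is an error by design.

## Simulation

The engine is an event-driven continuous-time structured coalescent:
competing exponential clocks for within-deme coalescence (rate
`k(k−1)/2` divided by the deme size in gene copies) and per-lineage
migration, interrupted at epoch boundaries where rate matrices switch and
demes merge. Autosomal loci use `2N` gene copies per deme, the
mitochondrial locus `N` (its quartered effective size is carried by the
prior, not by extra scaling). Loci are independent (free recombination
between loci, none within). The hot loop is numba-jitted and seeded
explicitly, so identical seeds give bit-identical genealogies.

Mutations follow an infinite-sites model: the count is Poisson(total
branch length × μ × locus length), each mutation lands on a branch with
probability proportional to its length and claims a fresh uniformly drawn
column, exported as A (ancestral) / T (derived). Every default summary
statistic depends only on segregating-site patterns, for which infinite
sites is equivalent to a finite-site DNA model at these divergences while
being cheaper and free of multiple-hit bias. If a draw produces more
mutations than columns, the locus falls back to finite sites (multiple
hits toggle the state) with a warning; with the default rates this does
not occur.

Per-locus mutation rates are not recoverable from the source analysis;
defaults are order-of-magnitude avian conventions, 10⁻⁹ /site/generation
for nuclear loci and 10⁻⁸ for the mitochondrial gene, both exposed in
every request object and logged in reports. Simulated sample sizes mirror
the observed per-locus presence matrix (one sequence = one gene copy), so
missing sample–locus combinations propagate into the simulated vectors.

The simulated statistic path never builds sequences: derived-allele counts
per deme are read off the genealogy's subtree population counts, with
integer accumulation and a single final division so the result is
bit-identical to computing the statistics on the exported alignment — a
property the test suite asserts. An independent cross-check against
msprime (two-deme isolation-with-migration configuration, KS test on the
distribution of segregating sites at α = 0.01) guards the simulator's
correctness beyond closed-form expectations.

## Summary statistics

One definition shared by observed and simulated data, in a fixed
documented order: `S_p` and `π_p` per population, pooled `S`, `d_pq`
(mean between-population pairwise differences) and Hudson's
`F_ST = 1 − π_w/π_b` per pair. Sites carrying IUPAC ambiguity codes
(unphased heterozygotes) or missing symbols are excluded pairwise/sitewise
everywhere — ambiguity codes are real data for trimming purposes but never
enter statistics, which avoids phasing assumptions at the cost of
discarding heterozygous information. Multilocus aggregation is the
arithmetic mean across loci for `S`, `π` and `d`; the `F_ST` entries are
computed from the across-locus means (ratio of averages), which is robust
to monomorphic loci, and set to 0 when the between-mean is zero
(monomorphic data carry no differentiation signal; the scalar
`pairwise_fst` API instead raises a distinct undefined-statistic error).
The exact statistic list used by the original analysis is unpublished;
this set covers within-population variability and between-population
differentiation and is held fixed across observed and simulated vectors.

Small-sample caveat: with literal duplicate groups the net between-group
distance and Hudson's FST are negative (self-pairs enter the between-group
mean), so "no differentiation ⇒ ≈ 0" holds for independent samples from a
common pool, not for copied groups; the tests exercise both readings.

## ABC

Statistics are scaled by their median absolute deviation across the
reference table (normal-consistent; SD fallback when the MAD is zero;
constant statistics are dropped with a warning), distances are Euclidean,
and the closest `⌈tolerance·N⌉` rows are retained with ties broken by row
index. Retained rows get Epanechnikov weights `1 − (d/δ)²` with δ the
acceptance radius. Stage tolerances mirror the study design: 10% for the
five-model first stage, 5% for the three-model nuclear refinement, 1% for
parameter estimation.

Model choice pools the retained rows of all models and fits a weighted
multinomial logistic regression of model label on standardised statistics
(scikit-learn, L2 with C = 100 — mild regularisation that keeps perfectly
separable tables finite), evaluated at the observed vector. Bayes factors
are posterior ratios under the equal model priors. Validation follows the
published workflow: a leave-one-out confusion matrix and mean-posterior
(soft) matrix over held-out table rows, a goodness-of-fit test whose
statistic is the median normalised distance to the retained set with a
null built from table rows processed identically (each excluded from its
own retained set), and posterior predictive tail probabilities per
statistic.

Parameter estimation logit-transforms each draw to an open scale using its
uniform prior bounds before any regression adjustment, guaranteeing
adjusted draws respect the prior support. Methods: plain rejection;
local-linear adjustment (weighted least squares of transformed parameters
on normalised statistics; the default because it is deterministic given
the retained set); and a neural-net adjustment (single hidden layer of 5
units, weight decay 0.01, 10 restarts aggregated by median, seeded) —
present because the original estimation used it. Degenerate regressions
fall back to rejection with a warning. Summaries are the published rows:
minimum and maximum of the retained draws, Epanechnikov-weighted 2.5%,
median, mean and 97.5% (weighted quantiles by interpolation on the
cumulative weight), and a weighted mode from a Gaussian KDE with Silverman
bandwidth evaluated on a 512-point grid, all on the natural parameter
scale. Known limitation: for weakly identified parameters (migration
rates) the regression adjustment can saturate draws at the prior bounds
after back-transformation; intervals remain valid but modes at a bound
should be read as "uninformative direction".

## Synthetic data

The generator emulates the real dataset's structure: 46 individuals over
three focal taxa, seven autosomal loci totalling 3711 bp
(609/573/555/540/516/486/432 — the published total with plausible
per-locus lengths), one 1118 bp mitochondrial locus, and Bernoulli(0.674)
per-sample-per-locus presence with at least two sequences per focal taxon
per locus. Sequences are biallelic A/T from the simulator; optional IUPAC
injection at a stated rate exercises the I/O rules only, since statistics
exclude ambiguity codes by design. Every dataset is reproducible
bit-for-bit from its preset (seed + parameters). What this generator does
not imitate: real base composition, rate variation among sites or loci,
sequencing error, phase-aware heterozygosity, intralocus recombination,
or outgroup taxa — a green recovery test establishes that the inference
machinery is self-consistent under the model, not that the model fits any
real dataset.

Preset worlds, chosen once:

* `paper_like_preset` — model G with the published nuclear posterior
  medians as truth and the realistic (low) mutation rates; structurally
  faithful, weak per-locus signal.
* `easy_preset` — 3×1000 bp loci, 10 sequences per taxon, full coverage,
  μ = 10⁻⁸ (10× elevated, chosen so even draws at the deep end of the
  divergence prior stay inside a 1000 bp infinite-sites budget). Used for
  desk-scale recovery and confusion checks with reduced (5×10⁴-row)
  tables.
* `glacial_contrast_preset` — the stage-2 discrimination world. At the
  published medians the 20,000-generation isolation window is ~12% of a
  within-deme pair-coalescence time (2N ≈ 1.7×10⁵) and separating model G
  from continuous flow needs full-scale (10⁶-row) tables, as in the
  original analysis. This preset keeps the window's absolute length but
  sets N = 2×10⁴, `T_CP` = 2×10⁵, `T_A` = 2×10⁶ and `m_CP` = 10⁻⁴ (prior
  top), making the window ~25% of a pair-coalescence time — a world where
  the glacial-isolation contrast is detectable with 2×10⁴-row tables. Six
  1000 bp loci, 10 sequences per taxon.
* `mito_b_preset` — the mitochondrial track: model B at the published
  mitochondrial medians, single 1118 bp maternal locus, μ = 5×10⁻⁸.

## Numerical and design choices

* Trimming treats {N, -, ?} as missing and IUPAC codes as data; it is
  defined per alignment, applied per locus or to a concatenation
  (concatenation-trimming is only meaningful for samples sequenced at
  every locus, since a wholly missing locus is an interior block, not a
  terminal overhang). Internally coordinates are 0-based half-open.
* Boundary ties in rejection sampling resolve by row index (stable sort);
  all-zero weight sets (single retained row at distance δ) reset to unit
  weights.
* Cross-validation defaults to 100 pseudo-observations per model
  (unstated in the source; a compromise between Monte-Carlo error and
  runtime), goodness-of-fit to ≥100 null replicates.
* Mitochondrial priors: the source never prints them; quartering the size
  bound reproduces the published posterior ceiling of 2.5×10⁴ and is the
  standard autosomal-to-mitochondrial effective-size ratio.
* Reference tables at full scale are 10⁶ rows per model; all desk-scale
  defaults (10⁴–5×10⁴ rows) are explicit arguments, never hidden
  constants.
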