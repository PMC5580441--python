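# coalabc

Structured-coalescent simulation and approximate Bayesian computation (ABC)
for multilocus gene-flow inference among three closely related populations.

## The problem

Did two parapatric Andean bird taxa exchange genes continuously, or only
during glacial periods when montane forest shifted downslope and connected
adjacent ridges? Given a modest multilocus Sanger dataset — a handful of
autosomal loci plus one mitochondrial gene for three focal taxa
(*albiceps*, *chilensis*, *pallatangae*) — likelihoods are intractable but
simulation is cheap, which is exactly the regime ABC was built for:

1. encode competing demographic histories as structured-coalescent models,
2. simulate large reference tables of (parameters, summary statistics)
   from uniform priors,
3. retain the simulations closest to the observed statistics and estimate
   model posterior probabilities by multinomial logistic regression,
4. estimate the winning model's parameters from the retained draws with
   regression adjustment and Epanechnikov-weighted summaries.

All seven models share the topology ((*chilensis*, *pallatangae*),
*albiceps*) with constant deme sizes `N_C, N_P, N_A`, split times
`T_CP < T_A` and per-lineage backward migration probabilities `m`:
no flow (A); sister-pair flow only (B); *chilensis*–*albiceps* flow only
(C); both edges with one shared rate (D); all three pairs (E); both edges
with independent rates, `m_CP > m_CA` (F); and the isolation–migration
model G — model F's gene flow restricted to before 20,000 generations ago,
i.e. gene flow during the last glacial period and isolation through the
current interglacial.

Summary statistics (identical definitions for observed and simulated
data): per-population segregating sites `S_p` and mean pairwise
differences `π_p`, pooled `S`, between-population mean pairwise
differences `d_pq`, and Hudson's `F_ST = 1 − π_within/π_between` per pair,
averaged across loci. Heterozygous sites encoded as IUPAC degenerate bases
and missing data are excluded sitewise (pairwise deletion), matching the
raw p-distance convention used for the net between-taxon distance matrix.

## Worked example

Simulator checkpoints and the effect of migration
(`python examples/03_coalescent_simulation.py`):

```
panmictic check: mean S = 14.20 (expect 14.14), mean pi = 5.03 (expect 5.00)
model A: mean pairwise FST = 0.931
model E: mean pairwise FST = 0.029
```

The first line verifies the neutral-coalescent expectations
(`E[S] = θ Σ 1/i`, `E[π] = θ` at `θ = 5`, n = 10); the FST contrast shows
gene flow (model E, `m = 10⁻⁴`) homogenising demes that are strongly
differentiated without it.

Stage-2 model selection on synthetic nuclear data generated under the
glacial-window model G, plus parameter recovery (from
`python scripts/acceptance.py --seed 1 --out results/acceptance.json`):

```
stage set2: best model G
  P(model D | data) = 0.1823
  P(model F | data) = 0.1466
  P(model G | data) = 0.6711
model G posterior (weighted medians vs truth):
  N_chilensis    median    2.443e+04   truth        2e+04
  m_cp           median    8.269e-05   truth       0.0001
```

The isolation–migration model is correctly preferred over continuous-flow
alternatives, and the weighted posterior medians land near the generating
values for the identifiable parameters. `examples/` contains five short
narrative scripts, one per capability: alignment statistics and distances,
the model catalog and priors, coalescent simulation, ABC model choice with
confusion-matrix validation, and parameter estimation.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's full analysis from scratch at desk scale: it
generates a pseudo-observed nuclear dataset under model G and a
mitochondrial dataset under model B, builds reference tables from the
priors, runs two-stage model selection (models D/F/G at 5% tolerance;
models A–E at 10% for the mitochondrial track) and neural-net parameter
estimation at 1% tolerance, then writes the result manifest to `--out`.
All randomness derives from `--seed`.

## Layout

```
src/coalabc/
  sequence_data.py       alignments, popmaps, trimming, site counts
  popgen_stats.py        S, π, FST, p-distances, statistic vectors
  demographic_models.py  models A–G, priors, epoch-resolved migration
  coalescent_engine.py   structured-coalescent simulation + mutations
  _simcore.py            numba-jitted event loop
  abc_engine.py          rejection, model choice, estimation, validation
  synthetic_data.py      pseudo-observed datasets, presets, recovery suite
  pipeline.py            two-stage orchestration, published-table reports
docs/methods.md          model assumptions, numerical choices, limitations
```
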