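# Methods

This note records the models, conventions and numerical choices behind
`zfqsar`, and what its tests do and do not establish.

## Absorption statistic (k-value)

Internal concentrations are regressed on bath doses by ordinary least
squares **with an intercept**; the slope is the k-value, in units of
10⁻⁵ mM internal concentration per mM bath concentration. The intercept
is retained because refitting the packaged concentration table with an
intercept reproduces the published k-values (e.g. cefradine 9.809 vs
published 9.8110, within 0.02%), whereas an origin-forced regression does
not. `r_squared` is the squared Pearson correlation of fitted vs observed
values, and is defined as 0 when the response is constant.

Zero concentrations (below-quantitation readings, printed as 0.00) enter
the regression unchanged; the published slopes are consistent with that
treatment. Back-calculated concentrations below zero are reported with a
warning, not clipped, so calibration extrapolation stays visible.
Unit conversion: 1 ng/mL = (100/MW)·10⁻⁵ mM for molecular weight MW in
g/mol; an optional dilution factor (default 1.0) covers sample work-up
dilution not folded into the measured values.

Refitting the packaged table reproduces every unflagged published k-value
to better than 1% (most to < 0.1%; cefotaxime is the worst at 0.6%,
consistent with inputs printed to 2–3 significant figures). Two data
quality flags are carried in the fixtures rather than silently corrected:
cefpirome's printed k (0.1689) is inconsistent with the slope of its own
printed concentrations (≈ 0.85) and is flagged `discrepant`; cefalexin
and cefotaxime share a verbatim-identical printed calibration line and
both carry `duplicate_flag`.

## Curated structures

The 19 pH-7 ionic forms ship as an editable `name<TAB>SMILES` file. They
were curated by hand from the known parent structures: C-4 carboxylate
deprotonated, α-amino/amidinium/ammonium side chains protonated,
permanent pyridinium centres kept charged. Every entry was validated
against the registry's molecular formula after charge-adjusted
reprotonation (the neutral parent has H<sub>charged</sub> − q hydrogens
for net charge q); the test suite re-runs that check. Stereocentre
assignments follow the cephem core convention but are not
descriptor-relevant for the five descriptors computed here.

## Descriptors

Four descriptors are 2D graph counts, one is a 3D surface descriptor.
All conventions are fixed constants of this package:

| descriptor | convention | default-relevant constants |
|---|---|---|
| HBD_Count | donor **atoms** (N/O bearing ≥ 1 H), each counted once | RDKit donor definition |
| Num_AliphaticSingleBonds | heavy-atom single bonds not flagged aromatic; bonds to H excluded | RDKit default aromaticity |
| Num_AromaticBonds | bonds flagged aromatic | RDKit default aromaticity |
| QED_MW | molecular-weight desirability of the QED scheme: asymmetric double sigmoid of average MW, normalized to supremum 1 | published QED parameters as shipped with RDKit |
| Jurs_WPSA_1 | PPSA-1 × TMSA / 100 (Å⁴/100): PPSA-1 = summed solvent-accessible surface of atoms with positive Gasteiger charge, TMSA = total surface | probe 1.4 Å, 960 lattice points/atom, RDKit van der Waals radii, hydrogens explicit |

The solvent-accessible surface is computed by an in-package
Shrake–Rupley implementation (Fibonacci sphere lattice, 960 points per
atom). It is cross-checked in the tests against two independent routes: a
Monte-Carlo random-direction surface integration and the FreeSASA
library run with identical radii (agreement within 2–3%, the sampling
resolution). The /100 surface-weighting follows the descriptor's
documented definition in the source analysis rather than the /1000 of
the original CPSA literature.

3D conformers come from ETKDGv3 embedding (seeded, deterministic)
followed by MMFF94 minimization (UFF when MMFF parameters do not cover
the molecule; up to 5000 iterations). This is this package's own
conformer convention — a standard open-source replacement for the
CHARMM-based minimization used upstream, chosen for determinism and
availability, and *not* claimed to reproduce it.

**Known limitation — descriptor provenance.** The published coefficients
were trained on descriptor values from a proprietary engine whose exact
conventions (charge model, radii, surface algorithm, donor definition)
are not reproducible. The graph counts and QED_MW agree across engines
to at most small offsets, but WPSA-1 is scale-sensitive: the values this
package computes for the 19 cephalosporins (≈ 1300–3600) are several-fold
larger than the range the published coefficient (−0.03463 per unit)
implies. Predictions made from locally computed descriptors therefore
carry a systematic offset and a `DescriptorProvenanceWarning`; the frozen
equation is exact *given* descriptor values on its original scale, and
relative comparisons between similar compounds remain meaningful.

Descriptor pruning drops columns with non-finite entries, variance below
1e-8, or a modal value covering more than 90% of rows; it never touches
rows and is idempotent.

## Model statistics

For an OLS fit with m descriptors on M samples (SSE = residual sum of
squares, SST = total sum of squares):

* r² = 1 − SSE/SST; r²_adj = 1 − (1 − r²)(M − 1)/(M − m − 1);
* **RMSE = √(SSE/M)** (the M-denominator). This convention is the one
  under which the reported lack-of-fit is reconstructible from the
  reported RMSE: SSE = 15·1.065² with c = 6, p = 5, d = 0.5 gives
  LOF ≈ 6.04, within 3% of the reported 5.888;
* PRESS = Σ(eᵢ/(1 − hᵢᵢ))² via the hat-matrix identity (QR-based
  leverages), equal to the explicit leave-one-out refit loop to numerical
  precision; q² = 1 − PRESS/SST. A leverage of 1 raises an error naming
  the offending sample;
* Friedman LOF = (SSE/M)/(1 − (c + d·p)/M)², with **c counting the
  intercept as a basis function** (c = m + 1), p = m features, and
  smoothing parameter d defaulting to 0.5. Counting the intercept and
  d = 0.5 are the round conventions nearest to back-solving the reported
  LOF (d ≈ 0.48 at c = 6); the exact upstream constants are not
  derivable, and the ≈ 2.6% residual gap is noted, not reconciled;
* overall-regression p from the F(m, M − m − 1) upper tail; coefficient
  p-values from two-sided t tests at M − m − 1 degrees of freedom;
* external validation uses the Q²-F1 convention (training-set mean in
  the denominator) and RMSE-EV = √(Σ(y − ŷ)²/n_test); the convention is
  named in the output because no single external-q² convention is
  universal.

The reported model block (r² = 0.928, q² = 0.839, RMSE-EV = 3.555, …)
depends on the unprinted upstream descriptor values and is therefore not
recomputable at the number level; the machinery is instead validated by
exact identities (PRESS dual route, q² ≤ r², LOF reconstruction above).

## Genetic Function Approximation

The search evolves a population of descriptor subsets scored by LOF.
Reported settings are the defaults: population 100, up to 5000
generations, subset sizes 2–6, pairwise |r| ≥ 0.95 prefiltered out
(greedy, keeping the higher-variance member; deterministic order with
name tie-break). The GA kernels are this package's own design, chosen
for simplicity and exposed in `GFAConfig`:

* elitism: the best subset survives unchanged (count 1);
* reproduction: each non-elite slot breeds its own member (in rank
  order) with a partner drawn by rank-based selection (weight N for the
  best down to 1 for the worst); with crossover and mutation rates at 0
  the population therefore reproduces itself exactly, a useful no-op
  invariant;
* crossover (rate 0.9): single point on each parent's sorted term list,
  child = head of one + tail of the other, deduplicated;
* mutation (rate 0.1): add, remove or replace one term, drawn from the
  full prefiltered pool (so terms absent from the population can
  re-enter); offspring are clamped to the allowed size range;
* singular or over-parameterized subsets receive infinite LOF rather
  than raising, for robustness inside the GA;
* early stopping: the run ends when the best LOF has not improved for
  200 generations (patience 0 disables it). On every test problem tried
  this reproduces the fixed-5000-generation best model at a fraction of
  the cost.

Fitness caching makes the whole run deterministic for a fixed seed, and
the returned evaluation log lets callers verify the best model optimizes
everything evaluated.

**Benchmark design for support identification.** The synthetic benchmark
(n = 30 samples, 40 i.i.d. standard-normal descriptors, response
2·x03 − 1·x17 + 0.5·x21 + ε with σ = 0.1) is nearly noiseless, and at
d = 0.5 the LOF penalty is then too weak to reject chance-correlated
supersets of the true support: the LOF *optimum* itself is a superset in
most realizations, so no optimizer can recover the exact support under
that scoring. Exact-support identification on this benchmark is
therefore run at the identification-strength setting d = 3, at which the
search recovers the exact support in ≥ 19 of 20 seeded runs; the
package-wide default stays d = 0.5 (the reported-LOF-compatible value).
Search *correctness* is established separately at the default d: on
12-descriptor pools the GA's best LOF equals the exhaustively enumerated
global optimum in 20 of 20 seeded runs.

The 80% training split rounds to the nearest integer (19 compounds →
15 training) and samples without replacement under a seed. The
externally reported four-compound test split is available as a named
fixture constant, with the alternative reading of its ambiguous
numbering preserved alongside.

## Synthetic data

The QSAR generator draws unit-variance multivariate-normal descriptor
columns with optional equicorrelated blocks (covariance validated by
Cholesky; invalid blocks are rejected) and a sparse linear response with
homoscedastic Gaussian noise — homoscedastic because the uptake analysis
itself treats the dose-response regression as ordinary least squares.
The uptake generator emulates the study design: three doses (0.28, 1.0,
2.0 mM), linear truth, Gaussian noise, concentrations truncated at zero
exactly as below-quantitation readings appear in the real table.

What the generators do **not** emulate: chorion-barrier kinetics,
dose-dependent (heteroscedastic) measurement error, inter-replicate
biological variability structure, or realistic descriptor marginals
(real descriptor matrices mix counts, bounded scores and heavy-tailed
surface areas). Passing recovery tests therefore demonstrates the
estimators and the search are correct under the assumed model, not that
the model captures every property of laboratory data.

## Problem sizes and runtimes

The test suite and the acceptance script were sized for a desk machine:
50 random datasets for the PRESS identity, 20 seeded runs for each GFA
benchmark, 500 replicates for uptake recovery, and a fixtures pipeline
run with a reduced GA (population 50, patience 50, subsets ≤ 4 — the
packaged study offers only five descriptors, below the default maximum
subset size of 6). The full suite runs in under two minutes; the
acceptance script in about one.
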