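# Methods

## The speciation chain and its assumptions

The package partitions the "environmentally available" iron of an anoxic
solid (the HNO₃-digest pool; structural silicate Fe is only partially
included) into four pools — amorphous and crystalline Fe(III), amorphous
and crystalline Fe(II) — by differencing operationally defined extractions.
The chain is exact arithmetic, so its validity rests entirely on the
selectivity assumptions of the extractions:

* **DCB** reductively dissolves all Fe (oxyhydr)oxides of either valence
  (ferrihydrite, lepidocrocite, goethite, akaganeite, hematite, green rust)
  but spares siderite, pyrite and vivianite. Subtracting ferrozine-available
  Fe(II) from the DCB pool therefore isolates Fe(III).
* **AOD** (ammonium oxalate, dark, pH ≈ 3) dissolves the amorphous/poorly
  crystalline oxides plus akaganeite, magnetite, siderite, amorphous FeS and
  green rust. The ferrous interferences (siderite, FeS, ferrozine-available
  Fe(II)) are subtracted to estimate amorphous Fe(III).
* **Ferrozine** (HEPES-buffered, no HCl) sees only readily available
  Fe(II): the sorbed/exchangeable pool and ferrous oxyhydroxides such as
  green rust — not magnetite, monosulfide, siderite or vivianite.
* Mineral-bound Fe(II) is inferred from partner elements: AVS sulfur →
  monosulfide Fe, Cr-reducible minus AVS sulfur → pyrite Fe, total minus
  Ca/Mg carbonate → siderite Fe, NaOH-extractable P → vivianite Fe.

Total Fe(II) is obtained by difference (`fe_total − fe3`), so it inherits
whatever the digest collects — including the digested share of structural
phyllosilicate Fe, which consequently inflates the *amorphous* Fe(II)
estimate (the crystalline Fe(II) sum is built only from the three accessory
minerals). The forward model quantifies this bias; see below.

### Conversion ratios

The conversion constants 1.7 (Fe:S in FeS), 1.1 (S₂:Fe in FeS₂), 1.07
(CO₃:Fe in FeCO₃) and 2.7 (Fe:P in vivianite) are the element **mass**
ratios of the named minerals rounded to 2–3 significant figures; the exact
values recomputed from the registry formulas are 1.742, 1.148, 1.075 and
2.704, all within 5% of the rounded forms. (They are not mole ratios: the
vivianite Fe:P mole ratio is 1.5.) `RatioSet(mode="paper")` — the default —
uses the rounded conventional constants so that published worked examples
reproduce digit for digit; `mode="exact"` uses the formula values and is
what the recovery analyses use, because the forward model emits partner
elements in exact stoichiometry and only the exact ratios invert it to
numerical precision.

### Clamping and mass balance

Differencing noisy measurements can produce negative pool estimates, which
are unphysical. Every subtraction is clamped at zero; the raw value is kept
in `FeSpeciation.raw` and a warning is recorded. Three clamps can inflate
the four-pool sum above `fe_total` (amorphous Fe(III) exceeding total
Fe(III); Fe(III) exceeding total Fe; crystalline Fe(II) exceeding total
Fe(II)); their magnitudes accumulate into `clamp_residual`, giving the exact
identity `Σ pools = fe_total + clamp_residual` for any non-negative input.
The clamps on Fe(III) and on amorphous Fe(III) against zero redistribute
mass between pools without breaking the sum and are logged only. A `strict`
mode turns any clamp into an error for pipelines that prefer rejection to
repair. On the shipped reference samples the chain genuinely clamps twice
(U2 and U3 amorphous Fe(III); U3 amorphous Fe(II), residual 0.0176 wt%), so
zero-clamping with an auditable residual is not a corner case but the
behaviour the published data require.

### Basis handling

Sulfide and phosphorus measurements are often made on the whole suspension
rather than the separated solid; `SampleMetadata.solids_fraction` divides
those fields (`s_avs`, `s_crr`, `p_febound`) by the solids fraction before
use. The default of 1.0 applies no conversion, which reproduces the
reference tables' apparent direct mixing of bases; the parameter exists so
users with known solids contents (~0.3 for mature fine tailings) can do
better.

### Precedence of derived columns

When a table carries both raw partner-element measurements and pre-derived
mineral-Fe columns, the derived columns win and any discrepancy is logged.
Rationale: published tables often print only the derived per-sample values
(the raw replicate-level sulfide data behind them are not recoverable), so
derived-first is the only order that reproduces them.

## Uncertainty propagation

Replicate statistics are reported as mean ± 1 sd over n = 2–4 replicates,
with no covariances. `propagate` draws each measured quantity independently
from a normal(mean, sd) truncated at zero (exact vectorised rejection
sampling on a seeded `numpy.random.Generator`), runs the full clamped chain
per draw, and summarises each pool (mean, sd, central percentile interval,
default 95%) plus the fraction of draws in which any clamp fired. Identical
(inputs, seed, n_draws) give bitwise-identical summaries. Truncation at zero
asserts that concentrations are non-negative; for the reference data the
means sit ≥ 5 sd above zero, so the truncation itself is negligible and any
MC/analytic discrepancy is attributable to chain clamps.

Because the chain is affine wherever no clamp fires, closed-form linear
propagation (`linear_propagation`, partials by finite differences — exact
for an affine map) is an independent oracle: on clamp-free inputs the MC
pool sds agree with it within Monte-Carlo error. On inputs that clamp
(e.g. reference sample U2, clamp rate ≈ 0.78) the MC sds are *smaller*
than the linear values for the clamped pools — the clamp truncates the low
tail — which is the honest dispersion of the estimator actually used.

## The forward model

`predict_measurements` is a linear operator: each measurable channel is the
selectivity-weighted sum of the assemblage's per-mineral Fe contents, with
S/P/CO₃ channels converted through exact stoichiometry and the ferrozine
channel weighted by each phase's ferrous fraction (green rust Fe₃(OH)₈ =
Fe(II)₂Fe(III), so 2/3; magnetite 1/3). Measurement noise is multiplicative
Gaussian with configurable CV, applied independently per replicate and
clipped at zero.

Three dissolution coefficients are qualitative in the underlying
literature ("partly", "some") and are modelling placeholders here: DCB on
amorphous FeS (default 0.3), AOD on goethite/hematite (0.05), acid digest
on phyllosilicate Fe (0.5). They are visible in the matrix, freely
overridable, and `SelectivityMatrix.interference_free()` zeroes all three.
Under the interference-free matrix, exact ratios and zero noise, the chain
inverts the forward model to ≤ 1e-9 for assemblages of single-valence
accessory minerals plus sorbed Fe(II) — the scheme is unbiased exactly when
its selectivity assumptions hold. Each interference then produces a
signed, quantified bias: DCB attack on FeS inflates Fe(III) by
coefficient × FeS-Fe; a ferrozine channel blind to green rust inflates
amorphous Fe(III) by the unseen ferrous mass; digested phyllosilicate Fe
lands in amorphous Fe(II).

## Synthetic scenarios

Three preset assemblages represent the study conditions the package was
built around: `initial` (oxidised baseline: ferrihydrite + goethite,
pyrite, traces of FeS and vivianite), `unamended` (incubated control:
goethite-rich, substantial siderite/pyrite, little amorphous Fe(II)) and
`amended` (methanogenic endpoint: ferric oxides drawn down, green rust +
large sorbed Fe(II) pool + more FeS — amorphous Fe(II) dominant). Each was
tuned once so that its zero-noise predictions fall within two printed
standard deviations of the corresponding published table row; the presets
are documented fixtures, not fitted quantities, and they deliberately
differ in phyllosilicate Fe because they match independently measured
samples, not a mass-conserving time course. Default noise CV is 0.05
(matching the 2–15% relative sds of the reference tables) with 3 replicates
per measurement.

What the generator does **not** emulate: correlated measurement errors
(each channel's noise is independent), extraction kinetics, within-scenario
compositional variability (all samples of a scenario share one true
assemblage; only noise varies), and measurement sets that are *internally
inconsistent* the way the real unamended samples are (a linear forward
model cannot drive the amorphous-Fe(III) subtraction negative at zero
noise). Passing recovery tests therefore demonstrate correctness of the
inversion under the stated selectivity model — not that any field sample
obeys that model.

Problem sizes used by the test suite and the acceptance script — 10⁵
Monte-Carlo draws, 200-sample recovery runs, 50-sample contrast runs, 1000
random conservation inputs — were chosen to make Monte-Carlo error small
against the tolerances they are checked with; the whole suite runs in
seconds.

## Community module

The OTU filter retains an OTU iff its per-sample relative abundance reaches
the threshold (default 1%, `>=`) in at least one sample, applied at the OTU
level (not after taxonomic collapsing). `retained_abundance` reports
survivor abundances against the *original* totals, so columns sum to
< 100% whenever anything was dropped — the convention used when such
filters are reported. The filter is idempotent; everything upstream of the
count table (QC, chimera removal, clustering, taxonomy) is out of scope.

## Known limitations

* The Fe(II)/Fe(III) split of "phyllosilicate_fe" is a 50:50 placeholder;
  structural clay Fe redox is sample-specific.
* Green rust composition varies widely in nature; the registry fixes the
  Fe₃(OH)₈ end-member. The chain itself never quantifies green rust — it
  can only appear as unattributed amorphous mass.
* The published 10–14% range for the FeS share of amorphous Fe(II) in
  amended tailings is not reproduced by the mean-based chain (8.0–8.8%);
  the discrepancy is consistent with replicate-level computation on data
  that were not printed, and the package asserts only the upper bound.
* No thermodynamic speciation: the chain and forward model are mass
  balance, not equilibrium chemistry.
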