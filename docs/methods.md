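# Methods

## Serial-transfer evolution model

The simulator approximates a serial-dilution evolution experiment as a
Wright–Fisher process punctuated by transfers. Within one passage the
culture expands from a bottleneck of `N` cells by a fixed fold
(`target_fold_expansion`, default 16, matching growth from OD600 ≈ 0.03 to
the mid-exponential transfer point ≈ 0.48), contributing
`g = log2(fold) = 4` generations. Growth is deterministic: a genotype with
relative fitness `w` contributes expected offspring proportional to `w^g`,
where `w = 1 + Σ s_i` over its mutated units' selection coefficients active
under the current carbon source. Stochasticity enters in exactly two places:

* **Mutation supply.** Arrivals per strain per passage are Poisson with
  mean `μ_eff · N · g`, `μ_eff = μ_basal · mutator_multiplier`. Each
  arrival converts one cell (sampled proportionally to grown genotype
  abundance) and hits one unit drawn uniformly from the catalog. Genotypes
  are sets of mutated units (infinite alleles at unit granularity); a
  repeat hit on an already-mutated unit of that genotype is ignored. A
  mutant enters as one cell of the grown census and its parent genotype is
  debited one cell, so supply never dilutes standing variation.
* **Bottleneck.** At transfer, exactly `N` cells are drawn multinomially
  from the grown population. The post-transfer census therefore equals `N`
  on every passage, and under neutrality allele frequencies form an exact
  martingale — a property the test suite checks directly.

All mutations within a passage are treated as arising at the end of the
passage (initial frequency `1/(N·fold)`); the distinction from mid-passage
arising times is absorbed into the effective supply and does not affect the
scale-free properties tested.

Checkpoint readout emulates population sequencing: at every
`checkpoint_interval` generations (default 100, out to 800), units whose
population frequency reaches `detection_floor` (default 0.10, the
conventional minimum variant frequency of short-read population variant
calling) are emitted as mutation records with a stable representative
position/allele; each SNV's ref→alt pair is drawn with configurable
transition:transversion odds (default 3:1, a mismatch-repair-deficient-like
spectrum) and a configurable indel fraction (default 0.1). The floor-free
frequency truth and every emitted unit's planted class are returned for
oracle-based testing.

### Default parameters

| parameter | default | rationale |
|---|---|---|
| `bottleneck_size` | 10⁴ cells | tractable stand-in for the ~10⁷–10⁸ cells of a real transfer; the properties asserted downstream (martingale, supply linearity) are scale-free |
| `target_fold_expansion` | 16 | OD 0.03 → 0.48 per passage, 4 generations |
| `total_generations` / `checkpoint_interval` | 800 / 100 | the emulated study design |
| `μ_basal` | 10⁻³ /genome/generation | order of the *E. coli* genomic mutation rate |
| `mutator_multiplier` | 50 | moderate end of the 50–800-fold range reported for ΔmutS |
| `detection_floor` | 0.10 | population-sequencing variant-caller floor |
| unit catalog | 6 generalist + 3 lactate- + 2 glycerol-specialist + 200 neutral units | mirrors the loci recurrently reported in carbon-limited *E. coli* evolution (rpoB/hfq/rph/ptsP/crp, pyrE–rph; ppsA/cyaA/ydcI; glpK/rpoC) |
| `s_generalist`, `s_specialist` | 0.08, 0.06 | per-carbon benefits; no effect-size distribution is published for this design, so these are user parameters, not estimates |

## Fitness kinetics

Per-passage generations, the accumulated-generation clock, and doubling
times follow the identities in the README. Decisions worth recording:

* "Time per passage" is wall-clock hours from inoculation to transfer,
  including any lag — no lag correction is attempted.
* The first passage is excluded from reported doubling times (stationary
  physiology carry-over) but still advances the generation clock.
* A later passage with zero/negative net growth is omitted from the
  trajectory and flagged rather than failing the lineage.
* OD600 is treated as proportional to cell density; no calibration curve.

The growth-rate estimator blank-subtracts, drops points with signal below
0.005 OD (plate-reader resolution), log-transforms, and fits every window
of `window_points` consecutive usable points, keeping the steepest slope
among windows with R² ≥ `min_r2`. Defaults (8 points ≈ 70 min, R² ≥ 0.98)
recover noiseless logistic rates in 0.1–0.8 /h within 2%; under 1–2%
multiplicative read noise, wider windows (20–24 points) with a
correspondingly relaxed gate (0.98/0.95) hold 10% accuracy **on
blank-corrected curves**. With an uncorrected medium-turbidity offset
(~0.05 OD) the same multiplicative noise is amplified roughly tenfold on
the log-signal scale while the signal is small, and no window length
rescues slow growers — this is a property of the measurement, not of the
estimator, and is why the plate analysis is run blank-aware.

## Competition quantification

Primer convention is fixed and documented: set A amplifies the
wild-type-specific target (inside the mutS locus), set B the
mutator-specific deletion-scar target; the ΔCq ratio `2^(Cq_A − Cq_B)` is
then mutator:wild-type. Perfect doubling (efficiency 1) is the default,
matching the base-2 convention; efficiency-corrected ratios
(`(1+E)^ΔCq`) are available. No amplification is an explicit sentinel
(`None` / `"NA"`), never a number; a one-sided detection is reported as an
outcome (fraction 0 or 1 in traces; exclusion with a warning in
calibration). Calibration regresses empirical on theoretical ratio —
R² of a simple OLS is direction-invariant, so the orientation choice does
not affect the reported fit quality. Within `calibrate` the duplicate
measurements are combined as per-replicate ratios averaged per mixing
point; the trace path instead averages duplicate Cq on the cycle scale
first. The two conventions coincide exactly in the noiseless case and are
both documented because the underlying protocol fixes neither.

## Mutation atlas

Classification is a total, mutually exclusive decision table over presence
patterns (see README). Two reconciliations are deliberate:

* Recurrence breadth (generalist/specific) is evaluated on replicate-merged
  strain × carbon groups, while the *random* category uses raw lineage
  uniqueness — merged reporting and eight-lineage uniqueness are otherwise
  in tension.
* A unit recurrent in both replicates of a single strain × carbon group has
  carbon-dependent selection evidence but unresolved strain breadth; it is
  assigned its carbon's specific category and flagged
  `single_strain_recurrence`.

Presence is assessed at the end-point checkpoint by default (any checkpoint
selectable). Intergenic units are named `upstream/downstream` by flanking
loci and participate in classification but not COG analysis. The mutation
count summary reports all three defensible definitions (distinct positions,
unit-level events, checkpoint observations), since "number of mutations" is
ambiguous between them. Repeat-region exclusion is honored via an optional
BED mask; no built-in repeat detection. COG over-representation uses the
one-sided hypergeometric tail with Benjamini–Hochberg q-values across
categories alongside raw p.

## Phenotype microarray

The negative-control well's apparent growth rate is the growth threshold;
growth requires strictly exceeding it (a rate equal to the control is
no-growth). The published wording for this rule is phrased on the
doubling-time scale, which taken literally would call fast growers
"no growth"; it is implemented on the specific-growth-rate scale, the
interpretation consistent with a nutrient-free control showing minimal
growth. Tier boundaries are half-open ([0.5, 1.0), [1.0, ∞)) so every
fold-change maps to exactly one tier. The t-test is two-sample,
equal-variance, two-sided on technical replicates — with the default n = 2
per strain it has 2 degrees of freedom and is exactly as fragile as that
design implies. Chi-squared contrasts default to no continuity correction
(Yates by flag) and are emitted in both per-carbon (denominator 95) and
pooled (denominator 190) constructions, because the published bounds do not
state which construction was used.

## What the simulator does and does not emulate

Emulated: bottleneck drift, carbon-dependent selection on designated gene
classes, mutator supply scaling, the detection floor, ideal-doubling qPCR
with optional Gaussian cycle noise, logistic well kinetics with
multiplicative lognormal read noise and a flat negative control.

Not emulated: clonal interference at sequence resolution (units are the
granularity), mutation-rate evolution, lag/diauxie/stationary-phase
kinetics, qPCR efficiency drift or melt-curve artifacts, plate edge
effects, and any real substrate identity (wells carry generic synthetic
labels; the commercial plate layout is not reproduced). Passing tests
therefore demonstrate correctness of the analysis chain under the stated
model, not robustness to every artifact of real plate or sequencing data.

## Test-scale choices

Monte-Carlo checks run at `N = 10⁴` with shortened horizons (100–400
generations), sizes at which the asserted properties are scale-free. Two
regimes are chosen deliberately rather than at the analysis defaults:

* **Supply linearity** is asserted at detection floor 0.001 with
  `μ_basal = 2×10⁻⁴` and a 5×10⁴-unit neutral catalog: neutral drift cannot
  reach a 10% floor at any realistic census, and supply must remain small
  relative to the catalog, else independent origins of the same unit sum
  across the floor and detection becomes superlinear in μ (observed +5% at
  μ = 10⁻³). The chosen regime realizes the infinite-alleles assumption the
  linearity expectation relies on.
* **Planted-effect recovery** on plates uses fold 2.2 on ancestor rates
  drawn in 0.2–0.35 /h. A planted fold of exactly 2.0 places the true
  log2 fold-change on the closed tier boundary (gain-high ⇔ log2fc ≥ 1.0),
  where recovery under measurement noise is a coin flip for any
  implementation; 2.2 plants an unambiguous high-tier effect.

## Known limitations

* The serial-transfer approximation ignores within-passage drift; variance
  accumulates only at transfers.
* Selection coefficients combine additively in `w`; epistasis is not
  modeled.
* The growth-rate estimator reports the steepest qualifying window, which
  under noise carries a small positive selection bias (a few percent at the
  tested noise levels); it is shared between compared strains and largely
  cancels in fold-changes.
* VCF ingestion is minimal (CHROM/POS/REF/ALT + INFO/AF, first ALT only).
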