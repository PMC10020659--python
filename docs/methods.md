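# Methods

## The evaluation problem

A strip-intercropping trial compares five local intercrops of *Aconitum
carmichaeli* against monoculture controls in two regions with different
cropping histories (Jiangyou: first-year soil; Chenggu: continuous-cropping
soil). Treatments must be ranked on two composite axes: herb growth and
quality (biomass of the two medicinal root products, polysaccharide,
monoester and diester diterpenoid alkaloids, disease index) and soil
quality (pH, nutrients, nitrogen-cycling gene abundances, enzyme
activities). TOPSIS turns each treatment × indicator matrix into a single
comprehensive benefit index per treatment.

## TOPSIS pipeline

Stages, in order: interval transform → normalization → weighting → ideal
solutions → Euclidean distances → closeness → rank.

- **Interval criteria.** Soil pH is the one interval indicator: the optimum
  range for this crop is 7–8. With M = max(lo − min(x), max(x) − hi), a
  value below the range maps to 1 − (lo − x)/M, above to 1 − (x − hi)/M,
  inside to 1. When all observations are below the lower bound this is
  exactly x̂ = (x − min)/(lo − min); the symmetric above-range branch is our
  generalization (a pH above 8 is also suboptimal), chosen so the transform
  is total while reducing to the classical form on the data regime the
  trial actually saw. If every value is inside the range, all outputs are 1
  and no division occurs.
- **Normalization.** The field study did not state its scheme, so the
  default is vector normalization r_ij = x_ij/‖x_j‖ — the canonical TOPSIS
  choice, and scale-invariant, so indicator units cannot steer the ranking.
  Cost indicators keep their direction and are resolved at the
  ideal-solution step (column min is the positive ideal). Min-max
  normalization is available as an option; it folds cost columns into
  benefit ones and rejects constant columns by name.
- **Weights.** Normalized to sum to 1, then applied by multiplying each
  normalized column (weight-after-normalize order). The original study
  assigned expert weights that were never published, so the default is
  equal weights, with user-supplied configs and entropy weighting as
  alternatives. Entropy weights use e_j = −(1/ln n) Σ p ln p on
  direction-aware min-max scaled columns; a constant column is treated as
  maximally even (e_j = 1 ⇒ weight 0) rather than an error, so an
  uninformative indicator silently drops out; only an all-constant matrix
  errors.
- **Closeness and rank.** Cᵢ = Dᵢ⁻/(Dᵢ⁺ + Dᵢ⁻); undefined (error) only
  when both distances vanish, which requires identical alternatives. Rank
  1 is the largest Cᵢ; ties keep stable input order, so the ranking is
  deterministic. Reports round D and C to 3 decimals, mirroring the
  published tables; a full-precision companion file is always written.

The published per-treatment (D⁺, D⁻, Cᵢ, rank) tables are bundled as the
worked example. Because the underlying 6- and 17-indicator raw values and
the assigned weights were never released, the end-to-end matrices cannot be
replayed; the D → C → rank stages are validated on the published rows, and
the full pipeline is certified against an independent brute-force
implementation on randomized matrices plus structural properties
(scale invariance, permutation invariance, monotonicity, C ∈ [0, 1]).

## Trial statistics

Derived traits follow the trial's definitions: total underground biomass =
Chuanwu + Fuzi weight; total biomass adds aboveground; root/shoot ratio;
total monoester (benzoylhypaconitine + benzoylaconitine +
benzoylmesaconitine) and diester (hypaconitine + aconitine + mesaconitine)
alkaloids and their sum. C/N uses organic carbon; when only organic matter
is measured it is converted with the van Bemmelen factor (OC = OM/1.724,
configurable). Effects are percent increments over the regional control
mean, tested with a two-sided two-sample t-test — Welch by default, since
the variance structure across treatments is unknown; the pooled-variance
variant is an option. Stars follow 0.05/0.01/0.001. The disease index is
the standard weighted severity score DI = 100·Σ n_s·s/(N·s_max) with
configurable maximum grade (the trial cites an external protocol for it;
this is the usual form of that index). The correlation screen reports
pairwise Pearson r with two-sided p, masks pairs at p ≥ α (α = 0.05
default), flags constant variables explicitly instead of emitting NaN, and
applies no multiplicity correction by default (matching common practice in
these trials); Benjamini–Hochberg is available as a flag.

## Community metrics

Richness is the count of taxa with positive abundance; Shannon H = −Σ p ln p
(natural log, vegan's default; base configurable); Simpson is reported as
Gini–Simpson 1 − Σp² (inverse Simpson optional); Pielou J = H/ln(richness),
undefined — returned as NaN, not 0 — for single-taxon samples. β-diversity
uses Bray–Curtis, BC = 1 − 2Σ min(a,b)/(Σa + Σb), the community standard
when the source analysis does not state its metric; ordination is out of
scope.

## Synthetic-trial generator

The generator reproduces the study design, not its data: 2 regions, 8
treatments, n = 45 replicates for agronomic traits, n = 4 for metabolite
and soil traits. Each replicate value is mean·effect·exp(ε) with
ε ~ N(−σ²/2, σ), σ² = ln(1 + CV²): lognormal noise keeps all biomass and
content traits strictly positive, and the −σ²/2 shift makes the configured
multiplier act on the arithmetic mean, so a 2.0× effect implies exactly
+100% expected increment (recovered within ±3 percentage points at n = 1000
in the tests). Additive Gaussian noise is available for traits where
negative values are meaningful. Replicates are i.i.d. within treatment — no
plot effects or spatial correlation, which real trials have; passing tests
therefore certify the estimators and pipeline plumbing, not robustness to
field-scale variance structure.

Default effect multipliers are fixtures placed inside the increment ranges
the field study reported (aboveground biomass +83.3–200.8%, Fuzi weight
+58.3–178.5%, Chuanwu weight +44.8–103.6%, soil-pH region averages +8.8%
in Jiangyou and +14.9% in Chenggu, disease index reduced, rice/maize/peanut
systems best overall); trait means and CVs not reported anywhere were set
once to field-plausible magnitudes (e.g. pH 6.0 in the below-7 regime the
interval transform assumes, gene abundances ~10⁶ copies·g⁻¹ with CV 0.25).
They are emulation parameters, not estimates of the real plots. The
17-indicator soil layout uses the published indicator names verbatim; the
6-indicator herb layout uses Fuzi weight, Chuanwu weight, polysaccharide
and total monoester alkaloids as benefit criteria and total diester
alkaloids (the toxic fraction) and disease index as cost criteria.

Problem sizes in the routine checks (500 simulated null trials at n = 10,
parameter recovery at n = 1000, 1000 randomized oracle matrices up to 5×5)
were chosen to give stable Monte-Carlo answers at desk scale.

## Numerical and degenerate-input choices

- Decision matrices reject non-finite entries, duplicate labels, fewer than
  2 treatments or 1 indicator, up front.
- Vector normalization errors on all-zero columns; min-max on constant
  columns, naming the offending indicator.
- `0·ln 0 := 0` throughout entropy computations.
- Stage failures in `run_topsis` are re-raised with the stage named.
- Seeded `numpy.random.default_rng` everywhere; identical design + seed
  reproduces outputs byte-for-byte, and every CLI output records seed,
  config hash and version in its `#` metadata header.

## Known limitations

- The bundled published tables validate only the distance → closeness →
  rank stages; absent the unpublished raw indicator values and weights, no
  end-to-end replay of the field evaluation is possible.
- The generator's i.i.d. replicate model understates real between-plot
  variance; significance rates on synthetic data transfer to field data
  only under that caveat.
- Welch-vs-pooled choice and the exact disease-index grading scheme of the
  original protocol are interpretations, flagged as such above.
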