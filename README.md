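# intercrop-eval

A comprehensive evaluation toolkit for intercropping field trials, built
around a two-region *Aconitum carmichaeli* (Fuzi/Chuanwu) strip-intercropping
study: 2 regions (Jiangyou, Chenggu), 8 treatments (five local intercrops
plus one monoculture control per region), replicate-level agronomic,
metabolite and rhizosphere-soil measurements. It is aimed at agronomists and
soil scientists who need to turn such a trial into a defensible ranking of
planting systems.

The package provides:

- **TOPSIS multi-criteria evaluation** (`intercrop_eval.topsis`) with
  benefit, cost and *interval* criteria. For an interval criterion such as
  soil pH with optimum range [7, 8], values are first mapped onto [0, 1]:

  ```
  M  = max(7 − min(x), max(x) − 8)
  x̂ᵢ = 1 − (7 − xᵢ)/M        (xᵢ < 7;  analogously above 8; x̂ᵢ = 1 inside)
  ```

  which for an all-below-7 sample reduces to x̂ᵢ = (xᵢ − min(x))/(7 − min(x)).
  After column normalization (vector norm by default) and weighting, each
  treatment i gets Euclidean distances Dᵢ⁺, Dᵢ⁻ to the positive/negative
  ideal solutions and the comprehensive benefit index

  ```
  Cᵢ = Dᵢ⁻ / (Dᵢ⁺ + Dᵢ⁻)  ∈ [0, 1],   rank 1 = largest Cᵢ.
  ```

  Weights come from config (equal by default) or from the entropy method.
- **Trial statistics** (`intercrop_eval.trial`): derived traits (total
  underground biomass = Chuanwu + Fuzi weight, total mono-/diester
  diterpenoid alkaloids, C/N ratio, ...), percent increments over the
  regional control with Welch t-tests, the weighted disease severity index,
  and a Pearson correlation screen with p < α masking.
- **Community metrics** (`intercrop_eval.diversity`): richness, Shannon,
  Gini–Simpson, Pielou evenness and Bray–Curtis dissimilarity (vegan
  conventions).
- **A seeded synthetic-trial generator** (`intercrop_eval.simulate`)
  emulating the study design (n = 45 agronomic / n = 4 metabolite-soil
  replicates, multiplicative lognormal treatment effects), so the whole
  pipeline is exercisable and testable without field data.
- A CLI (`intercrop-eval simulate|evaluate|stats|diversity`) and numbered
  drivers under `analysis/` that run the full narrative.

## Worked example

```bash
python analysis/01_simulate_trial.py --seed 1
python analysis/02_topsis_evaluation.py
```

prints, for the synthetic trial, the herb growth-and-quality ranking

```
herb evaluation (synthetic trial): best = J-rice (Ci=0.810)
  treatment  d_plus  d_minus  closeness  rank
     J-rice   0.019    0.081      0.810     1
    C-maize   0.021    0.071      0.775     2
   C-peanut   0.032    0.059      0.647     3
  ...
  J-control   0.081    0.011      0.116     8
```

— rice intercropping ranks first and both monoculture controls rank last,
the qualitative outcome the generator's effect multipliers encode — and then
checks the published field-trial tables bundled with the package:

```
published worked example (Ci recomputed from printed distances):
  herb: ranks reproduced=True, max |Ci gap|=0.0040
  soil: ranks reproduced=True, max |Ci gap|=0.0010
```

i.e. recomputing Cᵢ = Dᵢ⁻/(Dᵢ⁺ + Dᵢ⁻) from the published 3-decimal distances
reproduces every published rank, with Cᵢ gaps within the propagation of that
rounding. `analysis/03_trial_effects.py` reports the biomass increments
(e.g. aboveground biomass +83% to +194% over the controls, all significant)
and the region-average soil-pH rise; `analysis/04_community_diversity.py`
reports the diversity metrics.

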