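"""Seeded synthetic trial generator.

Emulates the two-region intercropping study design: 2 regions (Jiangyou,
Chenggu), 8 treatments (one monoculture control per region), 45 biological
replicates for agronomic traits and 4 for metabolite and soil traits.
Treatment effects are multiplicative on positive-valued traits; replicate
noise is lognormal (so traits stay positive) with the log-scale location
shifted by −σ²/2 so that the configured multiplier applies to the
arithmetic mean and configured percent increments are recovered exactly in
expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import trial as tr
from .topsis import DecisionMatrix, Indicator, TopsisError
from .trial import TrialDataset, TrialError

__all__ = [
    "TraitSpec",
    "TrialDesign",
    "default_design",
    "default_herb_indicators",
    "default_soil_indicators",
    "generate_trial",
    "generate_indicator_matrix",
    "generate_taxon_table",
]

#: the 17 published soil-quality indicator names
SOIL_INDICATOR_NAMES = (
    "pH", "organic matter", "NH4+-N", "NO3--N", "phosphate", "K",
    "amoA", "nxr", "narG", "nirS", "norB", "nosZ", "nifH",
    "catalase", "invertase", "urease", "acid phosphatase",
)


@dataclass(frozen=True)
class TraitSpec:
    """One simulated trait.

    ``effects`` maps treatment → multiplicative effect on the arithmetic
    mean (controls are fixed at 1).  ``trait_class`` selects the replicate
    count: "agronomic" traits get the large-n count, "soil" (which also
    covers metabolites) the small-n count.  ``cv`` is the within-treatment
    coefficient of variation.
    """

    name: str
    control_mean: float
    cv: float
    effects: Mapping[str, float] = field(default_factory=dict)
    trait_class: str = "agronomic"
    noise: str = "lognormal"

    def __post_init__(self) -> None:
        if self.control_mean <= 0:
            raise ValueError(f"trait {self.name!r}: control_mean must be > 0")
        if self.cv <= 0:
            raise ValueError(f"trait {self.name!r}: cv must be > 0")
        if self.trait_class not in ("agronomic", "soil"):
            raise ValueError(f"trait {self.name!r}: unknown trait_class {self.trait_class!r}")
        if self.noise not in ("lognormal", "normal"):
            raise ValueError(f"trait {self.name!r}: unknown noise model {self.noise!r}")
        for t, e in self.effects.items():
            if e <= 0:
                raise ValueError(f"trait {self.name!r}: effect for {t!r} must be > 0")


@dataclass(frozen=True)
class TrialDesign:
    """Region/treatment layout, replicate counts and trait specs."""

    regions: Mapping[str, tuple[str, ...]]
    controls: Mapping[str, str]
    traits: tuple[TraitSpec, ...]
    n_agronomic: int = 45
    n_soil: int = 4

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for region, treatments in self.regions.items():
            for t in treatments:
                if t in seen:
                    raise ValueError(f"treatment {t!r} appears in more than one region")
                seen.add(t)
            ctrl = self.controls.get(region)
            if ctrl is None or ctrl not in treatments:
                raise ValueError(f"region {region!r} must flag exactly one control treatment")
        if self.n_agronomic < 2 or self.n_soil < 2:
            raise ValueError("replicate counts must be >= 2")

    @property
    def treatments(self) -> list[str]:
        return [t for ts in self.regions.values() for t in ts]


def _lognormal_sigma(cv: float) -> float:
    return float(np.sqrt(np.log1p(cv**2)))


def generate_trial(design: TrialDesign, seed: int) -> TrialDataset:
    """Draw a full replicate-level dataset for a design.

    For the lognormal model each value is mean·effect·exp(ε) with
    ε ~ Normal(−σ²/2, σ), σ² = ln(1 + cv²), so E[value] = mean·effect.
    Identical design + seed reproduces the dataset bit for bit.
    """
    rng = np.random.default_rng(seed)
    records = []
    for spec in design.traits:
        n = design.n_agronomic if spec.trait_class == "agronomic" else design.n_soil
        sigma = _lognormal_sigma(spec.cv)
        for region, treatments in design.regions.items():
            for treatment in treatments:
                if treatment == design.controls[region]:
                    effect = 1.0
                else:
                    effect = float(spec.effects.get(treatment, 1.0))
                mean = spec.control_mean * effect
                if spec.noise == "lognormal":
                    mu = np.log(mean) - sigma**2 / 2.0
                    values = rng.lognormal(mean=mu, sigma=sigma, size=n)
                else:
                    values = rng.normal(loc=mean, scale=spec.cv * mean, size=n)
                for rep, v in enumerate(values, start=1):
                    records.append((region, treatment, rep, spec.name, float(v)))
    data = pd.DataFrame(records, columns=list(tr.REQUIRED_COLUMNS))
    return TrialDataset(data=data, controls=dict(design.controls))


def generate_indicator_matrix(
    dataset: TrialDataset, indicators: Sequence[Indicator]
) -> DecisionMatrix:
    """Treatment-level mean of each indicator's trait, as a decision matrix.

    Indicator names must match trait labels in the dataset (derive totals
    with :func:`intercrop_eval.trial.derive_traits` first if needed).  pH
    is left untransformed — the interval handling belongs to the TOPSIS
    stage.
    """
    names = [ind.name for ind in indicators]
    try:
        wide = dataset.treatment_means(names)
    except TrialError as exc:
        raise TopsisError(f"unknown indicator: {exc}") from exc
    return DecisionMatrix(values=wide, indicators=list(indicators))


def generate_taxon_table(
    n_samples: int,
    n_taxa: int,
    *,
    concentration: float = 50.0,
    depth: int = 10_000,
    seed: int = 0,
    prior: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Dirichlet-multinomial sample × taxon counts.

    Per sample, relative abundances are drawn from
    Dirichlet(concentration · prior) (uniform prior by default) and counts
    from Multinomial(depth).  Low concentration gives uneven, variable
    communities; high concentration approaches the prior composition.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if concentration <= 0:
        raise ValueError("concentration must be > 0")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if prior is None:
        alpha = np.full(n_taxa, concentration / n_taxa)
    else:
        prior = np.asarray(prior, dtype=float)
        if prior.shape != (n_taxa,) or (prior <= 0).any():
            raise ValueError("prior must hold n_taxa positive entries")
        alpha = concentration * prior / prior.sum()
    rng = np.random.default_rng(seed)
    counts = np.empty((n_samples, n_taxa), dtype=int)
    for i in range(n_samples):
        p = rng.dirichlet(alpha)
        counts[i] = rng.multinomial(depth, p)
    return pd.DataFrame(
        counts,
        index=[f"S{i + 1}" for i in range(n_samples)],
        columns=[f"T{j + 1}" for j in range(n_taxa)],
    )


def default_design() -> TrialDesign:
    """The bundled study-shaped design: 2 regions, 8 treatments, n = 45
    agronomic and n = 4 metabolite/soil replicates.

    Effect multipliers are fixtures chosen inside the increment ranges the
    trial reported (aboveground biomass +83–201%, Fuzi weight +58–179%,
    Chuanwu weight +45–104%, soil pH region averages +8.8% in Jiangyou and
    +14.9% in Chenggu, disease index reduced); trait means and CVs are
    field-plausible values, not estimates of the real plots.
    """
    J = ("J-maize", "J-rice", "J-control")
    C = ("C-peanut", "C-sesame", "C-maize", "C-mung bean", "C-control")
    regions = {"Jiangyou": J, "Chenggu": C}
    controls = {"Jiangyou": "J-control", "Chenggu": "C-control"}

    def eff(jm, jr, cp, cs, cm, cb):
        return {
            "J-maize": jm, "J-rice": jr,
            "C-peanut": cp, "C-sesame": cs, "C-maize": cm, "C-mung bean": cb,
        }

    traits = (
        # agronomic, n = 45
        TraitSpec(tr.PLANT_HEIGHT, 90.0, 0.10, eff(1.25, 1.30, 1.05, 1.04, 1.20, 1.03)),
        TraitSpec(tr.STEM_DIAMETER, 1.2, 0.12, eff(1.25, 1.35, 1.15, 1.12, 1.20, 1.10)),
        TraitSpec(tr.AGB, 120.0, 0.25, eff(2.60, 3.00, 1.90, 1.85, 2.20, 1.90)),
        TraitSpec(tr.FUZI_WEIGHT, 45.0, 0.30, eff(2.00, 2.78, 2.30, 1.70, 2.50, 1.60)),
        TraitSpec(tr.CHUANWU_WEIGHT, 30.0, 0.30, eff(1.60, 1.95, 1.85, 1.50, 2.03, 1.45)),
        TraitSpec(tr.DISEASE_INDEX, 40.0, 0.25, eff(0.60, 0.50, 0.70, 0.75, 0.65, 0.70)),
        # Fuzi metabolites, n = 4
        TraitSpec(tr.POLYSACCHARIDE, 55.0, 0.10, eff(1.30, 1.40, 1.20, 1.15, 1.25, 1.18),
                  trait_class="soil"),
        TraitSpec("benzoylhypaconitine", 0.060, 0.15,
                  eff(1.50, 1.70, 1.40, 1.30, 1.35, 1.30), trait_class="soil"),
        TraitSpec("benzoylaconitine", 0.040, 0.15,
                  eff(0.70, 0.65, 0.80, 0.75, 0.70, 0.80), trait_class="soil"),
        TraitSpec("benzoylmesaconitine", 0.050, 0.15,
                  eff(0.75, 0.70, 0.85, 0.80, 0.75, 0.85), trait_class="soil"),
        TraitSpec("hypaconitine", 0.030, 0.15,
                  eff(1.40, 1.50, 0.80, 0.85, 0.75, 0.80), trait_class="soil"),
        TraitSpec("aconitine", 0.020, 0.15,
                  eff(0.70, 0.65, 1.30, 1.05, 0.70, 1.25), trait_class="soil"),
        TraitSpec("mesaconitine", 0.025, 0.15,
                  eff(0.75, 0.70, 1.25, 1.05, 0.75, 1.20), trait_class="soil"),
        # soil chemistry / biology, n = 4 (names match the published
        # 17-indicator soil evaluation)
        TraitSpec("pH", 6.0, 0.02, eff(1.088, 1.088, 1.149, 1.149, 1.149, 1.149),
                  trait_class="soil"),
        TraitSpec("organic matter", 20.0, 0.12, eff(1.00, 1.30, 0.80, 0.82, 0.85, 0.80),
                  trait_class="soil"),
        TraitSpec("NH4+-N", 12.0, 0.15, eff(1.35, 1.40, 0.75, 1.30, 1.25, 0.80),
                  trait_class="soil"),
        TraitSpec("NO3--N", 18.0, 0.15, eff(0.70, 1.30, 1.00, 1.25, 0.75, 1.00),
                  trait_class="soil"),
        TraitSpec("phosphate", 25.0, 0.15, eff(1.35, 0.75, 1.00, 1.30, 1.30, 1.00),
                  trait_class="soil"),
        TraitSpec("K", 150.0, 0.12, eff(1.02, 1.03, 0.98, 1.02, 1.01, 0.99),
                  trait_class="soil"),
        TraitSpec("total_nitrogen", 1.3, 0.12, eff(1.20, 1.35, 1.05, 1.10, 1.10, 1.05),
                  trait_class="soil"),
        TraitSpec("amoA", 2.0e6, 0.25, eff(1.60, 1.80, 1.40, 1.35, 1.45, 1.30),
                  trait_class="soil"),
        TraitSpec("nxr", 1.5e6, 0.25, eff(0.80, 1.30, 0.75, 0.70, 0.75, 1.20),
                  trait_class="soil"),
        TraitSpec("narG", 3.0e6, 0.25, eff(1.40, 1.50, 1.30, 1.25, 1.35, 1.20),
                  trait_class="soil"),
        TraitSpec("nirS", 2.5e6, 0.25, eff(1.30, 1.40, 1.25, 1.20, 1.30, 1.15),
                  trait_class="soil"),
        TraitSpec("norB", 1.0e6, 0.25, eff(0.75, 0.80, 1.25, 1.20, 1.30, 1.15),
                  trait_class="soil"),
        TraitSpec("nosZ", 1.8e6, 0.25, eff(1.35, 1.45, 1.25, 0.80, 1.30, 1.20),
                  trait_class="soil"),
        TraitSpec("nifH", 2.2e6, 0.25, eff(1.40, 0.85, 1.30, 1.25, 1.35, 1.25),
                  trait_class="soil"),
        TraitSpec("catalase", 8.0, 0.15, eff(1.25, 1.30, 1.20, 1.15, 1.20, 1.10),
                  trait_class="soil"),
        TraitSpec("invertase", 15.0, 0.15, eff(1.20, 1.25, 1.15, 1.10, 1.15, 0.85),
                  trait_class="soil"),
        TraitSpec("urease", 5.0, 0.15, eff(1.25, 1.20, 1.15, 1.10, 1.20, 1.10),
                  trait_class="soil"),
        TraitSpec("acid phosphatase", 10.0, 0.15, eff(1.15, 0.85, 0.80, 1.10, 1.15, 1.05),
                  trait_class="soil"),
    )
    return TrialDesign(regions=regions, controls=controls, traits=traits)


def default_herb_indicators(weights: Mapping[str, float] | None = None) -> list[Indicator]:
    """The six-indicator herb growth-and-quality evaluation layout.

    Fuzi/Chuanwu biomass, polysaccharide and total monoester alkaloids are
    benefit indicators; total diester alkaloids (the toxic fraction) and
    the disease index are cost indicators.  Equal weights by default.
    """
    spec = [
        (tr.FUZI_WEIGHT, "benefit"),
        (tr.CHUANWU_WEIGHT, "benefit"),
        (tr.POLYSACCHARIDE, "benefit"),
        (tr.TOTAL_MDA, "benefit"),
        (tr.TOTAL_DDA, "cost"),
        (tr.DISEASE_INDEX, "cost"),
    ]
    weights = weights or {}
    return [Indicator(name, direction, weight=float(weights.get(name, 1.0)))
            for name, direction in spec]


def default_soil_indicators(weights: Mapping[str, float] | None = None) -> list[Indicator]:
    """The 17-indicator soil-quality evaluation layout.

    pH is the single interval indicator (optimum 7–8 for *A. carmichaeli*);
    everything else is benefit.  Equal weights by default.
    """
    weights = weights or {}
    out = []
    for name in SOIL_INDICATOR_NAMES:
        if name == "pH":
            out.append(Indicator(name, "interval", weight=float(weights.get(name, 1.0)),
                                 interval_low=7.0, interval_high=8.0))
        else:
            out.append(Indicator(name, "benefit", weight=float(weights.get(name, 1.0))))
    return out
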