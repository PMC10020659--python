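"""Replicate-level trial statistics: derived traits, treatment-vs-control
effect summaries, disease index and correlation screening.

The trial layout is two regions, each with one monoculture control and
several intercropping treatments; measurements are stored in long format
(region, treatment, replicate, trait, value).  Effect sizes are reported
as percent increments over the region's control, with Welch t-test
significance stars (* p<0.05, ** p<0.01, *** p<0.001).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TrialError",
    "TrialDataset",
    "EffectSummary",
    "CorrelationScreen",
    "derive_traits",
    "increment_vs_control",
    "effect_summary_table",
    "region_average_increment",
    "disease_index",
    "correlation_screen",
    "stars_from_p",
]

# canonical trait labels
PLANT_HEIGHT = "plant_height"
STEM_DIAMETER = "stem_diameter"
AGB = "aboveground_biomass"
CHUANWU_WEIGHT = "chuanwu_weight"
FUZI_WEIGHT = "fuzi_weight"
TOTAL_UNDERGROUND = "total_underground_biomass"
TOTAL_BIOMASS = "total_biomass"
ROOT_SHOOT_RATIO = "root_shoot_ratio"
DISEASE_INDEX = "disease_index"
POLYSACCHARIDE = "polysaccharide"
MONOESTERS = ("benzoylhypaconitine", "benzoylaconitine", "benzoylmesaconitine")
DIESTERS = ("hypaconitine", "aconitine", "mesaconitine")
TOTAL_MDA = "total_monoester_alkaloids"
TOTAL_DDA = "total_diester_alkaloids"
TOTAL_ALKALOIDS = "total_alkaloids"
ORGANIC_MATTER = "organic matter"
ORGANIC_CARBON = "organic_carbon"
TOTAL_NITROGEN = "total_nitrogen"
CN_RATIO = "C_N_ratio"

#: van Bemmelen factor: organic matter ≈ 1.724 × organic carbon
OM_TO_OC = 1.724

REQUIRED_COLUMNS = ("region", "treatment", "replicate", "trait", "value")


class TrialError(ValueError):
    """Raised for malformed trial datasets or undefined summaries."""


@dataclass
class TrialDataset:
    """Long-format replicate-level measurements plus the control map.

    ``data`` columns: region, treatment, replicate, trait, value.
    ``controls`` maps each region to its monoculture control treatment.
    """

    data: pd.DataFrame
    controls: dict[str, str]

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise TrialError(f"trial data missing columns: {missing}")
        key = ["region", "treatment", "replicate", "trait"]
        if self.data.duplicated(subset=key).any():
            raise TrialError("duplicate (region, treatment, replicate, trait) records")
        region_of = self.data.groupby("treatment", sort=False)["region"].nunique()
        if (region_of > 1).any():
            bad = region_of[region_of > 1].index.tolist()
            raise TrialError(f"treatments present in more than one region: {bad}")
        for region in self.data["region"].unique():
            ctrl = self.controls.get(region)
            if ctrl is None:
                raise TrialError(f"region {region!r} has no control treatment configured")
            present = self.data.loc[self.data["region"] == region, "treatment"].unique()
            if ctrl not in present:
                raise TrialError(f"control {ctrl!r} has no data in region {region!r}")

    @property
    def regions(self) -> list[str]:
        return list(dict.fromkeys(self.data["region"]))

    @property
    def treatments(self) -> list[str]:
        return list(dict.fromkeys(self.data["treatment"]))

    def region_of(self, treatment: str) -> str:
        rows = self.data.loc[self.data["treatment"] == treatment, "region"]
        if rows.empty:
            raise TrialError(f"unknown treatment {treatment!r}")
        return str(rows.iloc[0])

    def values(self, treatment: str, trait: str) -> np.ndarray:
        mask = (self.data["treatment"] == treatment) & (self.data["trait"] == trait)
        return self.data.loc[mask, "value"].to_numpy(dtype=float)

    def treatment_means(self, traits: Sequence[str]) -> pd.DataFrame:
        """Treatment × trait mean table (used to build decision matrices)."""
        sub = self.data[self.data["trait"].isin(traits)]
        wide = sub.pivot_table(index="treatment", columns="trait", values="value",
                               aggfunc="mean", sort=False)
        missing = [t for t in traits if t not in wide.columns]
        if missing:
            raise TrialError(f"traits absent from dataset: {missing}")
        return (wide.reindex(index=self.treatments, columns=list(traits))
                .rename_axis(index=None, columns=None))


@dataclass(frozen=True)
class EffectSummary:
    """Treatment-vs-control summary for one trait."""

    trait: str
    treatment: str
    region: str
    control_mean: float
    treatment_mean: float
    increment_pct: float
    p_value: float
    stars: str


def stars_from_p(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def _sum_rows(wide: pd.DataFrame, components: Sequence[str], derived: str) -> pd.Series:
    """Sum component traits, requiring all components wherever any is present."""
    present = [c for c in components if c in wide.columns]
    if not present:
        return pd.Series(dtype=float)
    any_mask = wide[present].notna().any(axis=1)
    missing_cols = [c for c in components if c not in wide.columns]
    if missing_cols and any_mask.any():
        idx = wide.index[any_mask][0]
        raise TrialError(
            f"cannot derive {derived!r}: trait {missing_cols[0]!r} missing for "
            f"replicate {tuple(idx)}"
        )
    block = wide[list(components)]
    partial = any_mask & block.isna().any(axis=1)
    if partial.any():
        idx = wide.index[partial][0]
        bad = block.columns[block.loc[idx].isna()][0]
        raise TrialError(
            f"cannot derive {derived!r}: trait {bad!r} missing for replicate {tuple(idx)}"
        )
    return block.loc[any_mask].sum(axis=1)


def derive_traits(dataset: TrialDataset) -> TrialDataset:
    """Add the standard derived traits to a dataset.

    total underground biomass = Chuanwu + Fuzi weight; total biomass adds
    the aboveground biomass; root/shoot ratio = underground / aboveground;
    total monoester (MDA) and diester (DDA) alkaloids are sums of their
    three named compounds; total alkaloids = MDA + DDA; C/N ratio =
    organic carbon / total nitrogen (organic matter is converted to carbon
    with the van Bemmelen factor 1.724 when carbon is not measured).
    Derived traits already present in the data are left untouched.
    """
    wide = dataset.data.pivot_table(
        index=["region", "treatment", "replicate"], columns="trait", values="value",
        sort=False,
    )
    new: dict[str, pd.Series] = {}

    def add(name: str, series: pd.Series) -> None:
        if name not in wide.columns and not series.empty:
            new[name] = series
            wide[name] = series  # so later derivations can build on it

    add(TOTAL_UNDERGROUND, _sum_rows(wide, (CHUANWU_WEIGHT, FUZI_WEIGHT), TOTAL_UNDERGROUND))
    add(TOTAL_BIOMASS, _sum_rows(wide, (AGB, TOTAL_UNDERGROUND), TOTAL_BIOMASS))
    if TOTAL_UNDERGROUND in wide.columns and AGB in wide.columns:
        both = wide[TOTAL_UNDERGROUND].notna() & wide[AGB].notna()
        add(ROOT_SHOOT_RATIO, (wide.loc[both, TOTAL_UNDERGROUND] / wide.loc[both, AGB]))
    add(TOTAL_MDA, _sum_rows(wide, MONOESTERS, TOTAL_MDA))
    add(TOTAL_DDA, _sum_rows(wide, DIESTERS, TOTAL_DDA))
    add(TOTAL_ALKALOIDS, _sum_rows(wide, (TOTAL_MDA, TOTAL_DDA), TOTAL_ALKALOIDS))

    if CN_RATIO not in wide.columns:
        if ORGANIC_CARBON in wide.columns:
            carbon = wide[ORGANIC_CARBON]
        elif ORGANIC_MATTER in wide.columns:
            carbon = wide[ORGANIC_MATTER] / OM_TO_OC
        else:
            carbon = None
        if carbon is not None and TOTAL_NITROGEN in wide.columns:
            both = carbon.notna() & wide[TOTAL_NITROGEN].notna()
            add(CN_RATIO, carbon[both] / wide.loc[both, TOTAL_NITROGEN])

    if not new:
        return TrialDataset(data=dataset.data.copy(), controls=dict(dataset.controls))

    extra = (
        pd.DataFrame(new)
        .rename_axis(columns="trait")
        .stack()
        .rename("value")
        .reset_index()
    )
    out = pd.concat([dataset.data, extra], ignore_index=True)
    return TrialDataset(data=out, controls=dict(dataset.controls))


def increment_vs_control(
    dataset: TrialDataset,
    trait: str,
    treatment: str,
    *,
    equal_var: bool = False,
) -> EffectSummary:
    """Percent increment of a treatment over its region's control, with a
    two-sided two-sample t-test (Welch by default)."""
    region = dataset.region_of(treatment)
    control = dataset.controls[region]
    t_vals = dataset.values(treatment, trait)
    c_vals = dataset.values(control, trait)
    if t_vals.size < 2 or c_vals.size < 2:
        raise TrialError(
            f"need >= 2 replicates of {trait!r} for {treatment!r} and its control"
        )
    c_mean = float(c_vals.mean())
    t_mean = float(t_vals.mean())
    if c_mean == 0:
        raise TrialError(f"control mean of {trait!r} is zero; increment undefined")
    increment = 100.0 * (t_mean - c_mean) / c_mean
    res = stats.ttest_ind(t_vals, c_vals, equal_var=equal_var)
    p = float(res.pvalue)
    return EffectSummary(
        trait=trait,
        treatment=treatment,
        region=region,
        control_mean=c_mean,
        treatment_mean=t_mean,
        increment_pct=increment,
        p_value=p,
        stars=stars_from_p(p),
    )


def effect_summary_table(
    dataset: TrialDataset,
    traits: Iterable[str] | None = None,
    *,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Tidy table of increment_vs_control for every non-control treatment
    × trait combination with data on both sides."""
    traits = list(traits) if traits is not None else sorted(dataset.data["trait"].unique())
    rows = []
    for treatment in dataset.treatments:
        region = dataset.region_of(treatment)
        if treatment == dataset.controls[region]:
            continue
        for trait in traits:
            if dataset.values(treatment, trait).size < 2:
                continue
            if dataset.values(dataset.controls[region], trait).size < 2:
                continue
            rows.append(increment_vs_control(dataset, trait, treatment, equal_var=equal_var))
    return pd.DataFrame([r.__dict__ for r in rows])


def region_average_increment(dataset: TrialDataset, trait: str, region: str) -> float:
    """Mean percent increment over the region's intercrop (non-control)
    treatments for one trait."""
    if region not in dataset.regions:
        raise TrialError(f"unknown region {region!r}")
    control = dataset.controls[region]
    treatments = [
        t for t in dataset.treatments
        if dataset.region_of(t) == region and t != control
    ]
    if not treatments:
        raise TrialError(f"region {region!r} has no intercrop treatments")
    incs = [increment_vs_control(dataset, trait, t).increment_pct for t in treatments]
    return float(np.mean(incs))


def disease_index(counts: Mapping[int, int] | Sequence[int], s_max: int) -> float:
    """Weighted disease severity index in percent.

    ``counts`` holds the number of plants at each severity grade
    0..s_max (mapping grade → count, or a sequence indexed by grade):
    DI = 100 · Σ_s n_s·s / (N·s_max).
    """
    if s_max < 1:
        raise TrialError("disease_index: s_max must be >= 1")
    if isinstance(counts, Mapping):
        items = list(counts.items())
    else:
        items = list(enumerate(counts))
    total = 0
    weighted = 0
    for grade, n in items:
        if not float(n).is_integer() or n < 0:
            raise TrialError("disease_index: counts must be non-negative integers")
        if grade < 0 or grade > s_max:
            raise TrialError(f"disease_index: grade {grade} outside 0..{s_max}")
        total += int(n)
        weighted += int(n) * grade
    if total == 0:
        raise TrialError("disease_index: no plants surveyed")
    return 100.0 * weighted / (total * s_max)


@dataclass
class CorrelationScreen:
    """Pairwise Pearson correlations with a significance mask.

    ``retained`` marks pairs with p < alpha; constant variables are masked
    with reason ``"constant"`` rather than propagating NaN silently.
    """

    r: pd.DataFrame
    p: pd.DataFrame
    retained: pd.DataFrame
    edges: pd.DataFrame
    alpha: float

    def masked_r(self) -> pd.DataFrame:
        return self.r.where(self.retained)


def correlation_screen(
    matrix: pd.DataFrame,
    alpha: float = 0.05,
    *,
    adjust: str | None = None,
) -> CorrelationScreen:
    """Pearson correlation screen over the columns of a samples × variables
    table; entries with p ≥ alpha are masked.  ``adjust="fdr_bh"`` applies
    Benjamini–Hochberg across the unique pairs before masking (off by
    default)."""
    if not 0 < alpha <= 1:
        raise TrialError("alpha must be in (0, 1]")
    X = matrix.dropna()
    if X.shape[0] < 3:
        raise TrialError("correlation_screen needs >= 3 complete observations")
    cols = list(X.columns)
    m = len(cols)
    r = pd.DataFrame(np.eye(m), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((m, m)), index=cols, columns=cols)
    reason = pd.DataFrame("", index=cols, columns=cols)
    constant = {c for c in cols if X[c].nunique() <= 1}

    pairs = []
    for i in range(m):
        for j in range(i + 1, m):
            a, b = cols[i], cols[j]
            if a in constant or b in constant:
                r.loc[a, b] = r.loc[b, a] = np.nan
                p.loc[a, b] = p.loc[b, a] = np.nan
                reason.loc[a, b] = reason.loc[b, a] = "constant"
                pairs.append((a, b, np.nan, np.nan, "constant"))
                continue
            res = stats.pearsonr(X[a], X[b])
            r.loc[a, b] = r.loc[b, a] = res.statistic
            p.loc[a, b] = p.loc[b, a] = res.pvalue
            pairs.append((a, b, float(res.statistic), float(res.pvalue), ""))

    edges = pd.DataFrame(pairs, columns=["var1", "var2", "r", "p", "reason"])
    if adjust == "fdr_bh" and edges["p"].notna().any():
        from statsmodels.stats.multitest import multipletests

        ok = edges["p"].notna()
        adj = multipletests(edges.loc[ok, "p"], method="fdr_bh")[1]
        edges.loc[ok, "p"] = adj
        for (_, row), q in zip(edges.loc[ok].iterrows(), adj):
            p.loc[row["var1"], row["var2"]] = q
            p.loc[row["var2"], row["var1"]] = q
    elif adjust not in (None, "fdr_bh"):
        raise TrialError(f"unknown adjustment {adjust!r}")

    retained = (p < alpha) & p.notna()
    np.fill_diagonal(retained.values, True)
    edges["retained"] = [
        bool(p.loc[v1, v2] < alpha) if reason.loc[v1, v2] == "" else False
        for v1, v2 in zip(edges["var1"], edges["var2"])
    ]
    return CorrelationScreen(r=r, p=p, retained=retained, edges=edges, alpha=alpha)
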