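"""Bundled reference tables.

The package ships the published TOPSIS evaluation tables of the two-region
*Aconitum carmichaeli* strip-intercropping field trial it was written
around: per-treatment distances to the positive and negative ideal
solutions (D⁺, D⁻), the comprehensive benefit index Cᵢ and the resulting
ranking, for the herb growth-and-quality evaluation (6 indicators) and the
soil-quality evaluation (17 indicators).  The underlying raw indicator
values and assigned weights were not published, so these tables serve as
the worked-example surface for the D → Cᵢ → rank stages.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_herb_topsis", "load_soil_topsis"]


def _load(name: str) -> pd.DataFrame:
    with resources.files("intercrop_eval.data").joinpath(name).open("rb") as fh:
        return pd.read_csv(fh)


def load_herb_topsis() -> pd.DataFrame:
    """Published herb growth-and-quality evaluation table
    (treatment, d_plus, d_minus, closeness, rank)."""
    return _load("herb_topsis_published.csv")


def load_soil_topsis() -> pd.DataFrame:
    """Published soil-quality evaluation table
    (treatment, d_plus, d_minus, closeness, rank)."""
    return _load("soil_topsis_published.csv")
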