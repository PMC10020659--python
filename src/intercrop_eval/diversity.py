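"""Alpha diversity and Bray–Curtis dissimilarity for sample × taxon tables.

Conventions follow the R vegan package: Shannon entropy uses the natural
logarithm by default, "simpson" means the Gini–Simpson index 1 − Σp², and
Pielou evenness is H / ln(richness).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["DiversityError", "alpha_diversity", "bray_curtis"]


class DiversityError(ValueError):
    """Raised for invalid abundance tables."""


def _as_table(table: pd.DataFrame) -> pd.DataFrame:
    if not isinstance(table, pd.DataFrame):
        table = pd.DataFrame(np.asarray(table, dtype=float))
    X = table.to_numpy(dtype=float)
    if (X < 0).any() or not np.isfinite(X).all():
        raise DiversityError("abundances must be finite and non-negative")
    if (X.sum(axis=1) <= 0).any():
        bad = table.index[X.sum(axis=1) <= 0][0]
        raise DiversityError(f"sample {bad!r} has zero total abundance")
    if table.index.duplicated().any() or table.columns.duplicated().any():
        raise DiversityError("sample and taxon labels must be unique")
    return table


def alpha_diversity(
    table: pd.DataFrame,
    *,
    log_base: float | None = None,
    simpson: str = "gini",
) -> pd.DataFrame:
    """Per-sample richness, Shannon, Simpson and Pielou indices.

    ``table`` holds one row per sample and one column per taxon.  With
    relative abundances p: richness = #{p > 0}; Shannon H = −Σ p log p
    (natural log unless ``log_base`` is given; 0·log 0 := 0); Simpson is
    the Gini–Simpson index 1 − Σp² (``simpson="inverse"`` gives 1/Σp²);
    Pielou J = H / log(richness), undefined (NaN) for single-taxon samples.
    """
    table = _as_table(table)
    if simpson not in ("gini", "inverse"):
        raise DiversityError(f"unknown simpson variant {simpson!r}")
    X = table.to_numpy(dtype=float)
    p = X / X.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    H = -plogp.sum(axis=1)
    if log_base is not None:
        if log_base <= 0 or log_base == 1:
            raise DiversityError("log_base must be positive and != 1")
        H = H / np.log(log_base)
    richness = (X > 0).sum(axis=1)
    d2 = (p**2).sum(axis=1)
    simpson_vals = 1.0 - d2 if simpson == "gini" else 1.0 / d2
    log_richness = np.where(richness >= 2, np.log(richness), np.nan)
    if log_base is not None:
        log_richness = log_richness / np.log(log_base)
    pielou = np.where(richness >= 2, H / log_richness, np.nan)
    return pd.DataFrame(
        {
            "richness": richness,
            "shannon": H,
            "simpson": simpson_vals,
            "pielou": pielou,
        },
        index=table.index,
    )


def bray_curtis(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray–Curtis dissimilarity between samples.

    BC(a, b) = 1 − 2·Σ_t min(a_t, b_t) / (Σ_t a_t + Σ_t b_t); symmetric,
    zero diagonal, values in [0, 1].
    """
    table = _as_table(table)
    if table.shape[0] < 2:
        raise DiversityError("bray_curtis needs at least 2 samples")
    X = table.to_numpy(dtype=float)
    n = X.shape[0]
    out = np.zeros((n, n))
    totals = X.sum(axis=1)
    for i in range(n):
        for j in range(i + 1, n):
            shared = np.minimum(X[i], X[j]).sum()
            out[i, j] = out[j, i] = 1.0 - 2.0 * shared / (totals[i] + totals[j])
    return pd.DataFrame(out, index=table.index, columns=table.index)
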