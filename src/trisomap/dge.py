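"""Fold-change rank-ordering statistics (FCROS) differential expression.

For a two-group experiment with n_c control and n_t test samples, every one
of the k = n_c * n_t test/control sample pairs yields a per-gene log2 fold
change. Within each pair the genes are ranked by fold change (ascending,
average ranks for ties) and the ranks are normalised by the gene count m so
they lie in (0, 1]. The per-gene mean normalised rank rbar over the k pairs
is standardised to a z-score — either empirically, by the mean and SD of the
rbar values themselves, or theoretically via the Normal(1/2, 1/(12k))
null for an average of k uniform ranks — and mapped through the standard
normal CDF to an f-value in (0, 1). Genes with f below alpha_low or above
alpha_high are called differentially expressed; the default 0.025/0.975
window flags 5% of genes under the complete null.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression import CONTROL, TRISOMIC, ExpressionMatrix

UP = "up"
DOWN = "down"


@dataclass
class DegCallParams:
    """f-value window and standardisation mode for DEG calling."""

    alpha_low: float = 0.025
    alpha_high: float = 0.975
    standardization: str = "empirical"  # or "theoretical"
    bh_adjust: bool = False  # optional BH on two-sided f-derived p-values

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha_low < self.alpha_high < 1.0:
            raise ValueError("need 0 < alpha_low < alpha_high < 1")
        if self.standardization not in ("empirical", "theoretical"):
            raise ValueError("standardization must be 'empirical' or 'theoretical'")


@dataclass
class FcrosResult:
    """Per-gene FCROS statistics.

    ``table`` columns: rbar (mean normalised rank), f_value, log2fc (median
    pairwise log2 fold change), is_deg, direction ('up'/'down'/'');
    plus q_value when BH adjustment was requested.
    """

    table: pd.DataFrame
    k: int
    params: DegCallParams

    @property
    def degs(self) -> pd.Index:
        return self.table.index[self.table["is_deg"]]


def pairwise_fold_changes(X: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene log2 fold change for every (control, test) sample pair.

    Column ``cI_tJ`` is test sample J minus control sample I (log2 scale);
    column order is control-major and deterministic.
    """
    controls = X.control_samples
    tests = X.trisomic_samples
    for label, samples in ((CONTROL, controls), (TRISOMIC, tests)):
        if len(samples) < 2:
            raise ValueError(f"group {label!r} has fewer than 2 samples")
    cols = {}
    for i, c in enumerate(controls, start=1):
        for j, t in enumerate(tests, start=1):
            cols[f"c{i}_t{j}"] = X.values[t] - X.values[c]
    return pd.DataFrame(cols, index=X.gene_ids)


def fcros_statistic(FC: pd.DataFrame, params: DegCallParams | None = None) -> FcrosResult:
    """Rank the pairwise fold changes and compute rbar, f-values and DEG calls."""
    params = params or DegCallParams()
    m, k = FC.shape
    if m < 10:
        raise ValueError("rank statistic needs at least 10 genes")
    ranks = FC.rank(axis=0, method="average") / m  # in (0, 1]
    rbar = ranks.mean(axis=1)

    degenerate = bool((FC.nunique(axis=0) <= 1).all())
    if params.standardization == "empirical":
        sd = float(rbar.std(ddof=1))
        # sd of identically-distributed rbar can be ~1e-17 instead of exactly 0
        if degenerate or sd < 1e-9:
            warnings.warn("degenerate fold-change matrix: all f-values set to 0.5")
            f = pd.Series(0.5, index=FC.index)
        else:
            f = pd.Series(stats.norm.cdf((rbar - rbar.mean()) / sd), index=FC.index)
    else:
        sd = math.sqrt(1.0 / (12.0 * k))
        if degenerate:
            warnings.warn("degenerate fold-change matrix: all f-values set to 0.5")
            f = pd.Series(0.5, index=FC.index)
        else:
            f = pd.Series(stats.norm.cdf((rbar - 0.5) / sd), index=FC.index)

    log2fc = FC.median(axis=1)
    table = pd.DataFrame(
        {"rbar": rbar, "f_value": f, "log2fc": log2fc}, index=FC.index
    )
    if params.bh_adjust:
        p_two = 2.0 * np.minimum(f, 1.0 - f)
        table["q_value"] = multipletests(np.clip(p_two, 0, 1), method="fdr_bh")[1]
        flagged = table["q_value"] < (params.alpha_low + (1.0 - params.alpha_high))
        table["is_deg"] = flagged
        table["direction"] = np.where(
            flagged, np.where(f > 0.5, UP, DOWN), ""
        )
    else:
        low = f < params.alpha_low
        high = f > params.alpha_high
        table["is_deg"] = low | high
        table["direction"] = np.where(high, UP, np.where(low, DOWN, ""))
    return FcrosResult(table=table, k=k, params=params)


def call_degs(result: FcrosResult) -> pd.DataFrame:
    """DEG table (gene, direction, f_value, log2fc), sorted by |log2fc|
    descending with a deterministic gene-id tie-break."""
    t = result.table[result.table["is_deg"]].copy()
    t["abs_fc"] = t["log2fc"].abs()
    t = (
        t.rename_axis("gene_id")
        .reset_index()
        .sort_values(["abs_fc", "gene_id"], ascending=[False, True], kind="mergesort")
        .drop(columns="abs_fc")
        .reset_index(drop=True)
    )
    return t[["gene_id", "direction", "f_value", "log2fc", "rbar"]]


def run_fcros(X: ExpressionMatrix, params: DegCallParams | None = None) -> FcrosResult:
    """Convenience wrapper: pairwise fold changes then the rank statistic."""
    return fcros_statistic(pairwise_fold_changes(X), params)
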