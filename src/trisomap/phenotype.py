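"""Quantification formulas for the non-transcriptome readouts.

- qPCR: comparative-Ct relative quantities, geNorm reference-gene stability
  selection, and light-induction fold changes normalised to the dark-housed
  baseline of each genotype.
- Western blot: protein signal over the loading control, normalised to the
  wild-type group mean.
- MRI morphometry: structure volumes normalised by whole-brain volume, with
  per-structure two-sample t-tests and Benjamini-Hochberg correction.
- Behaviour: the Shapiro-Wilk / Brown-Forsythe gated decision tree between
  one-way ANOVA (with Fisher's LSD post-hoc when the omnibus F passes 0.05)
  and Kruskal-Wallis, plus the one-sample test of novel-object preference
  against the 50% chance level.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


# --------------------------------------------------------------------- qPCR


def comparative_ct(ct: pd.DataFrame, efficiency: float = 2.0) -> pd.DataFrame:
    """Relative quantities from cycle thresholds: E^(Ct_min(gene) - Ct).

    ``ct`` is tidy with columns (sample, gene, ct) plus any metadata, which is
    carried through. The best-expressed sample of each gene gets quantity 1.
    """
    if efficiency <= 1.0:
        raise ValueError("amplification efficiency must exceed 1")
    if ct["ct"].isna().any():
        raise ValueError("missing Ct values")
    out = ct.copy()
    ct_min = out.groupby("gene")["ct"].transform("min")
    out["quantity"] = efficiency ** (ct_min - out["ct"])
    return out


@dataclass
class GenormResult:
    m_values: pd.Series          # initial stability M per candidate
    selected: list[str]          # references kept
    normalization_factor: pd.Series  # per-sample geometric mean of kept refs
    exclusion_order: list[str] = field(default_factory=list)


def _genorm_m(quant: pd.DataFrame) -> pd.Series:
    """Mean pairwise stability M_j = mean over k != j of
    SD_samples(log2 q_j/q_k)."""
    logs = np.log2(quant)
    genes = list(quant.columns)
    m = {}
    for j in genes:
        vs = [logs[j].sub(logs[k]).std(ddof=1) for k in genes if k != j]
        m[j] = float(np.mean(vs))
    return pd.Series(m)


def genorm_select(
    quantities: pd.DataFrame, n_keep: int = 2, m_threshold: float = 0.5
) -> GenormResult:
    """geNorm reference selection: iteratively drop the least stable candidate.

    ``quantities`` is samples x candidate genes (relative quantities, > 0).
    Candidates are removed (highest M first) until ``n_keep`` remain or every
    remaining M is below ``m_threshold``. The normalisation factor is the
    per-sample geometric mean of the kept references.
    """
    if quantities.shape[1] < 3:
        raise ValueError("need at least 3 candidate reference genes")
    if quantities.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if (quantities <= 0).any().any():
        raise ValueError("zero or negative quantity: log-ratio undefined")
    initial_m = _genorm_m(quantities)
    current = quantities.copy()
    excluded: list[str] = []
    while current.shape[1] > max(n_keep, 2):
        m = _genorm_m(current)
        if m.max() < m_threshold:
            break
        worst = m.sort_values(ascending=False).index[0]
        excluded.append(str(worst))
        current = current.drop(columns=worst)
    kept = list(current.columns)
    nf = np.exp(np.log(current).mean(axis=1))
    return GenormResult(
        m_values=initial_m,
        selected=kept,
        normalization_factor=nf,
        exclusion_order=excluded,
    )


def fold_induction(
    table: pd.DataFrame,
    quantity_col: str = "normalized_quantity",
    baseline_condition: str = "dark",
) -> pd.DataFrame:
    """Fold induction relative to the dark-housed mean of the same genotype.

    ``table`` is tidy with columns (sample, genotype, condition, gene,
    <quantity_col>). Adds ``fold_induction`` per row; group summaries (mean,
    SEM) come from :func:`induction_summary`.
    """
    out = table.copy()
    base = (
        out[out["condition"] == baseline_condition]
        .groupby(["genotype", "gene"])[quantity_col]
        .mean()
        .rename("baseline")
    )
    out = out.merge(base, left_on=["genotype", "gene"], right_index=True, how="left")
    if out["baseline"].isna().any():
        missing = out.loc[out["baseline"].isna(), ["genotype", "gene"]].drop_duplicates()
        raise ValueError(f"no dark-housed baseline for: {missing.to_dict('records')}")
    out["fold_induction"] = out[quantity_col] / out["baseline"]
    return out.drop(columns="baseline")


def induction_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Mean and SEM of fold induction per (genotype, condition, gene)."""
    g = table.groupby(["genotype", "condition", "gene"])["fold_induction"]
    return g.agg(mean="mean", sem=lambda x: x.std(ddof=1) / math.sqrt(len(x))).reset_index()


# ------------------------------------------------------------- western blot


def wb_relative(
    signal: pd.Series, loading: pd.Series, wt_samples: list[str]
) -> pd.Series:
    """(signal / loading control) normalised to the wild-type group mean.

    The wild-type group mean of the output is 1 by construction.
    """
    if (loading <= 0).any():
        raise ValueError("loading control signal must be positive")
    missing = [s for s in wt_samples if s not in signal.index]
    if missing or not wt_samples:
        raise ValueError("empty or invalid wild-type group")
    ratio = signal / loading
    wt_mean = ratio.loc[wt_samples].mean()
    if wt_mean == 0:
        raise ValueError("wild-type mean ratio is zero")
    return ratio / wt_mean


# ---------------------------------------------------------------------- MRI


def normalized_volumes(
    volumes: pd.DataFrame, whole_brain_col: str = "whole_brain"
) -> pd.DataFrame:
    """Structure volume / whole-brain volume per animal."""
    structures = [
        c for c in volumes.columns if c not in ("animal", "group", whole_brain_col)
    ]
    out = volumes[["animal", "group"]].copy()
    for s in structures:
        ratio = volumes[s] / volumes[whole_brain_col]
        if (ratio > 1).any():
            raise ValueError(f"structure {s!r} larger than the whole brain")
        out[s] = ratio
    return out


def mri_compare(
    volumes: pd.DataFrame,
    group_col: str = "group",
    whole_brain_col: str = "whole_brain",
) -> pd.DataFrame:
    """Per-structure Student t-test on normalised volumes with BH correction."""
    norm = normalized_volumes(volumes, whole_brain_col)
    groups = sorted(norm[group_col].unique())
    if len(groups) != 2:
        raise ValueError("expected exactly two groups")
    a, b = groups
    if (norm[group_col] == a).sum() < 2 or (norm[group_col] == b).sum() < 2:
        raise ValueError("need at least 2 animals per group")
    structures = [c for c in norm.columns if c not in ("animal", group_col)]
    rows = []
    for s in structures:
        x = norm.loc[norm[group_col] == a, s]
        y = norm.loc[norm[group_col] == b, s]
        t, p = stats.ttest_ind(x, y, equal_var=True)
        rows.append({"structure": s, "t": float(t), "p": float(p),
                     "mean_" + a: float(x.mean()), "mean_" + b: float(y.mean())})
    table = pd.DataFrame(rows)
    table["q"] = multipletests(table["p"], method="fdr_bh")[1]
    return table


# ---------------------------------------------------------------- behaviour


@dataclass
class BehaviourReport:
    measure: str
    test: str                 # 'anova' or 'kruskal'
    statistic: float
    p_value: float
    normality_p: dict[str, float]
    variance_p: float
    posthoc: pd.DataFrame | None
    notes: list[str] = field(default_factory=list)


def _fisher_lsd(values: list[np.ndarray], names: list[str]) -> pd.DataFrame:
    """Fisher's LSD: pairwise t-tests using the pooled ANOVA error term."""
    k = len(values)
    n_total = sum(len(v) for v in values)
    mse = sum(((v - v.mean()) ** 2).sum() for v in values) / (n_total - k)
    df = n_total - k
    rows = []
    for (i, a), (j, b) in itertools.combinations(enumerate(names), 2):
        x, y = values[i], values[j]
        se = math.sqrt(mse * (1 / len(x) + 1 / len(y)))
        t = (x.mean() - y.mean()) / se
        p = 2 * stats.t.sf(abs(t), df)
        rows.append({"group_a": a, "group_b": b, "t": float(t), "p": float(p)})
    return pd.DataFrame(rows)


def behaviour_stats(
    table: pd.DataFrame,
    measure: str,
    group_col: str = "group",
    alpha: float = 0.05,
) -> BehaviourReport:
    """Group comparison through the normality/homoscedasticity decision tree.

    Shapiro-Wilk per group and Brown-Forsythe across groups gate (at
    ``alpha``) the choice between one-way ANOVA and Kruskal-Wallis; Fisher's
    LSD post-hoc runs only when the ANOVA omnibus p < ``alpha``. Groups with
    fewer than 3 animals force the non-parametric path.
    """
    names = sorted(table[group_col].unique())
    if len(names) < 2:
        raise ValueError("need at least two groups")
    values = [table.loc[table[group_col] == g, measure].dropna().to_numpy() for g in names]
    notes: list[str] = []

    normality_p: dict[str, float] = {}
    parametric = True
    if any(len(v) < 3 for v in values):
        parametric = False
        notes.append("group with n < 3: non-parametric path forced")
        variance_p = float("nan")
    else:
        for g, v in zip(names, values):
            normality_p[g] = float(stats.shapiro(v).pvalue) if len(set(v)) > 1 else 0.0
        variance_p = float(stats.levene(*values, center="median").pvalue)
        parametric = all(p >= alpha for p in normality_p.values()) and variance_p >= alpha

    posthoc = None
    if parametric:
        stat, p = stats.f_oneway(*values)
        test = "anova"
        if p < alpha:
            posthoc = _fisher_lsd(values, names)
    else:
        stat, p = stats.kruskal(*values)
        test = "kruskal"
    return BehaviourReport(
        measure=measure,
        test=test,
        statistic=float(stat),
        p_value=float(p),
        normality_p=normality_p,
        variance_p=variance_p,
        posthoc=posthoc,
        notes=notes,
    )


def nor_chance_test(novel_pct: pd.Series | np.ndarray, chance: float = 50.0) -> tuple[float, float]:
    """Two-sided one-sample t-test of novel-object sniffing % against chance."""
    t, p = stats.ttest_1samp(np.asarray(novel_pct, dtype=float), chance)
    return float(t), float(p)
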