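"""Trisomic-gene bookkeeping: EG/DEG/TEG classification, dosage-compensation
percentages, cross-model fold-change correlation, DEG overlaps and sample
embeddings.

Terminology (following the field's usage for segmental-duplication panels):
EG = expressed gene; DEG = differentially expressed gene; TEG = trisomic
expressed gene, i.e. an EG lying inside a model's duplicated interval; a
"differential TEG" is a TEG that is also called DE. A TEG that is *not*
called DE despite the extra copy is dosage-compensated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_score

from .dge import FcrosResult
from .expression import ExpressionMatrix
from .synthetic_data import GenomeAnnotation, TrisomyModelSpec


@dataclass
class GeneClassification:
    """Per-gene flags for one model: expressed, deg, in_trisomic_region,
    teg (= expressed & in region), differential_teg (= teg & deg)."""

    model: str
    table: pd.DataFrame

    @property
    def n_teg(self) -> int:
        return int(self.table["teg"].sum())

    @property
    def n_differential_teg(self) -> int:
        return int(self.table["differential_teg"].sum())


@dataclass
class CompensationSummary:
    model: str
    n_teg: int
    n_differential_teg: int
    pct_differential: int
    pct_compensated: int


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero (printed-table
    convention; Python's round() would give banker's rounding)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def classify_genes(
    genome: GenomeAnnotation,
    model: TrisomyModelSpec,
    expressed: Iterable[str],
    degs: Iterable[str],
) -> GeneClassification:
    """Build the complete per-gene flag table for one model."""
    gene_ids = genome.gene_ids
    known = set(gene_ids)
    deg_set = set(degs)
    offenders = sorted(deg_set - known)
    if offenders:
        raise ValueError(f"DEG ids absent from the annotation: {offenders}")
    expressed_set = set(expressed) & known
    cis = set(model.cis_genes(genome))
    table = pd.DataFrame(index=gene_ids)
    table["expressed"] = [g in expressed_set for g in gene_ids]
    table["deg"] = [g in deg_set for g in gene_ids]
    table["in_trisomic_region"] = [g in cis for g in gene_ids]
    table["teg"] = table["expressed"] & table["in_trisomic_region"]
    table["differential_teg"] = table["teg"] & table["deg"]
    return GeneClassification(model=model.name, table=table)


def compensation_fraction(
    c: GeneClassification | tuple[int, int], model: str = ""
) -> CompensationSummary:
    """Dosage-compensation percentages from TEG counts.

    Accepts either a classification or a raw ``(n_teg, n_differential_teg)``
    pair. pct_differential = round(100 * differential / TEG), halves away from
    zero; pct_compensated is its complement to 100.
    """
    if isinstance(c, GeneClassification):
        n_teg, n_diff = c.n_teg, c.n_differential_teg
        model = model or c.model
    else:
        n_teg, n_diff = c
    if n_teg < 1:
        raise ValueError("compensation undefined: model has no TEGs")
    if n_diff > n_teg:
        raise ValueError("differential TEGs exceed TEGs")
    pct = round_half_away(100.0 * n_diff / n_teg)
    return CompensationSummary(
        model=model,
        n_teg=n_teg,
        n_differential_teg=n_diff,
        pct_differential=pct,
        pct_compensated=100 - pct,
    )


def cross_model_fc_correlation(
    results: Mapping[str, FcrosResult],
    universe: Iterable[str] | None = None,
    method: str = "pearson",
) -> pd.DataFrame:
    """Pairwise correlation of per-gene log2 fold changes between models.

    ``universe`` defaults to the union of all models' DEGs. Returns the
    correlation matrix (r in [-1, 1]); multiply by 100 for the percentage
    convention used when reporting.
    """
    if len(results) < 2:
        raise ValueError("need at least two models")
    if universe is None:
        universe_idx: pd.Index = pd.Index([])
        for r in results.values():
            universe_idx = universe_idx.union(r.degs)
    else:
        universe_idx = pd.Index(universe)
    common = universe_idx
    for r in results.values():
        common = common.intersection(r.table.index)
    if len(common) < 3:
        raise ValueError("fold-change universe has fewer than 3 measured genes")
    fc = pd.DataFrame({name: r.table.loc[common, "log2fc"] for name, r in results.items()})
    return fc.corr(method=method)


def deg_overlap(deg_sets: Mapping[str, Iterable[str]]) -> dict[str, int]:
    """Counts for every exclusive region of the Venn partition of DEG sets.

    Keys are '&'-joined sorted model names for the region where exactly those
    models (and no others) contain the gene, plus a 'union' entry.
    """
    sets = {name: set(v) for name, v in deg_sets.items()}
    if len(sets) < 2:
        raise ValueError("need at least two DEG sets")
    names = sorted(sets)
    union = set().union(*sets.values())
    out: dict[str, int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set().union(*(sets[n] for n in names if n not in combo), set())
            out["&".join(combo)] = len(inside - outside)
    out["union"] = len(union)
    return out


def sample_embedding(
    X: ExpressionMatrix,
    genes: Iterable[str] | None = None,
    method: str = "pca",
    n_components: int = 2,
    seed: int = 0,
) -> tuple[pd.DataFrame, float]:
    """Embed samples (PCA or t-SNE) on a gene subset and score the genotype
    separation with the silhouette coefficient.

    Returns (coordinates per sample, silhouette score).
    """
    values = X.values if genes is None else X.values.loc[list(genes)]
    data = values.T.to_numpy()  # samples x genes
    n_samples = data.shape[0]
    if n_samples < 4:
        raise ValueError("need at least 4 samples")
    if n_components >= n_samples:
        raise ValueError("fewer samples than requested components")
    if method == "pca":
        coords = PCA(n_components=n_components, random_state=seed).fit_transform(data)
    elif method == "tsne":
        coords = TSNE(
            n_components=n_components,
            random_state=seed,
            perplexity=min(5.0, (n_samples - 1) / 2),
            init="pca",
        ).fit_transform(data)
    else:
        raise ValueError("method must be 'pca' or 'tsne'")
    labels = X.groups.to_numpy()
    sil = float(silhouette_score(coords, labels)) if len(np.unique(labels)) > 1 else float("nan")
    frame = pd.DataFrame(
        coords, index=values.columns, columns=[f"dim{i+1}" for i in range(n_components)]
    )
    frame["genotype"] = X.groups.values
    return frame, sil


def table1_summary(
    classifications: Mapping[str, GeneClassification]
) -> pd.DataFrame:
    """Per-model summary mirroring the bookkeeping table: TEG counts, DEG
    counts, differential TEGs and compensation percentages."""
    rows = []
    for name, c in classifications.items():
        row = {
            "model": name,
            "n_teg": c.n_teg,
            "n_deg": int(c.table["deg"].sum()),
            "n_differential_teg": c.n_differential_teg,
            "pct_differential_teg": pd.NA,
            "pct_compensated": pd.NA,
        }
        if c.n_teg > 0:  # compensation is undefined for a TEG-free model
            summ = compensation_fraction(c)
            row["pct_differential_teg"] = summ.pct_differential
            row["pct_compensated"] = summ.pct_compensated
        rows.append(row)
    return pd.DataFrame(rows).set_index("model")
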