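"""Log2 expression matrix container shared by all analysis stages.

The matrix holds log2 intensities with genes as rows and samples as columns,
plus a genotype label ("control" / "trisomic") per sample. All differential
expression in this package is ratio-based, so values are kept on the log2
scale throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CONTROL = "control"
TRISOMIC = "trisomic"


@dataclass
class ExpressionMatrix:
    """Genes x samples log2 intensity matrix with a two-group design.

    Parameters
    ----------
    values
        DataFrame of log2 intensities, index = gene ids, columns = sample ids.
    groups
        Series mapping each sample id to ``"control"`` or ``"trisomic"``.
    """

    values: pd.DataFrame
    groups: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if not self.values.index.is_unique:
            raise ValueError("gene ids are not unique")
        self.groups = self.groups.reindex(self.values.columns)
        if self.groups.isna().any():
            missing = list(self.values.columns[self.groups.isna()])
            raise ValueError(f"samples missing a group label: {missing}")
        bad = set(self.groups.unique()) - {CONTROL, TRISOMIC}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        for label in (CONTROL, TRISOMIC):
            if (self.groups == label).sum() < 2:
                raise ValueError(f"group {label!r} has fewer than 2 samples")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    def samples(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])

    @property
    def control_samples(self) -> list[str]:
        return self.samples(CONTROL)

    @property
    def trisomic_samples(self) -> list[str]:
        return self.samples(TRISOMIC)

    # ------------------------------------------------------------------ I/O

    def to_tsv(self, expr_path: str | Path, sample_path: str | Path) -> None:
        """Write the matrix and its sample sheet as plain TSV files."""
        self.values.rename_axis("gene_id").to_csv(expr_path, sep="\t")
        (
            self.groups.rename("genotype")
            .rename_axis("sample")
            .to_frame()
            .to_csv(sample_path, sep="\t")
        )

    @classmethod
    def from_tsv(cls, expr_path: str | Path, sample_path: str | Path) -> "ExpressionMatrix":
        values = pd.read_csv(expr_path, sep="\t", index_col=0)
        sheet = pd.read_csv(sample_path, sep="\t", index_col=0)
        if "genotype" not in sheet.columns:
            raise ValueError("sample sheet needs a 'genotype' column")
        return cls(values=values, groups=sheet["genotype"])


def expressed_genes(X: ExpressionMatrix, threshold: float | None = None) -> pd.Index:
    """Genes whose mean log2 intensity exceeds a detection threshold.

    The microarray detection rule is a free choice here: by default the
    threshold is the matrix-wide 10th percentile of per-gene means, so ~90%
    of simulated genes count as expressed (EGs).
    """
    means = X.values.mean(axis=1)
    if threshold is None:
        threshold = float(np.percentile(means, 10.0))
    return X.gene_ids[means > threshold]
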