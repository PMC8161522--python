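"""Gene-set directional enrichment and meta-pathway aggregation.

The enrichment statistic follows the GAGE recipe for two-group designs: for
each of the k test/control sample pairs, the log2 fold changes of a set's
members are compared against all other measured genes with an
unequal-variance two-sample t-test; one-sided p-values (up and down) are
combined across the k pairs with Stouffer's method (with a correction for
the dependence induced by shared samples, see below); Benjamini–Hochberg
adjustment is applied across all sets within a model and a set is called
significant below a q cutoff (default 0.1) in the direction of the smaller
combined p.

Significant pathways are then aggregated into ten broad "meta-pathways"
(ribosome, mitochondria, synaptic function, ...) by ordered keyword rules,
yielding a signed count matrix (up-count / down-count per group and model).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

UP = "up"
DOWN = "down"
NONE = "none"


@dataclass
class GeneSet:
    name: str
    members: list[str]
    source: str = "custom"

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} has no members")


def read_gmt(path: str | Path, source: str = "custom") -> list[GeneSet]:
    """Load gene sets from a GMT file (gseapy parser underneath)."""
    from gseapy.parser import read_gmt as _read_gmt  # heavy import, keep lazy

    return [GeneSet(name=k, members=list(v), source=source) for k, v in _read_gmt(str(path)).items()]


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    lines = ["\t".join([s.name, s.source] + list(s.members)) for s in sets]
    Path(path).write_text("\n".join(lines) + "\n")


# ------------------------------------------------------------------ testing


import re

_PAIR_COL = re.compile(r"^c(\d+)_t(\d+)$")


def _stouffer_denominator(columns: Iterable[str]) -> float:
    """Variance of the sum of per-pair z-scores under the complete null.

    All-pairs fold changes reuse samples: two pairs sharing exactly one
    sample (the same control or the same test animal) have correlation 1/2
    under i.i.d. noise, so Var(sum z) = sum over pair pairs of their
    correlation rather than k. Columns named like ``c1_t2`` (the
    pairwise_fold_changes convention) carry the design; anything else is
    treated as independent replicates.
    """
    parsed = [_PAIR_COL.match(str(c)) for c in columns]
    if any(p is None for p in parsed):
        return float(np.sqrt(len(parsed)))
    ids = [(p.group(1), p.group(2)) for p in parsed]  # type: ignore[union-attr]
    total = 0.0
    for a, (ca, ta) in enumerate(ids):
        for cb, tb in ids:
            shared = (ca == cb) + (ta == tb)
            total += 1.0 if shared == 2 else (0.5 if shared == 1 else 0.0)
    return float(np.sqrt(total))


def _pair_t_stats(fc: np.ndarray, member_mask: np.ndarray) -> np.ndarray:
    """Welch t statistic (set members vs all other genes) for each pair
    (column) of the fold-change matrix. Vectorised over columns."""
    set_fc = fc[member_mask]
    rest_fc = fc[~member_mask]
    n1, n2 = set_fc.shape[0], rest_fc.shape[0]
    m1, m2 = set_fc.mean(axis=0), rest_fc.mean(axis=0)
    v1 = set_fc.var(axis=0, ddof=1)
    v2 = rest_fc.var(axis=0, ddof=1)
    denom = np.sqrt(v1 / n1 + v2 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, (m1 - m2) / denom, 0.0)
    return t


def gage_test(FC: pd.DataFrame, gene_set: GeneSet) -> dict:
    """GAGE-style directional test of one set against the genome background.

    Returns a dict with mean_stat, p_up, p_down, direction (set later by the
    q filter), n_members (measured) and a too_small flag.
    """
    member_mask = FC.index.isin(gene_set.members)
    n_members = int(member_mask.sum())
    if n_members < 2:
        return {
            "set": gene_set.name,
            "mean_stat": np.nan,
            "p_up": 1.0,
            "p_down": 1.0,
            "n_members": n_members,
            "too_small": True,
        }
    if n_members > FC.shape[0] // 2:
        raise ValueError(f"set {gene_set.name!r} covers more than half the universe")
    fc = FC.to_numpy()
    if (~member_mask).sum() < 2:
        t = np.zeros(FC.shape[1])
    else:
        t = _pair_t_stats(fc, member_mask)
    # one-sided p per pair; Welch df collapses to the member count - 1 when
    # the background is much larger than the set
    df = max(n_members - 1, 1)
    p_up = stats.t.sf(t, df)
    p_down = stats.t.cdf(t, df)
    z_up = stats.norm.isf(np.clip(p_up, 1e-300, 1.0))
    z_down = stats.norm.isf(np.clip(p_down, 1e-300, 1.0))
    denom = _stouffer_denominator(FC.columns)
    return {
        "set": gene_set.name,
        "mean_stat": float(t.mean()),
        "p_up": float(stats.norm.sf(z_up.sum() / denom)),
        "p_down": float(stats.norm.sf(z_down.sum() / denom)),
        "n_members": n_members,
        "too_small": False,
    }


def gage_analysis(
    FC: pd.DataFrame, sets: Iterable[GeneSet], q_cutoff: float = 0.1
) -> pd.DataFrame:
    """Run the set test for a collection and BH-adjust across sets.

    The BH input is the two-sided combined p (twice the smaller of the up /
    down Stouffer p-values, clipped at 1); direction is 'up'/'down' for sets
    with q < q_cutoff, 'none' otherwise.
    """
    rows = [gage_test(FC, s) for s in sets]
    table = pd.DataFrame(rows).set_index("set")
    p_two = np.clip(2.0 * np.minimum(table["p_up"], table["p_down"]), 0.0, 1.0)
    testable = ~table["too_small"]
    q = pd.Series(np.nan, index=table.index)
    if testable.any():
        q[testable] = multipletests(p_two[testable], method="fdr_bh")[1]
    table["p_two"] = p_two
    table["q"] = q
    sig = testable & (table["q"] < q_cutoff)
    table["direction"] = np.where(
        sig, np.where(table["p_up"] < table["p_down"], UP, DOWN), NONE
    )
    return table


# ------------------------------------------------------------ meta-pathways

# Ten broad functional groups with ordered keyword rules; a pathway name is
# assigned to the first group whose keyword it contains (case-insensitive).
# The grouping is a best-effort reconstruction of the usual hippocampal
# meta-pathway panels and is fully editable/shippable as config.
DEFAULT_META_MAP: list[tuple[str, list[str]]] = [
    ("Myelin & SNARE", ["myelin", "snare"]),
    ("Synaptic related", ["synap", "neurotransmitter", "dendrit", "axon", "glutamate", "gaba", "potentiation"]),
    ("Interferon related", ["interferon", "ifn", "jak-stat"]),
    ("Ribosome related", ["ribosom", "translation", "rrna"]),
    ("Mitochondria related", ["mitochond", "respirat", "oxidative phosphorylation", "atp synthesis"]),
    ("Transcription & epigenomics regulation", ["transcription", "chromatin", "histone", "methylation", "epigen", "dna binding"]),
    ("Phospho-kinase related", ["kinase", "phosphatase", "phosphorylation", "signaling cascade"]),
    ("Cell structure & organelle related", ["cytoskeleton", "organelle", "golgi", "endoplasmic", "lysosome", "peroxisome", "membrane", "vesicle", "cell junction"]),
    ("Enzyme activity", ["enzyme", "catalytic", "hydrolase", "transferase", "oxidoreductase", "protease"]),
    ("Metabolism related", ["metabol", "biosynth", "glycol", "lipid"]),
]


@dataclass
class MetaPathwayMap:
    """Ordered keyword rules mapping pathway names to meta-pathway groups."""

    rules: list[tuple[str, list[str]]] = field(default_factory=lambda: list(DEFAULT_META_MAP))

    @property
    def groups(self) -> list[str]:
        return [g for g, _ in self.rules]

    def assign(self, pathway_name: str) -> str | None:
        low = pathway_name.lower()
        for group, keywords in self.rules:
            if any(kw in low for kw in keywords):
                return group
        return None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MetaPathwayMap":
        import yaml

        payload = yaml.safe_load(Path(path).read_text())
        return cls(rules=[(e["group"], list(e["keywords"])) for e in payload])

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        payload = [{"group": g, "keywords": kws} for g, kws in self.rules]
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def assign_meta_pathways(
    results: Mapping[str, pd.DataFrame], meta_map: MetaPathwayMap | None = None
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Aggregate significant pathways into meta-pathway up/down counts.

    ``results`` maps model name -> gage_analysis table. Returns the count
    matrix (rows = meta groups, MultiIndex columns (model, 'up'/'down')) and
    the significant-but-unmapped pathway names per model.
    """
    meta_map = meta_map or MetaPathwayMap()
    groups = meta_map.groups
    cols = pd.MultiIndex.from_product([list(results), [UP, DOWN]], names=["model", "direction"])
    matrix = pd.DataFrame(0, index=pd.Index(groups, name="meta_pathway"), columns=cols)
    unmapped: dict[str, list[str]] = {}
    for model, table in results.items():
        unmapped[model] = []
        sig = table[table["direction"] != NONE]
        for name, row in sig.iterrows():
            group = meta_map.assign(str(name))
            if group is None:
                unmapped[model].append(str(name))
            else:
                matrix.loc[group, (model, row["direction"])] += 1
    return matrix, unmapped


def core_members(
    FC: pd.DataFrame, gene_set: GeneSet, direction: str
) -> set[str]:
    """Members driving a significant set's signal: measured members whose mean
    log2FC has the set's direction and magnitude above the set median."""
    members = [g for g in gene_set.members if g in FC.index]
    mean_fc = FC.loc[members].mean(axis=1)
    signed = mean_fc if direction == UP else -mean_fc
    cutoff = signed.median()
    return set(signed.index[(signed > 0) & (signed >= cutoff)])


def intermodel_connectivity(
    results: Mapping[str, pd.DataFrame],
    fcs: Mapping[str, pd.DataFrame],
    sets: Iterable[GeneSet],
    meta_map: MetaPathwayMap | None = None,
) -> dict[str, dict[tuple[str, str], set[str]]]:
    """Genes shared between the significant pathways of two models inside the
    same meta-pathway (core members in both models)."""
    meta_map = meta_map or MetaPathwayMap()
    sets_by_name = {s.name: s for s in sets}
    models = list(results)
    if len(models) < 2:
        raise ValueError("need at least two models")
    core: dict[str, dict[str, set[str]]] = {m: {} for m in models}  # model -> group -> genes
    for model in models:
        table = results[model]
        for name, row in table[table["direction"] != NONE].iterrows():
            group = meta_map.assign(str(name))
            if group is None or str(name) not in sets_by_name:
                continue
            genes = core_members(fcs[model], sets_by_name[str(name)], row["direction"])
            core[model].setdefault(group, set()).update(genes)
    out: dict[str, dict[tuple[str, str], set[str]]] = {}
    for group in meta_map.groups:
        per_pair: dict[tuple[str, str], set[str]] = {}
        for i, a in enumerate(models):
            for b in models[i + 1 :]:
                shared = core[a].get(group, set()) & core[b].get(group, set())
                per_pair[(a, b)] = shared
        out[group] = per_pair
    return out
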