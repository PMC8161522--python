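"""Synthetic study generator for segmental-duplication trisomy experiments.

Emulates the structure of a hippocampal expression screen across a panel of
overlapping trisomy mouse models: an annotated genome, a set of duplicated
intervals per model, per-model log2 expression matrices with ~1.5x cis dosage
and partial compensation, genome-wide trans effects partly shared between
models with overlapping intervals, a confidence-scored interaction network
with planted functional seed modules, and already-quantified phenotype tables
(qPCR Ct, western-blot signals, MRI volumes, behaviour scores).

Every generator takes an explicit seed and is deterministic given it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .expression import CONTROL, TRISOMIC, ExpressionMatrix

# truth labels for simulated genes
LABEL_CIS = "cis-effect"
LABEL_COMPENSATED = "cis-compensated"
LABEL_TRANS = "trans-effect"
LABEL_NULL = "null"


# --------------------------------------------------------------------- types


@dataclass
class GenomeAnnotation:
    """Gene coordinate table: gene_id, chromosome, start, end (1-based bp)."""

    genes: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"gene_id", "chromosome", "start", "end"}
        if not required.issubset(self.genes.columns):
            raise ValueError(f"annotation needs columns {sorted(required)}")
        if self.genes["gene_id"].duplicated().any():
            raise ValueError("gene ids are not unique")
        if (self.genes["start"] > self.genes["end"]).any():
            raise ValueError("gene with start > end")
        self.genes = self.genes.reset_index(drop=True)

    @property
    def gene_ids(self) -> pd.Index:
        return pd.Index(self.genes["gene_id"])

    def genes_in_interval(self, chromosome: str, start: int, end: int) -> list[str]:
        """Genes whose start lies within the closed interval (membership rule
        used pipeline-wide)."""
        g = self.genes
        hit = (g["chromosome"] == chromosome) & (g["start"] >= start) & (g["start"] <= end)
        return list(g.loc[hit, "gene_id"])

    def to_tsv(self, path: str | Path) -> None:
        self.genes.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenomeAnnotation":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass
class TrisomyModelSpec:
    """A trisomy model: named set of duplicated genomic intervals.

    ``nonsyntenic_intervals`` emulates extra triplicated material outside the
    region of interest (the Ts65Dn minichromosome situation); genes there are
    still cis genes of the model.
    """

    name: str
    duplicated_intervals: list[tuple[str, int, int]]
    copy_number: int = 3
    nonsyntenic_intervals: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.copy_number < 2:
            raise ValueError("copy_number must be >= 2")
        for chrom, start, end in self.all_intervals():
            if start > end:
                raise ValueError(f"degenerate interval on {chrom}: {start} > {end}")

    def all_intervals(self) -> list[tuple[str, int, int]]:
        return list(self.duplicated_intervals) + list(self.nonsyntenic_intervals)

    def cis_genes(self, genome: GenomeAnnotation) -> list[str]:
        """Genes inside any duplicated interval of this model (sorted, unique)."""
        chroms = set(genome.genes["chromosome"])
        out: set[str] = set()
        for chrom, start, end in self.all_intervals():
            if chrom not in chroms:
                raise ValueError(f"model {self.name}: unknown chromosome {chrom!r}")
            out.update(genome.genes_in_interval(chrom, start, end))
        return sorted(out)


@dataclass
class ExpressionDesign:
    """Parameters of the simulated two-group expression experiment.

    Defaults mirror the study conditions this generator emulates: 5 animals
    per group, cis genes at a 1.5x linear dosage ratio with ~45% compensation,
    a few hundred genome-wide trans effects, and array-like log2 noise.
    """

    n_control: int = 5
    n_trisomic: int = 5
    baseline_mean: float = 7.0
    baseline_sd: float = 2.0
    noise_sd: float = 0.15
    dosage_ratio: float = 1.5
    compensation_prob: float = 0.45
    n_trans_effects: int = 300
    trans_effect_sd: float = 0.3
    shared_program_fraction: float = 0.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control < 2 or self.n_trisomic < 2:
            raise ValueError("need at least 2 samples per group")
        if self.dosage_ratio <= 0:
            raise ValueError("dosage_ratio must be positive")
        for name in ("compensation_prob", "shared_program_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.noise_sd < 0 or self.trans_effect_sd < 0 or self.baseline_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.n_trans_effects < 0:
            raise ValueError("n_trans_effects must be >= 0")


class SimulatedExpression(NamedTuple):
    matrix: ExpressionMatrix
    truth: pd.DataFrame  # gene_id, label, effect (log2 shift applied)


# ------------------------------------------------------------------- genome


def generate_genome(n_genes: int, n_chromosomes: int, seed: int) -> GenomeAnnotation:
    """Evenly spread ``n_genes`` over ``n_chromosomes`` with sorted,
    non-overlapping coordinates."""
    if n_genes < 1 or n_chromosomes < 1:
        raise ValueError("counts must be positive")
    if n_genes < n_chromosomes:
        raise ValueError("need at least one gene per chromosome")
    rng = np.random.default_rng(seed)
    per = [n_genes // n_chromosomes] * n_chromosomes
    for i in range(n_genes % n_chromosomes):
        per[i] += 1
    rows = []
    gid = 0
    for c, count in enumerate(per, start=1):
        pos = 1
        for _ in range(count):
            gap = int(rng.integers(1_000, 50_000))
            length = int(rng.integers(1_000, 100_000))
            start = pos + gap
            end = start + length
            rows.append((f"g{gid:05d}", f"chr{c}", start, end))
            pos = end
            gid += 1
    return GenomeAnnotation(pd.DataFrame(rows, columns=["gene_id", "chromosome", "start", "end"]))


# -------------------------------------------------------------- model panel


def _span(genome: GenomeAnnotation, chrom: str, lo_frac: float, hi_frac: float) -> tuple[str, int, int]:
    """Closed interval covering the gene-start span between two quantile
    positions of a chromosome's gene list."""
    g = genome.genes[genome.genes["chromosome"] == chrom].sort_values("start")
    n = len(g)
    lo = min(int(lo_frac * n), n - 1)
    hi = min(int(hi_frac * n), n - 1)
    if hi < lo:
        raise ValueError("empty span")
    return (chrom, int(g.iloc[lo]["start"]), int(g.iloc[hi]["start"]))


def generate_model_panel(
    genome: GenomeAnnotation, layout: list[dict] | None = None
) -> list[TrisomyModelSpec]:
    """Build a panel of overlapping / nested trisomy models.

    The default layout mirrors the classic segmental-duplication panel on the
    region of interest (here chr1): one full-span model (Dp1Yey-like)
    containing three sub-span models (Dp3Yah-, Dp5Yah-, Dp1Rhr-like), a
    compound model equal to the union of two sub-spans (Dp5/Dp1-like), a
    single-gene transgenic model (Tg(Dyrk1a)-like) and a composite model that
    also carries a non-syntenic interval on another chromosome (Ts65Dn-like).

    A custom ``layout`` is a list of dicts with keys ``name``,
    ``intervals`` ([(chrom, start, end), ...]) and optionally
    ``nonsyntenic`` intervals and ``copy_number``.
    """
    if layout is not None:
        models = []
        chrom_bounds = {
            chrom: (int(g["start"].min()), int(g["end"].max()))
            for chrom, g in genome.genes.groupby("chromosome")
        }
        for entry in layout:
            for chrom, start, end in entry["intervals"] + entry.get("nonsyntenic", []):
                if chrom not in chrom_bounds:
                    raise ValueError(f"layout interval on unknown chromosome {chrom!r}")
                lo, hi = chrom_bounds[chrom]
                if end < lo or start > hi:
                    raise ValueError(
                        f"layout interval {chrom}:{start}-{end} outside genome bounds"
                    )
            models.append(
                TrisomyModelSpec(
                    name=entry["name"],
                    duplicated_intervals=[tuple(t) for t in entry["intervals"]],
                    copy_number=entry.get("copy_number", 3),
                    nonsyntenic_intervals=[tuple(t) for t in entry.get("nonsyntenic", [])],
                )
            )
        return models

    # The duplicated region is a small slice of one chromosome, as in real
    # panels (~10^2 region genes against ~10^4 measured genes).
    chrom = "chr1"
    full = _span(genome, chrom, 0.020, 0.080)
    prox = _span(genome, chrom, 0.020, 0.034)  # proximal sub-region
    mid = _span(genome, chrom, 0.038, 0.055)   # middle sub-region
    dist = _span(genome, chrom, 0.060, 0.076)  # distal sub-region (critical region)
    tel = _span(genome, chrom, 0.038, 0.080)   # telomeric part carried by the composite
    single = _span(genome, chrom, 0.070, 0.070)  # one driver gene inside the distal region
    n_chr2 = (genome.genes["chromosome"] == "chr2").sum()
    nonsyn = [_span(genome, "chr2", 0.0, 0.012)] if n_chr2 else []
    return [
        TrisomyModelSpec("Dp1Yey", [full]),
        TrisomyModelSpec("Dp3Yah", [prox]),
        TrisomyModelSpec("Ts65Dn", [tel], nonsyntenic_intervals=nonsyn),
        TrisomyModelSpec("Dp5/Dp1", [mid, dist]),
        TrisomyModelSpec("Dp5Yah", [mid]),
        TrisomyModelSpec("Dp1Rhr", [dist]),
        TrisomyModelSpec("Tg(Dyrk1a)", [single]),
    ]


def write_model_panel(models: list[TrisomyModelSpec], path: str | Path) -> None:
    payload = [
        {
            "name": m.name,
            "copy_number": m.copy_number,
            "intervals": [list(t) for t in m.duplicated_intervals],
            "nonsyntenic": [list(t) for t in m.nonsyntenic_intervals],
        }
        for m in models
    ]
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def read_model_panel(path: str | Path) -> list[TrisomyModelSpec]:
    payload = yaml.safe_load(Path(path).read_text())
    return [
        TrisomyModelSpec(
            name=e["name"],
            duplicated_intervals=[tuple(t) for t in e["intervals"]],
            copy_number=e.get("copy_number", 3),
            nonsyntenic_intervals=[tuple(t) for t in e.get("nonsyntenic", [])],
        )
        for e in payload
    ]


# --------------------------------------------------------------- expression


def _simulate_one(
    genome: GenomeAnnotation,
    model: TrisomyModelSpec,
    design: ExpressionDesign,
    rng: np.random.Generator,
    compensation_flags: pd.Series | None,
    shared_effects: list[tuple[str, float]],
) -> SimulatedExpression:
    gene_ids = genome.gene_ids
    m = len(gene_ids)
    cis = model.cis_genes(genome)
    cis_idx = pd.Index(cis)

    if compensation_flags is None:
        comp = pd.Series(rng.random(len(cis)) < design.compensation_prob, index=cis_idx)
    else:
        comp = compensation_flags.reindex(cis_idx).fillna(False).astype(bool)

    effect = pd.Series(0.0, index=gene_ids)
    label = pd.Series(LABEL_NULL, index=gene_ids)
    shift = math.log2(design.dosage_ratio)
    for g in cis:
        if comp[g]:
            label[g] = LABEL_COMPENSATED
        else:
            label[g] = LABEL_CIS
            effect[g] = shift

    # trans effects on non-cis genes: shared (gene, effect) draws first, then
    # private draws on genes untouched so far
    non_cis = [g for g in gene_ids if g not in set(cis)]
    taken = set(cis)
    n_shared = 0
    for g, e in shared_effects:
        if g in taken:
            continue
        effect[g] = e
        label[g] = LABEL_TRANS
        taken.add(g)
        n_shared += 1
    n_private = max(design.n_trans_effects - n_shared, 0)
    pool = [g for g in non_cis if g not in taken]
    if n_private > len(pool):
        raise ValueError("not enough non-cis genes for the requested trans effects")
    chosen = rng.choice(len(pool), size=n_private, replace=False) if n_private else []
    for i in chosen:
        g = pool[int(i)]
        effect[g] = rng.normal(0.0, design.trans_effect_sd)
        label[g] = LABEL_TRANS

    baseline = rng.normal(design.baseline_mean, design.baseline_sd, size=m)
    n_c, n_t = design.n_control, design.n_trisomic
    noise = rng.normal(0.0, design.noise_sd, size=(m, n_c + n_t))
    values = baseline[:, None] + noise
    values[:, n_c:] += effect.to_numpy()[:, None]

    columns = [f"wt_{i+1}" for i in range(n_c)] + [f"tg_{j+1}" for j in range(n_t)]
    groups = pd.Series([CONTROL] * n_c + [TRISOMIC] * n_t, index=columns)
    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=gene_ids, columns=columns), groups=groups
    )
    truth = pd.DataFrame(
        {"gene_id": gene_ids, "label": label.to_numpy(), "effect": effect.to_numpy()}
    )
    return SimulatedExpression(matrix, truth)


def simulate_expression(
    genome: GenomeAnnotation,
    model: TrisomyModelSpec,
    design: ExpressionDesign,
    seed: int | None = None,
) -> SimulatedExpression:
    """Simulate one model's log2 expression matrix plus ground-truth labels.

    Cis genes are shifted by log2(dosage_ratio) unless flagged compensated
    (probability ``compensation_prob``); ``n_trans_effects`` non-cis genes get
    Normal(0, trans_effect_sd) shifts; i.i.d. Normal(0, noise_sd) noise is
    added on the log2 scale.
    """
    rng = np.random.default_rng(design.rng_seed if seed is None else seed)
    return _simulate_one(genome, model, design, rng, None, [])


def simulate_panel(
    genome: GenomeAnnotation,
    models: list[TrisomyModelSpec],
    design: ExpressionDesign,
    seed: int | None = None,
) -> dict[str, SimulatedExpression]:
    """Simulate the whole model panel with shared structure across models.

    Two pieces of cross-model structure are planted: (i) compensation flags
    are drawn once per gene and shared by all models (compensated genes behave
    alike in every trisomic context); (ii) a global pool of trans
    (gene, effect) draws is reused between models in proportion to the overlap
    of their cis gene sets — a model reuses ``round(shared_program_fraction *
    o * n_trans_effects)`` pool entries, where ``o`` is the largest Jaccard
    overlap between its cis set and any other panel member's, so models with
    overlapping intervals share trans programs and cross-model fold-change
    correlation becomes a controllable generator parameter.
    """
    rng = np.random.default_rng(design.rng_seed if seed is None else seed)
    all_cis = {m.name: set(m.cis_genes(genome)) for m in models}
    union_cis = set().union(*all_cis.values()) if all_cis else set()
    comp_flags = pd.Series(
        rng.random(len(union_cis)) < design.compensation_prob, index=sorted(union_cis)
    )
    pool_genes = [g for g in genome.gene_ids if g not in union_cis]
    if design.n_trans_effects > len(pool_genes):
        raise ValueError("not enough non-cis genes for the requested trans effects")
    order = rng.choice(len(pool_genes), size=design.n_trans_effects, replace=False)
    pool = [
        (pool_genes[int(i)], float(rng.normal(0.0, design.trans_effect_sd))) for i in order
    ]

    out: dict[str, SimulatedExpression] = {}
    for model in models:
        o_max = 0.0
        for other in models:
            if other.name == model.name:
                continue
            a, b = all_cis[model.name], all_cis[other.name]
            if a or b:
                o_max = max(o_max, len(a & b) / len(a | b))
        n_shared = round(design.shared_program_fraction * o_max * design.n_trans_effects)
        out[model.name] = _simulate_one(
            genome, model, design, rng, comp_flags, pool[:n_shared]
        )
    return out


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- networks


def simulate_ppi(
    n_nodes: int,
    edges_per_node: int = 2,
    seed: int = 0,
    seed_clique_size: int = 0,
) -> tuple[nx.Graph, list[str]]:
    """Preferential-attachment interaction graph with confidence scores and an
    optionally planted, fully connected seed module.

    Returns the graph (nodes ``p0001``..., edge attribute ``confidence`` in
    [0, 1]) and the list of planted seed nodes.
    """
    if n_nodes < 3:
        raise ValueError("need at least 3 nodes")
    if seed_clique_size > n_nodes:
        raise ValueError("seed clique larger than the graph")
    rng = np.random.default_rng(seed)
    G0 = nx.barabasi_albert_graph(n_nodes, edges_per_node, seed=int(rng.integers(2**31)))
    names = {i: f"p{i:04d}" for i in G0.nodes}
    G = nx.relabel_nodes(G0, names)
    seeds: list[str] = []
    if seed_clique_size:
        picks = rng.choice(n_nodes, size=seed_clique_size, replace=False)
        seeds = sorted(names[int(i)] for i in picks)
        for i, u in enumerate(seeds):
            for v in seeds[i + 1 :]:
                G.add_edge(u, v)
    for u, v in G.edges:
        G.edges[u, v]["confidence"] = float(rng.uniform(0.4, 1.0))
    return G, seeds


def write_edge_table(G: nx.Graph, path: str | Path, scale: float = 1.0) -> None:
    """Write a STRING-style edge table (node_a, node_b, combined_score)."""
    rows = [
        (u, v, G.edges[u, v].get("confidence", 1.0) * scale)
        for u, v in sorted(G.edges)
    ]
    pd.DataFrame(rows, columns=["node_a", "node_b", "combined_score"]).to_csv(
        path, sep="\t", index=False
    )


# --------------------------------------------------------------- phenotypes


@dataclass
class PhenotypeDesign:
    """Group effects for the phenotype generators (0 = complete null)."""

    n_per_group: int = 10
    behaviour_effect: float = 0.0   # shift (in SD units) of the trisomic group
    behaviour_sd: float = 10.0      # SD of the behaviour percentage measures
    qpcr_induction_ct: float = 2.0  # Ct drop after light exposure (per step)
    qpcr_genotype_ct: float = 0.0   # extra Ct drop in trisomic animals
    mri_effect: dict[str, float] = field(default_factory=dict)  # structure -> fold
    mri_cv: float = 0.05
    n_structures: int = 8


def simulate_behaviour(design: PhenotypeDesign, seed: int, groups: tuple[str, ...] = ("wt", "tg")) -> pd.DataFrame:
    """Behaviour table: one row per animal with percentage-scale measures."""
    rng = np.random.default_rng(seed)
    rows = []
    for gi, group in enumerate(groups):
        shift = design.behaviour_effect * design.behaviour_sd if gi > 0 else 0.0
        for a in range(design.n_per_group):
            rows.append(
                {
                    "animal": f"{group}_{a+1}",
                    "group": group,
                    "alternation_pct": float(
                        np.clip(rng.normal(65 - shift, design.behaviour_sd), 0, 100)
                    ),
                    "arm_entries": float(max(rng.normal(25 + shift, 5), 0)),
                    "distance_cm": float(max(rng.normal(2500 + 40 * shift, 400), 0)),
                    "peripheral_pct": float(
                        np.clip(rng.normal(70 + shift, design.behaviour_sd), 0, 100)
                    ),
                    "novel_sniffing_pct": float(
                        np.clip(rng.normal(62 - shift, design.behaviour_sd), 0, 100)
                    ),
                    "freezing_pct": float(
                        np.clip(rng.normal(45 - shift, design.behaviour_sd), 0, 100)
                    ),
                    "target_quadrant_pct": float(
                        np.clip(rng.normal(38 - shift, design.behaviour_sd), 0, 100)
                    ),
                }
            )
    return pd.DataFrame(rows)


def simulate_qpcr(
    design: PhenotypeDesign,
    seed: int,
    genes: tuple[str, ...] = ("goi1", "goi2", "ref1", "ref2", "ref3"),
    conditions: tuple[str, ...] = ("dark", "1h", "3h", "7.5h"),
) -> pd.DataFrame:
    """Tidy qPCR Ct table over genotypes x light conditions.

    Genes named ``ref*`` are stable reference candidates; ``goi*`` genes are
    induced by light (Ct drops by ``qpcr_induction_ct`` per condition step,
    plus a genotype-specific extra drop in trisomic animals).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for genotype in ("wt", "tg"):
        for ci, cond in enumerate(conditions):
            for a in range(max(design.n_per_group // 2, 3)):
                sample = f"{genotype}_{cond}_{a+1}"
                for gene in genes:
                    base = 22.0 if gene.startswith("ref") else 26.0
                    ct = base + rng.normal(0.0, 0.15)
                    if not gene.startswith("ref") and ci > 0:
                        ct -= design.qpcr_induction_ct * ci
                        if genotype == "tg":
                            ct -= design.qpcr_genotype_ct * ci
                    rows.append(
                        {
                            "sample": sample,
                            "genotype": genotype,
                            "condition": cond,
                            "gene": gene,
                            "ct": float(ct),
                        }
                    )
    return pd.DataFrame(rows)


def simulate_morphometry(design: PhenotypeDesign, seed: int) -> pd.DataFrame:
    """MRI volume table: structure volumes (mm^3) and whole-brain volume.

    ``mri_effect`` maps structure name -> linear fold change in the trisomic
    group (e.g. {"s01": 1.2} for a 20% enlargement).
    """
    rng = np.random.default_rng(seed)
    structures = [f"s{i+1:02d}" for i in range(design.n_structures)]
    base = np.linspace(5.0, 40.0, design.n_structures)  # mm^3
    rows = []
    for group in ("wt", "tg"):
        for a in range(design.n_per_group):
            whole = float(rng.normal(450.0, 450.0 * design.mri_cv))
            row = {"animal": f"{group}_{a+1}", "group": group, "whole_brain": whole}
            for s, b in zip(structures, base):
                fold = design.mri_effect.get(s, 1.0) if group == "tg" else 1.0
                row[s] = float((b / 450.0) * whole * fold * rng.normal(1.0, design.mri_cv))
            rows.append(row)
    return pd.DataFrame(rows)


def simulate_phenotypes(
    design: PhenotypeDesign, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Behaviour, qPCR and morphometry tables from one seed."""
    rng = np.random.default_rng(seed)
    s1, s2, s3 = (int(x) for x in rng.integers(2**31, size=3))
    return (
        simulate_behaviour(design, s1),
        simulate_qpcr(design, s2),
        simulate_morphometry(design, s3),
    )
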