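"""End-to-end orchestration: simulate -> DE -> bookkeeping -> gene sets ->
network -> phenotypes, from a single YAML config, with a deterministic
manifest (parameters, seeds, per-output checksums).

Every choice the analysis leaves open (standardisation mode, null metric,
correlation universe, geNorm keep-count, detection threshold) is recorded
explicitly in the manifest so a run is reproducible from it alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bookkeeping, dge, genesets, network, phenotype, synthetic_data
from .expression import ExpressionMatrix, expressed_genes


@dataclass
class RunConfig:
    output_dir: Path
    seed: int = 17
    simulate: dict = field(default_factory=dict)   # synthetic-cohort parameters
    inputs: dict = field(default_factory=dict)     # or paths to real inputs
    dge_params: dict = field(default_factory=dict)
    geneset_params: dict = field(default_factory=dict)
    network_params: dict = field(default_factory=dict)
    phenotype_params: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text())
        cfg = cls(
            output_dir=Path(payload["output_dir"]),
            seed=int(payload.get("seed", 17)),
            simulate=payload.get("simulate", {}) or {},
            inputs=payload.get("inputs", {}) or {},
            dge_params=payload.get("dge", {}) or {},
            geneset_params=payload.get("genesets", {}) or {},
            network_params=payload.get("network", {}) or {},
            phenotype_params=payload.get("phenotypes", {}) or {},
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not self.simulate and not self.inputs:
            raise ValueError("config needs either a 'simulate' or an 'inputs' section")
        for key, p in self.inputs.items():
            if not Path(p).exists():
                raise ValueError(f"input {key!r} does not exist: {p}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest (also written to disk)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "outputs": {}}
    rng = np.random.default_rng(config.seed)

    def record(stage: str, params: dict, files: list[Path]) -> None:
        manifest["stages"][stage] = params
        for f in files:
            manifest["outputs"][str(f.relative_to(out))] = _sha256(f)

    def fail(stage: str, err: Exception) -> RuntimeError:
        return RuntimeError(f"pipeline stage {stage!r} failed: {err}")

    # ---------------------------------------------------------- simulate
    stage = "simulate"
    try:
        if config.simulate:
            sim = dict(config.simulate)
            n_genes = int(sim.pop("n_genes", 2000))
            n_chromosomes = int(sim.pop("n_chromosomes", 3))
            design = synthetic_data.ExpressionDesign(
                **{k: v for k, v in sim.items() if k in synthetic_data.ExpressionDesign.__dataclass_fields__}
            )
            genome = synthetic_data.generate_genome(
                n_genes, n_chromosomes, int(rng.integers(2**31))
            )
            models = synthetic_data.generate_model_panel(genome)
            panel = synthetic_data.simulate_panel(
                genome, models, design, int(rng.integers(2**31))
            )
            genome.to_tsv(out / "annotation.tsv")
            synthetic_data.write_model_panel(models, out / "models.yaml")
            files = [out / "annotation.tsv", out / "models.yaml"]
            matrices = {}
            for name, (X, truth) in panel.items():
                tag = name.replace("/", "-").replace("(", "").replace(")", "")
                X.to_tsv(out / f"expr_{tag}.tsv", out / f"samples_{tag}.tsv")
                synthetic_data.write_truth(truth, out / f"truth_{tag}.tsv")
                files += [out / f"expr_{tag}.tsv", out / f"samples_{tag}.tsv", out / f"truth_{tag}.tsv"]
                matrices[name] = X
            record(stage, {"n_genes": n_genes, "n_chromosomes": n_chromosomes,
                           "design": design.__dict__}, files)
        else:
            genome = synthetic_data.GenomeAnnotation.from_tsv(config.inputs["annotation"])
            models = synthetic_data.read_model_panel(config.inputs["models"])
            matrices = {
                m.name: ExpressionMatrix.from_tsv(
                    config.inputs[f"expr_{m.name}"], config.inputs[f"samples_{m.name}"]
                )
                for m in models
            }
            record(stage, {"inputs": {k: str(v) for k, v in config.inputs.items()}}, [])
    except Exception as e:  # noqa: BLE001
        raise fail(stage, e)

    # --------------------------------------------------------------- dge
    stage = "dge"
    try:
        params = dge.DegCallParams(**config.dge_params)
        results: dict[str, dge.FcrosResult] = {}
        fcs: dict[str, pd.DataFrame] = {}
        files = []
        for name, X in matrices.items():
            tag = name.replace("/", "-").replace("(", "").replace(")", "")
            fc = dge.pairwise_fold_changes(X)
            res = dge.fcros_statistic(fc, params)
            fcs[name] = fc
            results[name] = res
            deg_path = out / f"degs_{tag}.tsv"
            dge.call_degs(res).to_csv(deg_path, sep="\t", index=False)
            files.append(deg_path)
        record(stage, {"params": params.__dict__}, files)
    except Exception as e:  # noqa: BLE001
        raise fail(stage, e)

    # ----------------------------------------------------------- trisomy
    stage = "trisomy"
    try:
        classifications = {}
        for model in models:
            X = matrices[model.name]
            eg = expressed_genes(X)
            classifications[model.name] = bookkeeping.classify_genes(
                genome, model, eg, results[model.name].degs
            )
        summary = bookkeeping.table1_summary(classifications)
        summary.to_csv(out / "compensation_summary.tsv", sep="\t")
        corr = bookkeeping.cross_model_fc_correlation(results)
        corr.to_csv(out / "fc_correlation.tsv", sep="\t")
        venn = bookkeeping.deg_overlap({n: r.degs for n, r in results.items()})
        (out / "deg_overlap.json").write_text(json.dumps(venn, indent=1, sort_keys=True))
        record(stage, {"detection": "10th percentile of gene means",
                       "correlation_universe": "union of model DEGs"},
               [out / "compensation_summary.tsv", out / "fc_correlation.tsv",
                out / "deg_overlap.json"])
    except Exception as e:  # noqa: BLE001
        raise fail(stage, e)

    # ---------------------------------------------------------- genesets
    stage = "genesets"
    try:
        gp = dict(config.geneset_params)
        q_cutoff = float(gp.get("q", 0.1))
        if "gmt" in config.inputs:
            collection = genesets.read_gmt(config.inputs["gmt"])
        else:
            collection = _synthetic_gene_sets(
                genome, panel, int(gp.get("n_random_sets", 50)),
                int(gp.get("set_size", 20)), int(rng.integers(2**31)),
            )
        gs_results = {
            name: genesets.gage_analysis(fcs[name], collection, q_cutoff)
            for name in matrices
        }
        files = []
        for name, table in gs_results.items():
            tag = name.replace("/", "-").replace("(", "").replace(")", "")
            table.to_csv(out / f"pathways_{tag}.tsv", sep="\t")
            files.append(out / f"pathways_{tag}.tsv")
        matrix, unmapped = genesets.assign_meta_pathways(gs_results)
        matrix.to_csv(out / "meta_pathway_matrix.tsv", sep="\t")
        files.append(out / "meta_pathway_matrix.tsv")
        record(stage, {"q_cutoff": q_cutoff,
                       "unmapped": {k: len(v) for k, v in unmapped.items()}}, files)
    except Exception as e:  # noqa: BLE001
        raise fail(stage, e)

    # ----------------------------------------------------------- network
    stage = "network"
    try:
        np_ = dict(config.network_params)
        cs = float(np_.get("cs", 0.4))
        if "edges" in config.inputs:
            edge_table = network.load_edges(config.inputs["edges"], cs)
            seeds = Path(config.inputs["seeds"]).read_text().split()
        else:
            G, seeds = synthetic_data.simulate_ppi(
                int(np_.get("n_nodes", 300)),
                int(np_.get("edges_per_node", 2)),
                seed=int(rng.integers(2**31)),
                seed_clique_size=int(np_.get("seed_clique", 10)),
            )
            synthetic_data.write_edge_table(G, out / "edges.tsv")
            edge_table = network.load_edges(out / "edges.tsv", cs)
        net = network.build_minppinet(edge_table, seeds)
        hubs = network.betweenness_hubs(net)
        hubs.to_csv(out / "hub_report.tsv", sep="\t", index=False)
        # the null asks how unusual the seeds' connectivity is within the
        # whole filtered interactome, so it randomises the full graph
        import networkx as nx

        full = network.edges_to_graph(edge_table)
        giant = full.subgraph(max(nx.connected_components(full), key=len)).copy()
        null = network.degree_preserving_null(
            network.PPINetwork(graph=giant, seeds=[s for s in seeds if s in giant]),
            metric=str(np_.get("null_metric", "seed_internal_edges")),
            n_replicates=int(np_.get("null_replicates", 10_000)),
            seed=int(rng.integers(2**31)),
        )
        (out / "null_model.json").write_text(json.dumps(null.__dict__, indent=1))
        network.write_sif(net, out / "network.sif")
        record(stage, {"cs": cs, "null_metric": null.metric,
                       "null_replicates": null.n_replicates},
               [out / "hub_report.tsv", out / "null_model.json", out / "network.sif"])
    except Exception as e:  # noqa: BLE001
        raise fail(stage, e)

    # ------------------------------------------------------------- quant
    stage = "quant"
    try:
        pp = dict(config.phenotype_params)
        pheno_design = synthetic_data.PhenotypeDesign(
            **{k: v for k, v in pp.items() if k in synthetic_data.PhenotypeDesign.__dataclass_fields__}
        )
        behaviour, qpcr, morpho = synthetic_data.simulate_phenotypes(
            pheno_design, int(rng.integers(2**31))
        )
        rep = phenotype.behaviour_stats(behaviour, "alternation_pct")
        nor_t, nor_p = phenotype.nor_chance_test(behaviour["novel_sniffing_pct"])
        mri = phenotype.mri_compare(morpho)
        mri.to_csv(out / "mri_stats.tsv", sep="\t", index=False)
        quantities = phenotype.comparative_ct(qpcr)
        refs = quantities[quantities["gene"].str.startswith("ref")]
        wide = refs.pivot_table(index="sample", columns="gene", values="quantity")
        gen = phenotype.genorm_select(wide)
        behaviour_out = pd.DataFrame(
            [{"measure": rep.measure, "test": rep.test, "statistic": rep.statistic,
              "p": rep.p_value, "nor_t": nor_t, "nor_p": nor_p}]
        )
        behaviour_out.to_csv(out / "behaviour_stats.tsv", sep="\t", index=False)
        record(stage, {"genorm_selected": gen.selected},
               [out / "mri_stats.tsv", out / "behaviour_stats.tsv"])
    except Exception as e:  # noqa: BLE001
        raise fail(stage, e)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _synthetic_gene_sets(genome, panel, n_random: int, set_size: int, seed: int):
    """Random background sets plus planted sets built from each model's
    trans-effect genes, named so the meta-pathway keywords catch them."""
    rng = np.random.default_rng(seed)
    gene_ids = list(genome.gene_ids)
    sets = []
    for i in range(n_random):
        members = [gene_ids[int(j)] for j in rng.choice(len(gene_ids), set_size, replace=False)]
        sets.append(genesets.GeneSet(name=f"random set {i+1:03d}", members=members))
    first = next(iter(panel.values()))
    truth = first.truth
    up = truth.loc[(truth["label"] == synthetic_data.LABEL_TRANS) & (truth["effect"] > 0), "gene_id"]
    down = truth.loc[(truth["label"] == synthetic_data.LABEL_TRANS) & (truth["effect"] < 0), "gene_id"]
    if len(up) >= 5:
        sets.append(genesets.GeneSet(name="synaptic transmission program", members=list(up[:30])))
    if len(down) >= 5:
        sets.append(genesets.GeneSet(name="ribosome biogenesis program", members=list(down[:30])))
    return sets
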