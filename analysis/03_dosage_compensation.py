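"""Trisomic-gene bookkeeping across the panel.

Classifies every gene as EG/DEG/TEG per model, tabulates the differential
and compensated TEG percentages (the bookkeeping-table view), computes
cross-model fold-change correlations over the union of DEGs, the DEG Venn
partition, and the genotype separation of samples in a PCA embedding.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from _cohort import build_cohort

from trisomap import bookkeeping as bk
from trisomap.dge import run_fcros
from trisomap.expression import expressed_genes

RESULTS = Path(__file__).parent.parent / "results"


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    genome, models, design, panel = build_cohort()
    results = {}
    classifications = {}
    silhouettes = {}
    for model in models:
        X, _ = panel[model.name]
        res = run_fcros(X)
        results[model.name] = res
        classifications[model.name] = bk.classify_genes(
            genome, model, expressed_genes(X), res.degs
        )
        _, sil = bk.sample_embedding(X, genes=res.degs, method="pca")
        silhouettes[model.name] = round(sil, 3)

    summary = bk.table1_summary(classifications)
    summary.to_csv(RESULTS / "compensation_summary.tsv", sep="\t")
    print(f"compensation across models (generator truth: "
          f"{100 * design.compensation_prob:.0f}% compensated):")
    print(summary.to_string())

    corr = bk.cross_model_fc_correlation(results)
    corr.round(4).to_csv(RESULTS / "fc_correlation.tsv", sep="\t")
    print("\nfold-change correlation (% of r, union-DEG universe):")
    print((100 * corr).round(0).astype(int).to_string())

    venn = bk.deg_overlap({n: r.degs for n, r in results.items()})
    nonzero = {k: v for k, v in venn.items() if v}
    (RESULTS / "deg_overlap.json").write_text(json.dumps(venn, indent=1, sort_keys=True))
    print(f"\nDEG Venn partition: {venn['union']} genes in the union, "
          f"{len(nonzero) - 1} non-empty exclusive regions")

    print("\nPCA silhouette (trisomic vs control) on each model's DEGs:")
    for name, sil in silhouettes.items():
        print(f"  {name}: {sil}")


if __name__ == "__main__":
    main()
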