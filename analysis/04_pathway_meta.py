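"""Gene-set enrichment and meta-pathway aggregation across the panel.

Builds a gene-set collection of 120 random background sets plus planted
"program" sets drawn from the cohort's shared trans effects (named so the
meta-pathway keyword map catches them), runs the GAGE-style directional test
per model, aggregates significant sets (q < 0.1) into the ten meta-pathway
groups, and reports the genes shared between models inside each group.
"""

import json
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).parent))
from _cohort import COHORT_SEED, build_cohort

from trisomap import synthetic_data as sd
from trisomap.dge import pairwise_fold_changes
from trisomap.genesets import (
    GeneSet,
    assign_meta_pathways,
    gage_analysis,
    intermodel_connectivity,
    write_gmt,
)

RESULTS = Path(__file__).parent.parent / "results"
SCRATCH = Path(__file__).parent.parent / "scratch"

PROGRAM_NAMES = [
    "synaptic transmission program",
    "ribosome biogenesis program",
    "mitochondrial respiration program",
    "chromatin transcription program",
]


def build_sets(genome, panel, rng) -> list[GeneSet]:
    gene_ids = list(genome.gene_ids)
    sets = [
        GeneSet(
            f"random background set {i:03d}",
            [gene_ids[int(j)] for j in rng.choice(len(gene_ids), 25, replace=False)],
        )
        for i in range(120)
    ]
    # planted programs: slices of the shared trans-effect pool, so models
    # with overlapping duplications perturb the same sets
    first = next(iter(panel.values())).truth
    trans = first[first["label"] == sd.LABEL_TRANS].sort_values("gene_id")
    up = trans[trans["effect"] > 0]["gene_id"].tolist()
    down = trans[trans["effect"] < 0]["gene_id"].tolist()
    pools = [up[:25], down[:25], up[25:50], down[25:50]]
    for name, members in zip(PROGRAM_NAMES, pools):
        if len(members) >= 5:
            sets.append(GeneSet(name, members))
    return sets


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)
    genome, models, design, panel = build_cohort()
    rng = np.random.default_rng(COHORT_SEED + 2)
    sets = build_sets(genome, panel, rng)
    write_gmt(sets, SCRATCH / "gene_sets.gmt")

    fcs = {m.name: pairwise_fold_changes(panel[m.name].matrix) for m in models}
    tables = {name: gage_analysis(fc, sets, q_cutoff=0.1) for name, fc in fcs.items()}

    for name, table in tables.items():
        sig = table[table["direction"] != "none"]
        print(f"{name}: {len(sig)} significant sets "
              f"({[s for s in sig.index if 'program' in s]})")

    matrix, unmapped = assign_meta_pathways(tables)
    matrix.to_csv(RESULTS / "meta_pathway_matrix.tsv", sep="\t")
    active = matrix.loc[(matrix != 0).any(axis=1)]
    print("\nmeta-pathway up/down counts (non-zero rows):")
    print(active.to_string())

    conn = intermodel_connectivity(tables, fcs, sets)
    serialisable = {
        group: {f"{a}|{b}": sorted(genes) for (a, b), genes in pairs.items() if genes}
        for group, pairs in conn.items()
    }
    serialisable = {g: v for g, v in serialisable.items() if v}
    (RESULTS / "meta_pathway_connectivity.json").write_text(
        json.dumps(serialisable, indent=1, sort_keys=True)
    )
    n_pairs = sum(len(v) for v in serialisable.values())
    print(f"\nintermodel connectivity: {n_pairs} model pairs share core genes "
          f"inside {len(serialisable)} meta-pathways")


if __name__ == "__main__":
    main()
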