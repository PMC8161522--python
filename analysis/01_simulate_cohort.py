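"""Simulate the seven-model trisomy cohort and write it to disk.

Writes the annotation, model definitions and per-model expression matrices
(with ground-truth labels) under scratch/cohort/, and a per-model truth
summary under results/.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from _cohort import build_cohort

from trisomap import synthetic_data as sd

SCRATCH = Path(__file__).parent.parent / "scratch" / "cohort"
RESULTS = Path(__file__).parent.parent / "results"


def main() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
    genome, models, design, panel = build_cohort()
    genome.to_tsv(SCRATCH / "annotation.tsv")
    sd.write_model_panel(models, SCRATCH / "models.yaml")

    rows = []
    for model in models:
        X, truth = panel[model.name]
        tag = model.name.replace("/", "-").replace("(", "").replace(")", "")
        X.to_tsv(SCRATCH / f"expr_{tag}.tsv", SCRATCH / f"samples_{tag}.tsv")
        sd.write_truth(truth, SCRATCH / f"truth_{tag}.tsv")
        counts = truth["label"].value_counts()
        rows.append(
            {
                "model": model.name,
                "n_cis_effect": int(counts.get(sd.LABEL_CIS, 0)),
                "n_cis_compensated": int(counts.get(sd.LABEL_COMPENSATED, 0)),
                "n_trans_effect": int(counts.get(sd.LABEL_TRANS, 0)),
                "n_null": int(counts.get(sd.LABEL_NULL, 0)),
            }
        )
    summary = pd.DataFrame(rows).set_index("model")
    summary.to_csv(RESULTS / "simulation_summary.tsv", sep="\t")
    print(f"cohort: {len(models)} models x {genome.genes.shape[0]} genes, "
          f"{design.n_control}v{design.n_trisomic} animals")
    print(summary.to_string())


if __name__ == "__main__":
    main()
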