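"""Phenotype quantification: qPCR induction, western blot, MRI, behaviour.

Simulates phenotype tables with planted group effects (a light-induction
response stronger in the transgenic genotype, one enlarged brain structure,
a behavioural deficit) and runs the corresponding quantification formulas:
comparative-Ct + geNorm + fold induction, loading-control-normalised western
blot, normalised-volume t-tests with FDR, and the ANOVA / Kruskal-Wallis
decision tree plus the novel-object chance-level test.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from _cohort import COHORT_SEED

from trisomap import phenotype as ph
from trisomap import synthetic_data as sd

RESULTS = Path(__file__).parent.parent / "results"


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(COHORT_SEED + 4)
    design = sd.PhenotypeDesign(
        n_per_group=10,
        behaviour_effect=1.2,          # trisomic deficit, in SD units
        qpcr_genotype_ct=0.5,          # extra induction in the transgenics
        mri_effect={"s03": 1.15},      # one structure enlarged 15%
    )
    behaviour, qpcr, morpho = sd.simulate_phenotypes(design, seed=int(rng.integers(2**31)))

    # --- qPCR: comparative Ct, geNorm reference selection, fold induction
    quantities = ph.comparative_ct(qpcr)
    refs = quantities[quantities["gene"].str.startswith("ref")]
    wide = refs.pivot_table(index="sample", columns="gene", values="quantity")
    gen = ph.genorm_select(wide)
    print(f"geNorm: kept {gen.selected} "
          f"(M = {gen.m_values[gen.selected].round(3).to_dict()})")
    goi = quantities[~quantities["gene"].str.startswith("ref")].copy()
    goi["normalized_quantity"] = goi["quantity"] / gen.normalization_factor.reindex(
        goi["sample"]
    ).to_numpy()
    fi = ph.fold_induction(goi)
    summary = ph.induction_summary(fi)
    summary.to_csv(RESULTS / "qpcr_fold_induction.tsv", sep="\t", index=False)
    peak = summary[summary["condition"] == "7.5h"].set_index(["genotype", "gene"])
    print("fold induction at 7.5 h of light exposure (mean +/- SEM):")
    print(peak[["mean", "sem"]].round(2).to_string())

    # --- western blot: tg signal reduced 30% against a clean loading control
    wt = [f"wt_{i}" for i in range(1, 6)]
    tg = [f"tg_{i}" for i in range(1, 6)]
    signal = pd.Series(
        np.concatenate([rng.normal(1.0, 0.1, 5), rng.normal(0.7, 0.1, 5)]), index=wt + tg
    )
    loading = pd.Series(rng.normal(1.0, 0.05, 10), index=wt + tg)
    rel = ph.wb_relative(signal, loading, wt)
    print(f"\nwestern blot relative amount: wt {rel[wt].mean():.2f}, tg {rel[tg].mean():.2f}")

    # --- MRI: per-structure t-tests on normalised volumes with BH correction
    mri = ph.mri_compare(morpho)
    mri.to_csv(RESULTS / "mri_stats.tsv", sep="\t", index=False)
    hits = mri[mri["q"] < 0.05]["structure"].tolist()
    print(f"MRI: structures significant after FDR: {hits} (planted: ['s03'])")

    # --- behaviour: decision tree + NOR chance test per group
    rows = []
    for measure in ("alternation_pct", "distance_cm", "peripheral_pct"):
        rep = ph.behaviour_stats(behaviour, measure)
        rows.append({"measure": measure, "test": rep.test,
                     "statistic": round(rep.statistic, 3), "p": rep.p_value})
    for group in ("wt", "tg"):
        vals = behaviour.loc[behaviour["group"] == group, "novel_sniffing_pct"]
        t, p = ph.nor_chance_test(vals)
        rows.append({"measure": f"nor_vs_chance_{group}", "test": "one-sample t",
                     "statistic": round(t, 3), "p": p})
    stats = pd.DataFrame(rows)
    stats.to_csv(RESULTS / "behaviour_stats.tsv", sep="\t", index=False)
    print("\nbehaviour statistics:")
    print(stats.to_string(index=False))


if __name__ == "__main__":
    main()
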