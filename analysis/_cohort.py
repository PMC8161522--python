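"""Shared study conditions for the analysis drivers.

One synthetic cohort emulating the hippocampal screen: a 10,000-gene genome
over 3 chromosomes, the seven-model overlapping-duplication panel, 5 vs 5
animals per model, 1.5x cis dosage with 45% compensation, 300 trans effects
half-shared between overlapping models. All drivers derive their randomness
from COHORT_SEED so the whole analysis is reproducible end to end.
"""

from trisomap import synthetic_data as sd

COHORT_SEED = 2026
N_GENES = 10_000
N_CHROMOSOMES = 3


def build_cohort():
    genome = sd.generate_genome(N_GENES, N_CHROMOSOMES, seed=COHORT_SEED)
    models = sd.generate_model_panel(genome)
    design = sd.ExpressionDesign()
    panel = sd.simulate_panel(genome, models, design, seed=COHORT_SEED + 1)
    return genome, models, design, panel
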