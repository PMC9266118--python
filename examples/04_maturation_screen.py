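"""Screen for corneal maturation markers along the trajectory.

Genes must rise monotonically (at least two-fold per step) from the putative
LSCs through the LPCs to the differentiating LPCs, using unwounded clusters
only; the list is ranked by the fold difference between the endpoints.
"""

from limbtraj import run_all, simulated_pipeline_config
from limbtraj.screen import screen_to_frame

result = run_all(simulated_pipeline_config(seed=42, n_scale=0.5))

table = screen_to_frame(result.screen_results)
print(table[table.selected].round(2).to_string(index=False))
print("\nplanted monotone genes:", result.truth.planted_maturation_genes)
# All selected genes should be exactly the planted monotone maturation
# ladder (including the Krt12 ladder realized by the corneal stage means);
# fold_difference = (mean in differentiating LPCs) / (mean in LSCs).
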