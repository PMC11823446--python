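"""Pathway potency scoring and the FOC/BMC x 100 prioritization metric.

Maps gene-level BMCs onto gene sets, scores each pathway by its median
member BMC, ranks pathways by potency, and prints the prioritization metric
(max fold-over-control divided by the mean pathway-median BMC, x100) —
higher values flag pathways with large responses at low concentrations.
"""

import pandas as pd

import hepapod as hp
from hepapod.injury import SubstanceBMCSet

gene_bmcs = SubstanceBMCSet(
    substance="demo", run="R1",
    table=pd.DataFrame(
        {
            "probe_id": ["NR_1", "NR_2", "NR_3", "MET_1", "MET_2", "MET_3",
                         "STR_1", "STR_2", "STR_3"],
            "bmc": [5.0, 8.0, 12.0, 40.0, 60.0, 90.0, 300.0, 350.0, 420.0],
            "direction": ["up"] * 6 + ["down"] * 3,
            "max_fold_change": [12.0, 9.0, 15.0, 4.0, 3.5, 5.0, 2.5, 2.2, 3.0],
        }
    ),
)
genesets = {
    "nuclear_receptor_targets": ["NR_1", "NR_2", "NR_3"],
    "fatty_acid_metabolism": ["MET_1", "MET_2", "MET_3", "NR_3"],
    "cellular_stress": ["STR_1", "STR_2", "STR_3"],
}
summaries = hp.map_pathways(gene_bmcs, genesets, min_hits=3)
print(summaries[["pathway", "n_genes_with_bmc", "bmc_median",
                 "bmc_rank_order", "max_fold_change", "foc_over_bmc",
                 "direction"]].to_string(index=False))
print("\nThe nuclear-receptor set is both the most potent (rank 1) and the")
print("most responsive per unit potency (highest FOC/BMC x 100).")
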