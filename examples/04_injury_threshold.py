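"""BMC105 liver-injury thresholds and SILI classification.

The injury threshold is the 105th most potent surviving gene-level BMC.
Three synthetic substances illustrate the classification rules: calculable
in both runs (SILI), in one run (equivocal), in neither (non-SILI).
"""

import numpy as np
import pandas as pd

import hepapod as hp
from hepapod.injury import SubstanceBMCSet

rng = np.random.default_rng(0)


def bmc_set(substance, run, n, scale):
    bmcs = np.sort(rng.lognormal(np.log(scale), 1.0, n))
    return SubstanceBMCSet(
        substance=substance, run=run,
        table=pd.DataFrame({
            "probe_id": [f"g{i}" for i in range(n)], "bmc": bmcs,
            "direction": "up", "max_fold_change": 3.0,
        }),
    )


sets = [
    bmc_set("strong", "R1", 400, 5.0), bmc_set("strong", "R2", 350, 6.0),
    bmc_set("borderline", "R1", 150, 80.0), bmc_set("borderline", "R2", 90, 90.0),
    bmc_set("weak", "R1", 40, 300.0), bmc_set("weak", "R2", 30, 250.0),
]
table = hp.rank_substances(sets)
print(table.to_string(index=False))
print("\nA substance is SILI when the 105th-ranked BMC exists in both runs;")
print("fewer than 105 surviving BMCs in a run makes that run non-calculable.")
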