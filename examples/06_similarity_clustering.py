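"""BMC-set overlap and signed rank-score signature clustering.

Two families of substances with disjoint responder sets are rank-scored,
signed by direction, merged (missing features = 0) and clustered with Ward's
method. The overlap report counts shared vs possible BMC identities; the
clustering should recover the two planted families exactly.
"""

import numpy as np
import pandas as pd

import hepapod as hp

rng = np.random.default_rng(7)


def family_results(features, jitter_seed):
    jrng = np.random.default_rng(jitter_seed)
    return pd.DataFrame(
        {
            "probe_id": features,
            "bmc": base_bmc[tuple(features)] * jrng.lognormal(0, 0.1, len(features)),
            "max_fold_change": 5.0,
            "direction": base_dir[tuple(features)],
        }
    )


fam_a = [f"a_{i}" for i in range(30)]
fam_b = [f"b_{i}" for i in range(30)]
base_bmc = {tuple(fam_a): rng.uniform(1, 50, 30), tuple(fam_b): rng.uniform(1, 50, 30)}
base_dir = {tuple(fam_a): rng.choice(["up", "down"], 30),
            tuple(fam_b): rng.choice(["up", "down"], 30)}

overlap = hp.bmc_overlap({"A1": set(fam_a), "A2": set(fam_a[:25] + fam_b[:5])})
print(f"core overlap A1 vs A2: shared {overlap['shared']} of possible "
      f"{overlap['possible']} features ({overlap['percentage']}%)")

signatures = {}
for j in range(3):
    signatures[f"A_run{j}"] = hp.build_signature(family_results(fam_a, j), 25)
    signatures[f"B_run{j}"] = hp.build_signature(family_results(fam_b, 10 + j), 25)
assignment, linkage, mat = hp.merge_and_cluster(signatures, k=2)
print("\ncluster assignment:")
print(assignment.to_string())
print("\nnewick:", hp.linkage_to_newick(linkage, list(mat.index))[:70], "...")
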