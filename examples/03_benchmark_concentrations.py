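"""Benchmark-concentration modeling of one probe.

Fits the nine candidate dose-response models to a planted Hill responder
(true BMC 10 uM), selects the best by AIC, and reports the BMC at a 1-SD
benchmark response with profile-likelihood bounds. The recovered BMC should
land within about 2-fold of 10 uM with BMCL <= BMC <= BMCU.
"""

import hepapod as hp
from hepapod import bmd

design = hp.make_design(1, 500.0, 9)
responders = [hp.ResponderSpec("RESP_A", "hill", true_bmc=10.0,
                               max_fold_change=8.0, noise_sd=0.2)]
counts = hp.simulate_counts(design, responders, n_null_probes=300,
                            mean_depth=6e5, seed=4)
expr = hp.normalize(counts)
meta = expr.sample_meta
sel = meta[meta["run"] == "R1"]
doses = sel["concentration"].to_numpy()
y = expr.values.loc["RESP_A", sel.index].to_numpy()

for model in ("hill", "linear", "exp5"):
    fit = bmd.fit_model(model, doses, y)
    print(f"{model:>6}: AIC {fit.aic:8.2f}  fit-p {fit.fit_p_value:.3f}")

result = bmd.fit_probe("RESP_A", doses, y, substance="S01", run="R1")
print(f"\nbest model: {result.model}")
print(f"BMC {result.bmc:.2f} uM  [BMCL {result.bmcl:.2f}, BMCU {result.bmcu:.2f}]"
      f"  max fold-change {result.max_fold_change:.1f} ({result.direction})")
print("planted truth: BMC 10 uM")
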