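"""Recovery benchmark: how well does the consensus rule find spiked effects?

Simulates replicate experiments with spiked effects at three times the
pair-difference noise SD and scores the calls against ground truth,
under both the default (sample SD) and the robust (median/MAD) central
scale estimator.  With 10% of proteins genuinely changed, the spiked
proteins inflate the classical central SD, which costs sensitivity; the
robust scale recovers most of it.
"""

import numpy as np

from lfqpair import (
    PipelineConfig,
    SimConfig,
    analyze_experiment,
    recovery_metrics,
    simulate_experiment,
)

N_REPLICATES = 5

for robust in (False, True):
    sens, fdps, sds = [], [], []
    for rep in range(N_REPLICATES):
        cfg = SimConfig(n_proteins=1000, effect_log2fc=2.4, seed=300 + rep)
        sim = simulate_experiment(cfg)
        result = analyze_experiment(sim.runs, PipelineConfig(robust_sd=robust))
        m = recovery_metrics(result.calls, sim.truth)
        sens.append(m.sensitivity)
        fdps.append(m.fdp if m.fdp is not None else 0.0)
        sds.append(np.mean([s.central_sd for s in result.stats.values()]))
    label = "robust (median/MAD)" if robust else "classical (sample SD)"
    print(f"{label}:")
    print(f"  mean central scale: {np.mean(sds):.3f} log2 units "
          f"(generator pair noise SD: 0.8)")
    print(f"  sensitivity: {np.mean(sens):.2f}   FDP: {np.mean(fdps):.3f}\n")

print("The classical sample SD absorbs the spiked tail (scale > 1), so fewer "
      "true changes clear the 2 SD bar; the robust scale stays near the true "
      "noise SD and recovers them, at the same false-discovery level.")
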