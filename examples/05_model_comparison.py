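"""Bias/MSE comparison of the implicit and explicit null models.

Simulates a population of noisy checkerboard records whose ground truth is
the explicit mean surface with the consistency condition violated, refits
every record's conditionals, evaluates both null models, and runs the paired
one-sided Wilcoxon signed-rank test on the per-record mean squared errors.
"""

import numpy as np

from isobole import compare_models, simulate_population

records = simulate_population(
    n_records=50, scenario="both", truth_kind="mean", noise_sd=0.02, seed=11)

comparison = compare_models(records, model_a="gi", model_b="mean",
                            alternative="greater")

mse_gi = np.array([m[0] for m in comparison.mse_pairs])
mse_mean = np.array([m[1] for m in comparison.mse_pairs])
bias_gi = np.array([b[0] for b in comparison.bias_pairs])
bias_mean = np.array([b[1] for b in comparison.bias_pairs])

print(f"records compared: {comparison.n} (dropped: {len(comparison.dropped)})")
print(f"median mse  GI   = {np.median(mse_gi):.5f}")
print(f"median mse  mean = {np.median(mse_mean):.5f}")
print(f"median bias GI   = {np.median(bias_gi):+.5f}")
print(f"median bias mean = {np.median(bias_mean):+.5f}")
print(f"one-sided Wilcoxon p (GI mse greater) = {comparison.p_mse:.2e}")
# The generating model (explicit mean) attains the lower mse; the signed-rank
# test rejects equal errors in favour of the implicit model erring more.
# The bias of GI sits above the bias of the mean model: the explicit surface
# is contracted toward the origin, predicting stronger combined effects.
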