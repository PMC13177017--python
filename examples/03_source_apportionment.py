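"""Uncertainty-weighted PMF on a synthetic receptor dataset with known sources.

Builds a 5-source, 15-species campaign with 10% relative measurement noise,
fits the factorization from 10 random starts, matches fitted factors to the
ground truth and reports how well source contributions are recovered.
"""

import numpy as np

from pmrisk import pmf, synthetic as syn

F_true, G_true = syn.example_factor_design(k=5, n_species=15, n_samples=100, seed=0)
data, truth = syn.generate_pmf_dataset(F_true, G_true, K=0.10, seed=2)

result = pmf.pmf_fit(data, k=5, n_starts=10, seed=0)
print(f"Q = {result.Q:.0f}, Q_expected = {result.Q_expected:.0f}, "
      f"Q/Qexp = {result.Q / result.Q_expected:.2f} (≈1 means noise-consistent fit)")

perm, cosines, exact = pmf.match_factors(result.F, F_true)
print(f"factor matching cosines: {np.round(cosines, 4)} (1 = perfect profile recovery)")

est = pmf.contributions(result, data).to_numpy()[list(perm)]
per_factor = G_true.sum(axis=0)[:, None] * F_true
true_pct = 100 * per_factor / per_factor.sum(axis=0)
print(f"max contribution error: {np.abs(est - true_pct).max():.1f} percentage points")

print("\nfactor-count scan (the practitioner's evidence for choosing k):")
print(pmf.factor_scan(data, k_range=(3, 4, 5, 6), n_starts=10, seed=0).to_string(index=False))
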