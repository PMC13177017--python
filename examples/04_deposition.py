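"""Respiratory deposition fractions across particle sizes.

Evaluates the ICRP inhalable fraction and regional (head airway,
tracheobronchial, alveolar) deposition fractions on a size grid, and
mass-averages them over a lognormal PM2.5-like size distribution.
"""

import numpy as np

from pmrisk import deposition as dep

print("monodisperse deposition fractions:")
print(dep.fraction_table(np.array([0.01, 0.1, 1.0, 2.5, 10.0])).round(4).to_string(index=False))

f1 = dep.regional_fractions(1.0)
print(f"\nat 1 um: HA={f1.HA:.3f} > AR={f1.AR:.3f} > TB={f1.TB:.3f}")
print("  fine-particle deposition is head-airway dominated, then alveolar —")
print("  the ordering that shapes the regional risk estimates downstream.")

avg = dep.size_averaged_fractions(dep.ParticleSizeSpec(mmad_um=1.0, gsd=2.0, n_quadrature=17))
print(f"\nlognormal(MMAD 1 um, GSD 2) mass-weighted: IF={avg.IF:.3f}, "
      f"HA={avg.HA:.3f}, TB={avg.TB:.3f}, AR={avg.AR:.3f}")
print(f"sum of regions {avg.total:.3f} <= IF {avg.IF:.3f} (deposited cannot exceed inhaled)")
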