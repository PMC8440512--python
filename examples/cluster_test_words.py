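"""Cluster-corrected F-test for word differences in spectral density.

Draws five word groups of spectra from a common null distribution, injects
extra pentagon-band (angular frequency ~5) content into the 'surprising'
group, and shows that the resampling cluster test localizes the difference.
"""

import numpy as np

from animakin import WordCategory, cluster_ftest, gen_null_spectra

spectra, labels, grid = gen_null_spectra(n_per_group=20, n_points=101, seed=8)

bump = 1.5 * np.exp(-0.5 * ((grid - 5.0) / 0.2) ** 2)
rows = [i for i, lab in enumerate(labels) if lab is WordCategory.SURPRISING]
spectra[rows] += bump
spectra /= np.trapezoid(spectra, grid, axis=1)[:, None]

res = cluster_ftest(spectra, labels, n_boot=1000, alpha=0.05, seed=9)
print(f"pointwise F critical value: {res.f_critical:.2f}")
print(f"candidate clusters: {len(res.clusters)}, "
      f"significant: {len(res.significant_clusters)}")
for c in res.significant_clusters:
    print(f"  cluster {grid[c['start_idx']]:.2f}-{grid[c['end_idx']]:.2f} "
          f"cycles/2*pi, mass {c['cluster_stat']:.1f}, p = {c['p_value']:.4f}")
print("\nA significant cluster overlapping angular frequency 5 means the "
      "five words differ in pentagon-band trajectory content there.")
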