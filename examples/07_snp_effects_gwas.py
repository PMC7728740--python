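"""Back-solve per-SNP effects from predicted genetic values and call QTL.

Any model's genetic values a-hat can be decomposed into marker effects via
u = D Z'(Z D Z')^-1 a-hat with the diagonal weights D re-estimated for three
iterations. The reweighting sharpens large effects against the background,
turning a genomic-prediction fit into a GWAS-style scan.
"""

import numpy as np

from gwpred import (
    additive_relationship,
    backsolve_effects,
    call_qtl,
    fit_kernel_blup,
    fit_reml,
    simulate_genotypes,
    simulate_trait,
)

G = simulate_genotypes(n=400, p=1500, seed=60)
y, truth = simulate_trait(G, n_qtl=10, h2a=0.5, seed=61)

A = additive_relationship(G)
fit = fit_kernel_blup(y, A, vc=fit_reml(y, A))
traj = backsolve_effects(G, fit.values)

for t, u in enumerate(traj.u_by_iteration, start=1):
    ratio = np.max(np.abs(u)) / np.median(np.abs(u))
    print(f"iteration {t}: max|u| = {np.abs(u).max():.4f}, max/median = {ratio:.0f}")

threshold = 0.5 * np.abs(traj.u_by_iteration[2]).max()
hits = call_qtl(traj, threshold=threshold, iteration=3)
true_set = set(truth.qtl_indices.tolist())
print(f"\nQTL called at |u| > {threshold:.3f} (iteration 3):")
for marker, chrom, pos, effect in hits:
    idx = traj.marker_ids.index(marker)
    tag = "true QTL" if idx in true_set else "background"
    print(f"  {marker} chr{chrom}:{pos} effect {effect:+.3f}  [{tag}]")
# The max/median ratio grows across iterations - the reweighting concentrates
# signal on few markers, which is what makes the scan readable.
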