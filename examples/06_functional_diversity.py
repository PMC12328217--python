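"""Functional richness, projected FD loss, and uniqueness prioritization.

Species become Gaussian clouds in pPC morphospace on a 50-division grid
(trimmed to their 95% highest-density cells); the community density is
their sum.  Functional richness is the occupied volume.  Removing the
species projected extinct in each iteration gives an FD-loss distribution,
and functional uniqueness ranks threatened species for targeted recovery.
"""

import numpy as np

from threatspace import (
    bandwidth_select, build_grid, community_tpd, fd_loss,
    functional_richness, generate_world, ppca, preprocess_traits,
    prioritize_unique, select_components, species_tpd, uniqueness,
)

world = generate_world(n_species=200, seed=42)
scores = select_components(
    ppca(preprocess_traits(world.traits), world.tree), k=3)

grid = build_grid(scores, divisions=30)   # 30^3 cells for a quick demo
bw = bandwidth_select(scores)
print("plug-in bandwidth per axis:", np.round(bw, 3))
tpds = [species_tpd(scores.loc[s].to_numpy(), bw, grid)
        for s in world.species]

richness = functional_richness(community_tpd(tpds))
print(f"functional richness of the full assemblage: {richness:.2f}")

# a toy projection: kill off each at-risk species in 30% of 200 iterations
rng = np.random.default_rng(0)
at_risk = set(world.at_risk)
survival = np.ones((len(world.species), 200), dtype=int)
for i, s in enumerate(world.species):
    if s in at_risk:
        survival[i] = rng.random(200) > 0.3
losses = fd_loss(tpds, survival)
print(f"projected FD loss: {losses.mean():.1f} +- {losses.std(ddof=1):.1f}%"
      f" of functional richness")

u = uniqueness(tpds, world.species)
print("\nmost functionally unique species overall:")
print(u.sort_values(ascending=False).head(3).round(3).to_string())
top = prioritize_unique(u, world.categories, k=5)
print("\ntop-5 unique *threatened* (VU/EN/CR) recovery targets:", top)
print("\nProtecting these species (extinction probability set to zero)")
print("preserves the morphospace volume only they occupy.")
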