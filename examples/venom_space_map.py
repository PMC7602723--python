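"""A shared venom space across individuals.

Peaks are called per individual, so snakes are made comparable by
summing abundances into eleven fixed retention-time windows (R1-R11);
pairwise Aitchison distances between all samples are then embedded in
2-D by non-metric multidimensional scaling.
"""

from venomshift import bin_retention_windows, nmds, pairwise_aitchison
from venomshift.synthetic import SimConfig, default_peak_specs, simulate_snake
from venomshift.venom_space import window_centroids

tables = []
for seed in (1, 2, 3):
    cfg = SimConfig(n_peaks=18,
                    peak_specs=default_peak_specs(18, n_logistic=2, t0=400.0 + 150 * seed),
                    noise_sigma=0.05, seed=seed, snake_id=f"SIM{seed:04d}")
    tables.append(simulate_snake(cfg).table)

binned = bin_retention_windows(tables)
dmat = pairwise_aitchison(binned.binned_abundance)
space = nmds(dmat, n_starts=20, seed=0)

print(f"{dmat.shape[0]} samples embedded; Kruskal stress-1 = {space.stress:.4f}")
print("(stress < 0.05 means the 2-D map preserves the distance ranks well)\n")
print("first/last sample of each snake in venom space:")
for sid in sorted(set(binned.snake_ids)):
    idx = [i for i, s in enumerate(binned.snake_ids) if s == sid]
    x0, y0 = space.coords[idx[0]]
    x1, y1 = space.coords[idx[-1]]
    print(f"  {sid}: start ({x0:6.2f}, {y0:6.2f}) -> end ({x1:6.2f}, {y1:6.2f})")
# Ontogeny shows up as each individual's samples drifting through the map
# from its juvenile to its adult corner.
print("\nretention-window centroids (annotation aid):")
print(window_centroids(binned, space.coords).round(2))
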