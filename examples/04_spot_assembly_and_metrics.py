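"""Assemble placed cells into platform-style spots and score predictions.

Aggregates a patterned single-cell layout into Visium-like hexagonal spots,
shows the ground-truth composition, perturbs it to mimic an imperfect
deconvolution result, and scores the prediction with the composition
metric suite (PCC, SRCC, RMSE, JS) and the rank-aggregated accuracy score.
"""

import numpy as np

import spatsim as ss

ds = ss.generate_fixture_scrnaseq(ss.FixtureConfig(seed=1))
cfg = ss.RandomPatternConfig(grid_n=12, delta=2.0,
                             patterned_populations=ds.populations(), seed=6)
assign = ss.allocate_random_patterns(ds, cfg)

spec = ss.LatticeSpec(arrangement="hexagonal", target_cells_per_spot=10.5)
lattice = ss.generate_spot_lattice(spec, cell_density=ds.n_cells)
spots = ss.bin_cells_to_spots(assign, ds, lattice, spec)
print(f"{spots.n_spots} spots, mean {spots.mean_cells_per_spot():.1f} cells/spot")
print("ground-truth composition of spot 0:", spots.composition[0].round(3))

rng = np.random.default_rng(7)
noisy = np.abs(spots.composition + rng.normal(0, 0.05, spots.composition.shape))
noisy /= noisy.sum(axis=1, keepdims=True)

per_spot = [ss.compare_compositions(t, p)
            for t, p in zip(spots.composition, noisy)]
pcc, srcc, rmse, js = np.nanmean(np.asarray(per_spot, dtype=float), axis=0)
print(f"noisy prediction: PCC={pcc:.3f} SRCC={srcc:.3f} "
      f"RMSE={rmse:.3f} JS={js:.3f}")

scores = ss.MethodScores(
    pcc={"noisy": pcc, "perfect": 1.0},
    srcc={"noisy": srcc, "perfect": 1.0},
    rmse={"noisy": rmse, "perfect": 0.0},
    js={"noisy": js, "perfect": 0.0},
)
print("accuracy scores:", {k: round(v, 3) for k, v in ss.accuracy_score(scores).items()})
# the perfect method ranks first in all four metrics and scores AS = 1
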