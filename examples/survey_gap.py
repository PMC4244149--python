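"""Survey-gap prioritization: where should the next field campaign go?

Overlays a species' consensus prediction (downscaled to the remnant raster's
resolution) on habitat remnants, keeps remnant patches of at least 16 km²,
and drops cells that already hold a known record.
"""

from nichecmp import (
    consensus,
    downscale,
    fit_pca,
    generate_remnants,
    generate_scenario,
    priority_cells,
    project_grid,
    run_ensemble,
    select_components,
)
from nichecmp.surveygap import occurrence_fine_mask

sc = generate_scenario("divergent_allopatric", n_per_species=50, seed=7)
model = fit_pca(sc.grid)
pc = project_grid(sc.grid, model, select_components(model))
occ = sc.occurrences[0]
maps, evals = run_ensemble(occ, pc, sc.backgrounds[0], seed=7)
cons = consensus(maps, [e.tss for e in evals], cutoff=0.4)

fine_factor = 2  # e.g. 5 arc-min climate cells over a ~4 km remnant raster
remnants = generate_remnants(sc.grid, fine_factor, coverage=0.3, seed=7)
fine = downscale(cons, fine_factor)
known = occurrence_fine_mask(occ, sc.grid, fine_factor)

res = priority_cells(fine, remnants, known, min_patch_km2=16.0)
print(f"remnant raster: {remnants.shape[0]}x{remnants.shape[1]} cells of "
      f"{remnants.cell_area_km2:.1f} km² each, {remnants.mask.mean():.0%} forested")
print(f"predicted-presence fine cells:      {res.n_predicted}")
print(f"cells in remnants >= 16 km²:        {res.n_remnant_eligible}")
print(f"priority cells for future surveys:  {res.n_priority}")
print("\nPriority cells are predicted suitable, sit inside a large-enough\n"
      "habitat remnant, and hold no known record yet — the places a new\n"
      "survey is most likely to add an occurrence.")
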