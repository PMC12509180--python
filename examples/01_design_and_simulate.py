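"""Build the factorial layout and simulate one biomass realization.

Constructs the canonical 35-site network (3 randomized complete blocks of
the 2x2x2 biocide factorial per site), simulates plot biomass under a 10%
main-effect scenario with the default variance components, and prints the
cell means of the realization.
"""

import exclosim as ex

design = ex.build_design(ex.DesignSpec(n_sites=35, rng_seed=1))
print(f"layout: {design['site_id'].nunique()} sites x "
      f"{design.groupby('site_id')['block_id'].nunique().iloc[0]} blocks x 8 plots "
      f"= {len(design)} plots")

scenario = ex.scenario_from_preset("main_only", 10.0)  # +10 g per biocide
sim = ex.simulate_experiment(design, scenario, ex.PAPER_VC, seed=2)

cells = sim.groupby(list(ex.TREATMENT_COLUMNS))["biomass_g"].mean().round(1)
print("\nobserved cell means (g) over all sites (i, f, m):")
print(cells.to_string())
print("\nEach applied biocide adds ~10 g to the 100 g baseline; the large "
      "site-to-site spread (SD 372.7 g) does not obscure the within-block "
      "treatment contrasts.")
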