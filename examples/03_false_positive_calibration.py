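"""Within-block permutation calibration of per-term false-positive rates.

Simulates a 29-site null network (no treatment effects), then repeatedly
shuffles biomass within blocks and refits the log-biomass i*f*m mixed model
with -1/+1 coding, counting how often each term is "significant" by chance.
2,000 iterations keep the example quick; the full calibration uses 10,000.
"""

import exclosim as ex

design = ex.build_design(ex.DesignSpec(n_sites=29, rng_seed=1))
null_data = ex.simulate_experiment(
    design, ex.scenario_from_preset("null", 0.0), ex.PAPER_VC, seed=2
)
# site SD 372.7 g around a 100 g baseline makes some plots negative, so an
# offset is added before the log; the calibration is unaffected by it
res = ex.false_positive_analysis(
    null_data, n_iter=2000, alpha=0.05, seed=3, transform="log", offset=2000.0
)
print(res.as_frame().to_string(index=False))
print("\nEvery non-intercept proportion should sit near 0.05: the blocked "
      "permutation destroys any treatment-response association, so a "
      "well-calibrated test flags each term in ~5% of refits. The intercept "
      "(mean log biomass, far from zero) is always significant.")
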