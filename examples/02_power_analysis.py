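"""Monte-Carlo power of the 35-site design for a 10% superadditive synergy.

Simulates the experiment repeatedly, refits the full factorial mixed model
each time, and tests the fungicide:molluscicide interaction with a
likelihood-ratio test.  100 simulations keep this example quick; the
replication presets use 300.
"""

import exclosim as ex

scenario = ex.scenario_from_preset("superadditive", 10.0)
res = ex.estimate_power(
    scenario,
    vc=ex.PAPER_VC,
    design=ex.DesignSpec(n_sites=35, rng_seed=0),
    term="f:m",
    n_sim=100,
    seed=1,
)
print(f"scenario: mains +10 g each, extra +10 g when fungicide and "
      f"molluscicide are combined")
print(f"power to detect the f:m interaction: {res.power_pct:.1f}% "
      f"(95% CI {res.ci_lo_pct:.1f}, {res.ci_hi_pct:.1f}; "
      f"{res.n_reject}/{res.n_sim} rejections)")
print("\nThe interval is an exact Clopper-Pearson bound: with 100 "
      "simulations the power estimate itself is uncertain by ~+/-9 points.")
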