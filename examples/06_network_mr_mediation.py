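"""Network MR: how much of an exposure's effect runs through a mediator?

Simulates three GWAS tables with a planted chain (exposure -> mediator
alpha = 0.13, mediator -> outcome beta = 0.49, total effect 0.22 — the
regime of an adiposity -> fasting TG -> inflammation decomposition) and
chains three IVW fits into the product-of-coefficients mediation:
indirect effect alpha*beta and mediated proportion alpha*beta/gamma
(expected ~29%).  The reverse edge (mediator -> exposure) should be null.
"""

import postmeal as pm

tabs = pm.simulate_network_gwas(pm.NetworkMRSimConfig(seed=0))
report = pm.run_network_mr(
    tabs["exposure"], tabs["mediator"], tabs["outcome"],
    tabs["exposure_instruments"], tabs["mediator_instruments"],
)
med = report.mediation

print(f"alpha (exposure -> mediator): {med.alpha:.3f} +- {med.alpha_se:.3f}")
print(f"beta  (mediator -> outcome):  {med.beta_med:.3f} +- {med.beta_med_se:.3f}")
print(f"gamma (total effect):         {med.gamma_total:.3f} +- {med.gamma_se:.3f}")
print(f"indirect effect alpha*beta:   {med.indirect:.4f} +- {med.se_indirect:.4f}")
print(f"mediated proportion:          {med.proportion:.3f} ({med.proportion_pct}%)")
print(f"reverse edge (mediator -> exposure): beta {report.reverse.beta:.4f}, "
      f"p {report.reverse.p:.2f} (expected null)")
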