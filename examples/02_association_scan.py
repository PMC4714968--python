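"""Per-variant subphenotype association with cross-phenotype conditioning.

Scans the three tagged loci for CD disease location (multinomial, reference
colonic), then shows the key conditioning effect: a behaviour association
that is driven by location attenuates once location enters the model.
"""

from ibdpheno import ScanConfig, SimulationConfig, compute_pcs, run_scan, \
    simulate_cohort
from ibdpheno.scan import results_to_frame

cfg = SimulationConfig(n_samples=12000, seed=11, l3_margin=0.0,
                       missing_rates={}, misdiagnosis_rate=0.0)
G, P, _ = simulate_cohort(cfg)
pcs = compute_pcs(G, 5)
specials = G.subset_variants(["rs_NOD2", "rs_MHC", "rs_MST1"])

loc = run_scan(specials, P, ScanConfig(phenotype="location"), pcs=pcs)
print("CD location (multinomial, OR vs colonic):")
print(results_to_frame(loc)[["variant", "contrast", "or_hr", "p"]]
      .to_string(index=False))
# The NOD2-like locus shows a large ileal-vs-colonic OR (~2.5 by
# construction); the MHC-like locus is colonic-directed (OR < 1).

beh = run_scan(specials.subset_variants(["rs_NOD2"]), P,
               ScanConfig(phenotype="behaviour"), pcs=pcs)
beh_adj = run_scan(specials.subset_variants(["rs_NOD2"]), P,
                   ScanConfig(phenotype="behaviour",
                              condition_on=("location", "age")), pcs=pcs)
print(f"\nNOD2-like vs behaviour:  p = {beh[0].p:.3g} unadjusted, "
      f"p = {beh_adj[0].p:.3g} after location/age adjustment")
# Attenuation after adjustment indicates the behaviour signal is mediated
# by disease location rather than a direct genetic effect.
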