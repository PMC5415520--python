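"""FDist-style F_ST-vs-heterozygosity outlier scan.

Fits a finite-island coalescent null to the observed trimmed neutral mean
F_ST by bisection on the migration parameter, simulates a neutral
(heterozygosity, F_ST) cloud, and flags observed loci outside the
conditional 95% envelope.  A neutral dataset should flag ~5% of loci.
"""

from islepop import fdist_scan, lynx_default_scenario, simulate_scenario

scenario = lynx_default_scenario(seed=11, scale=0.1, s=0.05)
data, _ = simulate_scenario(scenario, track_trajectories=False)

res = fdist_scan(data, n_sim=5000, conf=0.95, mutation_model="smm", seed=3,
                 bisect_batch=200)
print(f"target (trimmed neutral) mean F_ST: {res.target_fst:.4f}")
print(f"fitted island-model migration parameter 4Nm: {res.fitted_M:.2f}")
print("\nPer-locus verdicts (envelope = conditional 95% band of F_ST | het):")
print(res.verdicts.round(3).to_string(index=False))
print(
    "\nLoci above the envelope are positive-selection candidates; below,"
    "\nbalancing candidates.  The candidate locus often stays inside the"
    "\nband here - F_ST-based scans are weaker than the Jost's-D envelope"
    "\nfor this design, which is why both are run."
)
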