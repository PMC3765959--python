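"""Call CpG-dyad states from hairpin BS + oxBS reads.

Hairpin sequencing reads both strands of one dyad; combining a plain-BS
pool (5mC and 5hmC read C) with an oxBS pool (only 5mC reads C) makes the
9-state dyad distribution estimable by EM, including hemimethylation and
a maintenance-efficiency estimate rho_hat = 2F/(2F+H).
"""

import cpgdyad as cd

truth = cd.DyadDistribution(
    {("m", "m"): 0.5, ("m", "u"): 0.25, ("h", "u"): 0.25}
)
errors = cd.ErrorRates()  # 0.5% conversion errors, 94% oxBS efficiency
bs = cd.generate_hairpin_reads(truth, 10_000, "BS", errors, seed=11)
ox = cd.generate_hairpin_reads(truth, 10_000, "oxBS", errors, seed=12)
print(bs.to_string(index=False))
print(ox.to_string(index=False))

est = cd.estimate_dyad_distribution(bs, ox, errors)
print("\nestimated dyad distribution (truth 0.50 / 0.25 / 0.25):")
for state in [("m", "m"), ("m", "u"), ("h", "u")]:
    print(f"  {state}: {est.distribution[state]:.3f}")
s = est.summaries
print(
    f"\nfully modified {s['fully_modified']:.3f}, "
    f"hemi {s['hemi_modified']:.3f}, "
    f"maintenance rho_hat = {s['maintenance_estimate']:.3f}"
)
print(
    "\nHalf the dyads are hemimodified, so the symmetric maintenance"
    "\nestimate sits near 2*0.5/(2*0.5+0.5) = 0.67: maintenance is failing."
)
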