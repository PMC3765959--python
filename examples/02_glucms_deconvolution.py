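"""Quantify absolute 5mC and 5hmC at one CpG site by GlucMS-qPCR.

Synthetic Ct triplets (mock / HpaII / MspI digestions of glucosylated DNA)
are generated from a known dyad distribution, then deconvolved back:
MspI resistance reports glucosyl-5hmC, HpaII resistance reports 5mC+5hmC.
"""

import cpgdyad as cd

# a locus mid-demethylation: 35% of strands 5mC, 12.5% 5hmC
truth = cd.DyadDistribution(
    {("m", "m"): 0.3, ("m", "u"): 0.1, ("h", "u"): 0.25, ("u", "u"): 0.35}
)
ct = cd.generate_glucms_ct(truth, cd.CtModel(sigma_ct=0.05), seed=7, replicates=3)
print(ct.round(3).to_string(index=False))

quant = cd.quantify_site(ct)
print(
    f"\nfrac_5hmC = {quant.frac_5hmC:.3f} +/- {quant.se_5hmC:.3f}"
    f"\nfrac_5mC  = {quant.frac_5mC:.3f} +/- {quant.se_5mC:.3f}"
    f"\n(strand-level truth: 5hmC 0.125, 5mC 0.350)"
)
print(
    "\nThe ~2-cycle delay of the MspI digestion relative to mock encodes"
    "\nthe ~25% 5hmC-protected fraction; Gaussian Ct noise of 0.05 cycles"
    "\npropagates to roughly 3-4% relative error on the fractions."
)
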