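"""Recover kinetic parameters from a noisy synthetic time course.

Observations are binomial-sampled 5mC/5hmC strand fractions (depth 500,
3 replicates) of the standard demethylating schedule; the oxidation
amplitude kappa_max and the relaxed maintenance level rho_lo are then
refit by bounded multistart maximum likelihood.
"""

import numpy as np
import pandas as pd

import cpgdyad as cd
from cpgdyad.fit import DEFAULT_PARAMS

rng = np.random.default_rng(3)
times = [0.0, 24.0, 72.0, 168.0, 264.0]
pred = cd.model_predict(dict(DEFAULT_PARAMS), times)
rows = []
for rep in range(1, 4):
    for row in pred.itertuples():
        for mark, p in (("5mC", row.frac_5mC), ("5hmC", row.frac_5hmC)):
            rows.append(dict(
                time_h=row.time_h, mark=mark,
                k=int(rng.binomial(500, p)), n=500, replicate_id=rep,
            ))
observed = pd.DataFrame(rows)

config = cd.FitConfig(
    free=("kappa_max", "rho_lo"), n_multistart=20, seed=3, noise="binomial"
)
result = cd.fit_timecourse(observed, config)
print(f"kappa_max = {result.estimates['kappa_max']:.4f}  (truth 0.30)")
print(f"rho_lo    = {result.estimates['rho_lo']:.4f}  (truth 0.35)")
print(f"negative log-likelihood = {result.objective:.2f}")
print(
    "\nBoth the 5mC decay and the 5hmC transient constrain kappa_max;"
    "\nwith depth-500 counts at 5 time points the oxidation amplitude is"
    "\nrecovered to within a few percent."
)
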