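# Methods

## Kinetic model

A CpG dyad is an ordered pair of strand marks from {u, m, h}; top carries
the parental strand after a division. One division applies, in pinned
order: (1) oxidation — every `m` strand independently becomes `h` with
probability κ; (2) semiconservative replication — each parental strand
retains its post-oxidation mark and templates a nascent partner that
acquires `m` with probability ρ_m / ρ_h / δ for template `m` / `h` / `u`,
and is otherwise `u`. Tracking the equal mixture of both daughter cells
(a population average, not a lineage tree) makes the daughter
distribution a function of the parental strand-marginal only, and yields
the closed-form strand recursion quoted in the README. Two consequences
are used as test oracles: with all rates zero the modified-strand
fraction is exactly p₀/2ⁿ after n divisions (passive dilution), and the
5mC fraction at any time is non-increasing in κ.

Assumptions: nascent strands never receive `h` directly (the
methyltransferases deposit 5mC only; 5hmC arises solely by oxidation of
5mC and is lost by replicative dilution — no active excision or repair
pathway); no 5fC/5caC intermediates; no non-CpG methylation; the cell
cycle is fixed at `T_cycle = 12 h` and unchanged by 2i (a modelling
choice — the experimental literature does not pin it). Measurement times
are snapped to the nearest completed division (7 d = 14 divisions,
11 d = 22, 24 d = 48) and the mapping is logged.

## Rate schedules

Time-dependent parameters use three elementary forms, evaluated at each
cycle midpoint (k − ½)·T_cycle so that a discrete division samples the
continuous schedule symmetrically:

- maintenance ρ_m(t) = ρ_lo + (ρ_hi − ρ_lo)·e^(−t/τ_D) — maintenance
  machinery is transcriptionally unchanged in 2i, so its impairment is
  modelled as a slow emergent relaxation (τ_D = 72 h, ρ 0.95 → 0.35);
- oxidation κ(t) = κ_max·(1 − e^(−t/τ_T)) — a saturating ramp consistent
  with Tet2 upregulation (κ_max = 0.30, τ_T = 72 h for the standard
  class; 0.90 and 12 h for the fast-oxidation locus);
- de novo δ(t) = δ₀·e^(−t/τ_δ) — the de novo enzymes decline within a
  day of the switch (δ₀ = 0.15, τ_δ = 12 h).

Serum schedules are constant (standard class: ρ_m = 0.95, ρ_h = 0.1,
κ = 0.02, δ = 0.15; the analytic fixed point of the recursion is then
m* = 0.15/0.238 ≈ 0.630, h* = 0.02·m* ≈ 0.0126, which the iterative
`steady_state` reproduces and the tests assert). Resistant classes
(ICR-, IAP-, satellite-like) keep identical serum and 2i parameters:
their protection is modelled as unimpaired maintenance, with elevated
5hmC read-through ρ_h (0.5–0.8) standing in for the observed ability of
some loci to re-read 5hmC as 5mC at replication. Whether resistance is
really protected maintenance or locus-targeted de novo methylation is
not distinguishable from bulk time courses; we chose the former.

The default panel has 10 loci — 4 standard demethylating, 1
fast-oxidation demethylating, 2 ICR-like, 2 IAP-like, 1 satellite-like —
five that demethylate and five controls, matching the design of targeted
validation assays.

## Synthetic data

Generators are pure functions of (truth, configuration, seed). They
emulate: Poisson read depth per CpG per strand (default mean 50);
binomial bisulphite calls with conversion failure f = 0.005,
inappropriate 5mC conversion e_m = 0.005, 5hmC-as-T under plain BS
e_h_bs = 0.005, and oxBS efficiency o = 0.94; hairpin BS and oxBS reads
drawn from separate molecule pools (the chemistries are destructive, so
the two treatments never see the same molecule); and qPCR Ct values with
perfect doubling (E_q = 2.0), baseline Ct 20 at full input and Gaussian
noise of 0.05 cycles, capped at Ct 40 when no template survives.

The in-silico RRBS digest cuts C^CGG (offset +1), pools cut sites per
chromosome, and retains CpGs inside fragments of 40–220 bp. CGI-flagged
panel loci are CpG- and MspI-dense (600 bp, 30 CpGs, 8 sites) versus
sparse non-CGI loci (2400 bp, 15 CpGs, 2 sites), so the digest enriches
for CGIs as real RRBS does.

GlucMS truth uses an assayed-strand convention: a molecule's digestion
resistance is decided by the mark on the internal C of the assayed
strand, so R_MspI equals the strand 5hmC fraction and R_HpaII the
modified-strand fraction. Real enzymes respond to either-strand
modification of the CCGG; the single-strand convention makes GlucMS
truth coincide with the BS-seq strand fraction so the two readouts are
directly comparable, and the behaviour of hemi-modified sites in the
real assay remains an open question.

What the generators do **not** emulate: read-level sequences, alignment
and mapping artefacts, PCR duplicates, sequence-context effects beyond
the assayed CpG, qPCR standard curves and melting behaviour, or
cell-to-cell heterogeneity. Passing tests therefore demonstrate
correctness of the estimators under the stated noise models, not
robustness to the full error structure of real libraries.

## Estimators

**GlucMS-qPCR.** Resistant fraction = E_q^(Ct_mock − Ct_digested) with a
single fixed efficiency (the procedure normalizes to mock only; no
standard curve). Values above 1 clip to 1 and capped Cts map to 0, both
flagged. Replicates are averaged on the fraction scale — the scale on
which results are reported — rather than the Ct scale; SEs are SD/√n of
per-replicate fractions. A replicate with HpaII resistance more than
0.05 below MspI resistance is flagged as inconsistent (HpaII resistance
must contain MspI resistance) and the composition is clipped to the
simplex.

**Hairpin BS/oxBS.** The 9-state dyad distribution θ maximizes the joint
multinomial likelihood of the two 4-pattern count tables, with known
error rates folded into per-strand emission probabilities (error rates
are supplied, not co-estimated: real studies calibrate them from
spike-ins). EM runs from a uniform start until the log-likelihood gain
falls below 1e-10 or 10,000 iterations. Because EM approaches the
simplex boundary sublinearly, an active-set refinement then zeroes
components below 1e-4 and re-runs EM restricted to that face until θ
stops moving at machine precision, keeping the result only if the
likelihood does not decrease; this is what makes zero-noise round trips
exact to 1e-9.

Identifiability: the unpaired BS and oxBS pattern marginals provide 6
independent observables against 8 free parameters, so the full 9-state θ
has a 2-dimensional likelihood ridge in general. The ridge directions
require mass in states whose nascent strand carries `h`; distributions on
the kinetic model's support (nascent strand ∈ {m, u}) sit on a boundary
face where every ridge direction is blocked and are fully identifiable.
With BS reads alone only the {m ∪ h} aggregate is identifiable and the
estimate carries an explicit confounding flag. An optional known-support
restriction serves estimation when the state space is known a priori.
Top and bottom strands are kept distinguishable (9 states); the
maintenance summary ρ̂ = 2F/(2F+H) is strand-age-agnostic because the
assay cannot label nascent versus parental strands.

**Methylome aggregation.** Feature methylation is count-weighted
(Σ meth / Σ total), robust at low depth; features without qualifying
CpGs report missing, never zero. CGI bins close at the lower edge
(high ⩾ 0.75, moderate ⩾ 0.50); "retained" means > 0.25. The pairwise
"unchanged" band is |Δ| ⩽ 0.1. Clustering uses average linkage on
Euclidean distances with pairwise NaN dropping; Newick export goes
through scikit-bio. Calls are 1-based internally, BED intervals 0-based
half-open; strand pooling onto the dyad is explicit, never implicit.

## Fitting

`model_predict` propagates the same exact recursion as the simulator
(the tests assert bit-level agreement with the 9-state path), starting
from the analytic serum fixed point. The loss is a binomial or Gaussian
negative log-likelihood with predictions clipped to [1e-9, 1 − 1e-9].
Optimization is bounded L-BFGS-B from Latin-hypercube starts (seeded;
objective tolerance 1e-10, parameter tolerance 1e-8); all starts are
logged and the best usable (finite-objective) one wins — a failed line
search at an exact minimum still returns the optimum and is not treated
as a failure. τ_D and τ_T are weakly identifiable from five time points,
so defaults fix τ_δ and free at most {κ_max, ρ_lo} plus one time
constant; a finite-difference Hessian with condition number above 1e8
triggers an identifiability warning. Confidence intervals come from a
percentile bootstrap over replicates; the coverage experiment in the
test suite uses 6 replicates of depth-500 counts at 5 time points with
200 resamples, where 3 replicates would give only 10 distinct resampled
datasets and visibly undercover.

## Problem sizes and numerical choices

The test suite uses 10⁵ molecules for Monte-Carlo/exact agreement (3σ
binomial bounds), 10⁴ reads per hairpin assay, depth-500 binomial counts
for parameter recovery, 25 simulated experiments for bootstrap coverage,
and a coarse-to-fine grid search (effective resolution 1e-4) as the
independent ML oracle on 3-support instances. Steady states iterate to
an L∞ tolerance of 1e-12 from full methylation; distribution validity is
enforced at 1e-12 for conservation and 1e-9 on input normalization. Ties
in the 5hmC peak-time argmax break toward the earlier sample.

## Known limitations

The model is a population average: it cannot represent lineage
correlations, division-time variability, or the bimodal locus states
single-molecule data can show. Oxidation acts once per cycle rather than
continuously, so κ is a per-division probability, not a rate constant.
The GlucMS single-strand convention and the fixed qPCR efficiency are
simplifications flagged above. Fitted time constants are reported but
should be interpreted cautiously at five time points; only amplitude
parameters (κ_max, ρ_lo) have tight synthetic-recovery guarantees.
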