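"""Dyad-state estimation from hairpin BS and oxBS read patterns.

A hairpin read reports both strands of one CpG dyad as (C, T) calls.  Two
destructive treatments are read separately: plain bisulphite (5mC and 5hmC
both read C) and oxidative bisulphite (only 5mC reads C).  The 9-state
dyad distribution theta is estimated by maximizing the joint multinomial
likelihood of the two pattern tables

    L(theta) = sum_assay sum_pattern n log sum_state theta_s P(pattern | s)

over the 9-simplex by EM, with known conversion-error rates baked into the
emission probabilities.  EM runs from a uniform start until the
log-likelihood gain drops below 1e-10 (at most 10,000 iterations); because
EM crawls near the simplex boundary, an active-set polish then zeroes
near-zero components and re-runs EM restricted to that face, keeping the
result only if the likelihood does not fall.

With only BS reads, 5mC and 5hmC are confounded (both protect the base):
only the {m or h} aggregate is identifiable and the estimate is flagged.
More generally the unpaired BS + oxBS pattern marginals determine the
joint modification pattern and the per-strand 5mC pattern but not every
cross-strand mark pairing; distributions whose nascent strand never
carries 5hmC (the kinetic model's support) are fully identifiable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chemistry import PATTERN_INDEX, PATTERNS, ErrorRates, emission_matrix
from .states import DYAD_STATES, DyadDistribution, summarize

EM_TOL = 1e-10
EM_MAX_ITER = 10_000
_POLISH_THRESHOLD = 1e-4
_POLISH_ITER = 10_000


def tabulate_patterns(reads: pd.DataFrame) -> pd.DataFrame:
    """Aggregate hairpin observations into a site x assay x pattern table.

    Input columns: site_id, assay, top_call, bottom_call, count (or one
    row per read without a count column).  All four patterns are present
    (zero-filled) for every site/assay that appears.
    """
    if len(reads) == 0:
        raise ValueError("no hairpin observations")
    df = reads.copy()
    if "count" not in df.columns:
        df["count"] = 1
    grouped = (
        df.groupby(["site_id", "assay", "top_call", "bottom_call"])["count"]
        .sum()
        .reset_index()
    )
    rows = []
    for (site_id, assay), grp in grouped.groupby(["site_id", "assay"]):
        counts = {p: 0 for p in PATTERNS}
        for _, row in grp.iterrows():
            counts[(row["top_call"], row["bottom_call"])] += int(row["count"])
        for (a, b), n in counts.items():
            rows.append(
                dict(site_id=site_id, assay=assay, top_call=a, bottom_call=b, count=n)
            )
    return pd.DataFrame(rows)


def _count_vector(table: pd.DataFrame | None) -> np.ndarray:
    vec = np.zeros(len(PATTERNS))
    if table is None or len(table) == 0:
        return vec
    for _, row in table.iterrows():
        vec[PATTERN_INDEX[(row["top_call"], row["bottom_call"])]] += float(
            row["count"]
        )
    return vec


@dataclass
class DyadEstimate:
    """ML estimate of the dyad distribution with derived summaries."""

    distribution: DyadDistribution
    log_likelihood: float
    n_iterations: int
    converged: bool
    m_h_confounded: bool = False
    flags: list[str] = field(default_factory=list)

    @property
    def summaries(self) -> dict[str, float]:
        return summarize_dyads(self)


def _loglik(theta, emissions, counts):
    ll = 0.0
    for B, c in zip(emissions, counts):
        mix = np.maximum(theta @ B, 1e-300)
        ll += float(np.sum(c * np.log(mix)))
    return ll


def _em(theta, emissions, counts, support, tol, max_iter, param_tol=None):
    """EM on the simplex restricted to ``support`` (bool mask).

    Stops when the log-likelihood gain drops below ``tol`` or, if
    ``param_tol`` is set, when the parameter vector stops moving.
    """
    theta = np.where(support, theta, 0.0)
    theta = theta / theta.sum()
    ll_prev = -math.inf
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        num = np.zeros_like(theta)
        ll = 0.0
        for B, c in zip(emissions, counts):
            mix = np.maximum(theta @ B, 1e-300)
            ll += float(np.sum(c * np.log(mix)))
            num += theta * (B @ (c / mix))
        theta_new = num / num.sum()
        moved = float(np.max(np.abs(theta_new - theta)))
        theta = theta_new
        if (ll - ll_prev < tol and n_iter > 1) or (
            param_tol is not None and moved < param_tol
        ):
            converged = True
            break
        ll_prev = ll
    return theta, ll, n_iter, converged


def estimate_dyad_distribution(
    bs_counts: pd.DataFrame | np.ndarray | None,
    oxbs_counts: pd.DataFrame | np.ndarray | None,
    error_rates: ErrorRates | None = None,
    support: list[tuple[str, str]] | None = None,
    polish: bool = True,
) -> DyadEstimate:
    """Joint-multinomial ML estimate of the 9-state dyad distribution.

    ``bs_counts`` / ``oxbs_counts`` are 4-pattern tables (or raw vectors in
    :data:`cpgdyad.chemistry.PATTERNS` order); either may be absent.
    ``support`` optionally restricts the estimate to a known set of states.
    """
    error_rates = error_rates or ErrorRates()
    counts = []
    emissions = []
    has_oxbs = False
    for assay, table in (("BS", bs_counts), ("oxBS", oxbs_counts)):
        vec = (
            np.asarray(table, dtype=float)
            if isinstance(table, (np.ndarray, list, tuple))
            else _count_vector(table)
        )
        if vec.sum() > 0:
            counts.append(vec)
            emissions.append(emission_matrix(assay, error_rates))
            if assay == "oxBS":
                has_oxbs = True
    if not counts:
        raise ValueError("all-zero hairpin counts: nothing to estimate")

    mask = np.ones(len(DYAD_STATES), dtype=bool)
    if support is not None:
        mask[:] = False
        for state in support:
            mask[DYAD_STATES.index(tuple(state))] = True
    theta0 = np.full(len(DYAD_STATES), 1.0 / len(DYAD_STATES))
    theta, ll, n_iter, converged = _em(
        theta0, emissions, counts, mask, EM_TOL, EM_MAX_ITER
    )
    flags = []
    if polish:
        face = mask & (theta > _POLISH_THRESHOLD)
        if face.sum() >= 1 and face.sum() < mask.sum():
            # the face interior converges linearly, so run until theta
            # stops moving at machine precision
            theta_f, ll_f, _, _ = _em(
                theta, emissions, counts, face, -math.inf, _POLISH_ITER,
                param_tol=1e-16,
            )
            if ll_f >= ll - 1e-6:
                theta, ll = theta_f, max(ll, ll_f)
                flags.append("active-set polish applied")
    confounded = not has_oxbs
    if confounded:
        flags.append("no oxBS reads: 5mC/5hmC confounded, only m+h identifiable")
    return DyadEstimate(
        distribution=DyadDistribution(theta / theta.sum()),
        log_likelihood=ll,
        n_iterations=n_iter,
        converged=converged,
        m_h_confounded=confounded,
        flags=flags,
    )


def summarize_dyads(est: DyadEstimate) -> dict[str, float]:
    """Dyad categories and the symmetric maintenance-efficiency estimate.

    rho_hat = 2F / (2F + H) with F = fully modified, H = hemi modified:
    under perfect maintenance every modified dyad stays fully modified
    (rho_hat = 1); maintenance failures convert fully to hemi dyads.
    Undefined (NaN, flagged) when no modified dyads remain.
    """
    s = summarize(est.distribution)
    F = s["fully_modified"]
    H = s["hemi_modified"]
    if F + H <= 0.0:
        maintenance = float("nan")
        flag = True
    else:
        maintenance = 2.0 * F / (2.0 * F + H)
        flag = False
    return dict(
        fully_modified=F,
        hemi_modified=H,
        unmodified=s["unmodified"],
        frac_5mC=s["frac_5mC"],
        frac_5hmC=s["frac_5hmC"],
        maintenance_estimate=maintenance,
        maintenance_undefined=flag,
    )


def estimate_sites(
    reads: pd.DataFrame,
    error_rates: ErrorRates | None = None,
    polish: bool = True,
) -> pd.DataFrame:
    """Estimate per site_id from a raw hairpin observation table."""
    table = tabulate_patterns(reads)
    rows = []
    for site_id, grp in table.groupby("site_id", sort=True):
        bs = grp[grp["assay"] == "BS"]
        ox = grp[grp["assay"] == "oxBS"]
        est = estimate_dyad_distribution(
            bs if len(bs) else None,
            ox if len(ox) else None,
            error_rates,
            polish=polish,
        )
        row = dict(site_id=site_id, log_likelihood=est.log_likelihood,
                   converged=est.converged, m_h_confounded=est.m_h_confounded)
        row.update(est.summaries)
        rows.append(row)
    return pd.DataFrame(rows)
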