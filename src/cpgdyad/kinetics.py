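"""Replication-coupled CpG-dyad methylation kinetics.

The model: at each cell division, (1) every 5mC strand is oxidized to 5hmC
with probability ``kappa``; (2) each parental strand seeds one daughter
dyad, retaining its (post-oxidation) mark on the top position, while the
nascent partner strand acquires 5mC with probability ``rho_m`` (template m,
maintenance), ``rho_h`` (template h, read-through) or ``delta`` (template u,
de novo), and is otherwise unmodified.  Nascent strands never acquire 5hmC
directly: 5hmC only arises by oxidation of existing 5mC, and is lost by
replicative dilution.  The population is the equal mixture over the two
daughter cells, so the daughter dyad distribution depends on the parent
only through its strand-marginal mark fractions.

The per-division strand recursion implied by the update is::

    m' = [(1-kappa) m (1 + rho_m) + rho_h (h + kappa m) + delta u] / 2
    h' = (h + kappa m) / 2

Under 2i the schedules relax: maintenance decays from ``rho_hi`` to
``rho_lo`` with time constant ``tau_D`` (hours), oxidation ramps to
``kappa_max`` with ``tau_T``, and de novo decays from ``delta_0`` with
``tau_delta``, reflecting rapid loss of the de novo enzymes, a transient
Tet-driven oxidation wave, and an emergent maintenance impairment.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .states import DYAD_STATES, MARK_INDEX, MARKS, DyadDistribution

logger = logging.getLogger(__name__)

#: Locus classes of the synthetic panel.
LOCUS_CLASSES = (
    "demethylating_standard",
    "demethylating_fast_ox",
    "icr_like",
    "iap_like",
    "satellite_like",
)

DEFAULT_T_CYCLE = 12.0  # hours per division


@dataclass(frozen=True)
class Rates:
    """Instantaneous per-division kinetic parameters."""

    rho_m: float  # maintenance: nascent gets m opposite an m template
    rho_h: float  # read-through: nascent gets m opposite an h template
    kappa: float  # oxidation: m strand becomes h
    delta: float  # de novo: nascent gets m opposite a u template

    def __post_init__(self):
        for name in ("rho_m", "rho_h", "kappa", "delta"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass(frozen=True)
class RateSchedule:
    """Time-dependent kinetic parameters.

    ``rho_m(t) = rho_lo + (rho_hi - rho_lo) exp(-t/tau_D)``;
    ``kappa(t) = kappa_0 + (kappa_max - kappa_0)(1 - exp(-t/tau_T))``;
    ``delta(t) = delta_0 exp(-t/tau_delta)`` when ``tau_delta`` is finite,
    else constant ``delta_0``.  A constant schedule is the special case
    ``rho_hi == rho_lo``, ``kappa_max == kappa_0``, ``tau_delta == inf``.
    Times are hours; rates are per division.
    """

    rho_hi: float
    rho_lo: float
    tau_D: float
    kappa_0: float
    kappa_max: float
    tau_T: float
    delta_0: float
    tau_delta: float
    rho_h: float
    T_cycle: float = DEFAULT_T_CYCLE

    def __post_init__(self):
        if self.T_cycle <= 0:
            raise ValueError("T_cycle must be positive")
        for name in ("rho_hi", "rho_lo", "kappa_0", "kappa_max", "delta_0", "rho_h"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("tau_D", "tau_T", "tau_delta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def constant(
        cls,
        rho_m: float,
        rho_h: float,
        kappa: float,
        delta: float,
        T_cycle: float = DEFAULT_T_CYCLE,
    ) -> "RateSchedule":
        return cls(
            rho_hi=rho_m,
            rho_lo=rho_m,
            tau_D=1.0,
            kappa_0=kappa,
            kappa_max=kappa,
            tau_T=1.0,
            delta_0=delta,
            tau_delta=math.inf,
            rho_h=rho_h,
            T_cycle=T_cycle,
        )

    def at(self, t: float) -> Rates:
        """Evaluate the schedule at time ``t`` (hours)."""
        if t < 0:
            raise ValueError(f"negative time t={t}")
        rho_m = self.rho_lo + (self.rho_hi - self.rho_lo) * math.exp(-t / self.tau_D)
        kappa = self.kappa_0 + (self.kappa_max - self.kappa_0) * (
            1.0 - math.exp(-t / self.tau_T)
        )
        if math.isinf(self.tau_delta):
            delta = self.delta_0
        else:
            delta = self.delta_0 * math.exp(-t / self.tau_delta)
        return Rates(rho_m=rho_m, rho_h=self.rho_h, kappa=kappa, delta=delta)


def eval_schedule(schedule: RateSchedule, t: float) -> Rates:
    """Functional alias for :meth:`RateSchedule.at`."""
    return schedule.at(t)


# Default schedules per locus class.  Serum schedules are constant; 2i
# schedules are time-dependent for demethylating classes and identical to
# serum for the resistant classes (icr/iap/satellite), whose protection is
# modeled as unimpaired maintenance.
_SERUM = {
    "demethylating_standard": dict(rho_m=0.95, rho_h=0.1, kappa=0.02, delta=0.15),
    "demethylating_fast_ox": dict(rho_m=0.95, rho_h=0.1, kappa=0.02, delta=0.15),
    "icr_like": dict(rho_m=0.95, rho_h=0.5, kappa=0.01, delta=0.15),
    "iap_like": dict(rho_m=0.92, rho_h=0.8, kappa=0.02, delta=0.15),
    "satellite_like": dict(rho_m=0.90, rho_h=0.5, kappa=0.02, delta=0.12),
}

_TWOI_DEMETH = dict(
    rho_hi=0.95,
    rho_lo=0.35,
    tau_D=72.0,
    kappa_0=0.0,
    kappa_max=0.30,
    tau_T=72.0,
    delta_0=0.15,
    tau_delta=12.0,
    rho_h=0.1,
)


def default_schedules(class_label: str, T_cycle: float = DEFAULT_T_CYCLE):
    """(serum, 2i) default schedules for a locus class."""
    if class_label not in LOCUS_CLASSES:
        raise ValueError(
            f"unknown locus class {class_label!r}; valid: {LOCUS_CLASSES}"
        )
    serum = RateSchedule.constant(**_SERUM[class_label], T_cycle=T_cycle)
    if class_label == "demethylating_standard":
        twoi = RateSchedule(**_TWOI_DEMETH, T_cycle=T_cycle)
    elif class_label == "demethylating_fast_ox":
        twoi = RateSchedule(
            **{**_TWOI_DEMETH, "kappa_max": 0.90, "tau_T": 12.0}, T_cycle=T_cycle
        )
    else:
        twoi = serum  # resistant classes: identical serum and 2i kinetics
    return serum, twoi


@dataclass(frozen=True)
class LocusParams:
    """Kinetic parameterization of one locus."""

    locus_id: str
    class_label: str
    serum_schedule: RateSchedule
    twoi_schedule: RateSchedule

    @classmethod
    def from_class(
        cls, locus_id: str, class_label: str, T_cycle: float = DEFAULT_T_CYCLE
    ) -> "LocusParams":
        serum, twoi = default_schedules(class_label, T_cycle)
        return cls(locus_id, class_label, serum, twoi)

    def with_kappa_scale(self, scale: float) -> "LocusParams":
        """Scale oxidation in both schedules (Tet-loss scenarios)."""

        def scaled(s: RateSchedule) -> RateSchedule:
            return replace(s, kappa_0=s.kappa_0 * scale, kappa_max=s.kappa_max * scale)

        return replace(
            self,
            serum_schedule=scaled(self.serum_schedule),
            twoi_schedule=scaled(self.twoi_schedule),
        )

    def with_delta_zero(self) -> "LocusParams":
        """Disable de novo methylation in both schedules (Dnmt3 knockdown)."""

        def zeroed(s: RateSchedule) -> RateSchedule:
            return replace(s, delta_0=0.0)

        return replace(
            self,
            serum_schedule=zeroed(self.serum_schedule),
            twoi_schedule=zeroed(self.twoi_schedule),
        )


# ---------------------------------------------------------------------------
# Propagation


def _nascent_probs(rates: Rates) -> np.ndarray:
    """P(nascent strand = m | template mark), in MARKS order."""
    return np.array([rates.rho_m, rates.rho_h, rates.delta])


def _oxidize_marginal(p: np.ndarray, kappa: float) -> np.ndarray:
    q = p.copy()
    m = MARK_INDEX["m"]
    h = MARK_INDEX["h"]
    q[h] = p[h] + kappa * p[m]
    q[m] = (1.0 - kappa) * p[m]
    return q


def advance_cycle(dist: DyadDistribution, rates: Rates) -> DyadDistribution:
    """One division: oxidation, then semiconservative replication.

    The daughter dyad places the parental (post-oxidation) mark on top and
    the nascent mark (m or u) on the bottom; the output is the equal
    mixture over the two parental strands, hence a function of the parent
    strand-marginal only.
    """
    if abs(float(dist.p.sum()) - 1.0) > 1e-9:
        raise ValueError("input distribution is not normalized")
    q = _oxidize_marginal(dist.strand_marginal("both"), rates.kappa)
    p_m = _nascent_probs(rates)
    out = np.zeros((len(MARKS), len(MARKS)))
    out[:, MARK_INDEX["m"]] = q * p_m
    out[:, MARK_INDEX["u"]] = q * (1.0 - p_m)
    return DyadDistribution(out.ravel())


def advance_strand_fractions(
    m: float, h: float, rates: Rates
) -> tuple[float, float]:
    """Closed-form strand recursion for one division (5mC, 5hmC fractions)."""
    u = 1.0 - m - h
    qh = h + rates.kappa * m
    qm = (1.0 - rates.kappa) * m
    m2 = (qm * (1.0 + rates.rho_m) + rates.rho_h * qh + rates.delta * u) / 2.0
    h2 = qh / 2.0
    return m2, h2


def steady_state(
    schedule: RateSchedule,
    tol: float = 1e-12,
    max_cycles: int = 100_000,
    init: DyadDistribution | None = None,
) -> DyadDistribution:
    """Fixed point of :func:`advance_cycle` under a constant schedule.

    The schedule is held at its t=0 value.  Raises if the successive-cycle
    L-infinity change has not fallen below ``tol`` within ``max_cycles``.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    rates = schedule.at(0.0)
    dist = init if init is not None else DyadDistribution.point("m", "m")
    for _ in range(max_cycles):
        nxt = advance_cycle(dist, rates)
        residual = float(np.max(np.abs(nxt.p - dist.p)))
        if residual < tol:
            return nxt
        dist = nxt
    raise RuntimeError(
        f"steady_state did not converge in {max_cycles} cycles "
        f"(last residual {residual:.3e})"
    )


@dataclass
class TimeCourse:
    """Dyad distributions per locus over a sampled 2i (or serum) time course.

    ``distributions[locus_id][t]`` is the DyadDistribution at sampled time
    ``t`` (hours, snapped to a completed division).  ``snap_map`` records
    requested -> snapped times.
    """

    sample_times: list[float]
    loci: list[LocusParams]
    distributions: dict[str, dict[float, DyadDistribution]]
    snap_map: dict[float, float] = field(default_factory=dict)
    mode: str = "exact"

    def strand_fractions(self, locus_id: str):
        """{time: (frac_5mC, frac_5hmC)} for one locus."""
        out = {}
        for t, dist in self.distributions[locus_id].items():
            marg = dist.strand_marginal("both")
            out[t] = (float(marg[MARK_INDEX["m"]]), float(marg[MARK_INDEX["h"]]))
        return out

    def to_dataframe(self):
        import pandas as pd

        from .states import summarize

        rows = []
        class_of = {lp.locus_id: lp.class_label for lp in self.loci}
        for locus_id, by_time in self.distributions.items():
            for t, dist in sorted(by_time.items()):
                s = summarize(dist)
                rows.append(
                    dict(
                        locus_id=locus_id,
                        class_label=class_of[locus_id],
                        time_h=t,
                        fraction_5mC=s["frac_5mC"],
                        fraction_5hmC=s["frac_5hmC"],
                        fraction_fully=s["fully_modified"],
                        fraction_hemi=s["hemi_modified"],
                    )
                )
        return pd.DataFrame(rows)


def _snap_times(sample_times, T_cycle: float) -> dict[float, int]:
    """Map each requested time to the nearest completed division count."""
    snapped = {}
    for t in sample_times:
        if t < 0:
            raise ValueError(f"negative sample time {t}")
        k = round(t / T_cycle)
        snapped[t] = int(k)
        if abs(k * T_cycle - t) > 1e-9:
            logger.info(
                "sample time %.6g h snapped to division %d (t=%.6g h)",
                t,
                k,
                k * T_cycle,
            )
    return snapped


def _mc_advance(states: np.ndarray, rates: Rates, rng: np.random.Generator):
    """Monte-Carlo one-division update of an array of dyad-state indices.

    Each molecule: oxidize each m strand w.p. kappa, pick one parental
    strand uniformly (population mixture), then synthesize the nascent
    strand by template-dependent probability.
    """
    n = len(states)
    top = states // len(MARKS)
    bottom = states % len(MARKS)
    m_idx = MARK_INDEX["m"]
    h_idx = MARK_INDEX["h"]
    for arr in (top, bottom):
        is_m = arr == m_idx
        ox = rng.random(n) < rates.kappa
        arr[is_m & ox] = h_idx
    pick_top = rng.random(n) < 0.5
    template = np.where(pick_top, top, bottom)
    p_m = _nascent_probs(rates)[template]
    nascent = np.where(
        rng.random(n) < p_m, m_idx, MARK_INDEX["u"]
    )
    return template * len(MARKS) + nascent


def simulate_timecourse(
    loci,
    sample_times,
    mode: str = "exact",
    n_molecules: int = 100_000,
    seed: int | None = None,
    condition: str = "twoi",
) -> TimeCourse:
    """Propagate each locus from its serum steady state under its 2i
    (or serum) schedule, sampling at the requested times.

    Divisions occur at ``t = T_cycle, 2 T_cycle, ...``; the schedule is
    evaluated at each cycle's midpoint ``(k - 1/2) T_cycle``.  Sample times
    not on the division grid are snapped to the nearest completed division
    and the mapping recorded.  ``mode='exact'`` propagates the distribution
    deterministically; ``mode='monte_carlo'`` tracks ``n_molecules``
    sampled molecules (reproducible given ``seed``).
    """
    if mode not in ("exact", "monte_carlo"):
        raise ValueError(f"unknown mode {mode!r}")
    if condition not in ("twoi", "serum"):
        raise ValueError(f"unknown condition {condition!r}")
    loci = list(loci)
    sample_times = sorted(float(t) for t in sample_times)
    distributions: dict[str, dict[float, DyadDistribution]] = {}
    snap_map_all: dict[float, float] = {}
    rng = np.random.default_rng(seed)
    for lp in loci:
        schedule = lp.twoi_schedule if condition == "twoi" else lp.serum_schedule
        T = schedule.T_cycle
        snap = _snap_times(sample_times, T)
        snap_map_all.update({t: k * T for t, k in snap.items()})
        want = {}
        for t, k in snap.items():
            want.setdefault(k, []).append(t)
        max_div = max(want)
        init = steady_state(lp.serum_schedule)
        by_time: dict[float, DyadDistribution] = {}
        if mode == "exact":
            dist = init
            if 0 in want:
                for t in want[0]:
                    by_time[t] = dist
            for k in range(1, max_div + 1):
                rates = schedule.at((k - 0.5) * T)
                dist = advance_cycle(dist, rates)
                if k in want:
                    for t in want[k]:
                        by_time[t] = dist
        else:
            states = rng.choice(
                len(DYAD_STATES), size=n_molecules, p=init.p
            ).astype(np.int64)
            if 0 in want:
                emp = _empirical(states)
                for t in want[0]:
                    by_time[t] = emp
            for k in range(1, max_div + 1):
                rates = schedule.at((k - 0.5) * T)
                states = _mc_advance(states, rates, rng)
                if k in want:
                    emp = _empirical(states)
                    for t in want[k]:
                        by_time[t] = emp
        distributions[lp.locus_id] = by_time
    return TimeCourse(
        sample_times=sample_times,
        loci=loci,
        distributions=distributions,
        snap_map=snap_map_all,
        mode=mode,
    )


def _empirical(states: np.ndarray) -> DyadDistribution:
    counts = np.bincount(states, minlength=len(DYAD_STATES)).astype(float)
    return DyadDistribution(counts / counts.sum())


def sample_molecules(
    dist: DyadDistribution, n: int, seed: int | None = None
) -> list[tuple[str, str]]:
    """Draw ``n`` dyad states i.i.d. from ``dist`` (reproducible by seed)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(DYAD_STATES), size=n, p=dist.p)
    return [DYAD_STATES[i] for i in idx]
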