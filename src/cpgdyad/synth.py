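"""Synthetic raw-data generators.

Every generator is a pure function of (truth, configuration, seed): the
same inputs give byte-identical outputs.  Truth comes from the kinetic
simulator; the generators add the measurement layer — binomially sampled
bisulphite calls with conversion errors, hairpin BS/oxBS read pairs drawn
from separate molecule pools, and qPCR Ct triplets with Gaussian noise.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .chemistry import ErrorRates, marginal_call_prob_c, strand_call_prob_c
from .kinetics import TimeCourse, simulate_timecourse
from .panel import LocusPanel, build_default_panel, write_panel_beds
from .states import MARK_INDEX, DyadDistribution

#: Ct value reported when a digestion leaves no amplifiable template.
CT_CAP = 40.0

#: Default 2i sampling grid (hours): 0, 24 h, 72 h, 7 d, 11 d, 24 d.
DEFAULT_SAMPLE_TIMES = (0.0, 24.0, 72.0, 168.0, 264.0, 576.0)

SCENARIOS = ("serum_steady", "twoi_timecourse", "tet_loss", "dnmt3_kd")


@dataclass(frozen=True)
class ReadDepthModel:
    """Poisson read depth per CpG per strand."""

    mean_depth: float = 50.0

    def __post_init__(self):
        if self.mean_depth < 0:
            raise ValueError("mean_depth must be >= 0")


@dataclass(frozen=True)
class CtModel:
    """qPCR response: Ct = ct_at_full_input - log(R)/log(E_q) + noise."""

    ct_at_full_input: float = 20.0
    efficiency: float = 2.0
    sigma_ct: float = 0.05

    def __post_init__(self):
        if not 1.0 < self.efficiency <= 2.0:
            raise ValueError("efficiency must be in (1, 2]")
        if self.sigma_ct < 0:
            raise ValueError("sigma_ct must be >= 0")


# ---------------------------------------------------------------------------
# WGBS / RRBS call tables


def _strand_truth(dist: DyadDistribution, strand: str) -> tuple[float, float, float]:
    marg = dist.strand_marginal("top" if strand == "+" else "bottom")
    return (
        float(marg[MARK_INDEX["m"]]),
        float(marg[MARK_INDEX["h"]]),
        float(marg[MARK_INDEX["u"]]),
    )


def generate_wgbs_calls(
    timecourse: TimeCourse,
    panel: LocusPanel,
    depth_model: ReadDepthModel | None = None,
    error_rates: ErrorRates | None = None,
    seed: int = 0,
) -> dict[float, pd.DataFrame]:
    """Per-CpG, per-strand bisulphite call tables, one per sample time.

    The + strand of a CpG reports the top strand of the dyad at position
    ``pos``; the - strand reports the bottom strand at ``pos + 1``.  Read
    totals are Poisson(mean_depth); methylated-call counts are binomial
    with P(C) = (1-e_m) P(m) + (1-e_h_bs) P(h) + f P(u).
    """
    depth_model = depth_model or ReadDepthModel()
    error_rates = error_rates or ErrorRates()
    if not timecourse.distributions:
        raise ValueError("empty timecourse")
    rng = np.random.default_rng(seed)
    tables: dict[float, pd.DataFrame] = {}
    for t in timecourse.sample_times:
        rows = []
        for locus in panel:
            dist = timecourse.distributions[locus.locus_id][t]
            for pos in locus.cpg_positions:
                for strand, call_pos in (("+", pos), ("-", pos + 1)):
                    p_m, p_h, p_u = _strand_truth(dist, strand)
                    p_c = marginal_call_prob_c(p_m, p_h, p_u, "BS", error_rates)
                    total = int(rng.poisson(depth_model.mean_depth))
                    meth = int(rng.binomial(total, p_c)) if total > 0 else 0
                    rows.append(
                        (locus.chrom, call_pos, strand, meth, total)
                    )
        table = pd.DataFrame(
            rows, columns=["chrom", "pos", "strand", "meth_count", "total_count"]
        )
        table["sample_id"] = f"t{t:g}h"
        if depth_model.mean_depth == 0:
            warnings.warn("mean_depth=0: call table has zero coverage")
        tables[t] = table
    return tables


def mspi_fragments(panel: LocusPanel) -> list[tuple[str, int, int]]:
    """In-silico MspI fragments (chrom, start, end), 0-based half-open.

    MspI cuts C^CGG: the cut position is offset +1 within each CCGG.
    Fragments are the intervals between consecutive cut positions on a
    chromosome (sites pooled across loci, as in a real digest).
    """
    cuts_by_chrom: dict[str, list[int]] = {}
    for locus in panel:
        cuts_by_chrom.setdefault(locus.chrom, []).extend(
            s + 1 for s in locus.mspi_sites
        )
    frags = []
    for chrom, cuts in cuts_by_chrom.items():
        cuts = sorted(set(cuts))
        for a, b in zip(cuts, cuts[1:]):
            frags.append((chrom, a, b))
    return frags


def generate_rrbs_subset(
    calls: pd.DataFrame,
    panel: LocusPanel,
    size_window: tuple[float, float] = (40, 220),
) -> pd.DataFrame:
    """Restrict a call table to CpGs inside size-selected MspI fragments.

    A call at 1-based position p lies in fragment [a, b) if a <= p-1 < b.
    """
    lo, hi = size_window
    frags = [
        (chrom, a, b)
        for chrom, a, b in mspi_fragments(panel)
        if lo <= (b - a) <= hi
    ]
    if not frags:
        warnings.warn("no MspI fragments in the size window; RRBS output empty")
        return calls.iloc[0:0].copy()
    keep = np.zeros(len(calls), dtype=bool)
    pos0 = calls["pos"].to_numpy() - 1
    chroms = calls["chrom"].to_numpy()
    for chrom, a, b in frags:
        keep |= (chroms == chrom) & (pos0 >= a) & (pos0 < b)
    return calls.loc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Hairpin reads


def generate_hairpin_reads(
    dist: DyadDistribution,
    n_reads: int,
    assay: str,
    error_rates: ErrorRates | None = None,
    seed: int = 0,
    site_id: str = "site",
) -> pd.DataFrame:
    """Hairpin read-pattern counts for one site under one assay.

    Each read reports (top_call, bottom_call) in {C,T}^2.  BS and oxBS
    reads come from separate molecule pools (the treatments are
    destructive), so call this once per assay with distinct seeds.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    error_rates = error_rates or ErrorRates()
    if assay not in ("BS", "oxBS"):
        raise ValueError(f"unknown assay {assay!r}")
    rng = np.random.default_rng(seed)
    from .states import DYAD_STATES

    idx = rng.choice(len(DYAD_STATES), size=n_reads, p=dist.p)
    counts: dict[tuple[str, str], int] = {}
    pc = {mark: strand_call_prob_c(mark, assay, error_rates) for mark in "mhu"}
    top_marks = np.array([MARK_INDEX[a] for a, _ in DYAD_STATES])[idx]
    bot_marks = np.array([MARK_INDEX[b] for _, b in DYAD_STATES])[idx]
    pc_vec = np.array([pc["m"], pc["h"], pc["u"]])
    top_c = rng.random(n_reads) < pc_vec[top_marks]
    bot_c = rng.random(n_reads) < pc_vec[bot_marks]
    for tc in (True, False):
        for bc in (True, False):
            n = int(np.sum((top_c == tc) & (bot_c == bc)))
            counts[("C" if tc else "T", "C" if bc else "T")] = n
    rows = [
        dict(site_id=site_id, assay=assay, top_call=a, bottom_call=b, count=n)
        for (a, b), n in sorted(counts.items())
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# GlucMS-qPCR Ct triplets


def resistant_truth(dist: DyadDistribution) -> tuple[float, float]:
    """(R_MspI, R_HpaII) under the assayed-strand convention.

    After glucosylation MspI is blocked by glucosyl-5hmC only, HpaII by
    any modification; a molecule's resistance is decided by the mark on
    the assayed strand, so R_MspI = P(strand h), R_HpaII = P(strand m or h).
    """
    marg = dist.strand_marginal("both")
    r_mspi = float(marg[MARK_INDEX["h"]])
    r_hpaii = float(marg[MARK_INDEX["m"]] + marg[MARK_INDEX["h"]])
    return r_mspi, r_hpaii


def generate_glucms_ct(
    dist: DyadDistribution,
    ct_model: CtModel | None = None,
    seed: int = 0,
    replicates: int = 3,
    site_id: str = "site",
) -> pd.DataFrame:
    """Mock/HpaII/MspI Ct triplets for one site.

    Ct = ct_at_full_input - log(R)/log(E_q) + N(0, sigma_ct); the mock
    digestion uses R = 1.  R = 0 gives the capped no-amplification Ct
    (flagged via the ``capped`` column).
    """
    ct_model = ct_model or CtModel()
    rng = np.random.default_rng(seed)
    r_mspi, r_hpaii = resistant_truth(dist)
    rows = []
    for rep in range(1, replicates + 1):
        for enzyme, r in (("mock", 1.0), ("hpaii", r_hpaii), ("mspi", r_mspi)):
            if r <= 0.0:
                ct, capped = CT_CAP, True
            else:
                ct = (
                    ct_model.ct_at_full_input
                    - math.log(r) / math.log(ct_model.efficiency)
                    + rng.normal(0.0, ct_model.sigma_ct)
                )
                ct, capped = min(ct, CT_CAP), ct >= CT_CAP
            rows.append(
                dict(
                    site_id=site_id,
                    replicate_id=rep,
                    enzyme=enzyme,
                    ct=ct,
                    capped=capped,
                )
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Scenario bundles


@dataclass
class SyntheticBundle:
    """Everything one scenario produces: truth plus raw measurement tables."""

    scenario: str
    panel: LocusPanel
    timecourse: TimeCourse
    wgbs_calls: dict[float, pd.DataFrame]
    hairpin_reads: pd.DataFrame
    ct_triplets: pd.DataFrame
    manifest: dict

    def write(self, out_dir) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_panel_beds(self.panel, out_dir / "annotations")
        for t, table in self.wgbs_calls.items():
            table.to_csv(
                out_dir / f"wgbs_t{t:g}h.tsv", sep="\t", index=False
            )
        self.hairpin_reads.to_csv(out_dir / "hairpin_reads.csv", index=False)
        self.ct_triplets.to_csv(out_dir / "ct_triplets.csv", index=False)
        self.timecourse.to_dataframe().to_csv(
            out_dir / "truth_timecourse.tsv", sep="\t", index=False
        )
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)
        return out_dir


def scenario(
    name: str,
    overrides: dict | None = None,
    seed: int = 0,
) -> SyntheticBundle:
    """Generate the full synthetic dataset bundle for a named scenario.

    ``serum_steady``     loci held under their serum schedules.
    ``twoi_timecourse``  the default 2i switch.
    ``tet_loss``         oxidation disabled (kappa scaled to 0) everywhere.
    ``dnmt3_kd``         de novo disabled under serum schedules; cells
                         start from the normal serum steady state.
    """
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; valid: {SCENARIOS}")
    overrides = dict(overrides or {})
    sample_times = tuple(overrides.pop("sample_times", DEFAULT_SAMPLE_TIMES))
    depth = ReadDepthModel(overrides.pop("mean_depth", 50.0))
    errors = overrides.pop("error_rates", None) or ErrorRates()
    ct_model = overrides.pop("ct_model", None) or CtModel()
    n_hairpin = int(overrides.pop("n_hairpin_reads", 10_000))
    if overrides:
        raise ValueError(f"unknown overrides: {sorted(overrides)}")

    panel = build_default_panel(seed=seed)
    condition = "twoi"
    if name == "serum_steady":
        condition = "serum"
    elif name == "tet_loss":
        panel = panel.map_params(lambda p: p.with_kappa_scale(0.0))
    elif name == "dnmt3_kd":
        # knockdown of the de novo enzymes in serum: delta -> 0 from t=0,
        # but the starting state is the pre-knockdown serum steady state,
        # so simulate under the (delta = 0) serum schedule as "2i" slot.
        panel = panel.map_params(
            lambda p: type(p)(
                locus_id=p.locus_id,
                class_label=p.class_label,
                serum_schedule=p.serum_schedule,
                twoi_schedule=p.with_delta_zero().serum_schedule,
            )
        )

    timecourse = simulate_timecourse(
        panel.locus_params(), sample_times, mode="exact", condition=condition
    )
    wgbs = generate_wgbs_calls(
        timecourse, panel, depth, errors, seed=seed + 1
    )
    hairpin_parts = []
    ct_parts = []
    sub = seed
    for locus in panel:
        for t in sample_times:
            dist = timecourse.distributions[locus.locus_id][t]
            tag = f"{locus.locus_id}@t{t:g}h"
            for assay in ("BS", "oxBS"):
                sub += 1
                hairpin_parts.append(
                    generate_hairpin_reads(
                        dist, n_hairpin, assay, errors, seed=sub, site_id=tag
                    )
                )
            sub += 1
            ct_parts.append(
                generate_glucms_ct(dist, ct_model, seed=sub, site_id=tag)
            )
    manifest = dict(
        scenario=name,
        seed=seed,
        sample_times=list(sample_times),
        snapped_times={str(k): v for k, v in timecourse.snap_map.items()},
        mean_depth=depth.mean_depth,
        n_hairpin_reads=n_hairpin,
        error_rates=asdict(errors),
        ct_model=asdict(ct_model),
        loci=[
            dict(
                locus_id=loc.locus_id,
                class_label=loc.class_label,
                chrom=loc.chrom,
                start=loc.start,
                end=loc.end,
                cgi=loc.cgi_flag,
                n_cpg=len(loc.cpg_positions),
                n_mspi=len(loc.mspi_sites),
            )
            for loc in panel
        ],
    )
    return SyntheticBundle(
        scenario=name,
        panel=panel,
        timecourse=timecourse,
        wgbs_calls=wgbs,
        hairpin_reads=pd.concat(hairpin_parts, ignore_index=True),
        ct_triplets=pd.concat(ct_parts, ignore_index=True),
        manifest=manifest,
    )
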