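"""GlucMS-qPCR deconvolution of absolute 5mC and 5hmC fractions.

Genomic 5hmC is glucosylated, then aliquots are digested with HpaII
(blocked by any modification of the CCGG's internal C), MspI (blocked only
by glucosyl-5hmC) or nothing (mock).  qPCR across the site quantifies the
resistant fraction of each digestion relative to mock, so

    frac_5hmC = R_MspI,     frac_5mC = R_HpaII - R_MspI.

The dCt -> fraction conversion uses a single fixed amplification
efficiency (mock-normalized, no standard curve); replicates are averaged
on the fraction scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synth import CT_CAP

#: HpaII below MspI by more than this margin flags an inconsistent replicate.
ORDER_TOL = 0.05


@dataclass(frozen=True)
class ResistantFraction:
    value: float
    clipped: bool = False
    capped: bool = False

    def __float__(self) -> float:
        return self.value


def resistant_fraction(
    ct_digested: float, ct_mock: float, efficiency: float = 2.0
) -> ResistantFraction:
    """Digestion-resistant fraction E_q^(ct_mock - ct_digested).

    Values above 1 (digested Ct below mock) are clipped to 1 with a flag;
    a capped no-amplification Ct maps to 0 with a flag.
    """
    if not 1.0 < efficiency <= 2.0:
        raise ValueError("efficiency must be in (1, 2]")
    if ct_mock is None or (isinstance(ct_mock, float) and math.isnan(ct_mock)):
        raise ValueError("missing mock Ct")
    if ct_digested >= CT_CAP:
        return ResistantFraction(0.0, capped=True)
    raw = float(efficiency) ** float(ct_mock - ct_digested)
    if raw > 1.0:
        return ResistantFraction(1.0, clipped=True)
    return ResistantFraction(raw)


@dataclass
class SiteQuant:
    """Absolute modification fractions at one CpG site."""

    site_id: str
    frac_5hmC: float
    frac_5mC: float
    frac_unmod: float
    se_5hmC: float
    se_5mC: float
    n_replicates: int
    clipped: bool = False
    inconsistent: bool = False
    flags: list[str] = field(default_factory=list)


def quantify_site(
    triplets: pd.DataFrame, efficiency: float = 2.0, site_id: str | None = None
) -> SiteQuant:
    """Deconvolve one site's Ct triplets into (5hmC, 5mC, unmodified).

    ``triplets`` holds columns replicate_id, enzyme in {mock, hpaii, mspi},
    ct.  Per replicate: frac_5hmC = R_MspI; frac_5mC = R_HpaII - R_MspI.
    Means are taken across replicates on the fraction scale, clipped to a
    valid composition; SEs are SD/sqrt(n) of the per-replicate fractions.
    A replicate with R_HpaII < R_MspI - 0.05 (a biologically impossible
    ordering: HpaII resistance includes MspI resistance) is flagged.
    """
    if len(triplets) == 0:
        raise ValueError("no replicates")
    if site_id is None:
        site_id = str(triplets["site_id"].iloc[0]) if "site_id" in triplets else "site"
    reps_h = []
    reps_m = []
    clipped = False
    inconsistent = False
    flags: list[str] = []
    for rep, grp in triplets.groupby("replicate_id"):
        by_enzyme = {str(e).lower(): float(c) for e, c in zip(grp["enzyme"], grp["ct"])}
        if "mock" not in by_enzyme:
            raise ValueError(f"replicate {rep}: missing mock Ct")
        mock = by_enzyme["mock"]
        r_mspi = resistant_fraction(by_enzyme["mspi"], mock, efficiency)
        r_hpaii = resistant_fraction(by_enzyme["hpaii"], mock, efficiency)
        clipped |= r_mspi.clipped or r_hpaii.clipped
        if r_hpaii.value < r_mspi.value - ORDER_TOL:
            inconsistent = True
            flags.append(f"replicate {rep}: HpaII resistance below MspI resistance")
        reps_h.append(r_mspi.value)
        reps_m.append(min(max(r_hpaii.value - r_mspi.value, 0.0), 1.0))
    if not reps_h:
        raise ValueError("no replicates")
    n = len(reps_h)
    frac_5hmC = float(np.mean(reps_h))
    frac_5mC = float(np.mean(reps_m))
    if frac_5hmC + frac_5mC > 1.0:
        clipped = True
        frac_5mC = 1.0 - frac_5hmC
    frac_unmod = 1.0 - frac_5hmC - frac_5mC
    se = lambda xs: float(np.std(xs, ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return SiteQuant(
        site_id=site_id,
        frac_5hmC=frac_5hmC,
        frac_5mC=frac_5mC,
        frac_unmod=frac_unmod,
        se_5hmC=se(reps_h),
        se_5mC=se(reps_m),
        n_replicates=n,
        clipped=clipped,
        inconsistent=inconsistent,
        flags=flags,
    )


def quantify_table(
    triplets: pd.DataFrame, efficiency: float = 2.0
) -> pd.DataFrame:
    """Apply :func:`quantify_site` per site_id; tabular output."""
    rows = []
    for site_id, grp in triplets.groupby("site_id", sort=True):
        q = quantify_site(grp, efficiency, site_id=str(site_id))
        rows.append(
            dict(
                site_id=q.site_id,
                frac_5hmC=q.frac_5hmC,
                frac_5mC=q.frac_5mC,
                frac_unmod=q.frac_unmod,
                se_5hmC=q.se_5hmC,
                se_5mC=q.se_5mC,
                n_replicates=q.n_replicates,
                clipped=q.clipped,
                inconsistent=q.inconsistent,
            )
        )
    return pd.DataFrame(rows)
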