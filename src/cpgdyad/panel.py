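"""The synthetic 10-locus panel.

Five loci demethylate under 2i (four standard, one with a fast, strong
oxidation ramp) and five resist erasure (two imprinting-control-like, two
IAP-retrotransposon-like, one major-satellite-like), mirroring the design
of targeted demethylation assays: a handful of regions that lose most of
their methylation plus controls that do not.

Genomic placement is synthetic: each locus gets a non-overlapping interval
on a simulated chromosome, a set of CpG positions, and a subset of CpGs
embedded in MspI CCGG sites.  CGI-flagged loci are CpG- and MspI-dense, so
an in-silico MspI digest with the usual RRBS size window enriches for them.
Coordinates follow the BED convention externally (0-based, half-open) and
are 1-based internally for per-CpG calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .kinetics import LocusParams

#: (class_label, count, cgi_flag) composition of the default panel.
DEFAULT_COMPOSITION = (
    ("demethylating_standard", 2, True),
    ("demethylating_standard", 2, False),
    ("demethylating_fast_ox", 1, False),
    ("icr_like", 2, True),
    ("iap_like", 2, False),
    ("satellite_like", 1, False),
)


@dataclass(frozen=True)
class PanelLocus:
    """One panel locus: kinetics plus genomic placement."""

    params: LocusParams
    chrom: str
    start: int  # 0-based
    end: int  # half-open
    cpg_positions: tuple[int, ...]  # 1-based position of the + strand C
    mspi_sites: tuple[int, ...]  # 0-based start of each CCGG
    cgi_flag: bool

    @property
    def locus_id(self) -> str:
        return self.params.locus_id

    @property
    def class_label(self) -> str:
        return self.params.class_label


@dataclass
class LocusPanel:
    loci: list[PanelLocus] = field(default_factory=list)

    def __iter__(self):
        return iter(self.loci)

    def __len__(self):
        return len(self.loci)

    def by_id(self, locus_id: str) -> PanelLocus:
        for locus in self.loci:
            if locus.locus_id == locus_id:
                return locus
        raise KeyError(locus_id)

    def locus_params(self) -> list[LocusParams]:
        return [locus.params for locus in self.loci]

    def classes(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for locus in self.loci:
            out[locus.class_label] = out.get(locus.class_label, 0) + 1
        return out

    def map_params(self, fn) -> "LocusPanel":
        """New panel with ``fn`` applied to every locus's LocusParams."""
        return LocusPanel(
            [replace(loc, params=fn(loc.params)) for loc in self.loci]
        )


def _place_cpgs(rng, start, end, n_cpg, n_mspi):
    """Random CpG positions; a subset sits inside MspI CCGG sites.

    A CCGG starting at 0-based s holds the CpG whose C is at 1-based s+2.
    MspI-site CpGs are kept >= 2 bp from the interval edges.
    """
    usable = np.arange(start + 2, end - 2)
    pos0 = np.sort(rng.choice(usable, size=n_cpg, replace=False))
    cpg_positions = tuple(int(p) + 1 for p in pos0)  # 1-based C position
    mspi_cpgs = rng.choice(n_cpg, size=min(n_mspi, n_cpg), replace=False)
    mspi_sites = tuple(sorted(int(pos0[i]) - 1 for i in mspi_cpgs))
    return cpg_positions, mspi_sites


def build_default_panel(seed: int = 0) -> LocusPanel:
    """Deterministic (given seed) default 10-locus panel.

    CGI loci: ~600 bp, 30 CpGs, 8 MspI sites (fragments mostly inside the
    RRBS size window).  Non-CGI loci: ~2400 bp, 15 CpGs, 2 MspI sites
    (fragments mostly outside it).
    """
    rng = np.random.default_rng(seed)
    loci = []
    cursor = 1000
    index = 0
    for class_label, count, cgi_flag in DEFAULT_COMPOSITION:
        for _ in range(count):
            index += 1
            locus_id = f"L{index:02d}_{class_label}"
            if cgi_flag:
                length, n_cpg, n_mspi = 600, 30, 8
            else:
                length, n_cpg, n_mspi = 2400, 15, 2
            start = cursor + int(rng.integers(200, 800))
            end = start + length
            cursor = end
            cpgs, mspi = _place_cpgs(rng, start, end, n_cpg, n_mspi)
            loci.append(
                PanelLocus(
                    params=LocusParams.from_class(locus_id, class_label),
                    chrom="chrS1",
                    start=start,
                    end=end,
                    cpg_positions=cpgs,
                    mspi_sites=mspi,
                    cgi_flag=cgi_flag,
                )
            )
    return LocusPanel(loci)


def write_panel_beds(panel: LocusPanel, out_dir) -> dict[str, Path]:
    """Per-class BED files plus a CGI BED (0-based half-open)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    by_class: dict[str, list[PanelLocus]] = {}
    for locus in panel:
        by_class.setdefault(locus.class_label, []).append(locus)
    written = {}
    for class_label, loci in sorted(by_class.items()):
        path = out_dir / f"{class_label}.bed"
        with open(path, "w") as fh:
            for locus in loci:
                fh.write(
                    f"{locus.chrom}\t{locus.start}\t{locus.end}\t{locus.locus_id}\n"
                )
        written[class_label] = path
    cgi_path = out_dir / "cgi.bed"
    with open(cgi_path, "w") as fh:
        for locus in panel:
            if locus.cgi_flag:
                fh.write(
                    f"{locus.chrom}\t{locus.start}\t{locus.end}\t{locus.locus_id}\n"
                )
    written["cgi"] = cgi_path
    return written


def panel_features(panel: LocusPanel):
    """Panel loci as a feature table (chrom, start, end, class_label, cgi_flag)."""
    import pandas as pd

    return pd.DataFrame(
        [
            dict(
                chrom=loc.chrom,
                start=loc.start,
                end=loc.end,
                feature_id=loc.locus_id,
                class_label=loc.class_label,
                cgi_flag=loc.cgi_flag,
            )
            for loc in panel
        ]
    )
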