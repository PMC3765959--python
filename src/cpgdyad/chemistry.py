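"""Bisulphite / oxidative-bisulphite read-out chemistry.

A strand mark is observed as C or T after conversion.  Under plain BS both
5mC and 5hmC protect the base (read C); under oxBS, 5hmC is first oxidized
so that only 5mC still reads C.  Conversion is imperfect:

- ``f``       bisulphite conversion failure: an unmodified C reads C.
- ``e_m``     inappropriate conversion of 5mC: reads T.
- ``o``       oxBS efficiency: probability that 5hmC is converted to a
              T-reading state under oxBS.
- ``e_h_bs``  5hmC read as T under plain BS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .states import DYAD_STATES, MARKS

ASSAYS = ("BS", "oxBS")

#: Read patterns (top_call, bottom_call) in fixed order.
PATTERNS: tuple[tuple[str, str], ...] = (
    ("C", "C"),
    ("C", "T"),
    ("T", "C"),
    ("T", "T"),
)
PATTERN_INDEX = {p: i for i, p in enumerate(PATTERNS)}


@dataclass(frozen=True)
class ErrorRates:
    f: float = 0.005
    e_m: float = 0.005
    o: float = 0.94
    e_h_bs: float = 0.005

    def __post_init__(self):
        for name in ("f", "e_m", "o", "e_h_bs"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")

    @classmethod
    def error_free(cls) -> "ErrorRates":
        return cls(f=0.0, e_m=0.0, o=1.0, e_h_bs=0.0)


def strand_call_prob_c(mark: str, assay: str, errors: ErrorRates) -> float:
    """P(read C | strand mark, assay)."""
    if assay == "BS":
        table = {"m": 1.0 - errors.e_m, "h": 1.0 - errors.e_h_bs, "u": errors.f}
    elif assay == "oxBS":
        table = {"m": 1.0 - errors.e_m, "h": 1.0 - errors.o, "u": errors.f}
    else:
        raise ValueError(f"unknown assay {assay!r}; valid: {ASSAYS}")
    return table[mark]


def marginal_call_prob_c(
    p_m: float, p_h: float, p_u: float, assay: str, errors: ErrorRates
) -> float:
    """P(read C) for a strand with the given mark fractions."""
    return (
        p_m * strand_call_prob_c("m", assay, errors)
        + p_h * strand_call_prob_c("h", assay, errors)
        + p_u * strand_call_prob_c("u", assay, errors)
    )


def emission_matrix(assay: str, errors: ErrorRates) -> np.ndarray:
    """(9 states x 4 patterns) matrix of P(pattern | dyad state, assay).

    Strand read-outs are conditionally independent given the dyad state.
    """
    pc = {mark: strand_call_prob_c(mark, assay, errors) for mark in MARKS}
    out = np.zeros((len(DYAD_STATES), len(PATTERNS)))
    for i, (a, b) in enumerate(DYAD_STATES):
        pa, pb = pc[a], pc[b]
        out[i] = [pa * pb, pa * (1 - pb), (1 - pa) * pb, (1 - pa) * (1 - pb)]
    return out
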