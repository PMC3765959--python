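"""CpG-dyad modification states and distributions.

Each strand of a CpG dyad carries one of three marks: ``u`` (unmodified
cytosine), ``m`` (5-methylcytosine) or ``h`` (5-hydroxymethylcytosine).
The two strands are distinguishable (top = parental convention after a
division), giving 9 ordered dyad states.  A :class:`DyadDistribution` is a
probability vector over those 9 states at one locus and time.
"""

from __future__ import annotations

from collections.abc import Mapping

import numpy as np

#: The three strand marks, in fixed index order.
MARKS: tuple[str, ...] = ("m", "h", "u")

MARK_INDEX = {mark: i for i, mark in enumerate(MARKS)}

#: The 9 ordered dyad states (top, bottom), row-major in MARKS order.
DYAD_STATES: tuple[tuple[str, str], ...] = tuple(
    (a, b) for a in MARKS for b in MARKS
)

STATE_INDEX = {state: i for i, state in enumerate(DYAD_STATES)}

_SUM_TOL = 1e-12


class DyadDistribution:
    """Probability distribution over the 9 ordered CpG-dyad states.

    Parameters
    ----------
    probs
    Mapping ``(top, bottom) -> probability`` or a length-9 array in
    :data:`DYAD_STATES` order.  Must be non-negative and sum to 1
    within 1e-12.
    """

    __slots__ = ("p",)

    def __init__(self, probs):
        if isinstance(probs, Mapping):
            vec = np.zeros(len(DYAD_STATES))
            for state, value in probs.items():
                vec[STATE_INDEX[tuple(state)]] = value
        else:
            vec = np.asarray(probs, dtype=float)
            if vec.shape != (len(DYAD_STATES),):
                raise ValueError(
                    f"expected {len(DYAD_STATES)} probabilities, got {vec.shape}"
                )
            vec = vec.copy()
        if np.any(vec < -_SUM_TOL):
            raise ValueError("dyad probabilities must be non-negative")
        vec = np.clip(vec, 0.0, None)
        total = vec.sum()
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"dyad probabilities sum to {total!r}, not 1")
        self.p = vec / total

    @classmethod
    def point(cls, top: str, bottom: str) -> "DyadDistribution":
        """Distribution concentrated on a single dyad state."""
        vec = np.zeros(len(DYAD_STATES))
        vec[STATE_INDEX[(top, bottom)]] = 1.0
        return cls(vec)

    def __getitem__(self, state) -> float:
        return float(self.p[STATE_INDEX[tuple(state)]])

    def as_dict(self) -> dict[tuple[str, str], float]:
        return {state: float(v) for state, v in zip(DYAD_STATES, self.p)}

    def strand_marginal(self, strand: str = "both") -> np.ndarray:
        """Marginal mark fractions (m, h, u) for ``top``, ``bottom`` or
        the population strand average ``both``."""
        mat = self.p.reshape(len(MARKS), len(MARKS))
        top = mat.sum(axis=1)
        bottom = mat.sum(axis=0)
        if strand == "top":
            return top
        if strand == "bottom":
            return bottom
        if strand == "both":
            return 0.5 * (top + bottom)
        raise ValueError(f"unknown strand {strand!r}")

    def allclose(self, other: "DyadDistribution", tol: float = 1e-12) -> bool:
        return bool(np.max(np.abs(self.p - other.p)) <= tol)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        nonzero = {
            "".join(s): round(float(v), 6)
            for s, v in zip(DYAD_STATES, self.p)
            if v > 1e-9
        }
        return f"DyadDistribution({nonzero})"


def summarize(dist: DyadDistribution) -> dict[str, float]:
    """Summaries of a dyad distribution.

    Returns strand-level mark fractions (each strand counted once, so the
    fraction of mark X is ``(2 P(X,X) + sum of P(X paired with other)) / 2``),
    dyad categories (fully modified = both strands in {m, h}; hemi = exactly
    one; unmodified = neither) and mark-resolved dyad categories.
    """
    marg = dist.strand_marginal("both")
    out = {
        "frac_5mC": float(marg[MARK_INDEX["m"]]),
        "frac_5hmC": float(marg[MARK_INDEX["h"]]),
        "frac_C": float(marg[MARK_INDEX["u"]]),
    }
    fully = hemi = unmod = 0.0
    fully_mm = fully_hh = fully_mixed = 0.0
    hemi_m = hemi_h = 0.0
    for (a, b), prob in zip(DYAD_STATES, dist.p):
        a_mod = a != "u"
        b_mod = b != "u"
        if a_mod and b_mod:
            fully += prob
            if a == "m" and b == "m":
                fully_mm += prob
            elif a == "h" and b == "h":
                fully_hh += prob
            else:
                fully_mixed += prob
        elif a_mod or b_mod:
            hemi += prob
            mark = a if a_mod else b
            if mark == "m":
                hemi_m += prob
            else:
                hemi_h += prob
        else:
            unmod += prob
    out.update(
        fully_modified=float(fully),
        hemi_modified=float(hemi),
        unmodified=float(unmod),
        fully_mm=float(fully_mm),
        fully_hh=float(fully_hh),
        fully_mixed=float(fully_mixed),
        hemi_m=float(hemi_m),
        hemi_h=float(hemi_h),
    )
    return out
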