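"""Observed/expected upper-bound fractions (OEUF) and derived cut-offs.

Given an observed count k and a model-expected count λ′, the constraint of
an element is summarised by a 90% interval on the ratio k/λ′ built on a
grid: for every ratio x on [0, 2] in steps of 0.001 the Poisson pmf
G(X=k | λ = x·λ′) is evaluated, the values are cumulatively summed and
normalised to end at 1, and the lower/upper bounds are the smallest grid
ratios whose normalised cumulative value reaches 0.05 and 0.95.  The upper
bound is the OEUF; by construction it is capped at the grid maximum 2.0.

SNVOEUF, MOEUF and LOEUF are the OEUF restricted to all SNVs, missense
variants, and loss-of-function variants (start-loss, stop-loss, stop-gain).
An element is "powered" for a class when it expects at least 10 variants
of that class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

GRID_STEP = 0.001
GRID_MAX = 2.0
POWERED_MIN_EXPECTED = 10.0

OEUF_CLASSES = ("SNVOEUF", "MOEUF", "LOEUF")


def poisson_bounds(
    observed: int,
    expected: float,
    step: float = GRID_STEP,
    grid_max: float = GRID_MAX,
) -> tuple[float, float]:
    """90% grid bounds on the observed/expected ratio of a Poisson count.

    Returns (lower, upper): the smallest grid ratios at which the
    normalised cumulative Poisson pmf reaches 0.05 and 0.95.
    """
    if expected <= 0:
        raise ValueError(f"expected count must be positive, got {expected}")
    if observed < 0 or observed != int(observed):
        raise ValueError(f"observed count must be a non-negative integer, got {observed}")
    n_steps = int(round(grid_max / step))
    xs = np.arange(n_steps + 1) * step
    pmf = stats.poisson.pmf(int(observed), xs * expected)
    cum = np.cumsum(pmf)
    total = cum[-1]
    if total <= 0:
        # the ratio k/expected lies so far above the grid that the pmf
        # underflows everywhere; all mass sits beyond the top of the grid
        return float(xs[-1]), float(xs[-1])
    norm = cum / total
    lower = float(xs[np.searchsorted(norm, 0.05, side="left")])
    upper = float(xs[np.searchsorted(norm, 0.95, side="left")])
    return lower, upper


@dataclass
class OEUFResult:
    """Constraint summary of one element for one variant class."""

    element_id: str
    oeuf_class: str  # SNVOEUF | MOEUF | LOEUF
    observed: int
    expected: float
    lower: float
    upper: float          # the OEUF
    point_ratio: float
    powered: bool
    computable: bool = True


def compute_oeuf(
    element_id: str,
    observed: int,
    expected: float,
    oeuf_class: str,
    powered_min_expected: float = POWERED_MIN_EXPECTED,
    step: float = GRID_STEP,
    grid_max: float = GRID_MAX,
) -> OEUFResult:
    """OEUF of one element/class; unpowered results are kept but flagged.

    An element with non-positive expected count for the class cannot be
    evaluated and comes back with ``computable=False``.
    """
    if expected <= 0:
        return OEUFResult(
            element_id=element_id, oeuf_class=oeuf_class, observed=observed,
            expected=expected, lower=float("nan"), upper=float("nan"),
            point_ratio=float("nan"), powered=False, computable=False,
        )
    lower, upper = poisson_bounds(observed, expected, step=step, grid_max=grid_max)
    return OEUFResult(
        element_id=element_id,
        oeuf_class=oeuf_class,
        observed=observed,
        expected=expected,
        lower=lower,
        upper=upper,
        point_ratio=observed / expected,
        powered=expected >= powered_min_expected,
    )


def decile_cutoff(
    values: Sequence[float],
    ids: Sequence[str] | None = None,
) -> tuple[float, list[int]]:
    """Equal-count decile binning of an OEUF distribution.

    Values are sorted ascending (ties broken by element id for
    determinism), split into 10 equal-count bins, and the cut-off is the
    maximum value of the most constrained (lowest) bin.  Returns the
    cut-off and each input value's decile index 1..10 in input order.
    Rank r (0-based) of n values falls in decile 1 + (r*10)//n, so the
    lowest decile holds the first ceil(n/10) values when 10 does not
    divide n.
    """
    n = len(values)
    if n < 10:
        raise ValueError(f"need at least 10 values to form deciles, got {n}")
    if ids is None:
        ids = [str(i) for i in range(n)]
    order = sorted(range(n), key=lambda i: (values[i], ids[i]))
    deciles = [0] * n
    cutoff = None
    for rank, i in enumerate(order):
        d = 1 + (rank * 10) // n
        deciles[i] = d
        if d == 1:
            cutoff = values[i] if cutoff is None else max(cutoff, values[i])
    return float(cutoff), deciles


def frame_respect_flag(moeuf: OEUFResult, snvoeuf: OEUFResult) -> bool:
    """True when missense constraint is tighter than all-SNV constraint.

    An sORF whose MOEUF upper bound is strictly below its SNVOEUF upper
    bound is more likely constrained in its own reading frame rather than
    reflecting out-of-frame background.  Both results must be powered and
    refer to the same element.
    """
    if moeuf.element_id != snvoeuf.element_id:
        raise ValueError(
            f"element mismatch: {moeuf.element_id} vs {snvoeuf.element_id}"
        )
    if not (moeuf.powered and snvoeuf.powered):
        raise ValueError("frame-respect comparison requires both classes powered")
    return moeuf.upper < snvoeuf.upper


def regional_utr_constraint(
    gene_id: str,
    utr_deciles: Sequence[int],
    utr_expected: Sequence[float],
    utr_lengths: Sequence[int] | None = None,
    min_len: int = 0,
    powered_min_expected: float = POWERED_MIN_EXPECTED,
) -> bool:
    """Regional UTR constraint of one gene from its UTRs' decile indices.

    Deciles come from ``decile_cutoff`` over the *full* UTR OEUF
    distribution.  After dropping UTRs that expect fewer than 10 variants
    or are shorter than ``min_len``, the gene is regionally constrained
    when some pair of its UTRs sits in separated deciles delimited by at
    least two other deciles, i.e. decile indices differ by >= 3.
    """
    if utr_lengths is None:
        if min_len > 0:
            raise ValueError("utr_lengths required when min_len > 0")
        utr_lengths = [0] * len(utr_deciles)
    kept = [
        d
        for d, e, ln in zip(utr_deciles, utr_expected, utr_lengths)
        if e >= powered_min_expected and ln >= min_len
    ]
    if len(kept) < 2:
        return False
    return max(kept) - min(kept) >= 3
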