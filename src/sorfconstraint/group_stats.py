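"""Effect sizes, rank summaries and orchestrated distribution comparisons.

The Vargha–Delaney A measure and pooled mean ranks are computed natively;
the classical tests (Kolmogorov–Smirnov, Mann–Whitney U, Wilcoxon
signed-rank, Kendall tau) are delegated to scipy.  Comparisons between
independent groups exclude sORF classes that overlap canonical coding
sequence (intORF, uoORF, doORF), whose constraint values are not
independent of the overlapped gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

#: sORF classes whose constraint is independent of canonical coding regions
INDEPENDENT_CLASSES = ("uORF", "dORF", "lncRNA-ORF")

P_FLOOR = 0.001


def format_p(p: float, floor: float = P_FLOOR) -> str:
    """Human-readable p-value with the conventional reporting floor."""
    return f"<{floor:g}" if p < floor else f"{p:.3g}"


def vargha_delaney_a(x: Sequence[float], y: Sequence[float]) -> float:
    """Probability that a value from group one exceeds one from group two.

    A = (#{x_i > y_j} + 0.5 * #{x_i = y_j}) / (|x| * |y|), computed through
    pooled ranks so it stays O(n log n).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = len(x), len(y)
    ranks = stats.rankdata(np.concatenate([x, y]))
    r1 = ranks[:n1].sum()
    return float((r1 / n1 - (n1 + 1) / 2) / n2)


@dataclass
class RankSummary:
    """Pooled-rank summary of a two-group comparison."""

    m_rank1: float
    m_rank2: float
    u: float  # Mann-Whitney U of group 1
    n1: int
    n2: int


def mean_ranks(x: Sequence[float], y: Sequence[float]) -> RankSummary:
    """Per-group mean of pooled average ranks and the U statistic.

    Ranks are assigned on the concatenated sample with average ranks for
    ties; U follows from the rank-sum relation U1 = R1 - n1(n1+1)/2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = len(x), len(y)
    ranks = stats.rankdata(np.concatenate([x, y]))
    r1 = float(ranks[:n1].sum())
    r2 = float(ranks[n1:].sum())
    return RankSummary(
        m_rank1=r1 / n1, m_rank2=r2 / n2, u=r1 - n1 * (n1 + 1) / 2, n1=n1, n2=n2
    )


@dataclass
class Comparison:
    """One planned comparison between two value vectors."""

    name: str
    x: np.ndarray
    y: np.ndarray
    paired: bool = False
    kendall: bool = False
    # class labels aligned with x; rows from overlap classes are excluded
    # before independence-assuming tests
    x_classes: Sequence[str] | None = None


def _independent_subset(values: np.ndarray, classes: Sequence[str] | None) -> np.ndarray:
    if classes is None:
        return values
    mask = np.array([c in INDEPENDENT_CLASSES for c in classes])
    return values[mask]


def run_comparisons(plan: Sequence[Comparison]) -> pd.DataFrame:
    """Run the planned comparisons and assemble a tidy report.

    Independent comparisons get KS, Mann–Whitney U with mean ranks and
    Vargha–Delaney A; paired comparisons get the Wilcoxon signed-rank test
    (pairs with a missing member are dropped and logged); Kendall tau-b is
    added where requested.  Raw p-values are retained alongside the
    floored display form.
    """
    rows: list[dict] = []
    for comp in plan:
        x = np.asarray(comp.x, dtype=float)
        y = np.asarray(comp.y, dtype=float)
        if comp.paired:
            if len(x) != len(y):
                raise ValueError(f"{comp.name}: paired vectors differ in length")
            ok = np.isfinite(x) & np.isfinite(y)
            dropped = int((~ok).sum())
            if dropped:
                log.info("%s: dropped %d incomplete pairs", comp.name, dropped)
            x, y = x[ok], y[ok]
            w = stats.wilcoxon(x, y)
            rows.append(_row(comp.name, "wilcoxon", w.statistic, w.pvalue, n1=len(x), n2=len(y)))
            if comp.kendall:
                tau = stats.kendalltau(x, y)  # tau-b: tie-corrected
                rows.append(_row(comp.name, "kendall_tau", tau.statistic, tau.pvalue,
                                 n1=len(x), n2=len(y)))
            continue

        x = _independent_subset(x, comp.x_classes)
        x = x[np.isfinite(x)]
        y = y[np.isfinite(y)]
        ks = stats.ks_2samp(x, y)
        rows.append(_row(comp.name, "ks_2samp", ks.statistic, ks.pvalue, n1=len(x), n2=len(y)))
        mwu = stats.mannwhitneyu(x, y, alternative="two-sided")
        ranksum = mean_ranks(x, y)
        rows.append(
            _row(
                comp.name, "mannwhitneyu", mwu.statistic, mwu.pvalue,
                n1=len(x), n2=len(y),
                m_rank1=ranksum.m_rank1, m_rank2=ranksum.m_rank2,
                vd_a=vargha_delaney_a(x, y),
            )
        )
    return pd.DataFrame(rows)


def _row(name, test, statistic, p, **extra):
    row = {
        "comparison": name,
        "test": test,
        "statistic": float(statistic),
        "p_raw": float(p),
        "p_display": format_p(float(p)),
    }
    row.update(extra)
    return row
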