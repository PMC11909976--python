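"""Independent oracle implementations used to cross-check the package.

Everything here is deliberately written from first principles (pure
Python loops, Biopython translation) so that agreement with the package
is evidence, not tautology.
"""

from __future__ import annotations

import math


def poisson_grid_bounds_oracle(k: int, expected: float, step: float = 0.001, grid_max: float = 2.0):
    """Grid bounds computed with a hand-rolled Poisson pmf and explicit loops."""
    n_steps = int(round(grid_max / step))
    log_kfact = math.lgamma(k + 1)
    pmf = []
    for n in range(n_steps + 1):
        lam = n * step * expected
        if lam == 0.0:
            pmf.append(1.0 if k == 0 else 0.0)
        else:
            pmf.append(math.exp(k * math.log(lam) - lam - log_kfact))
    total = sum(pmf)
    cum = 0.0
    lower = upper = None
    for n, p in enumerate(pmf):
        cum += p
        value = cum / total
        if lower is None and value >= 0.05:
            lower = n * step
        if upper is None and value >= 0.95:
            upper = n * step
            break
    return lower, upper


def translate_codon_oracle(codon: str) -> str:
    """Translate one codon via Biopython (independent of the package table)."""
    from Bio.Seq import Seq

    return str(Seq(codon).translate())


def consequence_oracle(codon: str, pos: int, alt: str, is_start: bool, is_stop: bool) -> str:
    """Translate-and-compare consequence classification."""
    new = codon[:pos] + alt + codon[pos + 1 :]
    aa_old = translate_codon_oracle(codon)
    aa_new = translate_codon_oracle(new)
    if is_start:
        return "synonymous" if aa_new == aa_old else "start_loss"
    if is_stop:
        return "synonymous" if aa_new == "*" else "stop_loss"
    if aa_new == "*":
        return "stop_gain"
    return "synonymous" if aa_new == aa_old else "missense"


def vargha_delaney_a_bruteforce(x, y) -> float:
    """A-measure by explicit pair counting."""
    gt = sum(1 for xi in x for yj in y if xi > yj)
    eq = sum(1 for xi in x for yj in y if xi == yj)
    return (gt + 0.5 * eq) / (len(x) * len(y))


def mann_whitney_u_bruteforce(x, y) -> float:
    """U statistic of group one by explicit pair counting."""
    return sum(1.0 if xi > yj else 0.5 if xi == yj else 0.0 for xi in x for yj in y)
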