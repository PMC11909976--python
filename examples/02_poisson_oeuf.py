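"""Poisson-grid OEUF bounds for a few observed/expected configurations.

For each pair (observed k, expected lam') the 90% interval on the ratio
k/lam' is computed on the 0..2 grid; the upper bound is the OEUF.  Lower
OEUF means stronger depletion of variation (constraint); a wide interval
means the element is under-powered.
"""

from sorfconstraint import compute_oeuf

cases = [
    ("strongly constrained", 2, 30.0),
    ("neutral, well powered", 30, 30.0),
    ("neutral, borderline", 10, 10.0),
    ("under-powered", 1, 3.0),
]

print(f"{'case':<24}{'obs':>4}{'exp':>7}{'ratio':>7}{'lower':>7}{'OEUF':>7}  powered")
for label, k, lam in cases:
    res = compute_oeuf("demo", k, lam, "SNVOEUF")
    print(
        f"{label:<24}{res.observed:>4}{res.expected:>7.1f}{res.point_ratio:>7.2f}"
        f"{res.lower:>7.3f}{res.upper:>7.3f}  {res.powered}"
    )
print("\nAn element needs >= 10 expected variants before its OEUF is interpretable;")
print("under-powered intervals stretch toward the grid maximum of 2.")
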