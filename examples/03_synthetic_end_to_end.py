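"""Full workflow on synthetic data: neutral run vs missense-depleted run.

Generates a genome with planted sORFs and a variant table sampled from
the mutational model, then runs the whole constraint pipeline: expected
counts, synonymous calibration, OEUF bounds, decile cut-off and the
frame-respect comparison (MOEUF < SNVOEUF).
"""

from sorfconstraint import variant_sites_from_frame
from sorfconstraint.constraint_metrics import decile_cutoff
from sorfconstraint.pipeline import frame_respect_summary, pooled_ratios, run_pipeline
from sorfconstraint.synthetic import SimulationConfig, simulate

for label, selection in (("neutral", {}), ("missense factor 0.5", {"missense": 0.5})):
    ds = simulate(SimulationConfig(seed=42, selection=selection))
    res = run_pipeline(
        ds.genome, ds.sorfs, variant_sites_from_frame(ds.variants), ds.rates, ds.methylation
    )
    ratios = pooled_ratios(res)
    n_true, n_pairs = frame_respect_summary(res)
    snv = [e.oeuf["SNVOEUF"] for e in res.elements if e.oeuf["SNVOEUF"].powered]
    cutoff, _ = decile_cutoff([r.upper for r in snv], [r.element_id for r in snv])
    print(f"--- {label} ({len(res.elements)} sORFs, {len(ds.variants)} variant sites)")
    print(f"calibration constant k = {res.calibration_k:.3e}")
    print(
        "pooled observed/expected: "
        + ", ".join(f"{c}={ratios[c]:.3f}" for c in ("SNV", "synonymous", "missense", "lof"))
    )
    print(f"SNVOEUF decile-1 cut-off: {cutoff:.3f}")
    print(f"frame-respect (MOEUF < SNVOEUF): {n_true}/{n_pairs} powered sORFs\n")

print("Neutral ratios sit near 1 by construction; depleting missense variation")
print("pulls the missense ratio toward 0.5 and flips the frame-respect flag for")
print("most sORFs -- the signature of constraint acting in the sORF's own frame.")
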