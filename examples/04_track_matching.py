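"""Pair genomic elements with a windowed constraint score track.

Shows the two matching paths: averaging windows contained in the element,
and the two-closest-interval fallback for elements smaller than any
window, plus the constrained-percentile cut-off at a score of 4.
"""

import pandas as pd

from sorfconstraint import ScoreTrack, gnocchi_constrained, match_element

track = ScoreTrack(
    pd.DataFrame(
        {
            "chrom": "chr1",
            "start": [0, 1000, 2000, 3000, 4000],
            "end": [1000, 2000, 3000, 4000, 5000],
            "score": [0.2, 4.5, 5.1, 1.0, -0.3],
        }
    )
)

large = match_element(("chr1", 900, 3100), track)          # contains two windows
small = match_element(("chr1", 2400, 2600), track)          # contained in none
print(f"large element: mean score {large.score:.2f} over {large.n_intervals} windows")
print(f"small element: fallback mean {small.score:.2f} of the two closest windows")
for name, res in (("large", large), ("small", small)):
    print(f"  {name} element constrained (score >= 4): {gnocchi_constrained(res.score)}")
print("Scores are constraint z-scores per window; the mean summarises the")
print("element's neighbourhood, and >= 4 marks the most constrained percentile.")
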