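# Methods

## Model overview

The package estimates purifying selection on short open reading frames
(sORFs) by comparing observed variation in a population callset against a
neutral mutational expectation, per consequence class.

**Mutational opportunity.** Every codon of an sORF admits 9 single-base
changes. Each change is classified against the standard nuclear genetic
code with the priority `start_loss > stop_loss > stop_gain >
(synonymous | missense)`: any amino-acid-changing substitution in the
first codon is a start-loss; a stop-codon change yielding another stop is
synonymous; one yielding a coding codon is a stop-loss. This native
classifier replaces an external annotator, so no splice classes exist;
when externally annotated variants are imported, records whose only
annotation is a splice class can be dropped with an import-time filter.

**Context and methylation.** Mutation rates are looked up by the genomic
trinucleotide around each base (middle base = the mutated base), the
alternate allele, and a methylation bin. Contexts are *genomic*
(pre-splicing): the mutation mechanism acts on DNA, so across a splice
junction the intronic neighbour is used, while codons are read from the
spliced sequence. Both are oriented to the coding strand; rate lookups
fall back to the reverse-complement context, matching strand-collapsed
published tables. Methylation is the mean fraction across epigenome
tracks, discretised into 16 equal bins on [0, 1] (left-closed, last bin
closed). Because methylation only modulates mutability at CpG sites, the
bin is consulted only where the context contains a CpG dinucleotide and
forced to 0 elsewhere (flag `cpg_only_methylation`, on by default).

**Observed and excluded sites.** Observed variants count once per unique
(chrom, pos, ref, alt) and must be SNVs with AF < 0.1%, FILTER = PASS and
site depth ≥ 1. Symmetrically, possible variants at sites the callset
cannot inform are excluded from the expectation: positions carrying a
low-quality call, alleles at AF ≥ 0.1%, or depth < 1. The source
protocol quotes "median depth" for observed filtering and "mean depth"
for possible-variant exclusion; the package deliberately uses a single
per-site depth statistic for both (knob `depth_min`, default 1). Depth
defaults to 30 at positions without a record — a production depth summary
covers every position, whereas the toy inputs carry depth only at called
sites.

**Calibration.** Expected counts are E = k·Σμ per class. k is the slope
of a zero-intercept least-squares fit of observed synonymous counts on
synonymous rate sums across reference elements (synonymous variation is
assumed neutral). The fit is a deliberately simple stand-in for the full
proportion-observed calibration used by large constraint pipelines; with
no reference set, k = 1 and expectations are relative rates (a warning is
logged).

## OEUF bounds

For observed k and expected λ′ > 0, the Poisson pmf
G(X=k | λ = x·λ′) is evaluated at x = n·0.001, n = 0…2000, cumulatively
summed and normalised to end at 1. The lower/upper bounds are the
smallest grid ratios whose normalised cumulative value reaches 0.05 and
0.95; the upper bound is the OEUF, capped at 2 by construction. The
source text is internally inconsistent about the grid (prose: steps of
0.001 over [0, 2]; formula: x = n·0.0001 with n ≤ 2000, which spans only
[0, 0.2]); the prose range is used and the step is configurable. When
k/λ′ lies so far above 2 that the pmf underflows on the whole grid, both
bounds are pinned at the grid maximum. An element is *powered* for a
class when λ′ ≥ 10; unpowered results are retained but flagged, and
elements with λ′ = 0 are marked not computable.

Equal-count deciles: values sorted ascending (ties broken by element id),
rank r of n falling in decile 1 + ⌊10r/n⌋, so the most constrained decile
holds the first ⌈n/10⌉ values; the cut-off is that decile's maximum.
Regional UTR constraint: after dropping UTRs with λ′ < 10 or shorter than
`utr_min_len` (default 800 bp), a gene is regionally constrained when two
of its UTRs sit in deciles differing by ≥ 3 (separated and delimited by
at least two other deciles).

Frame respect: an sORF with both MOEUF and SNVOEUF powered is flagged
when MOEUF < SNVOEUF (strict), suggesting missense-specific depletion in
its own reading frame rather than out-of-frame background.

## Track matching

Windowed tracks (e.g. 1 kb constraint z-scores slid by 100 bp) are paired
to an element as the unweighted mean of windows fully contained in the
element span; if none is contained, the two closest windows by distance
are averaged (ties resolved one window per side). An `any_overlap` mode
exists because containment is rare for elements shorter than the window.
Per-position tracks (e.g. phyloP) are averaged over block positions with
the covered fraction reported. The constrained-percentile cut-off of 4 is
boundary-inclusive.

## Statistics

Vargha–Delaney A and pooled mean ranks are computed natively from average
ranks (A = (R₁/n₁ − (n₁+1)/2)/n₂, equivalent to pair counting with ½ for
ties; U₁ = R₁ − n₁(n₁+1)/2). KS, Mann–Whitney U, Wilcoxon signed-rank and
Kendall tau are delegated to scipy; the tie-corrected tau-b variant is
used since OEUF data carries ties. Comparisons assuming independence
exclude sORF classes overlapping canonical CDS (intORF, uoORF, doORF).
p-values below 0.001 are displayed as "<0.001"; raw values are kept in
machine output.

## Synthetic data

The generator emulates the statistical structure of the real inputs at
desk scale. Defaults (one seed drives every draw):

| parameter | default | why |
|---|---|---|
| genome | 400 kb, GC 0.42 | human-like composition, large enough for 300 elements |
| sORFs | 300 (65/65/70 uORF/dORF/lncRNA-ORF, 35/35/30 intORF/uoORF/doORF) | all six classes, majority non-overlapping as in the catalogue |
| sORF length | 30–90 codons, 1–3 blocks | "short" reading frames with splicing |
| rate table | transversion 2e-9, transition 6e-9, CpG transition 2e-8·(1+0.05·bin) | transitions 3x transversions, CpG 10x, methylation-sensitive |
| cohort scale | 1.8e7 | mean per-site observation probability ~5–7% |
| methylation | 37 tracks, CpG-localised, bimodal (mostly high) | somatic-tissue-like CpG methylation |
| planted artefacts | 2% common alleles, 1% low-quality (also non-PASS), 0.5% depth < 1 | exercises every exclusion rule symmetrically |
| score track | window 1000, slide 100 | sliding-window constraint-score geometry |

Each possible variant is observed with probability
1 − exp(−scale·μ·s_class). The cohort scale and the shallow methylation
slope are chosen together so that even the hottest CpG sites stay near
the linear regime of that map (max scale·μ ≈ 0.6): the proportional
synonymous calibration assumes linearity, and in the strongly saturated
regime (real CpG sites in very large cohorts are saturated) a simple
slope fit is biased per class. Consequently the generator validates the
workflow's logic, not its behaviour under saturation; likewise it has no
linkage, no demography, no genotypes (site-level AF summaries only), and
host "genes" for overlap classes are reserved intervals, not transcribed
models. Passing tests therefore demonstrate correctness of enumeration,
filtering, calibration and interval estimation — not calibration accuracy
on a real saturated callset.

Selection factors in (0, 1] deplete classes; 1 everywhere is the neutral
condition under which the pipeline recovers pooled observed/expected
ratios within [0.95, 1.05] for every class, and missense factor 0.5
flips the frame-respect flag for the majority of powered elements.

## Numerical choices and degenerate inputs

- Internal coordinates are 0-based half-open everywhere; conversion only
  at format boundaries (BED in, GTF out, VCF in).
- BED12 records whose block lengths are not divisible by 3 (or < 6 bases)
  cannot hold a reading frame and are skipped with a warning.
- Reference N bases flag their codon; flagged codons are excluded from
  enumeration and contribute no possible variants.
- Non-ATG first codons are accepted (the start-loss rule then compares
  encoded amino acids) — the consensus catalogue is ATG-only, so this
  matters mainly for user-supplied elements.
- AF thresholds are exclusive on the inclusion side (< 0.1%) and
  inclusive on the exclusion side (≥ 0.1%); depth is inclusive (≥ 1).
- Decile ties: stable sort by (value, element id) for determinism; CLI
  tables use fixed `%.6g` float formatting and stable sorts so reruns are
  byte-identical.
- Stop-codon changes to another stop are counted synonymous; this choice
  is isolated in one function (`classify_change`).

## Problem sizes

Default test and reproduction runs use 300 sORFs (~150 kb of coding
sequence, ~160k possible variants), 2000 replicates for interval
coverage, and the full 64-codon × 9-change lattice for the consequence
oracle — sizes chosen so the whole suite completes in well under a minute
while keeping Monte-Carlo standard errors a few-fold below the asserted
tolerances.
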