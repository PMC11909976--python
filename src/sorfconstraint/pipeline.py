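"""End-to-end orchestration: inputs -> per-element constraint table.

The pipeline walks each sORF through sequence extraction, consequence
classification, possible-variant enumeration and filtering, observed
counting, synonymous calibration, and the Poisson-grid OEUF bounds for
the three variant classes (all SNVs, missense, loss-of-function).  Decile
indices are assigned per class over the powered elements.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .consequence import ConsequenceType, classify_all
from .constraint_metrics import (
    GRID_MAX,
    GRID_STEP,
    POWERED_MIN_EXPECTED,
    OEUFResult,
    compute_oeuf,
    decile_cutoff,
    frame_respect_flag,
)
from .io_formats import SORFRecord, VariantSite
from .mutation_model import (
    ExpectedCounts,
    MethylationMap,
    MutationRateTable,
    SiteTable,
    enumerate_possible,
    expected_counts,
    filter_possible,
    fit_calibration,
)
from .observed_counts import ObservedCounts, count_observed, filter_observed
from .sequence_model import extract_coding_sequence

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Thresholds and mode flags of one pipeline run."""

    af_max: float = 0.001
    depth_min: float = 1.0
    default_depth: float = 30.0
    powered_min_expected: float = POWERED_MIN_EXPECTED
    grid_step: float = GRID_STEP
    grid_max: float = GRID_MAX
    gnocchi_cutoff: float = 4.0
    utr_min_len: int = 800
    match_mode: str = "containment"
    cpg_only_methylation: bool = True
    calibration_k: float | None = None  # None -> fit on synonymous counts

    def __post_init__(self) -> None:
        for name in ("af_max", "depth_min", "powered_min_expected", "grid_step", "grid_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class ElementResult:
    """All per-element artefacts for one sORF."""

    sorf: SORFRecord
    observed: ObservedCounts
    expected: ExpectedCounts
    oeuf: dict[str, OEUFResult]  # SNVOEUF / MOEUF / LOEUF


@dataclass
class PipelineResult:
    elements: list[ElementResult]
    calibration_k: float
    table: pd.DataFrame  # tidy per element x class

    def results_for(self, oeuf_class: str) -> list[OEUFResult]:
        return [e.oeuf[oeuf_class] for e in self.elements]


def run_pipeline(
    genome: Mapping,
    sorfs: Sequence[SORFRecord],
    variants: Sequence[VariantSite],
    rates: MutationRateTable,
    methylation: MethylationMap,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the constraint workflow over a set of sORFs.

    The site table used to prune uninformative possible variants is built
    from the *raw* callset (common and low-quality calls are exactly what
    prunes them); the observed counts use the filtered callset.
    """
    config = config or PipelineConfig()
    sites = SiteTable(variants, default_depth=config.default_depth)
    observed_pass = filter_observed(variants, af_max=config.af_max, depth_min=config.depth_min)

    per_element: list[dict] = []
    for sorf in sorfs:
        cds = extract_coding_sequence(genome, sorf)
        possible = enumerate_possible(
            cds, methylation, rates, cpg_only_methylation=config.cpg_only_methylation
        )
        retained = filter_possible(
            possible, sites, af_max=config.af_max, depth_min=config.depth_min
        )
        cons_map = classify_all(cds)
        obs = count_observed(observed_pass, cons_map, element_id=sorf.id, chrom=sorf.chrom)
        per_element.append({"sorf": sorf, "possible": retained, "observed": obs})

    if config.calibration_k is not None:
        k = config.calibration_k
    else:
        reference = []
        for item in per_element:
            raw = expected_counts(item["possible"], calibration_k=1.0, sorf_id=item["sorf"].id)
            reference.append(
                (item["observed"].get(ConsequenceType.SYNONYMOUS),
                 raw.rate_sum[ConsequenceType.SYNONYMOUS])
            )
        if len(reference) >= 2:
            k = fit_calibration(reference)
        else:
            k = 1.0
            log.warning(
                "no synonymous reference set; calibration_k defaults to 1.0 and "
                "expected counts are relative rates"
            )

    elements: list[ElementResult] = []
    for item in per_element:
        sorf, obs = item["sorf"], item["observed"]
        exp = expected_counts(item["possible"], calibration_k=k, sorf_id=sorf.id)
        oeuf = {
            "SNVOEUF": compute_oeuf(
                sorf.id, obs.snv_total, exp.snv_expected, "SNVOEUF",
                powered_min_expected=config.powered_min_expected,
                step=config.grid_step, grid_max=config.grid_max,
            ),
            "MOEUF": compute_oeuf(
                sorf.id, obs.get(ConsequenceType.MISSENSE),
                exp.expected[ConsequenceType.MISSENSE], "MOEUF",
                powered_min_expected=config.powered_min_expected,
                step=config.grid_step, grid_max=config.grid_max,
            ),
            "LOEUF": compute_oeuf(
                sorf.id, obs.lof_total, exp.lof_expected, "LOEUF",
                powered_min_expected=config.powered_min_expected,
                step=config.grid_step, grid_max=config.grid_max,
            ),
        }
        elements.append(ElementResult(sorf=sorf, observed=obs, expected=exp, oeuf=oeuf))

    table = _tidy_table(elements)
    return PipelineResult(elements=elements, calibration_k=k, table=table)


def _tidy_table(elements: list[ElementResult]) -> pd.DataFrame:
    rows = []
    for el in elements:
        for cls, res in el.oeuf.items():
            rows.append(
                {
                    "element_id": el.sorf.id,
                    "sorf_class": el.sorf.sorf_class,
                    "oeuf_class": cls,
                    "observed": res.observed,
                    "expected": res.expected,
                    "lower": res.lower,
                    "upper": res.upper,
                    "point_ratio": res.point_ratio,
                    "powered": res.powered,
                    "computable": res.computable,
                }
            )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    # equal-count decile index per class over powered, computable elements
    df["decile"] = pd.NA
    for cls, sub in df.groupby("oeuf_class"):
        eligible = sub[sub["powered"] & sub["computable"]]
        if len(eligible) >= 10:
            _, deciles = decile_cutoff(
                eligible["upper"].tolist(), eligible["element_id"].tolist()
            )
            df.loc[eligible.index, "decile"] = deciles
    return df.sort_values(["element_id", "oeuf_class"], kind="stable").reset_index(drop=True)


def pooled_ratios(result: PipelineResult) -> dict[str, float]:
    """Pooled observed/expected ratio per class: Σ observed / Σ expected."""
    sums: dict[str, list[float]] = {}

    def add(name: str, obs: float, exp: float) -> None:
        o, e = sums.setdefault(name, [0.0, 0.0])
        sums[name] = [o + obs, e + exp]

    for el in result.elements:
        add("SNV", el.observed.snv_total, el.expected.snv_expected)
        add("synonymous", el.observed.get(ConsequenceType.SYNONYMOUS),
            el.expected.expected[ConsequenceType.SYNONYMOUS])
        add("missense", el.observed.get(ConsequenceType.MISSENSE),
            el.expected.expected[ConsequenceType.MISSENSE])
        add("lof", el.observed.lof_total, el.expected.lof_expected)
    return {name: (o / e if e > 0 else float("nan")) for name, (o, e) in sums.items()}


def frame_respect_summary(result: PipelineResult) -> tuple[int, int]:
    """(elements with MOEUF < SNVOEUF, elements with both classes powered)."""
    n_true = 0
    n_pairs = 0
    for el in result.elements:
        m, s = el.oeuf["MOEUF"], el.oeuf["SNVOEUF"]
        if m.computable and s.computable and m.powered and s.powered:
            n_pairs += 1
            if frame_respect_flag(m, s):
                n_true += 1
    return n_true, n_pairs
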