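"""Per-case and cohort orchestration of the relapse-pattern analysis.

For each co-registered baseline/relapse case the pipeline

1. segments the baseline and relapse biological tumor volumes from PET by
   TBR autocontouring and the MRI enhancement volumes by thresholding;
2. quantifies the (typically poor) FET/MRI overlap at both time points;
3. rebuilds the study's target volumes — boost PTV-1 (FET-based CTV, no
   additional margin) and standard PTV-2 (MRI-based CTV with a 15 mm
   clinical margin plus a 5 mm setup margin) — and measures how much of the
   relapse volume each received;
4. simulates alternative CTVs grown from the baseline FET and MRI volumes
   over a margin ladder (0/5/7/10 mm) and records the coverage of the
   relapse volume and the resulting PTV sizes;
5. classifies the recurrence as local / local+distant / distant from the
   connected components of the relapse volume relative to PTV-2; and
6. aggregates cohort summary rows and exact paired Wilcoxon tests.

Two entry modes exist because the underlying patient images are not
publicly available: imaging mode (this module, on volumes such as the
synthetic phantoms) and fixture mode (:mod:`fetrelapse.tables`, on the
packaged per-patient tables).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import EmptyStructureError, UndefinedFractionError
from .geometry import (
    DEFAULT_MARGIN_LADDER_MM,
    DEFAULT_SETUP_MARGIN_MM,
    TargetStructure,
    build_ctv,
    build_ptv,
    cavity_dynamics,
    coverage_fraction,
    intersection_stats,
)
from .grid import BinaryMask, PatientCase
from .segmentation import (
    DEFAULT_TBR_THRESHOLD,
    autocontour_tbr,
    compute_tbr,
    enhancement_mask,
)
from .stats import summarize, wilcoxon_signed_rank

REPORT_SCHEMA_VERSION = "1.0"

RecurrenceLabel = Literal["local", "local+distant", "distant"]


@dataclass
class PipelineConfig:
    """Thresholds and margins steering the per-case analysis."""

    tbr_threshold: float = DEFAULT_TBR_THRESHOLD
    mri_threshold: float = 0.5
    margins_mm: tuple[float, ...] = DEFAULT_MARGIN_LADDER_MM
    setup_margin_mm: float = DEFAULT_SETUP_MARGIN_MM
    ctv2_margin_mm: float = 15.0  # clinical margin of the MRI-based standard CTV
    component_threshold_pct: float = 5.0
    clip_to_brain: bool = True


@dataclass
class SegmentedCase:
    """The four delineated tumor masks of one case."""

    fet1: BinaryMask
    mri1: BinaryMask
    fet2: BinaryMask
    mri2: BinaryMask


@dataclass
class OverlapRecord:
    """Row of the baseline/relapse FET-MRI overlap table for one case."""

    case_id: str
    fet1_ml: float
    mri1_ml: float
    intersect1_ml: float | None
    intersect1_pct_of_fet1: float | None
    fet2_ml: float
    mri2_ml: float
    intersect2_ml: float | None
    intersect2_pct_of_fet2: float | None


@dataclass
class BoostCoverageRecord:
    """Relapse FET volume in relation to the boost PTV-1 and standard PTV-2."""

    case_id: str
    fet2_ml: float
    fet2_in_ptv1_ml: float
    fet2_in_ptv1_pct: float
    fet2_in_ptv2_pct: float


@dataclass
class PtvVolumeRecord:
    """Delivered standard PTV-2 volume next to simulated FET-based PTVs."""

    case_id: str
    ptv2_standard_ml: float
    ptv_fet_ml_by_margin: dict[float, float]


def segment_case(case: PatientCase, config: PipelineConfig) -> SegmentedCase:
    """Delineate FET-1/2 by TBR autocontouring and MRI-1/2 by thresholding."""
    fet1 = autocontour_tbr(
        compute_tbr(case.pet_baseline, case.background_mask), config.tbr_threshold
    )
    fet2 = autocontour_tbr(
        compute_tbr(case.pet_relapse, case.background_mask), config.tbr_threshold
    )
    mri1 = enhancement_mask(case.mri_baseline, config.mri_threshold)
    mri2 = enhancement_mask(case.mri_relapse, config.mri_threshold)
    return SegmentedCase(fet1=fet1, mri1=mri1, fet2=fet2, mri2=mri2)


def analyze_overlap(
    case: PatientCase,
    config: PipelineConfig | None = None,
    segmented: SegmentedCase | None = None,
) -> OverlapRecord:
    """Volumes and FET∩MRI intersections at baseline and relapse.

    Fraction columns are left as nulls (None) when the FET denominator mask
    is empty; the case itself is reported, not dropped.
    """
    config = config or PipelineConfig()
    seg = segmented or segment_case(case, config)
    rec = OverlapRecord(
        case_id=case.case_id,
        fet1_ml=seg.fet1.volume_ml,
        mri1_ml=seg.mri1.volume_ml,
        intersect1_ml=None,
        intersect1_pct_of_fet1=None,
        fet2_ml=seg.fet2.volume_ml,
        mri2_ml=seg.mri2.volume_ml,
        intersect2_ml=None,
        intersect2_pct_of_fet2=None,
    )
    if not seg.fet1.is_empty:
        ml, frac = intersection_stats(seg.fet1, seg.mri1)
        rec.intersect1_ml, rec.intersect1_pct_of_fet1 = ml, 100.0 * frac
    if not seg.fet2.is_empty:
        ml, frac = intersection_stats(seg.fet2, seg.mri2)
        rec.intersect2_ml, rec.intersect2_pct_of_fet2 = ml, 100.0 * frac
    return rec


def build_study_targets(
    case: PatientCase, segmented: SegmentedCase, config: PipelineConfig
) -> tuple[TargetStructure, TargetStructure]:
    """The study's delivered structures: boost PTV-1 and standard PTV-2.

    PTV-1 is the FET-based CTV with no additional margin (72 Gy boost);
    PTV-2 is the MRI-based CTV (clinical margin, default 15 mm) plus the
    5 mm setup margin (60 Gy).
    """
    brain = case.brain_mask if config.clip_to_brain else None
    ctv1 = build_ctv(segmented.fet1, 0.0, brain, source="FET", nominal_dose_Gy=72.0)
    ptv1 = build_ptv(ctv1, setup_margin_mm=0.0)
    ctv2 = build_ctv(
        segmented.mri1, config.ctv2_margin_mm, brain, source="MRI",
        nominal_dose_Gy=60.0,
    )
    ptv2 = build_ptv(ctv2, setup_margin_mm=config.setup_margin_mm)
    return ptv1, ptv2


def analyze_boost_coverage(
    case: PatientCase,
    ptv1: TargetStructure,
    ptv2: TargetStructure,
    fet2: BinaryMask,
) -> BoostCoverageRecord:
    """Relapse FET volume and its fractions inside the boost and standard PTVs."""
    if fet2.is_empty:
        raise UndefinedFractionError(
            f"case {case.case_id}: relapse FET volume is empty"
        )
    in_ptv1_ml, in_ptv1 = intersection_stats(fet2, ptv1.mask)
    _, in_ptv2 = intersection_stats(fet2, ptv2.mask)
    return BoostCoverageRecord(
        case_id=case.case_id,
        fet2_ml=fet2.volume_ml,
        fet2_in_ptv1_ml=in_ptv1_ml,
        fet2_in_ptv1_pct=100.0 * in_ptv1,
        fet2_in_ptv2_pct=100.0 * in_ptv2,
    )


def simulate_targets(
    case: PatientCase,
    segmented: SegmentedCase,
    config: PipelineConfig,
) -> tuple[dict[tuple[str, float], float], PtvVolumeRecord]:
    """Margin-ladder simulation for one case.

    Returns the coverage-matrix row — coverage of the relapse FET volume by
    CTVs grown from the baseline FET and MRI masks at every ladder margin —
    and the PTV volume record (each FET-based CTV margin plus the setup
    margin, next to the standard MRI-based PTV-2).
    """
    for name, mask in (
        ("baseline FET", segmented.fet1),
        ("baseline MRI", segmented.mri1),
        ("relapse FET", segmented.fet2),
    ):
        if mask.is_empty:
            raise EmptyStructureError(
                f"case {case.case_id}: {name} volume is empty"
            )
    brain = case.brain_mask if config.clip_to_brain else None
    coverage_row: dict[tuple[str, float], float] = {}
    ptv_by_margin: dict[float, float] = {}
    for margin in config.margins_mm:
        for source, source_mask in (("FET", segmented.fet1), ("MRI", segmented.mri1)):
            ctv = build_ctv(source_mask, margin, brain, source=source)
            coverage_row[(source, margin)] = coverage_fraction(segmented.fet2, ctv)
            if source == "FET":
                ptv = build_ptv(ctv, setup_margin_mm=config.setup_margin_mm)
                ptv_by_margin[margin] = ptv.volume_ml
    _, ptv2 = build_study_targets(case, segmented, config)
    record = PtvVolumeRecord(
        case_id=case.case_id,
        ptv2_standard_ml=ptv2.volume_ml,
        ptv_fet_ml_by_margin=ptv_by_margin,
    )
    return coverage_row, record


def classify_recurrence(
    fet2: BinaryMask,
    ptv2: TargetStructure,
    component_threshold_pct: float = 5.0,
) -> RecurrenceLabel:
    """Label a recurrence local / local+distant / distant relative to PTV-2.

    Each 26-connected component of the relapse mask is labelled *local* if
    more than ``component_threshold_pct`` percent of the component's volume
    lies inside PTV-2, else *distant*; the case label aggregates the
    component labels.
    """
    if fet2.is_empty:
        raise EmptyStructureError("cannot classify an empty recurrence mask")
    fet2.grid.require_compatible(ptv2.mask.grid, "recurrence and PTV-2")
    labels, n_comp = ndimage.label(fet2.data, structure=np.ones((3, 3, 3), dtype=int))
    has_local = has_distant = False
    for comp in range(1, n_comp + 1):
        comp_mask = labels == comp
        inside = float((comp_mask & ptv2.mask.data).sum()) / float(comp_mask.sum())
        if inside * 100.0 > component_threshold_pct:
            has_local = True
        else:
            has_distant = True
    if has_local and has_distant:
        return "local+distant"
    return "local" if has_local else "distant"


@dataclass
class CohortReport:
    """All per-case records plus cohort summary rows and paired tests."""

    schema_version: str
    n_cases: int
    overlap: pd.DataFrame
    boost_coverage: pd.DataFrame
    coverage_matrix: pd.DataFrame
    ptv_volumes: pd.DataFrame
    cavity: pd.DataFrame
    recurrence_labels: dict[str, str]
    summaries: dict = field(default_factory=dict)
    wilcoxon: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "schema_version": self.schema_version,
            "n_cases": self.n_cases,
            "overlap": self.overlap.to_dict(orient="records"),
            "boost_coverage": self.boost_coverage.to_dict(orient="records"),
            "coverage_matrix": self.coverage_matrix.to_dict(orient="records"),
            "ptv_volumes": self.ptv_volumes.to_dict(orient="records"),
            "cavity": self.cavity.to_dict(orient="records"),
            "recurrence_labels": self.recurrence_labels,
            "summaries": self.summaries,
            "wilcoxon": self.wilcoxon,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    def write(self, out_dir: str | Path) -> None:
        """Write per-table CSVs and the JSON report (byte-deterministic)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.overlap.to_csv(out / "overlap.csv", index=False)
        self.boost_coverage.to_csv(out / "boost_coverage.csv", index=False)
        self.coverage_matrix.to_csv(out / "coverage_matrix.csv", index=False)
        self.ptv_volumes.to_csv(out / "ptv_volumes.csv", index=False)
        self.cavity.to_csv(out / "cavity_dynamics.csv", index=False)
        (out / "report.json").write_text(self.to_json() + "\n")


def _summary_dict(values: Sequence[float]) -> dict:
    arr = [v for v in values if v is not None and not np.isnan(v)]
    if not arr:
        return {}
    s = summarize(arr)
    return {
        "n": s.n, "mean": s.mean, "median": s.median,
        "sd": s.sd, "min": s.min, "max": s.max,
    }


def run_cohort(
    cases: Sequence[PatientCase],
    config: PipelineConfig | None = None,
) -> CohortReport:
    """Run the full per-case analysis over a cohort and aggregate it.

    Deterministic given the inputs and configuration.  Paired tests are
    skipped with a warning when fewer than two cases are available; cases
    with degenerate structures surface their error rather than being
    dropped silently.
    """
    config = config or PipelineConfig()
    if not cases:
        raise ValueError("cohort is empty")
    overlap_rows, boost_rows, coverage_rows, ptv_rows, cavity_rows = [], [], [], [], []
    labels: dict[str, str] = {}
    for case in cases:
        seg = segment_case(case, config)
        overlap_rows.append(asdict(analyze_overlap(case, config, segmented=seg)))
        ptv1, ptv2 = build_study_targets(case, seg, config)
        boost_rows.append(
            asdict(analyze_boost_coverage(case, ptv1, ptv2, seg.fet2))
        )
        cov_row, ptv_rec = simulate_targets(case, seg, config)
        flat = {"case_id": case.case_id}
        for (source, margin), frac in sorted(cov_row.items()):
            flat[f"coverage_{source}_{margin:g}mm"] = frac
        coverage_rows.append(flat)
        ptv_flat = {"case_id": case.case_id, "ptv2_standard_ml": ptv_rec.ptv2_standard_ml}
        for margin, vol in sorted(ptv_rec.ptv_fet_ml_by_margin.items()):
            ptv_flat[f"ptv_fet_{margin:g}mm_ml"] = vol
        ptv_rows.append(ptv_flat)
        labels[case.case_id] = classify_recurrence(
            seg.fet2, ptv2, config.component_threshold_pct
        )
        if case.cavity_baseline is not None and case.cavity_relapse is not None:
            dyn = cavity_dynamics(case.cavity_baseline, case.cavity_relapse)
            cavity_rows.append(
                {
                    "case_id": case.case_id,
                    "shrinkage_ml": dyn.shrinkage_ml,
                    "shift_mm": dyn.shift_mm,
                }
            )

    overlap_df = pd.DataFrame(overlap_rows)
    boost_df = pd.DataFrame(boost_rows)
    coverage_df = pd.DataFrame(coverage_rows)
    ptv_df = pd.DataFrame(ptv_rows)
    cavity_df = pd.DataFrame(
        cavity_rows, columns=["case_id", "shrinkage_ml", "shift_mm"]
    )

    summaries: dict = {}
    for name, df in (
        ("overlap", overlap_df),
        ("boost_coverage", boost_df),
        ("coverage_matrix", coverage_df),
        ("ptv_volumes", ptv_df),
        ("cavity", cavity_df),
    ):
        summaries[name] = {
            col: _summary_dict(df[col].to_list())
            for col in df.columns
            if col != "case_id" and len(df) > 0
        }

    wilcoxon: dict = {}
    if len(cases) >= 2:
        pairs = {
            "ptv2_vs_fet_plus7_volume": (
                ptv_df["ptv2_standard_ml"],
                ptv_df.get("ptv_fet_7mm_ml"),
            ),
            "baseline_fet_vs_mri_volume": (
                overlap_df["fet1_ml"],
                overlap_df["mri1_ml"],
            ),
        }
        for margin in config.margins_mm:
            pairs[f"coverage_fet_vs_mri_ctv_{margin:g}mm"] = (
                coverage_df.get(f"coverage_FET_{margin:g}mm"),
                coverage_df.get(f"coverage_MRI_{margin:g}mm"),
            )
        for name, (a, b) in pairs.items():
            if a is None or b is None:
                continue
            try:
                res = wilcoxon_signed_rank(
                    np.asarray(a, dtype=float), np.asarray(b, dtype=float),
                    mode="auto",
                )
            except Exception as exc:  # degenerate comparisons stay reported
                wilcoxon[name] = {"error": str(exc)}
                continue
            wilcoxon[name] = {
                "w_statistic": res.w_statistic,
                "n_effective": res.n_effective,
                "p_two_sided": res.p_two_sided,
                "method": res.method,
            }
    else:
        warnings.warn("fewer than two cases: paired tests skipped", stacklevel=2)

    return CohortReport(
        schema_version=REPORT_SCHEMA_VERSION,
        n_cases=len(cases),
        overlap=overlap_df,
        boost_coverage=boost_df,
        coverage_matrix=coverage_df,
        ptv_volumes=ptv_df,
        cavity=cavity_df,
        recurrence_labels=labels,
        summaries=summaries,
        wilcoxon=wilcoxon,
    )
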