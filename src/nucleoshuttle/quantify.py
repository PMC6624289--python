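"""Per-cell compartment intensity statistics.

For each nucleus the protein channel is partitioned into the nucleolar area
(union of that nucleus's nucleoli) and the nucleoplasmic area (nucleus minus
its nucleoli).  The central statistic is the ratio of mean fluorescence
intensities

    R = mean(protein | nucleoli) / mean(protein | nucleoplasm)

with the display convention R - 1, so 0 marks a homogeneous distribution,
positive values nucleolar accumulation and negative values nucleolar
depletion.  Integrated sums over the same partition are reported alongside
the means; their total is conserved under pure compartment shuttling, which
is the computable counterpart of checking that a protein relocates rather
than degrades.

The three-category scheme (strong / medium / without) mirrors the manual
scoring of cells by eye: a symmetric band of half-width ``delta`` around
R = 1 operationalizes "homogeneous".
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .readwrite import MultiChannelField, records_to_frame
from .segmentation import LabelMask, SegmentationError

logger = logging.getLogger(__name__)

__all__ = [
    "NucleusRecord",
    "CategoryParams",
    "QC_OK",
    "QC_NO_NUCLEOLUS",
    "QC_DEGENERATE_DENOMINATOR",
    "CATEGORIES",
    "quantify_field",
    "pooled_field_ratio",
    "categorize",
    "category_fractions",
]

QC_OK = "ok"
QC_NO_NUCLEOLUS = "no_nucleolus"
QC_DEGENERATE_DENOMINATOR = "degenerate_denominator"

CATEGORIES = ("strong", "medium", "without")


@dataclass
class NucleusRecord:
    """Measurements for one nucleus; `ratio` is None when undefined."""

    field_id: str
    nucleus_label: int
    genotype: str = ""
    treatment: str = ""
    dose: Optional[float] = None
    timepoint: Optional[float] = None
    replicate_id: str = ""
    nucleus_area_px: int = 0
    nucleolar_area_px: int = 0
    mean_nucleolar: Optional[float] = None
    mean_nucleoplasmic: Optional[float] = None
    ratio: Optional[float] = None
    displayed_ratio: Optional[float] = None
    sum_total: float = 0.0
    sum_nucleolar: float = 0.0
    sum_nucleoplasmic: float = 0.0
    category: str = "undefined"
    qc_flag: str = QC_OK


@dataclass(frozen=True)
class CategoryParams:
    """Half-width of the 'medium' band around R = 1, and the minimum
    nucleolar area below which the ratio is treated as undefined."""

    delta: float = 0.1
    min_nucleolar_area_px: int = 1

    def validate(self) -> None:
        if not 0 < self.delta < 1:
            raise ValueError("delta must lie in (0, 1)")
        if self.min_nucleolar_area_px < 1:
            raise ValueError("min_nucleolar_area_px must be >= 1")


def categorize(ratio: Optional[float], params: CategoryParams = CategoryParams()) -> str:
    """Classify a per-cell ratio as strong / medium / without.

    strong:  R > 1 + delta   (nucleolar accumulation)
    medium:  |R - 1| <= delta (homogeneous distribution)
    without: R < 1 - delta   (nucleolar depletion)
    """
    params.validate()
    if ratio is None or (isinstance(ratio, float) and np.isnan(ratio)):
        return "undefined"
    if ratio > 1.0 + params.delta:
        return "strong"
    if ratio < 1.0 - params.delta:
        return "without"
    return "medium"


def quantify_field(
    field: MultiChannelField,
    nuclei: LabelMask,
    nucleoli: LabelMask,
    params: CategoryParams = CategoryParams(),
    background_subtract: float = 0.0,
) -> List[NucleusRecord]:
    """One record per nucleus: compartment areas, means, ratio, sums, category.

    ``background_subtract`` optionally removes a constant from the protein
    channel before measuring (default 0, i.e. off).  A containment
    violation between the masks is an upstream bug and raises.
    """
    params.validate()
    field.require_roles(("protein",))
    protein = field.channel("protein").pixels.astype(np.float64)
    if protein.shape != nuclei.shape or protein.shape != nucleoli.shape:
        raise SegmentationError("field and masks do not share a pixel grid")
    if np.any((nucleoli.labels > 0) & (nuclei.labels == 0)):
        raise SegmentationError(
            "containment violation: nucleolus pixels outside all nuclei"
        )
    if background_subtract:
        protein = np.clip(protein - background_subtract, 0.0, None)

    md = field.metadata
    records: List[NucleusRecord] = []
    for lab in nuclei.label_ids():
        in_nucleus = nuclei.labels == lab
        in_nucleolus = in_nucleus & (nucleoli.labels > 0)
        in_nucleoplasm = in_nucleus & ~in_nucleolus

        nucleolar_px = protein[in_nucleolus]
        nucleoplasm_px = protein[in_nucleoplasm]
        sum_nucl = float(nucleolar_px.sum())
        sum_npl = float(nucleoplasm_px.sum())
        rec = NucleusRecord(
            field_id=md.field_id,
            nucleus_label=lab,
            genotype=md.genotype,
            treatment=md.treatment,
            dose=md.dose,
            timepoint=md.timepoint,
            replicate_id=md.replicate_id,
            nucleus_area_px=int(in_nucleus.sum()),
            nucleolar_area_px=int(in_nucleolus.sum()),
            sum_nucleolar=sum_nucl,
            sum_nucleoplasmic=sum_npl,
            # total over the disjoint partition, so conservation is exact
            sum_total=sum_nucl + sum_npl,
        )
        if rec.nucleolar_area_px < params.min_nucleolar_area_px:
            rec.qc_flag = QC_NO_NUCLEOLUS
            records.append(rec)
            continue
        rec.mean_nucleolar = float(nucleolar_px.mean())
        rec.mean_nucleoplasmic = (
            float(nucleoplasm_px.mean()) if nucleoplasm_px.size else 0.0
        )
        if rec.mean_nucleoplasmic == 0.0:
            rec.qc_flag = QC_DEGENERATE_DENOMINATOR
            records.append(rec)
            continue
        rec.ratio = rec.mean_nucleolar / rec.mean_nucleoplasmic
        rec.displayed_ratio = rec.ratio - 1.0
        rec.category = categorize(rec.ratio, params)
        records.append(rec)
    return records


def pooled_field_ratio(
    field: MultiChannelField,
    nuclei: LabelMask,
    nucleoli: LabelMask,
    background_subtract: float = 0.0,
) -> float:
    """Field-level ratio on pooled pixels (all nucleoli vs all nucleoplasm).

    Alternative to the per-cell statistic for workflows that measure whole
    images rather than single cells.
    """
    field.require_roles(("protein",))
    protein = field.channel("protein").pixels.astype(np.float64)
    if background_subtract:
        protein = np.clip(protein - background_subtract, 0.0, None)
    in_nucleus = nuclei.labels > 0
    in_nucleolus = in_nucleus & (nucleoli.labels > 0)
    in_nucleoplasm = in_nucleus & ~in_nucleolus
    if not in_nucleolus.any() or not in_nucleoplasm.any():
        return float("nan")
    denom = protein[in_nucleoplasm].mean()
    if denom == 0:
        return float("nan")
    return float(protein[in_nucleolus].mean() / denom)


def category_fractions(
    records: Union[Iterable[NucleusRecord], pd.DataFrame],
    grouping: Sequence[str] = ("genotype", "treatment", "timepoint"),
) -> pd.DataFrame:
    """Per-condition fractions of strong / medium / without cells.

    Fractions are over cells with a defined category and sum to 1 per
    group; undefined cells are reported separately as ``undefined_count``.
    Groups containing only undefined cells are omitted with a warning.
    """
    frame = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    grouping = [g for g in grouping if g in frame.columns]
    rows = []
    for key, grp in frame.groupby(list(grouping), dropna=False, sort=True):
        if not isinstance(key, tuple):
            key = (key,)
        defined = grp[grp["category"].isin(CATEGORIES)]
        undefined_count = int(len(grp) - len(defined))
        if defined.empty:
            warnings.warn(
                f"group {dict(zip(grouping, key))} has no defined categories; omitted",
                stacklevel=2,
            )
            continue
        n = len(defined)
        row = dict(zip(grouping, key))
        for cat in CATEGORIES:
            row[f"frac_{cat}"] = float((defined["category"] == cat).sum() / n)
        row["n_defined"] = n
        row["undefined_count"] = undefined_count
        rows.append(row)
    return pd.DataFrame(rows)
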