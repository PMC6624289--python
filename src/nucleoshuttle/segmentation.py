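"""Nuclear and nucleolar segmentation from the dye and marker channels.

The nuclear area is taken from the DNA-dye channel (Gaussian smooth, global
Otsu or fixed threshold, hole filling so chromatin-poor nucleoli stay part of
the nucleus, optional watershed splitting of touching nuclei, area and border
filters).  The nucleolar area is taken from the nucleolar-marker channel,
thresholded within nuclear pixels only — per-nucleus Otsu by default, so each
cell's staining level sets its own cutoff — and every retained nucleolus is
assigned to its parent nucleus.  All operators are classical and
deterministic; there are no trained components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.segmentation import watershed

logger = logging.getLogger(__name__)

__all__ = [
    "LabelMask",
    "SegParams",
    "SegmentationError",
    "GridMismatchError",
    "segment_nuclei",
    "segment_nucleoli",
    "mask_iou",
    "IoUReport",
]


class SegmentationError(ValueError):
    """Invalid segmentation parameters or inputs."""


class GridMismatchError(SegmentationError):
    """Two masks/images that must share a pixel grid do not."""


@dataclass
class LabelMask:
    """Integer-labelled segmentation; 0 is background, labels run 1..n.

    For nucleolus masks, ``parent_map`` maps each nucleolus label to the
    label of the nucleus containing it.
    """

    labels: np.ndarray
    parent_map: Optional[Dict[int, int]] = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise SegmentationError("label mask must be 2-D")

    @property
    def n_labels(self) -> int:
        return int(self.labels.max(initial=0))

    @property
    def shape(self) -> Tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def label_ids(self) -> List[int]:
        ids = np.unique(self.labels)
        return [int(i) for i in ids if i != 0]

    def validate_contiguous(self) -> None:
        ids = self.label_ids()
        if ids != list(range(1, len(ids) + 1)):
            raise SegmentationError(f"labels not contiguous from 1: {ids}")

    def validate_containment(self, nuclei: "LabelMask") -> None:
        """Every non-zero pixel must lie inside its parent nucleus."""
        if self.shape != nuclei.shape:
            raise GridMismatchError(
                f"mask grids differ: {self.shape} vs {nuclei.shape}"
            )
        if self.parent_map is None:
            raise SegmentationError("nucleolus mask lacks a parent map")
        for lab in self.label_ids():
            parent = self.parent_map.get(lab)
            if parent is None:
                raise SegmentationError(f"nucleolus {lab} has no parent entry")
            under = nuclei.labels[self.labels == lab]
            if not np.all(under == parent):
                raise SegmentationError(
                    f"nucleolus {lab} leaks outside nucleus {parent}"
                )


@dataclass(frozen=True)
class SegParams:
    """Tunable segmentation parameters (all classical operators).

    ``smoothing_sigma_px=2`` suppresses shot noise before thresholding;
    ``watershed_min_distance_px=15`` keeps distance-transform seeds of one
    nucleus from splitting it; ``min_nucleus_area_px=500`` /
    ``min_nucleolus_area_px=20`` drop debris below plausible organelle
    sizes at this magnification; border nuclei are excluded by default
    because their areas are truncated.
    """

    smoothing_sigma_px: float = 2.0
    threshold_method: str = "otsu"  # "otsu" | "fixed"
    fixed_threshold: Optional[float] = None
    split_touching: bool = True
    watershed_min_distance_px: int = 15
    min_nucleus_area_px: int = 500
    min_nucleolus_area_px: int = 20
    exclude_border_nuclei: bool = True
    nucleolus_threshold_scope: str = "per_nucleus"  # "per_nucleus" | "global"

    def validate(self) -> None:
        if self.threshold_method not in ("otsu", "fixed"):
            raise SegmentationError(
                f"unknown threshold_method {self.threshold_method!r}"
            )
        if (self.threshold_method == "fixed") != (self.fixed_threshold is not None):
            raise SegmentationError(
                "fixed_threshold must be given iff threshold_method='fixed'"
            )
        if self.smoothing_sigma_px < 0:
            raise SegmentationError("smoothing_sigma_px must be >= 0")
        if self.watershed_min_distance_px <= 0:
            raise SegmentationError("watershed_min_distance_px must be positive")
        if self.min_nucleus_area_px <= 0 or self.min_nucleolus_area_px <= 0:
            raise SegmentationError("minimum areas must be positive")
        if self.nucleolus_threshold_scope not in ("per_nucleus", "global"):
            raise SegmentationError(
                f"unknown nucleolus_threshold_scope {self.nucleolus_threshold_scope!r}"
            )


def _smooth(img: np.ndarray, sigma: float) -> np.ndarray:
    img = np.asarray(img, dtype=np.float64)
    if sigma > 0:
        return gaussian(img, sigma=sigma, preserve_range=True)
    return img


def _relabel_lut(labels: np.ndarray) -> np.ndarray:
    """Lookup table relabeling contiguously from 1 in scan order of first pixel."""
    flat = labels.ravel()
    uniq, first = np.unique(flat, return_index=True)
    keep = uniq != 0
    uniq, first = uniq[keep], first[keep]
    lut = np.zeros(int(labels.max(initial=0)) + 1, dtype=np.int32)
    lut[uniq[np.argsort(first)]] = np.arange(1, len(uniq) + 1, dtype=np.int32)
    return lut


def _relabel_scan_order(labels: np.ndarray) -> np.ndarray:
    """Relabel contiguously from 1, ordered by first pixel in scan order."""
    return _relabel_lut(labels)[labels]


def segment_nuclei(nuclear_dye, params: SegParams = SegParams()) -> LabelMask:
    """Segment nuclei from the DNA-dye channel.

    Pipeline: Gaussian smooth -> global threshold -> fill holes ->
    optional distance-transform watershed split -> area filter ->
    optional border exclusion -> contiguous relabel.
    """
    params.validate()
    img = np.asarray(getattr(nuclear_dye, "pixels", nuclear_dye), dtype=np.float64)
    sm = _smooth(img, params.smoothing_sigma_px)

    if params.threshold_method == "fixed":
        thr = float(params.fixed_threshold)  # type: ignore[arg-type]
    else:
        if sm.max() == sm.min():
            logger.warning("constant nuclear-dye image; returning empty mask")
            return LabelMask(labels=np.zeros(img.shape, dtype=np.int32))
        thr = threshold_otsu(sm)

    fg = sm > thr
    fg = ndi.binary_fill_holes(fg)

    if params.split_touching and fg.any():
        distance = ndi.distance_transform_edt(fg)
        # smoothed EDT for seeding only: avoids spurious ridge maxima
        seeds_img = gaussian(distance, sigma=1.0, preserve_range=True)
        comp, _ = ndi.label(fg)
        coords = peak_local_max(
            seeds_img,
            min_distance=params.watershed_min_distance_px,
            labels=comp,
            exclude_border=False,
        )
        markers = np.zeros(fg.shape, dtype=np.int32)
        for k, (r, c) in enumerate(coords, start=1):
            markers[r, c] = k
        labels = watershed(-distance, markers, mask=fg).astype(np.int32)
        # components that received no seed (tiny objects) keep their own label
        residual = fg & (labels == 0)
        if residual.any():
            extra, n_extra = ndi.label(residual)
            labels = labels + np.where(extra > 0, extra + labels.max(), 0).astype(
                np.int32
            )
    else:
        labels, _ = ndi.label(fg)
        labels = labels.astype(np.int32)

    if labels.max() > 0:
        sizes = np.bincount(labels.ravel())
        too_small = np.flatnonzero(sizes < params.min_nucleus_area_px)
        kill = np.isin(labels, too_small[too_small > 0])
        labels[kill] = 0

    if params.exclude_border_nuclei and labels.max() > 0:
        border = np.unique(
            np.concatenate(
                [labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]
            )
        )
        labels[np.isin(labels, border[border > 0])] = 0

    return LabelMask(labels=_relabel_scan_order(labels))


def segment_nucleoli(
    nucleolar_marker,
    nuclei: LabelMask,
    params: SegParams = SegParams(),
) -> LabelMask:
    """Segment nucleoli from the marker channel, within nuclei only.

    The marker is thresholded per nucleus (Otsu over that nucleus's pixels
    by default, or a global within-nuclei Otsu / fixed threshold), small
    components are dropped, and each nucleolus is clipped to and assigned
    its parent nucleus, so containment holds by construction.  A nucleus
    whose within-nucleus marker signal is constant yields no nucleoli.
    """
    params.validate()
    img = np.asarray(getattr(nucleolar_marker, "pixels", nucleolar_marker), dtype=np.float64)
    if img.shape != nuclei.shape:
        raise GridMismatchError(
            f"marker grid {img.shape} does not match nuclei grid {nuclei.shape}"
        )
    sm = _smooth(img, params.smoothing_sigma_px)

    global_thr: Optional[float] = None
    if params.threshold_method == "fixed":
        global_thr = float(params.fixed_threshold)  # type: ignore[arg-type]
    elif params.nucleolus_threshold_scope == "global":
        inside = sm[nuclei.labels > 0]
        if inside.size and inside.max() > inside.min():
            global_thr = threshold_otsu(inside)

    out = np.zeros(img.shape, dtype=np.int32)
    parent_map: Dict[int, int] = {}
    next_label = 0
    objects = ndi.find_objects(nuclei.labels)
    for lab in nuclei.label_ids():
        sl = objects[lab - 1]
        if sl is None:
            continue
        region = nuclei.labels[sl] == lab
        vals = sm[sl][region]
        if vals.max() == vals.min():
            continue  # constant marker: no nucleoli for this nucleus
        if global_thr is not None:
            thr = global_thr
        else:
            thr = threshold_otsu(vals)
        blob = region & (sm[sl] > thr)
        comp, n = ndi.label(blob)
        for k in range(1, n + 1):
            part = comp == k
            if part.sum() < params.min_nucleolus_area_px:
                continue
            next_label += 1
            view = out[sl]
            view[part] = next_label
            parent_map[next_label] = lab

    # scan-order relabelling permutes labels; remap the parent assignments
    lut = _relabel_lut(out)
    mask = LabelMask(
        labels=lut[out],
        parent_map={int(lut[lab]): parent for lab, parent in parent_map.items()},
    )
    return mask


@dataclass
class IoUReport:
    """Object-level agreement between a predicted and a truth label mask."""

    per_truth_iou: Dict[int, float]
    matches: Dict[int, int]  # truth label -> best-overlap predicted label
    unmatched_truth: List[int]
    unmatched_predicted: List[int]

    @property
    def mean_iou(self) -> float:
        """Mean IoU over truth objects; unmatched truth objects count as 0."""
        vals = list(self.per_truth_iou.values()) + [0.0] * len(self.unmatched_truth)
        return float(np.mean(vals)) if vals else float("nan")


def mask_iou(predicted: LabelMask, truth: LabelMask) -> IoUReport:
    """Match objects by maximal pixel overlap and score each match by IoU."""
    if predicted.shape != truth.shape:
        raise GridMismatchError(
            f"mask grids differ: {predicted.shape} vs {truth.shape}"
        )
    p, t = predicted.labels, truth.labels
    per_truth: Dict[int, float] = {}
    matches: Dict[int, int] = {}
    unmatched_truth: List[int] = []
    p_sizes = np.bincount(p.ravel())
    matched_preds = set()
    for lab in truth.label_ids():
        sel = t == lab
        overlap = np.bincount(p[sel])
        overlap[0] = 0
        if overlap.max(initial=0) == 0:
            unmatched_truth.append(lab)
            continue
        best = int(overlap.argmax())
        inter = int(overlap[best])
        union = int(sel.sum()) + int(p_sizes[best]) - inter
        per_truth[lab] = inter / union
        matches[lab] = best
        matched_preds.add(best)
    unmatched_predicted = [
        lab for lab in predicted.label_ids() if lab not in matched_preds
    ]
    return IoUReport(
        per_truth_iou=per_truth,
        matches=matches,
        unmatched_truth=unmatched_truth,
        unmatched_predicted=unmatched_predicted,
    )
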