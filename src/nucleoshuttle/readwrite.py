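"""Reading and writing fields, label masks and per-cell record tables.

Images travel as TIFF (single- or multi-page) via :mod:`tifffile`;
intensities are never rescaled on read.  Per-cell measurements travel as a
CSV with a fixed header; floats are serialized with full (shortest
round-trip) precision.  Condition metadata travels in a sidecar record, not
in filenames.
"""

from __future__ import annotations

import csv
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import tifffile

from .segmentation import LabelMask

__all__ = [
    "ChannelImage",
    "FieldMetadata",
    "MultiChannelField",
    "ReadWriteError",
    "UnreadableFileError",
    "MissingChannelRoleError",
    "ChannelShapeMismatchError",
    "REQUIRED_ROLES",
    "RECORD_COLUMNS",
    "read_field",
    "write_field",
    "read_label_mask",
    "write_label_mask",
    "write_records",
    "read_records",
]

#: channel roles a field must carry for quantification
REQUIRED_ROLES = ("nuclear_dye", "nucleolar_marker", "protein")

#: canonical page order when writing multi-page TIFFs
PAGE_ORDER = ("nuclear_dye", "nucleolar_marker", "protein")

#: fixed header of the per-cell records CSV
RECORD_COLUMNS = [
    "field_id",
    "nucleus_label",
    "genotype",
    "treatment",
    "dose",
    "timepoint",
    "replicate_id",
    "nucleus_area_px",
    "nucleolar_area_px",
    "mean_nucleolar",
    "mean_nucleoplasmic",
    "ratio",
    "displayed_ratio",
    "sum_total",
    "sum_nucleolar",
    "sum_nucleoplasmic",
    "category",
    "qc_flag",
]


class ReadWriteError(Exception):
    """Base class for field/record I/O failures."""


class UnreadableFileError(ReadWriteError):
    """A file is missing or cannot be parsed as a TIFF."""


class MissingChannelRoleError(ReadWriteError):
    """A required channel role is absent from the channel map or field."""


class ChannelShapeMismatchError(ReadWriteError):
    """Channels of one field do not share a pixel grid."""


@dataclass
class ChannelImage:
    """One single-channel intensity image with its stain role."""

    pixels: np.ndarray
    role: str = "other"
    source_path: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ReadWriteError("channel must be a non-empty 2-D image")
        if not np.all(np.isfinite(self.pixels)):
            raise ReadWriteError(f"channel {self.role!r} has non-finite pixels")
        if self.pixels.min() < 0:
            raise ReadWriteError(f"channel {self.role!r} has negative intensities")


@dataclass
class FieldMetadata:
    """Experimental condition of one acquired field."""

    genotype: str = ""
    treatment: str = ""
    dose: Optional[float] = None
    dose_units: str = ""
    timepoint: Optional[float] = None
    timepoint_units: str = "h"
    replicate_id: str = ""
    field_id: str = ""


@dataclass
class MultiChannelField:
    """Co-registered channels plus condition metadata; the pipeline's input unit."""

    channels: Dict[str, ChannelImage]
    metadata: FieldMetadata = field(default_factory=FieldMetadata)

    def __post_init__(self) -> None:
        shapes = {c.pixels.shape for c in self.channels.values()}
        if len(shapes) > 1:
            raise ChannelShapeMismatchError(
                f"channel shapes differ across roles: {sorted(shapes)}"
            )

    @property
    def shape(self):
        return next(iter(self.channels.values())).pixels.shape

    def require_roles(self, roles: Sequence[str] = REQUIRED_ROLES) -> None:
        missing = [r for r in roles if r not in self.channels]
        if missing:
            raise MissingChannelRoleError(
                f"field {self.metadata.field_id!r} lacks channel role(s): {missing}"
            )

    def channel(self, role: str) -> ChannelImage:
        if role not in self.channels:
            raise MissingChannelRoleError(
                f"field {self.metadata.field_id!r} lacks channel role {role!r}"
            )
        return self.channels[role]


def _read_tiff(path: Union[str, Path]) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise UnreadableFileError(f"no such file: {path}")
    try:
        return tifffile.imread(path)
    except Exception as exc:  # noqa: BLE001 - re-raise as a named error
        raise UnreadableFileError(f"cannot read TIFF {path}: {exc}") from exc


def read_field(
    source: Union[str, Path, Mapping[str, Union[str, Path]]],
    channel_map: Optional[Mapping[str, int]] = None,
    metadata: Optional[FieldMetadata] = None,
) -> MultiChannelField:
    """Load a field from one multi-page TIFF or a mapping of per-role files.

    Parameters
    ----------
    source
        Either a path to a multi-page TIFF (then ``channel_map`` assigns a
        page index to each role) or a mapping ``role -> single-page path``.
    channel_map
        Role -> page index; required for multi-page input.  Must cover
        every role in :data:`REQUIRED_ROLES`.
    metadata
        Condition metadata; defaults to an empty record.

    Intensities are preserved as stored — 8/16-bit integer and float TIFFs
    are accepted and never rescaled.
    """
    channels: Dict[str, ChannelImage] = {}
    if isinstance(source, Mapping):
        for role, p in source.items():
            arr = _read_tiff(p)
            if arr.ndim != 2:
                raise ReadWriteError(f"{p}: expected a single-page 2-D TIFF")
            channels[role] = ChannelImage(pixels=arr, role=role, source_path=str(p))
    else:
        if channel_map is None:
            raise ReadWriteError("channel_map is required for multi-page input")
        stack = _read_tiff(source)
        if stack.ndim == 2:
            stack = stack[None, ...]
        for role, page in channel_map.items():
            if not 0 <= int(page) < stack.shape[0]:
                raise ReadWriteError(
                    f"page {page} for role {role!r} out of range "
                    f"(file has {stack.shape[0]} pages)"
                )
            channels[role] = ChannelImage(
                pixels=stack[int(page)], role=role, source_path=str(source)
            )
    missing = [r for r in REQUIRED_ROLES if r not in channels]
    if missing:
        raise MissingChannelRoleError(f"channel map lacks required role(s): {missing}")
    shapes = {c.pixels.shape for c in channels.values()}
    if len(shapes) > 1:
        raise ChannelShapeMismatchError(
            f"channel shapes differ across roles: {sorted(shapes)}"
        )
    return MultiChannelField(channels=channels, metadata=metadata or FieldMetadata())


def write_field(
    field_obj: MultiChannelField,
    path: Union[str, Path],
    dtype: Optional[str] = None,
) -> Dict[str, int]:
    """Write a field as a multi-page grayscale TIFF in canonical page order.

    With ``dtype=None`` the stored arrays are written as-is (lossless round
    trip, float pages for noisy synthetic data).  ``dtype="uint16"`` rounds
    and clips to the 16-bit range for interoperability with acquisition
    software; this is lossy for non-integer intensities.

    Returns the role -> page index map that :func:`read_field` needs.
    """
    roles = [r for r in PAGE_ORDER if r in field_obj.channels] + [
        r for r in field_obj.channels if r not in PAGE_ORDER
    ]
    pages = [field_obj.channels[r].pixels for r in roles]
    if dtype == "uint16":
        pages = [
            np.clip(np.rint(p), 0, np.iinfo(np.uint16).max).astype(np.uint16)
            for p in pages
        ]
    elif dtype is not None:
        pages = [p.astype(dtype) for p in pages]
    tifffile.imwrite(Path(path), np.stack(pages), photometric="minisblack")
    return {r: i for i, r in enumerate(roles)}


def write_label_mask(mask: LabelMask, path: Union[str, Path]) -> None:
    """Write a label mask as a 16-bit TIFF, with parent map as a sidecar CSV."""
    if mask.labels.max(initial=0) > np.iinfo(np.uint16).max:
        raise ReadWriteError("more than 65535 labels cannot be stored as uint16")
    tifffile.imwrite(Path(path), mask.labels.astype(np.uint16))
    if mask.parent_map is not None:
        side = Path(path).with_suffix(".parents.csv")
        with open(side, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["nucleolus_label", "nucleus_label"])
            for k in sorted(mask.parent_map):
                w.writerow([k, mask.parent_map[k]])


def read_label_mask(path: Union[str, Path]) -> LabelMask:
    arr = _read_tiff(path).astype(np.int32)
    side = Path(path).with_suffix(".parents.csv")
    parent_map = None
    if side.exists():
        parent_map = {}
        with open(side, newline="") as fh:
            for row in csv.DictReader(fh):
                parent_map[int(row["nucleolus_label"])] = int(row["nucleus_label"])
    return LabelMask(labels=arr, parent_map=parent_map)


def records_to_frame(records: Iterable) -> pd.DataFrame:
    """Normalize NucleusRecord objects (or dicts) to the fixed CSV schema."""
    rows = []
    for r in records:
        d = asdict(r) if hasattr(r, "__dataclass_fields__") else dict(r)
        rows.append({c: d.get(c) for c in RECORD_COLUMNS})
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def write_records(records: Iterable, path: Union[str, Path]) -> None:
    """Write per-cell records as CSV with the fixed header.

    An empty record list writes a header-only file.  Undefined ratios
    (``None``/NaN) serialize as empty cells; floats use shortest
    round-trip representation, so read-back reproduces them exactly.
    """
    frame = records_to_frame(records)
    try:
        frame.to_csv(Path(path), index=False)
    except OSError as exc:
        raise ReadWriteError(f"cannot write records to {path}: {exc}") from exc


def read_records(path: Union[str, Path]) -> pd.DataFrame:
    """Read a records CSV back into a DataFrame with the fixed schema."""
    path = Path(path)
    if not path.exists():
        raise UnreadableFileError(f"no such file: {path}")
    frame = pd.read_csv(
        path,
        dtype={
            "field_id": str,
            "genotype": str,
            "treatment": str,
            "replicate_id": str,
            "category": str,
            "qc_flag": str,
        },
    )
    missing = [c for c in RECORD_COLUMNS if c not in frame.columns]
    if missing:
        raise ReadWriteError(f"records CSV {path} lacks column(s): {missing}")
    return frame[RECORD_COLUMNS]
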