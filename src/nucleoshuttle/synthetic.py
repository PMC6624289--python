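"""Synthetic multi-channel immunofluorescence fields with known ground truth.

The generator emulates fixed-cell confocal fields of adherent cells stained
with a DNA dye (nuclear channel), a nucleolar marker such as fibrillarin
(marker channel), and an antibody against a protein of interest (protein
channel).  Nuclei are non-overlapping ellipses fully interior to the image;
each nucleus carries a sampled number of disjoint circular nucleoli strictly
inside it.  The protein channel is piecewise constant before noise:
``background`` outside nuclei, ``nucleoplasm_mean_intensity`` in the
nucleoplasm and ``e * nucleoplasm_mean_intensity`` inside nucleoli, where the
enrichment factor ``e`` is the ground-truth counterpart of the measured
nucleolar/nucleoplasmic intensity ratio.

Noise follows a standard shot + read model: per-pixel
``Poisson(I * photon_scale) / photon_scale + N(0, read_noise_sigma)``,
clipped at zero.  Everything is deterministic given the spec seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Tuple

import numpy as np

from .segmentation import LabelMask

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "TimecourseSpec",
    "PlacementError",
    "SpecValidationError",
    "generate_field",
    "enrichment_trajectory",
    "generate_timecourse",
]

#: cap on rejection-sampling attempts for nucleus / nucleolus placement
MAX_PLACEMENT_ATTEMPTS = 10_000


class SpecValidationError(ValueError):
    """A generator spec violates one of its invariants."""


class PlacementError(RuntimeError):
    """Rejection sampling could not place the requested geometry."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic field.

    Defaults describe the assay being emulated: 1152 x 1152 px acquisition,
    ~12 well-separated nuclei per field (so a handful of fields yields the
    >90 cells a condition comprises), nuclei of 40-70 px radius each with
    2-5 nucleoli of 5-15 px radius, and intensity levels in arbitrary units
    with the protein channel's nucleoplasmic mean at 100.
    """

    image_height_px: int = 1152
    image_width_px: int = 1152
    n_nuclei: int = 12
    nucleus_radius_range_px: Tuple[float, float] = (40.0, 70.0)
    nucleoli_per_nucleus_range: Tuple[int, int] = (2, 5)
    nucleolus_radius_range_px: Tuple[float, float] = (5.0, 15.0)
    enrichment_factor_e: float = 3.0
    nucleoplasm_mean_intensity: float = 100.0
    background_intensity: float = 5.0
    nuclear_dye_intensity: float = 200.0
    nucleolar_dye_dimming: float = 0.4
    marker_intensity: float = 150.0
    photon_scale: float = 1.0
    read_noise_sigma: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.image_height_px <= 0 or self.image_width_px <= 0:
            raise SpecValidationError("image dimensions must be positive")
        if self.n_nuclei < 0:
            raise SpecValidationError("n_nuclei must be non-negative")
        for name in ("nucleus_radius_range_px", "nucleolus_radius_range_px"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise SpecValidationError(f"{name} must satisfy 0 < min <= max")
        lo, hi = self.nucleoli_per_nucleus_range
        if not (0 <= lo <= hi):
            raise SpecValidationError(
                "nucleoli_per_nucleus_range must satisfy 0 <= min <= max"
            )
        if self.nucleolus_radius_range_px[1] >= self.nucleus_radius_range_px[0]:
            raise SpecValidationError(
                "max nucleolus radius must be smaller than min nucleus radius"
            )
        if self.enrichment_factor_e <= 0:
            raise SpecValidationError("enrichment_factor_e must be positive")
        if not 0.0 <= self.nucleolar_dye_dimming <= 1.0:
            raise SpecValidationError("nucleolar_dye_dimming must lie in [0, 1]")
        for name in (
            "nucleoplasm_mean_intensity",
            "nuclear_dye_intensity",
            "marker_intensity",
        ):
            if getattr(self, name) <= 0:
                raise SpecValidationError(f"{name} must be positive")
        for name in ("background_intensity", "photon_scale", "read_noise_sigma"):
            if getattr(self, name) < 0:
                raise SpecValidationError(f"{name} must be non-negative")


@dataclass
class GroundTruth:
    """True segmentation and enrichment underlying one synthetic field."""

    nucleus_mask: LabelMask
    nucleolus_mask: LabelMask
    per_nucleus_true_enrichment: Dict[int, float]


@dataclass(frozen=True)
class TimecourseSpec:
    """Release-then-recovery kinetics of the ground-truth enrichment.

    The enrichment decays from its baseline ``e0`` toward a release floor
    ``e_floor`` at rate ``k_rel`` (per hour); from the recovery onset
    ``tau_h`` it relaxes back toward ``e0`` at rate ``k_rec``.  A floor
    below 1 models the depleted-nucleolus state in which the compartment
    ratio drops under 1 (displayed ratio negative); ``e_floor = 1`` gives
    the purely homogeneous endpoint.
    """

    timepoints_h: Tuple[float, ...] = (0.0, 0.5, 1.0, 2.0, 4.0, 8.0, 24.0)
    e0: float = 3.0
    k_rel: float = 2.0
    tau_h: float = 3.0
    k_rec: float = 0.5
    e_floor: float = 0.5

    def validate(self) -> None:
        tp = tuple(self.timepoints_h)
        if len(tp) == 0 or any(t < 0 for t in tp):
            raise SpecValidationError("timepoints_h must be non-negative")
        if any(b <= a for a, b in zip(tp, tp[1:])):
            raise SpecValidationError("timepoints_h must be strictly increasing")
        if self.e0 <= 0 or self.e_floor <= 0:
            raise SpecValidationError("e0 and e_floor must be positive")
        if self.k_rel < 0 or self.k_rec < 0 or self.tau_h < 0:
            raise SpecValidationError("rates and tau_h must be non-negative")


def enrichment_trajectory(tc: TimecourseSpec, t: float) -> float:
    """True enrichment e(t) under the release/recovery model.

    For t <= tau:  e(t) = e_floor + (e0 - e_floor) * exp(-k_rel * t)
    For t >  tau:  e(t) = e(tau) + (e0 - e(tau)) * (1 - exp(-k_rec * (t - tau)))

    Continuous at tau; monotone toward e_floor on [0, tau] and back toward
    e0 afterwards.  With e_floor = 1 this is the classical
    e(t) = 1 + (e0 - 1) * f(t) release/recovery form.
    """
    tc.validate()
    if t < 0:
        raise ValueError(f"timepoint must be non-negative, got {t}")
    e0, floor = tc.e0, tc.e_floor

    def _release(u: float) -> float:
        return floor + (e0 - floor) * math.exp(-tc.k_rel * u)

    if t <= tc.tau_h:
        return _release(t)
    e_tau = _release(tc.tau_h)
    return e_tau + (e0 - e_tau) * (1.0 - math.exp(-tc.k_rec * (t - tc.tau_h)))


# ---------------------------------------------------------------------------
# geometry sampling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _Ellipse:
    cy: float
    cx: float
    a: float  # semi-major, px
    b: float  # semi-minor, px
    theta: float  # orientation, rad

    def contains(self, y: np.ndarray, x: np.ndarray, shrink: float = 0.0) -> np.ndarray:
        """Elementwise membership test, optionally with both axes shrunk."""
        dy, dx = y - self.cy, x - self.cx
        ct, st = math.cos(self.theta), math.sin(self.theta)
        u = dx * ct + dy * st
        v = -dx * st + dy * ct
        a, b = self.a - shrink, self.b - shrink
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _sample_nuclei(spec: SyntheticSpec, rng: np.random.Generator) -> List[_Ellipse]:
    lo, hi = spec.nucleus_radius_range_px
    margin = 2.0
    placed: List[_Ellipse] = []
    attempts = 0
    while len(placed) < spec.n_nuclei:
        if attempts >= MAX_PLACEMENT_ATTEMPTS:
            raise PlacementError(
                f"could not place {spec.n_nuclei} nuclei of radius "
                f"{spec.nucleus_radius_range_px} px in a "
                f"{spec.image_height_px}x{spec.image_width_px} image after "
                f"{MAX_PLACEMENT_ATTEMPTS} attempts; reduce n_nuclei or radii"
            )
        attempts += 1
        r1, r2 = rng.uniform(lo, hi, size=2)
        a, b = max(r1, r2), min(r1, r2)
        theta = rng.uniform(0.0, math.pi)
        cy = rng.uniform(a + margin, spec.image_height_px - a - margin)
        cx = rng.uniform(a + margin, spec.image_width_px - a - margin)
        if cy <= a + margin - 1 or cx <= a + margin - 1:  # image too small
            continue
        cand = _Ellipse(cy, cx, a, b, theta)
        # conservative non-overlap: bounding circles separated by the margin
        if all(
            math.hypot(cand.cy - e.cy, cand.cx - e.cx) > cand.a + e.a + margin
            for e in placed
        ):
            placed.append(cand)
    return placed


def _rasterize_ellipse(e: _Ellipse, shape: Tuple[int, int]) -> Tuple[np.ndarray, np.ndarray]:
    """Pixel coordinates (rows, cols) inside the ellipse."""
    y0 = max(int(math.floor(e.cy - e.a)), 0)
    y1 = min(int(math.ceil(e.cy + e.a)) + 1, shape[0])
    x0 = max(int(math.floor(e.cx - e.a)), 0)
    x1 = min(int(math.ceil(e.cx + e.a)) + 1, shape[1])
    yy, xx = np.mgrid[y0:y1, x0:x1]
    inside = e.contains(yy.astype(float), xx.astype(float))
    return yy[inside], xx[inside]


def _sample_nucleoli(
    spec: SyntheticSpec,
    nucleus: _Ellipse,
    nucleus_pixels: np.ndarray,
    shape: Tuple[int, int],
    rng: np.random.Generator,
) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Disjoint circular nucleoli strictly inside one nucleus.

    Containment is enforced both continuously (circle inside the ellipse)
    and at pixel level (raster subset of the nucleus raster), so the mask
    invariant holds exactly.
    """
    k_lo, k_hi = spec.nucleoli_per_nucleus_range
    r_lo, r_hi = spec.nucleolus_radius_range_px
    k = int(rng.integers(k_lo, k_hi + 1))
    taken = np.zeros(shape, dtype=bool)
    in_nucleus = np.zeros(shape, dtype=bool)
    in_nucleus[nucleus_pixels] = True
    out: List[Tuple[np.ndarray, np.ndarray]] = []
    attempts = 0
    while len(out) < k:
        if attempts >= MAX_PLACEMENT_ATTEMPTS:
            raise PlacementError(
                f"could not place {k} nucleoli of radius "
                f"{spec.nucleolus_radius_range_px} px inside a nucleus with "
                f"semi-axes ({nucleus.a:.1f}, {nucleus.b:.1f}) px after "
                f"{MAX_PLACEMENT_ATTEMPTS} attempts"
            )
        attempts += 1
        r = rng.uniform(r_lo, r_hi)
        # sample the centre from the shrunken ellipse, then verify exactly
        t = rng.uniform(0.0, 2.0 * math.pi)
        rho = math.sqrt(rng.uniform())
        ct, st = math.cos(nucleus.theta), math.sin(nucleus.theta)
        u = rho * (nucleus.a - r - 1.0) * math.cos(t)
        v = rho * (nucleus.b - r - 1.0) * math.sin(t)
        if nucleus.a - r - 1.0 <= 0 or nucleus.b - r - 1.0 <= 0:
            continue
        cx = nucleus.cx + u * ct - v * st
        cy = nucleus.cy + u * st + v * ct
        y0 = max(int(math.floor(cy - r)) - 2, 0)
        y1 = min(int(math.ceil(cy + r)) + 3, shape[0])
        x0 = max(int(math.floor(cx - r)) - 2, 0)
        x1 = min(int(math.ceil(cx + r)) + 3, shape[1])
        yy, xx = np.mgrid[y0:y1, x0:x1]
        disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        ys, xs = yy[disc], xx[disc]
        if ys.size == 0:
            continue
        if not in_nucleus[ys, xs].all():  # strict containment, pixelwise
            continue
        # disjoint from siblings with a >=1 px gap, so distinct nucleoli
        # never touch and remain separable as connected components
        gap = (yy - cy) ** 2 + (xx - cx) ** 2 <= (r + 1.5) ** 2
        if taken[yy[gap], xx[gap]].any():
            continue
        taken[ys, xs] = True
        out.append((ys, xs))
    return out


# ---------------------------------------------------------------------------
# field generation
# ---------------------------------------------------------------------------


def generate_field(spec: SyntheticSpec):
    """Render one synthetic field and its ground truth.

    Returns
    -------
    (MultiChannelField, GroundTruth)
        Three co-registered channels (``nuclear_dye``, ``nucleolar_marker``,
        ``protein``) plus the true label masks and per-nucleus enrichment.
    """
    from .readwrite import ChannelImage, FieldMetadata, MultiChannelField

    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shape = (spec.image_height_px, spec.image_width_px)

    nuclei = _sample_nuclei(spec, rng)
    nucleus_labels = np.zeros(shape, dtype=np.int32)
    nucleolus_labels = np.zeros(shape, dtype=np.int32)
    parent_map: Dict[int, int] = {}

    dye = np.full(shape, spec.background_intensity, dtype=np.float64)
    marker = np.full(shape, spec.background_intensity, dtype=np.float64)
    protein = np.full(shape, spec.background_intensity, dtype=np.float64)

    e = spec.enrichment_factor_e
    nucleolus_id = 0
    for i, ell in enumerate(nuclei, start=1):
        ys, xs = _rasterize_ellipse(ell, shape)
        nucleus_labels[ys, xs] = i
        dye[ys, xs] = spec.nuclear_dye_intensity
        protein[ys, xs] = spec.nucleoplasm_mean_intensity
        for nys, nxs in _sample_nucleoli(spec, ell, (ys, xs), shape, rng):
            nucleolus_id += 1
            nucleolus_labels[nys, nxs] = nucleolus_id
            parent_map[nucleolus_id] = i
            dye[nys, nxs] = spec.nuclear_dye_intensity * (1.0 - spec.nucleolar_dye_dimming)
            marker[nys, nxs] = spec.marker_intensity
            protein[nys, nxs] = e * spec.nucleoplasm_mean_intensity

    def _noise(img: np.ndarray) -> np.ndarray:
        out = img
        if spec.photon_scale > 0:
            out = rng.poisson(out * spec.photon_scale).astype(np.float64) / spec.photon_scale
        if spec.read_noise_sigma > 0:
            out = out + rng.normal(0.0, spec.read_noise_sigma, size=out.shape)
        return np.clip(out, 0.0, None)

    dye, marker, protein = _noise(dye), _noise(marker), _noise(protein)

    field_obj = MultiChannelField(
        channels={
            "nuclear_dye": ChannelImage(pixels=dye, role="nuclear_dye"),
            "nucleolar_marker": ChannelImage(pixels=marker, role="nucleolar_marker"),
            "protein": ChannelImage(pixels=protein, role="protein"),
        },
        metadata=FieldMetadata(field_id=f"synthetic_seed{spec.seed}"),
    )
    truth = GroundTruth(
        nucleus_mask=LabelMask(labels=nucleus_labels),
        nucleolus_mask=LabelMask(labels=nucleolus_labels, parent_map=parent_map),
        per_nucleus_true_enrichment={i: e for i in range(1, len(nuclei) + 1)},
    )
    return field_obj, truth


def generate_timecourse(spec: SyntheticSpec, tc: TimecourseSpec):
    """One independently sampled field per timepoint (fixed-cell imaging).

    The enrichment of field *i* is ``enrichment_trajectory(tc, t_i)``; its
    geometry and noise derive from ``spec.seed + i`` so fields are
    reproducible but independent, as in fixed-cell immunofluorescence where
    each timepoint is a different coverslip.
    """
    spec.validate()
    tc.validate()
    out = []
    for i, t in enumerate(tc.timepoints_h):
        e_t = enrichment_trajectory(tc, t)
        sub = replace(spec, enrichment_factor_e=e_t, seed=spec.seed + i)
        fld, truth = generate_field(sub)
        fld.metadata.timepoint = float(t)
        fld.metadata.field_id = f"tc_seed{spec.seed}_t{t:g}"
        out.append((fld, truth))
    return out
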