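"""Threshold-based lesion delineation and SUV-derived lesion metrics.

The quantification scheme mirrors routine clinical FDG-PET workstation
practice: a volume of interest (VOI) is the 26-connected set of voxels at or
above a segmentation level, either an absolute SUV cut-off (the classic 2.5)
or a fraction of the lesion's own SUVmax (40-70 %SUVmax).  From the VOI we
derive

* ``suv_max`` / ``suv_mean`` -- maximum and arithmetic-mean SUV,
* ``mtv_ml``  -- metabolic tumor volume, voxel count times voxel volume (mL),
* ``tlg``     -- total lesion glycolysis, SUVmean x MTV,
* ``hi``      -- heterogeneity index, SUVmax / SUVmean (>= 1; 1 for uniform
  uptake, larger for steeper intra-lesional gradients).

Voxel coordinates are 0-based integer indices; physical positions follow the
voxel-center convention (index x spacing).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "SUVolume",
    "ThresholdSpec",
    "LesionVOI",
    "LesionMetrics",
    "EmptyVOIError",
    "compute_suv",
    "segment_voi",
    "lesion_metrics",
    "metric_grid",
    "CLINICAL_THRESHOLDS",
]

#: 26-connectivity structuring element (all neighbors sharing a face, edge
#: or corner).  Fixed: the permissive standard for bright blobs.
_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


class EmptyVOIError(ValueError):
    """No voxel in the seed's component reaches the segmentation level."""


@dataclass(frozen=True)
class SUVolume:
    """A 3D grid of dimensionless SUV values with voxel spacing in mm."""

    values: np.ndarray
    voxel_size_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 3:
            raise ValueError(f"SUV grid must be 3D, got ndim={values.ndim}")
        if not np.all(np.isfinite(values)):
            raise ValueError("SUV grid contains non-finite values")
        spacing = self.voxel_size_mm
        if np.isscalar(spacing):
            spacing = (float(spacing),) * 3
        spacing = tuple(float(s) for s in spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"voxel spacing must be 3 positive lengths, got {spacing}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "voxel_size_mm", spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in mL (1 mL = 1000 mm^3)."""
        return float(np.prod(self.voxel_size_mm)) / 1000.0


def compute_suv(
    activity_kbq_per_ml: np.ndarray,
    body_weight_kg: float,
    injected_dose_mbq: float,
    voxel_size_mm: tuple[float, float, float] | float = 1.0,
) -> SUVolume:
    """Convert an activity-concentration grid to body-weight-normalized SUV.

    SUV = C[kBq/mL] * weight[g] / dose[kBq], which with the 1 g/mL tissue
    density convention reduces to ``C * weight_kg / dose_MBq`` (the unit
    factors of 1000 cancel).

    Parameters
    ----------
    activity_kbq_per_ml
        Decay-corrected activity concentration, kBq/mL.
    body_weight_kg, injected_dose_mbq
        Patient weight (kg) and injected tracer dose (MBq); both must be
        positive.
    """
    if body_weight_kg <= 0:
        raise ValueError(f"body weight must be positive, got {body_weight_kg}")
    if injected_dose_mbq <= 0:
        raise ValueError(f"injected dose must be positive, got {injected_dose_mbq}")
    activity = np.asarray(activity_kbq_per_ml, dtype=float)
    return SUVolume(activity * body_weight_kg / injected_dose_mbq, voxel_size_mm)


@dataclass(frozen=True)
class ThresholdSpec:
    """Segmentation level: an absolute SUV or a fraction of the lesion SUVmax."""

    mode: str  # "absolute" | "relative"
    value: float

    def __post_init__(self) -> None:
        if self.mode not in ("absolute", "relative"):
            raise ValueError(f"unknown threshold mode {self.mode!r}")
        if self.mode == "absolute" and not self.value > 0:
            raise ValueError(f"absolute threshold must be > 0, got {self.value}")
        if self.mode == "relative" and not 0 < self.value < 1:
            raise ValueError(
                f"relative threshold must be a fraction in (0,1), got {self.value}"
            )

    @classmethod
    def parse(cls, label: str | float) -> "ThresholdSpec":
        """Parse ``"2.5"`` (absolute SUV) or ``"40%"`` (fraction of SUVmax)."""
        if isinstance(label, ThresholdSpec):
            return label
        if isinstance(label, (int, float)):
            return cls("absolute", float(label))
        text = str(label).strip()
        if text.endswith("%"):
            return cls("relative", float(text[:-1]) / 100.0)
        return cls("absolute", float(text))

    @property
    def label(self) -> str:
        if self.mode == "relative":
            return f"{self.value * 100:g}%"
        return f"{self.value:g}"


#: The five clinical delineation levels: absolute SUV 2.5 and 40-70 %SUVmax.
CLINICAL_THRESHOLDS: tuple[ThresholdSpec, ...] = tuple(
    ThresholdSpec.parse(t) for t in ("2.5", "40%", "50%", "60%", "70%")
)


@dataclass
class LesionVOI:
    """A delineated lesion: a non-empty 26-connected voxel set at one level."""

    indices: np.ndarray  # (N, 3) int voxel indices
    shape: tuple[int, int, int]
    seed: tuple[int, int, int]
    level: float  # resolved SUV level actually applied
    spec: ThresholdSpec
    site: str | None = None
    ct_confirmed: bool = True
    background_warning: bool = False
    local_suv_max: float | None = None

    def __len__(self) -> int:
        return self.indices.shape[0]

    @property
    def mask(self) -> np.ndarray:
        m = np.zeros(self.shape, dtype=bool)
        m[tuple(self.indices.T)] = True
        return m

    def bounding_box_extent_mm(self, voxel_size_mm) -> float:
        """Largest axis-aligned extent of the VOI bounding box, in mm."""
        span = self.indices.max(axis=0) - self.indices.min(axis=0) + 1
        return float(np.max(span * np.asarray(voxel_size_mm, dtype=float)))


def _estimate_background(values: np.ndarray) -> tuple[float, float]:
    """Robust (median, sigma) of the volume; lesions occupy few voxels."""
    med = float(np.median(values))
    mad = float(np.median(np.abs(values - med)))
    return med, 1.4826 * mad


def _component_containing(mask: np.ndarray, voxel: tuple[int, int, int]) -> np.ndarray:
    labels, _ = ndimage.label(mask, structure=_STRUCT_26)
    return labels == labels[voxel]


def segment_voi(
    volume: SUVolume,
    seed: tuple[int, int, int],
    spec: ThresholdSpec | str | float,
    site: str | None = None,
    ct_confirmed: bool = True,
) -> LesionVOI:
    """Delineate the VOI around ``seed`` at the requested threshold.

    Absolute mode keeps the 26-connected component of ``SUV >= level``
    containing the seed.  Relative mode first bounds the lesion with a
    deterministic bootstrap region -- the component grown from the seed at
    ``max(2.5, background + 3*sigma)`` -- takes the local SUVmax inside it,
    then keeps the component of ``SUV >= fraction * local SUVmax`` containing
    that maximum voxel.  Comparison is inclusive (>=), so the maximum voxel
    always survives its own relative threshold.

    Raises
    ------
    EmptyVOIError
        If the seed voxel itself is below an absolute level.
    """
    spec = ThresholdSpec.parse(spec)
    values = volume.values
    seed = tuple(int(i) for i in seed)
    if any(not 0 <= s < n for s, n in zip(seed, values.shape)):
        raise IndexError(f"seed {seed} outside grid {values.shape}")

    background, noise_sigma = _estimate_background(values)
    floor = background + 3.0 * noise_sigma

    if spec.mode == "absolute":
        level = spec.value
        if values[seed] < level:
            raise EmptyVOIError(
                f"seed voxel SUV {values[seed]:.3g} below absolute level {level:g}"
            )
        component = _component_containing(values >= level, seed)
        local_max = float(values[component].max())
    else:
        boot_level = max(2.5, floor)
        if values[seed] >= boot_level:
            region = _component_containing(values >= boot_level, seed)
        else:
            # Seed never reaches the bootstrap floor: fall back to the seed
            # voxel alone (the background warning below will fire).
            region = np.zeros_like(values, dtype=bool)
            region[seed] = True
        local_max = float(values[region].max())
        level = spec.value * local_max
        flat = np.where(region.ravel(), values.ravel(), -np.inf)
        max_voxel = np.unravel_index(int(np.argmax(flat)), values.shape)
        component = _component_containing(values >= level, max_voxel)

    indices = np.argwhere(component)
    return LesionVOI(
        indices=indices,
        shape=values.shape,
        seed=seed,
        level=float(level),
        spec=spec,
        site=site,
        ct_confirmed=ct_confirmed,
        background_warning=bool(local_max <= floor),
        local_suv_max=local_max,
    )


@dataclass(frozen=True)
class LesionMetrics:
    """SUV metrics of one lesion at one delineation level."""

    suv_max: float
    suv_mean: float
    mtv_ml: float
    tlg: float
    hi: float
    diameter_mm: float  # largest bounding-box extent of this VOI
    n_voxels: int
    threshold: str


def lesion_metrics(voi: LesionVOI, volume: SUVolume) -> LesionMetrics:
    """Compute SUVmax, SUVmean, MTV, TLG and HI over a delineated VOI."""
    if len(voi) == 0:
        raise EmptyVOIError("cannot compute metrics of an empty VOI")
    suvs = volume.values[tuple(voi.indices.T)]
    suv_max = float(suvs.max())
    suv_mean = float(suvs.mean())
    if suv_mean <= 0:
        raise ValueError("SUVmean must be positive inside a lesion VOI")
    mtv_ml = len(voi) * volume.voxel_volume_ml
    return LesionMetrics(
        suv_max=suv_max,
        suv_mean=suv_mean,
        mtv_ml=mtv_ml,
        tlg=suv_mean * mtv_ml,
        hi=suv_max / suv_mean,
        diameter_mm=voi.bounding_box_extent_mm(volume.voxel_size_mm),
        n_voxels=len(voi),
        threshold=voi.spec.label,
    )


def metric_grid(
    volume: SUVolume,
    seed: tuple[int, int, int],
    thresholds=CLINICAL_THRESHOLDS,
) -> tuple[dict[str, LesionMetrics], dict[str, str]]:
    """Per-threshold metrics for one lesion.

    Returns ``(metrics, failures)``: a dict keyed by threshold label, and a
    dict of threshold label -> error message for levels at which delineation
    failed (e.g. the seed never reaches the absolute cut-off).
    """
    thresholds = [ThresholdSpec.parse(t) for t in thresholds]
    if not thresholds:
        raise ValueError("threshold list must be non-empty")
    out: dict[str, LesionMetrics] = {}
    failures: dict[str, str] = {}
    for spec in thresholds:
        try:
            voi = segment_voi(volume, seed, spec)
            out[spec.label] = lesion_metrics(voi, volume)
        except EmptyVOIError as exc:
            failures[spec.label] = str(exc)
    return out, failures
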