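"""Shared domain types, angle conventions and exceptions.

Coordinate conventions used throughout the package:

* Cross-section coordinates are millimetres in the plane of the nerve
  section, origin at the nerve centroid, x rightward and y upward when the
  section is viewed from the cranial aspect.
* Angles are degrees in [0, 360), measured **clockwise from the +y axis**
  (12 o'clock), so a structure "at the top" of the cross-section is at 0°.
* Raster maps live on the unit disk: pixel (i, j) of an ``n × n`` grid has
  its centre at ``x = -1 + (j + 0.5) * 2/n``, ``y = 1 - (i + 0.5) * 2/n``
  (row 0 at the top); a pixel belongs to the disk iff its centre is inside
  the unit circle.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np

# ---------------------------------------------------------------------------
# Controlled vocabularies

ORGAN_LABELS = (
    "cardiac",
    "recurrent_laryngeal",
    "pulmonary",
    "cardiopulmonary",
    "laryngopulmonary",
)
FIBER_CLASSES = ("afferent", "efferent", "mixed")
GROUPS = ("laryngeal", "pulmonary", "cardiac_efferent", "cardiac_afferent")
MODALITIES = ("HR", "BR", "EtCO2", "EMG")
CONDITIONS = ("pre_vagotomy", "post_vagotomy", "post_double_vagotomy")

#: Functional group -> organ labels whose fascicles contain fibers of that
#: group.  Pure cardiac fascicles are 100% efferent; cardiopulmonary
#: fascicles carry the cardiac afferents (they originate from the nodose
#: ganglion and project to the heart).
GROUP_MEMBERSHIP: dict[str, tuple[str, ...]] = {
    "cardiac_efferent": ("cardiac",),
    "cardiac_afferent": ("cardiopulmonary",),
    "pulmonary": ("pulmonary", "cardiopulmonary", "laryngopulmonary"),
    "laryngeal": ("recurrent_laryngeal", "laryngopulmonary"),
}

MAP_KINDS = ("binary", "response", "atlas")


# ---------------------------------------------------------------------------
# Exceptions

class VagusMapError(Exception):
    """Base class for all package-specific errors."""


class FormatError(VagusMapError):
    """A file does not conform to the expected on-disk format."""


class ValidationError(VagusMapError):
    """Parsed data violates a domain invariant."""


class GenerationError(VagusMapError):
    """The synthetic generator could not satisfy its constraints."""


class AlignmentError(VagusMapError):
    """Map alignment has no usable reference (empty cardiac-efferent map)."""


class TitrationError(VagusMapError):
    """Amplitude titration failed to converge.

    Carries the amplitude/pair-count trajectory explored before failure.
    """

    def __init__(self, message: str, trajectory: list[tuple[float, int]]):
        super().__init__(message)
        self.trajectory = trajectory


class InsufficientDataError(VagusMapError):
    """Too few usable animals for the requested statistic."""


class UndefinedBaselineError(VagusMapError):
    """A percent change is undefined because the baseline is zero."""


# ---------------------------------------------------------------------------
# Angle helpers (clockwise-from-top convention)

def polar_to_xy(theta_deg, r):
    """Cartesian (x, y) of polar (angle clockwise from +y, radius)."""
    th = np.deg2rad(theta_deg)
    return r * np.sin(th), r * np.cos(th)


def xy_to_angle_deg(x, y):
    """Angle in [0, 360), clockwise from +y, of Cartesian (x, y)."""
    return np.rad2deg(np.arctan2(x, y)) % 360.0


def wrap_angle_deg(a):
    """Wrap to [0, 360)."""
    return np.asarray(a) % 360.0


def signed_angle_diff_deg(a, b):
    """Signed circular difference a - b in (-180, 180]."""
    d = (np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 360.0
    return np.where(d > 180.0, d - 360.0, d)


# ---------------------------------------------------------------------------
# Raster grid helpers

@functools.lru_cache(maxsize=16)
def pixel_centers(grid_size: int) -> tuple[np.ndarray, np.ndarray]:
    """(X, Y) pixel-centre coordinate arrays on the [-1, 1]^2 square."""
    n = grid_size
    j = np.arange(n)
    x = -1.0 + (j + 0.5) * 2.0 / n
    y = 1.0 - (j + 0.5) * 2.0 / n
    X, Y = np.meshgrid(x, y)  # X varies along columns, Y along rows
    return X, Y


@functools.lru_cache(maxsize=16)
def disk_mask(grid_size: int) -> np.ndarray:
    """Boolean mask of pixels whose centre lies inside the unit circle."""
    X, Y = pixel_centers(grid_size)
    return X**2 + Y**2 < 1.0


# ---------------------------------------------------------------------------
# Domain dataclasses

@dataclass
class ElectrodeArray:
    """Geometry of the multi-pad epineural cuff.

    The cuff is tubular; each of ``n_pairs`` pad pairs sits at a fixed
    angular position on the inner wall, and current is driven through the
    two pads of a pair (one per ring) so a pair is characterised by a single
    angle.  Defaults describe a 14-pair cuff of 2.7 mm inner diameter with
    equally spaced pads.
    """

    n_pairs: int = 14
    pad_angles_deg: tuple[float, ...] = ()
    cuff_inner_diameter_mm: float = 2.7
    pad_length_mm: float = 3.00
    pad_width_mm: float = 0.35

    def __post_init__(self):
        if not self.pad_angles_deg:
            self.pad_angles_deg = tuple(
                i * 360.0 / self.n_pairs for i in range(self.n_pairs)
            )
        self.pad_angles_deg = tuple(float(a) for a in self.pad_angles_deg)
        if self.cuff_inner_diameter_mm <= 0:
            raise ValidationError("cuff_inner_diameter_mm must be positive")
        if len(self.pad_angles_deg) != self.n_pairs:
            raise ValidationError(
                f"n_pairs={self.n_pairs} but {len(self.pad_angles_deg)} pad angles given"
            )
        a = np.asarray(self.pad_angles_deg)
        if np.any(a < 0) or np.any(a >= 360):
            raise ValidationError("pad angles must lie in [0, 360)")
        if np.any(np.diff(a) <= 0):
            raise ValidationError("pad angles must be strictly increasing")

    @property
    def radius_mm(self) -> float:
        return self.cuff_inner_diameter_mm / 2.0

    def pad_xy_mm(self) -> np.ndarray:
        """(n_pairs, 2) Cartesian pad positions on the cuff circle, mm."""
        x, y = polar_to_xy(np.asarray(self.pad_angles_deg), self.radius_mm)
        return np.column_stack([x, y])


@dataclass
class StimParams:
    """Biphasic pulse-train stimulation parameters for one trial."""

    amplitude_mA: float = 1.0
    pulse_width_us: float = 1000.0
    frequency_Hz: float = 10.0
    on_s: float = 15.0
    off_s: float = 15.0

    def __post_init__(self):
        for name in ("amplitude_mA", "pulse_width_us", "frequency_Hz", "on_s", "off_s"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be strictly positive")

    def with_amplitude(self, amplitude_mA: float) -> "StimParams":
        return StimParams(
            amplitude_mA=amplitude_mA,
            pulse_width_us=self.pulse_width_us,
            frequency_Hz=self.frequency_Hz,
            on_s=self.on_s,
            off_s=self.off_s,
        )


@dataclass
class Fascicle:
    """One traced fascicle in the mid-cuff cross-section."""

    fascicle_id: str
    center_x_mm: float
    center_y_mm: float
    radius_mm: float
    organ_label: str
    fiber_class: str

    def __post_init__(self):
        if self.radius_mm <= 0:
            raise ValidationError(f"fascicle {self.fascicle_id}: radius_mm must be > 0")
        if self.organ_label not in ORGAN_LABELS:
            raise ValidationError(
                f"fascicle {self.fascicle_id}: organ_label {self.organ_label!r} "
                f"not in {ORGAN_LABELS}"
            )
        if self.fiber_class not in FIBER_CLASSES:
            raise ValidationError(
                f"fascicle {self.fascicle_id}: fiber_class {self.fiber_class!r} "
                f"not in {FIBER_CLASSES}"
            )

    @property
    def angle_deg(self) -> float:
        """Angular position about the nerve centroid (0° if at the centre)."""
        if self.center_x_mm == 0.0 and self.center_y_mm == 0.0:
            return 0.0
        return float(xy_to_angle_deg(self.center_x_mm, self.center_y_mm))

    @property
    def r_mm(self) -> float:
        return float(np.hypot(self.center_x_mm, self.center_y_mm))

    @property
    def area_mm2(self) -> float:
        return float(np.pi * self.radius_mm**2)


@dataclass
class NerveSection:
    """All traced fascicles of one nerve at the mid-cuff level."""

    nerve_id: str
    animal_id: str
    nerve_radius_mm: float
    fascicles: list[Fascicle] = field(default_factory=list)

    def __post_init__(self):
        if self.nerve_radius_mm <= 0:
            raise ValidationError("nerve_radius_mm must be > 0")
        bad = [
            f.fascicle_id
            for f in self.fascicles
            if f.r_mm > self.nerve_radius_mm + 1e-9
        ]
        if bad:
            raise ValidationError(
                f"nerve {self.nerve_id}: fascicle centroids beyond the nerve "
                f"boundary: {', '.join(bad)}"
            )

    def group_fascicles(self, group: str) -> list[Fascicle]:
        """Fascicles containing fibers of the given functional group."""
        if group not in GROUP_MEMBERSHIP:
            raise ValidationError(f"unknown group {group!r}; expected one of {GROUPS}")
        labels = GROUP_MEMBERSHIP[group]
        return [f for f in self.fascicles if f.organ_label in labels]


@dataclass
class CircularMap:
    """Raster over the unit disk.

    ``kind`` distinguishes binary fascicle-presence maps, signed
    back-projected response maps, and cross-animal atlas maps (fractions in
    [0, 1]).  ``rotation_applied_deg`` records the alignment rotation, or
    ``None`` for an unaligned map.
    """

    values: np.ndarray
    group: str
    animal_id: str = ""
    kind: str = "binary"
    rotation_applied_deg: float | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValidationError("map values must be a square 2-D array")
        if self.kind not in MAP_KINDS:
            raise ValidationError(f"kind {self.kind!r} not in {MAP_KINDS}")
        # zero outside the disk, always
        m = disk_mask(self.grid_size)
        self.values = np.where(m, self.values, 0.0)
        if self.kind == "binary":
            uniq = np.unique(self.values)
            if not np.all(np.isin(uniq, (0.0, 1.0))):
                raise ValidationError("binary map values must be 0 or 1")
        if self.kind == "atlas":
            if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
                raise ValidationError("atlas map values must lie in [0, 1]")

    @property
    def grid_size(self) -> int:
        return self.values.shape[0]

    @property
    def disk(self) -> np.ndarray:
        return disk_mask(self.grid_size)

    @property
    def is_aligned(self) -> bool:
        return self.rotation_applied_deg is not None

    def copy_with(self, values: np.ndarray, **kw) -> "CircularMap":
        args = dict(
            values=values,
            group=self.group,
            animal_id=self.animal_id,
            kind=self.kind,
            rotation_applied_deg=self.rotation_applied_deg,
        )
        args.update(kw)
        return CircularMap(**args)


@dataclass
class ResponseTable:
    """Per-pair percent-change responses of one modality in one condition."""

    nerve_id: str
    animal_id: str
    modality: str
    condition: str
    pct_change: np.ndarray
    stim: StimParams | None = None

    def __post_init__(self):
        self.pct_change = np.asarray(self.pct_change, dtype=float)
        if self.modality not in MODALITIES:
            raise ValidationError(f"modality {self.modality!r} not in {MODALITIES}")
        if self.condition not in CONDITIONS:
            raise ValidationError(f"condition {self.condition!r} not in {CONDITIONS}")
        if self.pct_change.ndim != 1:
            raise ValidationError("pct_change must be a 1-D vector")
        if not np.all(np.isfinite(self.pct_change)):
            raise ValidationError("pct_change values must be finite")

    @property
    def n_pairs(self) -> int:
        return len(self.pct_change)


@dataclass
class CoM:
    """Weighted centre of mass of a circular map, in polar form."""

    group: str
    animal_id: str
    angle_deg: float
    r_norm: float
    weight_total: float


@dataclass
class SeparationResult:
    """Angular separation between two groups' CoMs across animals."""

    group_pair: tuple[str, str]
    per_animal_separation_deg: list[float]
    mean_deg: float
    sd_deg: float
    p_value: float | None = None

    @property
    def n(self) -> int:
        return len(self.per_animal_separation_deg)


@dataclass
class OverlapResult:
    """Area fractions of two regions and their mutual overlap percentages."""

    group_pair: tuple[str, str]
    area_pct_a: float
    area_pct_b: float
    overlap_pct_of_a: float | None
    overlap_pct_of_b: float | None
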