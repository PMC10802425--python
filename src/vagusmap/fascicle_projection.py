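"""Co-registration of traced fascicles onto the cuff-anchored unit disk.

The nerve cross-section is circularised by projecting each fascicle onto
the unit disk so that its radial distance to the nearest electrode pad is
preserved (normalised by the cuff radius) while its own angular coordinate
about the nerve centroid is kept.  Selected fascicles are rasterised as
filled disks into per-group binary maps, which are then rotated so the
cardiac-efferent centre of mass sits at 0° (the top), removing the unknown
per-animal cuff rotation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import (
    AlignmentError,
    CircularMap,
    ElectrodeArray,
    Fascicle,
    NerveSection,
    disk_mask,
    pixel_centers,
    polar_to_xy,
)

log = logging.getLogger(__name__)


@dataclass
class Placement:
    """Normalised polar placement of one fascicle on the unit disk."""

    fascicle_id: str
    theta_deg: float
    r_norm: float
    radius_norm: float
    nearest_pair: int


def nearest_electrode(
    fascicle: Fascicle, nerve: NerveSection, array: ElectrodeArray
) -> tuple[int, float]:
    """Nearest pad pair (1-based index) and its centroid-to-pad distance, mm.

    The nerve is assumed centred in the cuff, with pads on the circle of
    radius ``cuff_inner_diameter/2`` at ``pad_angles_deg``.  Ties break to
    the lowest pair index.
    """
    pads = array.pad_xy_mm()
    d = np.hypot(pads[:, 0] - fascicle.center_x_mm, pads[:, 1] - fascicle.center_y_mm)
    # ties (within floating rounding) break to the lowest pair index
    dmin = d.min()
    k = int(np.nonzero(d <= dmin * (1 + 1e-12) + 1e-12)[0][0])
    return k + 1, float(d[k])


def project_fascicle(
    fascicle: Fascicle, nerve: NerveSection, array: ElectrodeArray
) -> Placement:
    """Project a fascicle onto the unit disk.

    Radial coordinate: ``r_norm = clamp((R_cuff - d_nearest)/R_cuff, 0, 1)``
    so the distance to the nearest electrode is preserved in cuff-radius
    units.  Angular coordinate: the fascicle's own angle about the nerve
    centroid (0° for a fascicle exactly at the centre).
    """
    pair, d = nearest_electrode(fascicle, nerve, array)
    r_cuff = array.radius_mm
    r_norm = float(np.clip((r_cuff - d) / r_cuff, 0.0, 1.0))
    return Placement(
        fascicle_id=fascicle.fascicle_id,
        theta_deg=fascicle.angle_deg,
        r_norm=r_norm,
        radius_norm=fascicle.radius_mm / r_cuff,
        nearest_pair=pair,
    )


def build_group_map(
    nerve: NerveSection,
    array: ElectrodeArray,
    group: str,
    grid_size: int = 256,
    snap_to_pad_angle: bool = False,
) -> CircularMap:
    """Binary presence map of one functional group for one nerve.

    Each fascicle containing fibers of ``group`` is projected and drawn as a
    filled disk of radius ``radius_norm`` at ``(theta_deg, r_norm)``; the map
    is the union.  ``snap_to_pad_angle`` replaces each fascicle's angle with
    its nearest pad's angle (sensitivity-analysis variant).
    """
    selected = nerve.group_fascicles(group)
    values = np.zeros((grid_size, grid_size))
    if not selected:
        log.warning(
            "nerve %s: no fascicles in group %r; emitting an all-zero map",
            nerve.nerve_id,
            group,
        )
    X, Y = pixel_centers(grid_size)
    for f in selected:
        p = project_fascicle(f, nerve, array)
        theta = (
            array.pad_angles_deg[p.nearest_pair - 1] if snap_to_pad_angle else p.theta_deg
        )
        cx, cy = polar_to_xy(theta, p.r_norm)
        values[(X - cx) ** 2 + (Y - cy) ** 2 <= p.radius_norm**2] = 1.0
    values[~disk_mask(grid_size)] = 0.0
    return CircularMap(
        values=values, group=group, animal_id=nerve.animal_id, kind="binary"
    )


def rotate_map(cmap: CircularMap, delta_deg: float, record: bool = True) -> CircularMap:
    """Rotate map content by ``delta_deg`` (clockwise-from-top convention).

    A feature at angle θ moves to θ + δ.  Binary maps are resampled
    nearest-neighbour and re-thresholded; other kinds bilinearly.  The
    applied rotation is accumulated in ``rotation_applied_deg`` when
    ``record`` is set.
    """
    n = cmap.grid_size
    X, Y = pixel_centers(n)
    th = np.deg2rad(delta_deg)
    # sample source at angle θ - δ, same radius
    xs = X * np.cos(th) - Y * np.sin(th)
    ys = X * np.sin(th) + Y * np.cos(th)
    # invert the pixel-centre mapping: col = (x + 1) * n/2 - 0.5, row = (1 - y) * n/2 - 0.5
    cols = (xs + 1.0) * n / 2.0 - 0.5
    rows = (1.0 - ys) * n / 2.0 - 0.5
    order = 0 if cmap.kind == "binary" else 1
    out = ndimage.map_coordinates(
        cmap.values, [rows, cols], order=order, mode="constant", cval=0.0
    )
    if cmap.kind == "binary":
        out = (out > 0.5).astype(float)
    out[~disk_mask(n)] = 0.0
    prev = cmap.rotation_applied_deg
    rot = ((prev or 0.0) + delta_deg) % 360.0 if record else prev
    return cmap.copy_with(out, rotation_applied_deg=rot)


def align_maps(maps: dict[str, CircularMap]) -> dict[str, CircularMap]:
    """Rotate all of one animal's group maps so cardiac-efferent CoM is at 0°.

    The reference angle is the |value|-weighted centre-of-mass angle of the
    (unrotated) cardiac-efferent map; every map is rotated by its negation.
    """
    from .spatial_stats import center_of_mass

    ref = maps.get("cardiac_efferent")
    if ref is None or not np.any(ref.values):
        raise AlignmentError(
            "cannot align: cardiac_efferent map is missing or empty"
        )
    ref_angle = center_of_mass(ref).angle_deg
    return {g: rotate_map(m, -ref_angle) for g, m in maps.items()}
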