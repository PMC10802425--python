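"""Cross-animal atlas maps.

Aligned per-animal maps of one group are averaged pixel-wise.  For binary
fascicle maps the mean is already the fraction of animals with a fascicle
of the group at each location (0 = none, 1 = all animals), so no rescaling
is applied.  For signed response maps the mean of absolute values is
peak-normalised to 1 so bradycardic and tachycardic animals reinforce
rather than cancel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import CircularMap, ValidationError


@dataclass
class AtlasMap:
    """A cross-animal average map with values in [0, 1]."""

    map: CircularMap
    n_animals: int
    source_kind: str

    @property
    def values(self) -> np.ndarray:
        return self.map.values

    @property
    def grid_size(self) -> int:
        return self.map.grid_size

    @property
    def group(self) -> str:
        return self.map.group


def build_atlas(maps: list[CircularMap], source_kind: str) -> AtlasMap:
    """Pixel-wise average of aligned per-animal maps of one group."""
    if not maps:
        raise ValidationError("need at least one map")
    if source_kind not in ("binary", "response"):
        raise ValidationError(f"source_kind {source_kind!r} must be binary or response")
    g0, n0 = maps[0].group, maps[0].grid_size
    for m in maps:
        if m.group != g0:
            raise ValidationError(f"mixed groups: {m.group!r} vs {g0!r}")
        if m.grid_size != n0:
            raise ValidationError(f"mixed grid sizes: {m.grid_size} vs {n0}")
        if not m.is_aligned:
            raise ValidationError(
                f"map (group={m.group!r}, animal={m.animal_id!r}) has no recorded "
                "alignment rotation"
            )
    if source_kind == "binary":
        mean = np.mean([m.values for m in maps], axis=0)
    else:
        mean = np.mean([np.abs(m.values) for m in maps], axis=0)
        peak = mean.max()
        if peak > 0:
            mean = mean / peak
    atlas_map = CircularMap(
        values=mean,
        group=g0,
        animal_id="",
        kind="atlas",
        rotation_applied_deg=0.0,
    )
    return AtlasMap(map=atlas_map, n_animals=len(maps), source_kind=source_kind)


def atlas_support(atlas: AtlasMap, tau: float | None = None) -> np.ndarray:
    """Binary region of atlas pixels strictly above ``tau``.

    Defaults: ``tau=0`` for binary-sourced atlases (union of all animals'
    pixels) and ``tau=0.5`` for response-sourced atlases.
    """
    if tau is None:
        tau = 0.0 if atlas.source_kind == "binary" else 0.5
    if not (0 <= tau < 1):
        raise ValidationError("tau must lie in [0, 1)")
    return atlas.values > tau
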