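"""Per-pair response quantification, sector back-projection and titration.

Physiological trials are reduced to a signed percent change per electrode
pair (mean-based for rate/pressure-like signals, RMS-based for EMG), then
back-projected onto the unit disk by painting each pair's value over its
angular sector.  The selectivity rule of the stimulation protocol — a
response on fewer than half of the 14 pairs — and the amplitude-titration
loop that enforces it are implemented here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .core import (
    AlignmentError,
    CircularMap,
    ElectrodeArray,
    MODALITIES,
    ResponseTable,
    StimParams,
    TitrationError,
    UndefinedBaselineError,
    ValidationError,
    disk_mask,
    pixel_centers,
    signed_angle_diff_deg,
    xy_to_angle_deg,
)
from .fascicle_projection import rotate_map

log = logging.getLogger(__name__)

#: Expected response direction per (modality, condition): -1 responses must
#: be negative, +1 positive, 0 either sign.  Efferent (pre-vagotomy) HR is
#: bradycardic; afferent (post-vagotomy) HR may go either way per animal.
EXPECTED_SIGN: dict[tuple[str, str], int] = {
    ("HR", "pre_vagotomy"): -1,
    ("HR", "post_vagotomy"): 0,
    ("HR", "post_double_vagotomy"): 0,
    ("BR", "pre_vagotomy"): -1,
    ("BR", "post_vagotomy"): -1,
    ("BR", "post_double_vagotomy"): -1,
    ("EtCO2", "pre_vagotomy"): 0,
    ("EtCO2", "post_vagotomy"): 0,
    ("EtCO2", "post_double_vagotomy"): 0,
    ("EMG", "pre_vagotomy"): 1,
    ("EMG", "post_vagotomy"): 1,
    ("EMG", "post_double_vagotomy"): 1,
}


@dataclass
class TrialTrace:
    """One physiological time series with its stimulation schedule.

    ``schedule`` lists (pair_index, on_start_s, on_end_s) per stimulation
    window; the baseline of a window is the ``baseline_window_s`` seconds
    immediately preceding it (the preceding off period).
    """

    modality: str
    sampling_rate_Hz: float
    samples: np.ndarray
    schedule: list[tuple[int, float, float]]
    baseline_window_s: float

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.modality not in MODALITIES:
            raise ValidationError(f"modality {self.modality!r} not in {MODALITIES}")
        if self.sampling_rate_Hz <= 0 or self.baseline_window_s <= 0:
            raise ValidationError("sampling rate and baseline window must be positive")
        t_total = len(self.samples) / self.sampling_rate_Hz
        prev_end = -np.inf
        for pair, t0, t1 in self.schedule:
            if not (0 <= t0 < t1 <= t_total + 1e-9):
                raise ValidationError(
                    f"pair {pair}: window [{t0}, {t1}] outside the trace"
                )
            if t0 < prev_end:
                raise ValidationError("stimulation windows overlap or are unordered")
            prev_end = t1

    def _window(self, t0: float, t1: float) -> np.ndarray:
        i0 = int(round(t0 * self.sampling_rate_Hz))
        i1 = int(round(t1 * self.sampling_rate_Hz))
        return self.samples[max(i0, 0) : i1]


def percent_change(trace: TrialTrace, pair_index: int) -> float:
    """Signed percent change of one pair's on-window vs its baseline.

    HR/BR/EtCO2 use window means; EMG uses window RMS.
    """
    matches = [w for w in trace.schedule if w[0] == pair_index]
    if not matches:
        raise ValidationError(f"pair {pair_index} has no on-window in the schedule")
    _, t0, t1 = matches[0]
    on = trace._window(t0, t1)
    base = trace._window(max(t0 - trace.baseline_window_s, 0.0), t0)
    if len(on) == 0 or len(base) == 0:
        raise ValidationError(f"pair {pair_index}: empty on or baseline window")
    if trace.modality == "EMG":
        stat_on = float(np.sqrt(np.mean(on**2)))
        stat_base = float(np.sqrt(np.mean(base**2)))
    else:
        stat_on = float(np.mean(on))
        stat_base = float(np.mean(base))
    if stat_base == 0.0:
        raise UndefinedBaselineError(
            f"pair {pair_index}: baseline {'RMS' if trace.modality == 'EMG' else 'mean'} is zero"
        )
    return 100.0 * (stat_on - stat_base) / stat_base


def table_from_trace(
    trace: TrialTrace,
    nerve_id: str = "",
    animal_id: str = "",
    condition: str = "pre_vagotomy",
    stim: StimParams | None = None,
) -> ResponseTable:
    """Reduce a scheduled trace to a per-pair response table."""
    pairs = sorted({w[0] for w in trace.schedule})
    if pairs != list(range(1, len(pairs) + 1)):
        raise ValidationError(f"schedule pairs {pairs} are not contiguous from 1")
    pct = np.array([percent_change(trace, p) for p in pairs])
    return ResponseTable(
        nerve_id=nerve_id,
        animal_id=animal_id,
        modality=trace.modality,
        condition=condition,
        pct_change=pct,
        stim=stim,
    )


# ---------------------------------------------------------------------------
# Sector back-projection

def sector_indices(array: ElectrodeArray, grid_size: int) -> np.ndarray:
    """Per-pixel 1-based sector index (0 outside the disk).

    A disk pixel belongs to the sector of its angularly nearest pad; the
    shared boundary between two adjacent sectors goes with the half-open
    interval ``[pad_k - w/2, pad_k + w/2)``.
    """
    X, Y = pixel_centers(grid_size)
    ang = xy_to_angle_deg(X, Y)
    pads = np.asarray(array.pad_angles_deg)
    d = signed_angle_diff_deg(ang[..., None], pads[None, None, :])
    # smallest |d|; on an exact tie the pad with d == -w/2 (pixel at its
    # interval's closed lower edge) wins: penalise positive boundary values
    key = np.abs(d) + np.where(d > 0, 1e-9, 0.0)
    idx = np.argmin(key, axis=-1) + 1
    idx[~disk_mask(grid_size)] = 0
    return idx


def build_sector_map(
    table: ResponseTable, array: ElectrodeArray, grid_size: int = 256
) -> CircularMap:
    """Paint each pair's percent change over its angular sector."""
    if table.n_pairs != array.n_pairs:
        raise ValidationError(
            f"table has {table.n_pairs} pairs, array has {array.n_pairs}"
        )
    idx = sector_indices(array, grid_size)
    values = np.zeros((grid_size, grid_size))
    inside = idx > 0
    values[inside] = table.pct_change[idx[inside] - 1]
    group = _group_for(table.modality, table.condition)
    return CircularMap(
        values=values, group=group, animal_id=table.animal_id, kind="response"
    )


def _group_for(modality: str, condition: str) -> str:
    if modality == "HR":
        return "cardiac_efferent" if condition == "pre_vagotomy" else "cardiac_afferent"
    if modality == "EMG":
        return "laryngeal"
    return "pulmonary"  # BR / EtCO2


def align_response_maps(maps: dict[str, CircularMap]) -> dict[str, CircularMap]:
    """Rotate one animal's response maps so the cardiac-efferent |value|
    CoM sits at 0°."""
    from .spatial_stats import center_of_mass

    ref = maps.get("cardiac_efferent")
    if ref is None or not np.any(ref.values):
        raise AlignmentError(
            "cannot align: cardiac_efferent response map is missing or all zero"
        )
    ref_angle = center_of_mass(ref).angle_deg
    return {g: rotate_map(m, -ref_angle) for g, m in maps.items()}


# ---------------------------------------------------------------------------
# Selectivity and titration

def effective_pairs(table: ResponseTable, threshold_pct: float = 5.0) -> set[int]:
    """Pairs whose response exceeds the threshold in the expected direction."""
    if threshold_pct <= 0:
        raise ValidationError("threshold_pct must be positive")
    sign = EXPECTED_SIGN[(table.modality, table.condition)]
    out = set()
    for i, v in enumerate(table.pct_change, start=1):
        if abs(v) >= threshold_pct and (sign == 0 or np.sign(v) == sign):
            out.add(i)
    return out


def is_selective(
    table: ResponseTable,
    threshold_pct: float = 5.0,
    max_effective: int = 6,
) -> bool:
    """Selectivity rule: responses on fewer than half of the 14 pairs.

    The strict reading (at most 6 of 14) is the default; pass
    ``max_effective=7`` for the inclusive variant.
    """
    return len(effective_pairs(table, threshold_pct)) <= max_effective


def titrate(
    stim_model: Callable[[float], ResponseTable],
    start: StimParams,
    step_fraction: float = 0.25,
    max_iters: int = 100,
    threshold_pct: float = 5.0,
    max_effective: int = 6,
) -> tuple[StimParams, ResponseTable]:
    """Adjust amplitude until the response is selective and non-empty.

    From the starting amplitude: while the response is non-selective the
    amplitude is multiplied by ``1 - step_fraction``; while no pair responds
    it is multiplied by ``1 + step_fraction``.  Stops at the first amplitude
    that is selective with at least one responsive pair.
    """
    if not (0 < step_fraction < 1):
        raise ValidationError("step_fraction must be in (0, 1)")
    amp = start.amplitude_mA
    trajectory: list[tuple[float, int]] = []
    for _ in range(max_iters):
        table = stim_model(amp)
        n_eff = len(effective_pairs(table, threshold_pct))
        trajectory.append((amp, n_eff))
        if 1 <= n_eff <= max_effective:
            return start.with_amplitude(amp), table
        amp = amp * (1 - step_fraction) if n_eff > max_effective else amp * (1 + step_fraction)
    raise TitrationError(
        f"no selective amplitude with >= 1 responsive pair in {max_iters} steps",
        trajectory,
    )
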