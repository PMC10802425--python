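"""End-to-end cohort pipelines.

Two arms mirror the two measurement techniques:

* the **microCT arm** rasterises each nerve's traced fascicles into four
  binary group maps, then aligns them to the cardiac-efferent CoM;
* the **ephys arm** titrates stimulation amplitude per functional target,
  back-projects the titrated 14-pair response profiles onto sector maps,
  and aligns them the same way.

Animals whose cardiac-efferent map is empty (no pure cardiac fascicle, or
no responsive pair) have no alignment reference and are dropped with a log
message.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import GROUPS, AlignmentError, CircularMap, CoM, ElectrodeArray, TitrationError
from .fascicle_projection import align_maps, build_group_map
from .response_mapping import (
    align_response_maps,
    build_sector_map,
    effective_pairs,
    titrate,
)
from .spatial_stats import UndefinedCoMError, center_of_mass, group_separation
from .synthetic_cohort import (
    START_PARAMS,
    Cohort,
    simulate_responses,
)

log = logging.getLogger(__name__)

#: Functional target -> (modality, condition) measured for it.
TARGET_TRIALS: dict[str, tuple[str, str]] = {
    "cardiac_efferent": ("HR", "pre_vagotomy"),
    "cardiac_afferent": ("HR", "post_vagotomy"),
    "pulmonary": ("EtCO2", "pre_vagotomy"),
    "laryngeal": ("EMG", "pre_vagotomy"),
}

AlignedCohortMaps = dict[str, dict[str, CircularMap]]


def microct_arm(
    cohort: Cohort, array: ElectrodeArray, grid_size: int = 256
) -> AlignedCohortMaps:
    """Per-animal aligned binary group maps from the traced fascicles."""
    aligned: AlignedCohortMaps = {}
    for nerve in cohort.nerves:
        maps = {g: build_group_map(nerve, array, g, grid_size) for g in GROUPS}
        try:
            aligned[nerve.animal_id] = align_maps(maps)
        except AlignmentError:
            log.warning(
                "animal %s: no cardiac-efferent fascicle; excluded from the "
                "microCT arm",
                nerve.animal_id,
            )
    return aligned


@dataclass
class EphysArmResult:
    aligned: AlignedCohortMaps
    titrated_amplitude_mA: dict[str, dict[str, float]] = field(default_factory=dict)
    effective_pairs: dict[str, dict[str, set[int]]] = field(default_factory=dict)
    tables: dict[str, dict[str, object]] = field(default_factory=dict)


def ephys_arm(
    cohort: Cohort,
    array: ElectrodeArray,
    grid_size: int = 256,
    threshold_pct: float = 5.0,
) -> EphysArmResult:
    """Titration + back-projection + alignment for every animal."""
    seed_rng = np.random.default_rng((cohort.config.seed + 1) % 2**31)
    result = EphysArmResult(aligned={})
    for nerve in cohort.nerves:
        truth = cohort.truths[nerve.animal_id]
        maps: dict[str, CircularMap] = {}
        amps: dict[str, float] = {}
        effs: dict[str, set[int]] = {}
        tabs: dict[str, object] = {}
        for target, (modality, condition) in TARGET_TRIALS.items():
            start = START_PARAMS[target]
            noise_seed = int(seed_rng.integers(2**31))

            def stim_model(a, _m=modality, _c=condition, _s=start, _ns=noise_seed):
                return simulate_responses(
                    nerve,
                    array,
                    _s.with_amplitude(a),
                    _m,
                    _c,
                    truth,
                    np.random.default_rng(_ns),
                    config=cohort.config,
                )

            try:
                params, table = titrate(
                    stim_model, start, threshold_pct=threshold_pct
                )
            except TitrationError:
                log.warning(
                    "animal %s: titration failed for %s; no %s map",
                    nerve.animal_id,
                    target,
                    target,
                )
                continue
            amps[target] = params.amplitude_mA
            effs[target] = effective_pairs(table, threshold_pct)
            tabs[target] = table
            maps[target] = build_sector_map(table, array, grid_size)
        try:
            result.aligned[nerve.animal_id] = align_response_maps(maps)
        except AlignmentError:
            log.warning(
                "animal %s: cardiac-efferent response map unusable; excluded "
                "from the ephys arm",
                nerve.animal_id,
            )
            continue
        result.titrated_amplitude_mA[nerve.animal_id] = amps
        result.effective_pairs[nerve.animal_id] = effs
        result.tables[nerve.animal_id] = tabs
    return result


def coms_by_group(aligned: AlignedCohortMaps) -> dict[str, list[CoM]]:
    """CoMs of every aligned map, grouped; empty maps are skipped."""
    out: dict[str, list[CoM]] = {g: [] for g in GROUPS}
    for animal, by_group in aligned.items():
        for g, m in by_group.items():
            try:
                out[g].append(center_of_mass(m))
            except UndefinedCoMError:
                log.debug("animal %s: group %s map empty, CoM undefined", animal, g)
    return out


def cardiac_separation(aligned: AlignedCohortMaps):
    """Cardiac afferent-efferent separation across an aligned cohort."""
    coms = coms_by_group(aligned)
    return group_separation(coms["cardiac_afferent"], coms["cardiac_efferent"])
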