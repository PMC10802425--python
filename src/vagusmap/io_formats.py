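"""On-disk formats: fascicle tables, response tables, raster maps, geometry.

All tabular formats are comma-separated UTF-8 text with a mandatory header
row and "." decimals.  Raster maps are written as a CSV numeric grid plus a
JSON sidecar (``<path>.json``) carrying the metadata needed to reconstruct
the :class:`~vagusmap.core.CircularMap`; round-trips are bit-exact.
"""

from __future__ import annotations

import json
import pathlib

import numpy as np
import pandas as pd
import yaml

from .core import (
    CircularMap,
    ElectrodeArray,
    Fascicle,
    FormatError,
    NerveSection,
    ORGAN_LABELS,
    ResponseTable,
    StimParams,
    ValidationError,
)

FASCICLE_COLUMNS = [
    "nerve_id",
    "animal_id",
    "nerve_radius_mm",
    "fascicle_id",
    "x_mm",
    "y_mm",
    "radius_mm",
    "organ_label",
    "fiber_class",
]

RESPONSE_COLUMNS = ["nerve_id", "modality", "pair_index", "pct_change"]
RESPONSE_OPTIONAL = [
    "animal_id",
    "condition",
    "amplitude_mA",
    "pulse_width_us",
    "frequency_Hz",
]


def _read_csv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as e:
        raise FormatError(f"{path}: empty file with no header") from e


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")


# ---------------------------------------------------------------------------
# Fascicle tables

def read_fascicle_table(path) -> list[NerveSection]:
    """Read a fascicle tracing table; one NerveSection per distinct nerve_id."""
    df = _read_csv(path)
    _require_columns(df, FASCICLE_COLUMNS, path)
    bad_organ = df.loc[~df["organ_label"].isin(ORGAN_LABELS), "organ_label"].unique()
    if len(bad_organ):
        raise ValidationError(
            f"{path}: organ_label value(s) outside the vocabulary "
            f"{ORGAN_LABELS}: {', '.join(map(str, bad_organ))}"
        )
    nerves = []
    for nerve_id, rows in df.groupby("nerve_id", sort=False):
        fascicles = [
            Fascicle(
                fascicle_id=str(r.fascicle_id),
                center_x_mm=float(r.x_mm),
                center_y_mm=float(r.y_mm),
                radius_mm=float(r.radius_mm),
                organ_label=str(r.organ_label),
                fiber_class=str(r.fiber_class),
            )
            for r in rows.itertuples()
        ]
        nerves.append(
            NerveSection(
                nerve_id=str(nerve_id),
                animal_id=str(rows["animal_id"].iloc[0]),
                nerve_radius_mm=float(rows["nerve_radius_mm"].iloc[0]),
                fascicles=fascicles,
            )
        )
    return nerves


def write_fascicle_table(nerves: list[NerveSection], path) -> None:
    rows = [
        dict(
            nerve_id=n.nerve_id,
            animal_id=n.animal_id,
            nerve_radius_mm=n.nerve_radius_mm,
            fascicle_id=f.fascicle_id,
            x_mm=f.center_x_mm,
            y_mm=f.center_y_mm,
            radius_mm=f.radius_mm,
            organ_label=f.organ_label,
            fiber_class=f.fiber_class,
        )
        for n in nerves
        for f in n.fascicles
    ]
    pd.DataFrame(rows, columns=FASCICLE_COLUMNS).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Response tables

def read_response_table(path) -> list[ResponseTable]:
    """Read per-pair responses; one table per (nerve_id, modality, condition)."""
    df = _read_csv(path)
    _require_columns(df, RESPONSE_COLUMNS, path)
    if "condition" not in df.columns:
        df = df.assign(condition="pre_vagotomy")
    if "animal_id" not in df.columns:
        df = df.assign(animal_id="")
    tables = []
    for (nerve_id, modality, condition), rows in df.groupby(
        ["nerve_id", "modality", "condition"], sort=False
    ):
        idx = rows["pair_index"].astype(int).to_numpy()
        dupes = sorted({int(i) for i in idx if (idx == i).sum() > 1})
        if dupes:
            raise FormatError(
                f"{path}: duplicate pair_index {dupes} for "
                f"({nerve_id}, {modality}, {condition})"
            )
        expected = set(range(1, len(idx) + 1))
        missing = sorted(expected - set(idx.tolist()))
        if missing:
            raise FormatError(
                f"{path}: missing pair_index {missing} for "
                f"({nerve_id}, {modality}, {condition})"
            )
        order = np.argsort(idx)
        pct = rows["pct_change"].to_numpy(dtype=float)[order]
        stim = None
        if {"amplitude_mA", "pulse_width_us", "frequency_Hz"} <= set(df.columns):
            r0 = rows.iloc[0]
            stim = StimParams(
                amplitude_mA=float(r0["amplitude_mA"]),
                pulse_width_us=float(r0["pulse_width_us"]),
                frequency_Hz=float(r0["frequency_Hz"]),
            )
        tables.append(
            ResponseTable(
                nerve_id=str(nerve_id),
                animal_id=str(rows["animal_id"].iloc[0]),
                modality=str(modality),
                condition=str(condition),
                pct_change=pct,
                stim=stim,
            )
        )
    return tables


def write_response_tables(tables: list[ResponseTable], path) -> None:
    rows = []
    for t in tables:
        for i, v in enumerate(t.pct_change, start=1):
            row = dict(
                nerve_id=t.nerve_id,
                animal_id=t.animal_id,
                modality=t.modality,
                condition=t.condition,
                pair_index=i,
                pct_change=v,
            )
            if t.stim is not None:
                row.update(
                    amplitude_mA=t.stim.amplitude_mA,
                    pulse_width_us=t.stim.pulse_width_us,
                    frequency_Hz=t.stim.frequency_Hz,
                )
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Raster maps

def _sidecar_path(path) -> pathlib.Path:
    return pathlib.Path(str(path) + ".json")


def write_map(cmap: CircularMap, path) -> None:
    """Write the grid as CSV (full precision) plus a JSON metadata sidecar."""
    path = pathlib.Path(path)
    np.savetxt(path, cmap.values, delimiter=",", fmt="%.17g")
    meta = dict(
        grid_size=cmap.grid_size,
        group=cmap.group,
        animal_id=cmap.animal_id,
        rotation_applied_deg=cmap.rotation_applied_deg,
        kind=cmap.kind,
    )
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))


def read_map(path) -> CircularMap:
    path = pathlib.Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"{path}: sidecar {sidecar.name} not found")
    meta = json.loads(sidecar.read_text())
    values = np.loadtxt(path, delimiter=",", ndmin=2)
    if values.shape != (meta["grid_size"], meta["grid_size"]):
        raise FormatError(
            f"{path}: grid shape {values.shape} does not match sidecar "
            f"grid_size {meta['grid_size']}"
        )
    return CircularMap(
        values=values,
        group=meta["group"],
        animal_id=meta["animal_id"],
        kind=meta["kind"],
        rotation_applied_deg=meta["rotation_applied_deg"],
    )


# ---------------------------------------------------------------------------
# Electrode geometry and configuration

def read_electrode_array(path) -> ElectrodeArray:
    """Read a cuff geometry descriptor (JSON or YAML mapping)."""
    text = pathlib.Path(path).read_text()
    try:
        data = yaml.safe_load(text)  # YAML is a superset of JSON
    except yaml.YAMLError as e:
        raise FormatError(f"{path}: not parseable as JSON/YAML: {e}") from e
    if not isinstance(data, dict):
        raise FormatError(f"{path}: expected a mapping of geometry fields")
    known = {
        "n_pairs",
        "pad_angles_deg",
        "cuff_inner_diameter_mm",
        "pad_length_mm",
        "pad_width_mm",
    }
    unknown = set(data) - known
    if unknown:
        raise FormatError(f"{path}: unknown field(s): {', '.join(sorted(unknown))}")
    if "pad_angles_deg" in data:
        data["pad_angles_deg"] = tuple(data["pad_angles_deg"])
    return ElectrodeArray(**data)


def write_electrode_array(array: ElectrodeArray, path) -> None:
    data = dict(
        n_pairs=array.n_pairs,
        pad_angles_deg=list(array.pad_angles_deg),
        cuff_inner_diameter_mm=array.cuff_inner_diameter_mm,
        pad_length_mm=array.pad_length_mm,
        pad_width_mm=array.pad_width_mm,
    )
    pathlib.Path(path).write_text(json.dumps(data, indent=2))


def read_config(path):
    """Read a synthetic-cohort config (YAML/JSON mapping)."""
    from .synthetic_cohort import SyntheticConfig

    data = yaml.safe_load(pathlib.Path(path).read_text())
    if not isinstance(data, dict):
        raise FormatError(f"{path}: expected a mapping of config fields")
    return SyntheticConfig.from_dict(data)
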