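"""Measurement data model and CSV round-tripping.

A measurement table is a long-format :class:`pandas.DataFrame` with one row
per reading:

====================  =======================================================
column                meaning
====================  =======================================================
``participant_id``    opaque subject identifier (string)
``round``             measurement-round label, e.g. ``R1`` / ``R2``
``device``            ``test`` (instrument under evaluation) or ``reference``
``replicate``         1-based replicate index within (participant, round,
                      device)
``temperature_c``     reading in degrees Celsius
``group``             optional participant attribute (e.g. skin-colour
                      category) used by the group-comparison statistics
====================  =======================================================

The paired table derived from it has one row per (participant, round,
replicate) shared by both devices, with ``diff = t_test - t_ref``.  The sign
convention is fixed: a negative difference means the test instrument reads
low relative to the reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("participant_id", "round", "device", "replicate", "temperature_c")
DEVICE_TEST = "test"
DEVICE_REFERENCE = "reference"


class SchemaError(ValueError):
    """A required column is missing or mislabelled."""


class MeasurementDataError(ValueError):
    """Row-level problem: unparsable value, duplicate key, unpaired cell."""


@dataclass(frozen=True)
class MeasurementSchema:
    """Column-name and device-label mapping for reading foreign CSV layouts.

    ``columns`` maps canonical names (the keys of :data:`REQUIRED_COLUMNS`)
    to the names used in the file; ``device_labels`` maps the file's device
    labels onto ``test`` / ``reference``.
    """

    columns: dict[str, str] = field(default_factory=dict)
    device_labels: dict[str, str] = field(default_factory=dict)

    def column(self, canonical: str) -> str:
        return self.columns.get(canonical, canonical)


def read_measurements(path, schema: MeasurementSchema | None = None) -> pd.DataFrame:
    """Read a long-format measurement CSV into a canonical table.

    Raises :class:`SchemaError` naming the first missing column and
    :class:`MeasurementDataError` (with 1-based data line numbers) for
    temperatures that do not parse as finite numbers.
    """
    schema = schema or MeasurementSchema()
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    for canonical in REQUIRED_COLUMNS:
        col = schema.column(canonical)
        if col not in raw.columns:
            raise SchemaError(f"missing required column {col!r} (for {canonical!r})")
    table = pd.DataFrame(
        {canonical: raw[schema.column(canonical)] for canonical in REQUIRED_COLUMNS}
    )
    if "group" in raw.columns or schema.column("group") in raw.columns:
        gcol = schema.column("group") if schema.column("group") in raw.columns else "group"
        table["group"] = raw[gcol]

    temps = pd.to_numeric(table["temperature_c"], errors="coerce")
    bad = ~np.isfinite(temps.to_numpy(dtype=float))
    if bad.any():
        lines = (np.flatnonzero(bad) + 2).tolist()  # +2: header + 1-based
        raise MeasurementDataError(f"unparsable temperature on file line(s) {lines}")
    table["temperature_c"] = temps.astype(float)
    table["replicate"] = pd.to_numeric(table["replicate"], errors="raise").astype(int)
    if (table["replicate"] < 1).any():
        raise MeasurementDataError("replicate indices must be >= 1")
    if schema.device_labels:
        table["device"] = table["device"].map(lambda d: schema.device_labels.get(d, d))
    unknown = set(table["device"]) - {DEVICE_TEST, DEVICE_REFERENCE}
    if unknown:
        raise MeasurementDataError(
            f"unknown device label(s) {sorted(unknown)}; expected "
            f"{DEVICE_TEST!r}/{DEVICE_REFERENCE!r} or a schema device_labels map"
        )
    return table.reset_index(drop=True)


def write_measurements(table: pd.DataFrame, path) -> None:
    """Write a canonical measurement table as CSV (UTF-8, header row)."""
    cols = [c for c in (*REQUIRED_COLUMNS, "group") if c in table.columns]
    table.loc[:, cols].to_csv(path, index=False)


def validate(table: pd.DataFrame) -> list[str]:
    """Return a list of invariant violations (empty when the table is clean).

    Checks key uniqueness, finite temperatures, positive replicate indices
    and equal replicate counts across every (participant, round, device)
    cell.  Never mutates or raises on dirty data.
    """
    issues: list[str] = []
    for canonical in REQUIRED_COLUMNS:
        if canonical not in table.columns:
            issues.append(f"missing column {canonical!r}")
    if issues:
        return issues
    key = ["participant_id", "round", "device", "replicate"]
    dup = table.duplicated(subset=key)
    if dup.any():
        offenders = table.loc[dup, key].to_records(index=False).tolist()
        issues.append(f"duplicate (participant, round, device, replicate) keys: {offenders[:5]}")
    temps = table["temperature_c"].to_numpy(dtype=float)
    if not np.isfinite(temps).all():
        issues.append("non-finite temperature values present")
    if (table["replicate"] < 1).any():
        issues.append("replicate index < 1 present")
    counts = table.groupby(["participant_id", "round", "device"], sort=False).size()
    if counts.nunique() > 1:
        issues.append(
            "unequal replicate counts across (participant, round, device) cells: "
            f"{sorted(counts.unique().tolist())}"
        )
    return issues


def pair_replicates(table: pd.DataFrame) -> pd.DataFrame:
    """Match test and reference replicates within each (participant, round).

    The two instruments measure sequentially, so replicate ``i`` of one
    device is paired with replicate ``i`` of the other.  Returns a frame
    with columns ``participant_id, round, replicate, t_test, t_ref, diff``
    where ``diff = t_test - t_ref`` exactly.

    Raises :class:`MeasurementDataError` listing every (participant, round)
    cell that lacks one of the devices.
    """
    devices_per_cell = table.groupby(["participant_id", "round"], sort=False)["device"].agg(set)
    incomplete = devices_per_cell[
        devices_per_cell.map(lambda s: not {DEVICE_TEST, DEVICE_REFERENCE} <= s)
    ]
    if len(incomplete):
        raise MeasurementDataError(
            f"cells missing a device: {incomplete.index.tolist()}"
        )
    wide = table.pivot_table(
        index=["participant_id", "round", "replicate"],
        columns="device",
        values="temperature_c",
        aggfunc="first",
        sort=False,
    ).reset_index()
    wide = wide.dropna(subset=[DEVICE_TEST, DEVICE_REFERENCE])
    paired = wide.rename(columns={DEVICE_TEST: "t_test", DEVICE_REFERENCE: "t_ref"})
    paired.columns.name = None
    paired["diff"] = paired["t_test"] - paired["t_ref"]
    if "group" in table.columns:
        groups = table.drop_duplicates("participant_id").set_index("participant_id")["group"]
        paired["group"] = paired["participant_id"].map(groups)
    return paired.reset_index(drop=True)
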