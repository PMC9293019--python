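"""Readers/writers for kinetic-trace CSV, landscape YAML and selectivity reports."""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .landscape import (
    CONFORMERS,
    CYCLES,
    FreeEnergyLandscape,
    LandscapeError,
    REACTION_TYPES,
    ROLES,
    StationaryPoint,
    StereoLabel,
)
from .microkinetics import SelectivityResult, Trajectory
from .nmr import KineticTrace, TraceDataError

TIME_COLUMN = "time_s"
DEFAULT_REFERENCE = "TFA"


class ParseError(ValueError):
    """A file failed validation; the message names the offending location."""


def read_trace_csv(
    path,
    signals: Optional[list] = None,
    reference: str = DEFAULT_REFERENCE,
) -> KineticTrace:
    """Load a kinetic trace from a tidy CSV (time_s, signal columns, reference).

    If ``signals`` is omitted, every column other than time and reference is
    treated as a signal. Malformed cells and ordering problems are reported
    with 1-based data row numbers.
    """
    df = pd.read_csv(path)
    if TIME_COLUMN not in df.columns:
        raise ParseError(f"{path}: missing required column {TIME_COLUMN!r}")
    if reference not in df.columns:
        raise ParseError(f"{path}: missing reference column {reference!r}")
    if signals is None:
        signals = [c for c in df.columns if c not in (TIME_COLUMN, reference)]
    missing = [s for s in signals if s not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing signal columns {missing}")
    if not signals:
        raise ParseError(f"{path}: no signal columns found")

    for col in [TIME_COLUMN, *signals, reference]:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.index[numeric.isna()]
        if len(bad):
            raise ParseError(f"{path}: non-numeric value in column {col!r}, row {bad[0] + 1}")
        df[col] = numeric

    times = df[TIME_COLUMN].to_numpy()
    steps = np.diff(times)
    if np.any(steps <= 0):
        row = int(np.flatnonzero(steps <= 0)[0]) + 2
        raise ParseError(f"{path}: time not strictly increasing at row {row}")
    for col in [*signals, reference]:
        vals = df[col].to_numpy()
        if np.any(vals <= 0):
            row = int(np.flatnonzero(vals <= 0)[0]) + 1
            raise ParseError(f"{path}: non-positive integral in column {col!r}, row {row}")

    try:
        return KineticTrace(
            times=times,
            signals={s: df[s].to_numpy() for s in signals},
            reference=df[reference].to_numpy(),
        )
    except TraceDataError as exc:  # defensive: trace-level validation
        raise ParseError(f"{path}: {exc}") from exc


def write_trace_csv(trace: KineticTrace, path, reference: str = DEFAULT_REFERENCE) -> None:
    """Write a trace in the same tidy layout :func:`read_trace_csv` expects."""
    df = pd.DataFrame({TIME_COLUMN: trace.times})
    for name, col in trace.signals.items():
        df[name] = col
    df[reference] = trace.reference
    df.to_csv(path, index=False)


def _stereo_from_mapping(m: dict, name: str) -> Optional[StereoLabel]:
    fp = m.get("face_pair")
    pc = m.get("product_config")
    if fp is None and pc is None:
        return None
    if fp is None or pc is None:
        raise ParseError(
            f"point {name!r}: face_pair and product_config must be given together"
        )
    return StereoLabel(face_pair=fp, product_config=pc, topology=m.get("topology"))


def read_landscape(path) -> FreeEnergyLandscape:
    """Load a free-energy landscape from a nested key-value (YAML) document."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ParseError(f"{path}: expected a mapping at top level")
    rt = doc.get("reaction_type")
    if rt not in REACTION_TYPES:
        raise ParseError(f"{path}: reaction_type must be one of {REACTION_TYPES}, got {rt!r}")
    temperature = float(doc.get("temperature", 298.15))
    raw_points = doc.get("points")
    if not isinstance(raw_points, list) or not raw_points:
        raise ParseError(f"{path}: 'points' must be a non-empty list")

    points = []
    for i, m in enumerate(raw_points):
        name = m.get("name", f"<point {i}>")
        for fld in ("name", "role", "g_rel"):
            if fld not in m:
                raise ParseError(f"{path}: point {name!r} missing field {fld!r}")
        role = m["role"]
        if role not in ROLES:
            raise ParseError(f"{path}: point {name!r}: role must be one of {ROLES}, got {role!r}")
        cycle = m.get("cycle", "A")
        if cycle not in CYCLES:
            raise ParseError(f"{path}: point {name!r}: cycle must be one of {CYCLES}, got {cycle!r}")
        conformer = m.get("conformer", "n/a")
        if conformer not in CONFORMERS:
            raise ParseError(
                f"{path}: point {name!r}: conformer must be one of {CONFORMERS}, got {conformer!r}"
            )
        try:
            points.append(StationaryPoint(
                name=m["name"], role=role, g_rel=float(m["g_rel"]),
                cycle=cycle, conformer=conformer,
                stereo=_stereo_from_mapping(m, name),
            ))
        except LandscapeError as exc:
            raise ParseError(f"{path}: {exc}") from exc

    try:
        return FreeEnergyLandscape(rt, points, temperature)
    except LandscapeError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_landscape(landscape: FreeEnergyLandscape, path) -> None:
    """Serialize a landscape to YAML; round-trips through :func:`read_landscape`."""
    points = []
    for p in landscape.points:
        m = {
            "name": p.name,
            "role": p.role,
            "cycle": p.cycle,
            "conformer": p.conformer,
            "g_rel": float(p.g_rel),
        }
        if p.stereo is not None:
            m["face_pair"] = p.stereo.face_pair
            m["product_config"] = p.stereo.product_config
            if p.stereo.topology is not None:
                m["topology"] = p.stereo.topology
        points.append(m)
    doc = {
        "reaction_type": landscape.reaction_type,
        "temperature": float(landscape.temperature),
        "points": points,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def write_trajectory_csv(traj: Trajectory, path) -> None:
    """Tidy long-format trajectory: time_s, species, conc_M."""
    n_t = traj.times.size
    frames = pd.DataFrame({
        "time_s": np.tile(traj.times, len(traj.species_names)),
        "species": np.repeat(traj.species_names, n_t),
        "conc_M": traj.concentrations.ravel(),
    })
    frames.to_csv(path, index=False)


def _ratio(a: float, b: float, table_style: bool) -> str:
    if table_style:
        return f"{round(a):d} : {round(b):d}"
    return f"{a:.1f} : {b:.1f}"


def report_selectivity(result: SelectivityResult, style: str = "default") -> str:
    """Human-readable selectivity report.

    ``style='table'`` rounds ratios to integers (the convention of printed
    tables); the default keeps one decimal.
    """
    table = style == "table"
    major = result.major_class
    minor = "syn" if major == "anti" else "anti"
    lines = [
        f"reaction_type: {result.reaction_type}",
        f"{major}:{minor} {_ratio(result.dr[major], result.dr[minor], table)}, "
        f"ee {result.ee:+.1f}%",
        f"A : B = {_ratio(result.cycle_partition.get('A', 0.0), result.cycle_partition.get('B', 0.0), table)}",
        f"conversion: {100.0 * result.conversion:.1f}%",
        "channel yields (M):",
    ]
    for (cycle, config, faces), y in sorted(result.channel_yields.items()):
        lines.append(f"  cycle {cycle}  ({faces})  {config}: {y:.4e}")
    return "\n".join(lines)


def selectivity_record(result: SelectivityResult) -> dict:
    """Flat machine-readable form of a selectivity result."""
    major = result.major_class
    minor = "syn" if major == "anti" else "anti"
    rec = {
        "reaction_type": result.reaction_type,
        f"dr_{major}_pct": result.dr[major],
        f"dr_{minor}_pct": result.dr[minor],
        "ee_pct": result.ee,
        "cycle_A_pct": result.cycle_partition.get("A", 0.0),
        "cycle_B_pct": result.cycle_partition.get("B", 0.0),
        "conversion_pct": 100.0 * result.conversion,
    }
    return rec


def write_selectivity_csv(result: SelectivityResult, path) -> None:
    rec = selectivity_record(result)
    pd.DataFrame([rec]).to_csv(path, index=False)
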