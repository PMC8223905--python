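"""Trial, TRC and results I/O.

Native interchange format: a trial is a directory holding
``markers.tsv``, ``standing.tsv``, ``forces.tsv`` and ``meta.yaml``.
The marker files are a self-describing tab-separated dialect::

    # proswing-markers 1
    # rate 120
    # units m
    # labels L_HJC L_KNE ...
    time <tab> x y z per marker ...

Gap samples are empty fields, surfaced as flags on read and never
silently interpolated.  Any declared unit among m/mm/cm is normalized
to meters on read.  Floats are written with 17 significant digits so
that write-then-read is bit-exact.  The TRC marker format is supported
as a convenience reader/writer for interoperability with capture
software.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import (
    DampingCondition,
    FEATURE_COLUMNS,
    ForceChannel,
    MarkerTrajectorySet,
    TrialBundle,
    required_labels,
)
from .errors import FormatError, MissingMarkerError, UnitError

_UNIT_SCALE = {"m": 1.0, "mm": 0.001, "cm": 0.01}
_FLOAT_FMT = "%.17g"


def _unit_scale(unit: str) -> float:
    try:
        return _UNIT_SCALE[unit.lower()]
    except KeyError:
        raise UnitError(f"unknown length unit {unit!r} "
                        f"(expected one of {sorted(_UNIT_SCALE)})") from None


# ---------------------------------------------------------------------------
# native marker TSV
# ---------------------------------------------------------------------------

def write_markers_tsv(mset: MarkerTrajectorySet, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# proswing-markers 1\n")
        fh.write(f"# rate {_FLOAT_FMT % mset.rate}\n")
        fh.write("# units m\n")
        fh.write("# labels " + "\t".join(mset.labels) + "\n")
        for i in range(mset.n_frames):
            cells = [_FLOAT_FMT % (i / mset.rate)]
            for j in range(len(mset.labels)):
                if mset.gaps[i, j]:
                    cells.extend(["", "", ""])
                else:
                    cells.extend(_FLOAT_FMT % v for v in mset.positions[i, j])
            fh.write("\t".join(cells) + "\n")


def read_markers_tsv(path) -> MarkerTrajectorySet:
    path = Path(path)
    lines = path.read_text().splitlines()
    header: dict[str, str] = {}
    body_start = 0
    for k, line in enumerate(lines):
        if not line.startswith("#"):
            body_start = k
            break
        parts = line[1:].strip().split(None, 1)
        if parts:
            header[parts[0]] = parts[1] if len(parts) > 1 else ""
    else:
        body_start = len(lines)
    if header.get("proswing-markers") != "1":
        raise FormatError(f"{path}: not a proswing marker file")
    try:
        rate = float(header["rate"])
        labels = header["labels"].split("\t")
        scale = _unit_scale(header["units"])
    except KeyError as exc:
        raise FormatError(f"{path}: missing header field {exc}") from None
    n_cols = 1 + 3 * len(labels)
    rows = []
    for line in lines[body_start:]:
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != n_cols:
            raise FormatError(
                f"{path}: row has {len(cells)} columns, header declares "
                f"{n_cols}")
        rows.append([float(c) if c != "" else np.nan for c in cells[1:]])
    pos = np.asarray(rows, dtype=float).reshape(len(rows), len(labels), 3)
    return MarkerTrajectorySet(rate, labels, pos * scale)


# ---------------------------------------------------------------------------
# trial bundle
# ---------------------------------------------------------------------------

def write_trial(bundle: TrialBundle, path) -> None:
    """Write a trial bundle to a directory (created if absent)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    write_markers_tsv(bundle.trial, path / "markers.tsv")
    write_markers_tsv(bundle.standing, path / "standing.tsv")
    sides = sorted(bundle.forces)
    rates = {bundle.forces[s].rate for s in sides}
    if len(rates) != 1:
        raise FormatError("force channels must share one rate")
    with (path / "forces.tsv").open("w") as fh:
        fh.write("# proswing-forces 1\n")
        fh.write(f"# rate {_FLOAT_FMT % rates.pop()}\n")
        fh.write("# sides " + "\t".join(sides) + "\n")
        n = max(bundle.forces[s].fz.size for s in sides)
        rate = bundle.forces[sides[0]].rate
        for i in range(n):
            cells = [_FLOAT_FMT % (i / rate)]
            for s in sides:
                fz = bundle.forces[s].fz
                cells.append(_FLOAT_FMT % fz[i] if i < fz.size else "")
            fh.write("\t".join(cells) + "\n")
    meta = {
        "format": "proswing-trial",
        "version": 1,
        "units": "m",
        "foot_length_m": float(bundle.foot_length),
        "marker_radius_m": float(bundle.marker_radius),
        "prosthetic_side": bundle.prosthetic_side,
        "condition": {
            "label": bundle.condition.label,
            "coefficient": float(bundle.condition.coefficient),
            "friction_torque": float(bundle.condition.friction_torque),
        },
    }
    (path / "meta.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))


def read_trial(path) -> TrialBundle:
    """Read a trial bundle directory written by :func:`write_trial`."""
    path = Path(path)
    meta_path = path / "meta.yaml"
    if not meta_path.exists():
        raise FormatError(f"{path}: no meta.yaml; not a trial bundle")
    meta = yaml.safe_load(meta_path.read_text())
    if meta.get("format") != "proswing-trial":
        raise FormatError(f"{path}: unrecognized bundle format")
    _unit_scale(meta.get("units", "m"))  # validates the declared unit
    trial = read_markers_tsv(path / "markers.tsv")
    standing = read_markers_tsv(path / "standing.tsv")
    for label in required_labels():
        for mset, name in ((trial, "markers.tsv"), (standing, "standing.tsv")):
            if not mset.has(label):
                raise MissingMarkerError(f"{path}/{name}: missing marker "
                                         f"{label!r}")
    lines = (path / "forces.tsv").read_text().splitlines()
    header: dict[str, str] = {}
    body = []
    for line in lines:
        if line.startswith("#"):
            parts = line[1:].strip().split(None, 1)
            if parts:
                header[parts[0]] = parts[1] if len(parts) > 1 else ""
        elif line.strip():
            body.append(line.split("\t"))
    if header.get("proswing-forces") != "1":
        raise FormatError(f"{path}/forces.tsv: bad header")
    rate = float(header["rate"])
    sides = header["sides"].split("\t")
    forces = {}
    for k, side in enumerate(sides):
        col = [row[1 + k] for row in body if len(row) > 1 + k
               and row[1 + k] != ""]
        forces[side] = ForceChannel(rate=rate, side=side,
                                    fz=np.array([float(v) for v in col]))
    cond = meta.get("condition", {})
    return TrialBundle(
        trial=trial,
        forces=forces,
        standing=standing,
        foot_length=float(meta["foot_length_m"]),
        marker_radius=float(meta["marker_radius_m"]),
        prosthetic_side=meta["prosthetic_side"],
        condition=DampingCondition(
            label=cond.get("label", "A"),
            coefficient=float(cond.get("coefficient", 0.0)),
            friction_torque=float(cond.get("friction_torque", 0.0)),
        ),
    )


# ---------------------------------------------------------------------------
# TRC
# ---------------------------------------------------------------------------

def write_trc(mset: MarkerTrajectorySet, path, units: str = "mm") -> None:
    """Write a marker set in the TRC capture interchange format."""
    path = Path(path)
    scale = 1.0 / _unit_scale(units)
    n, m = mset.n_frames, len(mset.labels)
    with path.open("w") as fh:
        fh.write(f"PathFileType\t4\t(X/Y/Z)\t{path.name}\n")
        fh.write("DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\t"
                 "OrigDataRate\tOrigDataStartFrame\tOrigNumFrames\n")
        fh.write(f"{mset.rate:g}\t{mset.rate:g}\t{n}\t{m}\t{units}\t"
                 f"{mset.rate:g}\t1\t{n}\n")
        fh.write("Frame#\tTime\t" + "\t\t\t".join(mset.labels) + "\t\t\n")
        fh.write("\t\t" + "\t".join(
            f"X{j + 1}\tY{j + 1}\tZ{j + 1}" for j in range(m)) + "\n")
        for i in range(n):
            cells = [str(i + 1), _FLOAT_FMT % (i / mset.rate)]
            for j in range(m):
                if mset.gaps[i, j]:
                    cells.extend(["", "", ""])
                else:
                    cells.extend(_FLOAT_FMT % (v * scale)
                                 for v in mset.positions[i, j])
            fh.write("\t".join(cells) + "\n")


def read_trc(path) -> MarkerTrajectorySet:
    """Read a TRC marker file; coordinates are returned in meters."""
    lines = Path(path).read_text().splitlines()
    if len(lines) < 5:
        raise FormatError(f"{path}: truncated TRC header")
    keys = lines[1].split("\t")
    vals = lines[2].split("\t")
    header = dict(zip(keys, vals))
    try:
        rate = float(header["DataRate"])
        n_markers = int(header["NumMarkers"])
        scale = _unit_scale(header["Units"])
    except KeyError as exc:
        raise FormatError(f"{path}: TRC header missing {exc}") from None
    labels = [c for c in lines[3].split("\t")[2:] if c.strip()]
    if len(labels) != n_markers:
        raise FormatError(f"{path}: header declares {n_markers} markers, "
                          f"label row has {len(labels)}")
    n_cols = 2 + 3 * n_markers
    rows = []
    for line in lines[5:]:
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) < n_cols:
            cells += [""] * (n_cols - len(cells))
        if len(cells) > n_cols and any(c.strip() for c in cells[n_cols:]):
            raise FormatError(f"{path}: data row wider than header")
        rows.append([float(c) if c.strip() != "" else np.nan
                     for c in cells[2:n_cols]])
    pos = np.asarray(rows, dtype=float).reshape(len(rows), n_markers, 3)
    return MarkerTrajectorySet(rate, labels, pos * scale)


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

def write_features(features, path) -> None:
    """Per-stride feature table as TSV (fixed column order, 9 sig digits)."""
    if hasattr(features, "as_row"):
        features = [features]
    if not isinstance(features, pd.DataFrame):
        rows = [f.as_row() if hasattr(f, "as_row") else f for f in features]
        features = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    if features.empty:
        raise FormatError("refusing to write an empty feature table")
    features.to_csv(path, sep="\t", index=False, float_format="%.9g")


def read_features(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_trends(report_df: pd.DataFrame, path) -> None:
    """Trend/R^2 or direction-check table as TSV."""
    if report_df.empty:
        raise FormatError("refusing to write an empty trend table")
    report_df.to_csv(path, sep="\t", index=False, float_format="%.9g")
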