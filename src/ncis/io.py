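"""Delimited-text readers/writers for sweeps, growth curves and experiments.

All formats are plain text: data rows in comma- or tab-separated columns
under a header line, metadata in ``# key = value`` comment lines above it.
An experiment is a directory of per-channel curve files plus a
``manifest.txt`` of flat ``key = value`` lines.  Parse errors always carry
the file path and 1-based line number.
"""

from __future__ import annotations

import io as _io
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .circuit import SWEEP_COLUMNS, ImpedanceSweep
from .errors import InvalidInputError, ParseError
from .growth import GrowthCurve
from .pipeline import GrowthExperiment

CURVE_COLUMNS = ("time_h", "value")

_FLOAT_FMT = "%.17g"


def _parse_text_table(path) -> tuple[dict, pd.DataFrame, list[int]]:
    """Split a file into '#'-metadata, a header+data table and line numbers."""
    path = Path(path)
    meta: dict = {}
    header = None
    rows: list[str] = []
    line_nos: list[int] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    meta[key.strip()] = val.strip()
                continue
            if header is None:
                header = (line, lineno)
            else:
                rows.append(line)
                line_nos.append(lineno)
    if header is None:
        raise ParseError(path, 1, "no header line found (comment-only or empty file)")
    sep = "\t" if "\t" in header[0] else ","
    cols = [c.strip() for c in header[0].split(sep)]
    table = pd.read_csv(_io.StringIO("\n".join(rows)), sep=sep, header=None,
                        names=cols, dtype=str, skipinitialspace=True) \
        if rows else pd.DataFrame(columns=cols)
    return meta, table, line_nos


def _numeric(path, table: pd.DataFrame, line_nos, columns) -> pd.DataFrame:
    for col in columns:
        if col not in table.columns:
            raise ParseError(path, 1, f"missing required column {col!r}")
    out = {}
    for col in columns:
        vals = pd.to_numeric(table[col], errors="coerce")
        bad = np.nonzero(vals.isna().to_numpy() & table[col].notna().to_numpy())[0]
        if table[col].isna().any():
            bad = np.union1d(bad, np.nonzero(table[col].isna().to_numpy())[0])
        if len(bad):
            raise ParseError(path, line_nos[bad[0]],
                             f"non-numeric value in column {col!r}: "
                             f"{table[col].iloc[bad[0]]!r}")
        out[col] = vals.to_numpy(dtype=float)
    return pd.DataFrame(out)


def _write_table(path, meta: dict, frame: pd.DataFrame) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, val in meta.items():
            fh.write(f"# {key} = {val}\n")
        frame.to_csv(fh, index=False, float_format=_FLOAT_FMT)


# -- sweeps -----------------------------------------------------------------

def write_sweep(sweep: ImpedanceSweep, path) -> None:
    meta = {"baseline_label": sweep.baseline_label}
    meta.update(sweep.metadata)
    _write_table(path, meta, sweep.data[list(SWEEP_COLUMNS)])


def read_sweep(path) -> ImpedanceSweep:
    meta, table, line_nos = _parse_text_table(path)
    if table.empty:
        raise ParseError(path, 1, "sweep file contains no data rows")
    data = _numeric(path, table, line_nos, SWEEP_COLUMNS)
    dup = data.duplicated(["freq_hz", "kappa_s_per_m"])
    if dup.any():
        raise ParseError(path, line_nos[int(np.nonzero(dup.to_numpy())[0][0])],
                         "duplicate (freq, kappa) pair")
    baseline = meta.pop("baseline_label", "unknown")
    for key in ("eps_r", "kappa_b"):
        if key in meta:
            meta[key] = float(meta[key])
    try:
        return ImpedanceSweep(data=data, baseline_label=baseline, metadata=meta)
    except InvalidInputError as exc:
        raise ParseError(path, 1, str(exc)) from exc


# -- growth curves ----------------------------------------------------------

def write_curve(curve: GrowthCurve, path) -> None:
    meta = {"channel": curve.channel, "kind": curve.kind,
            "invert": int(curve.invert)}
    frame = pd.DataFrame({"time_h": curve.times, "value": curve.values})
    _write_table(path, meta, frame)


def read_curve(path) -> GrowthCurve:
    meta, table, line_nos = _parse_text_table(path)
    if table.empty:
        raise ParseError(path, 1, "curve file contains no data rows")
    data = _numeric(path, table, line_nos, CURVE_COLUMNS)
    try:
        return GrowthCurve(
            data["time_h"].to_numpy(), data["value"].to_numpy(),
            channel=meta.get("channel", Path(path).stem),
            kind=meta.get("kind", "ncis"),
            invert=bool(int(meta.get("invert", 0))),
        )
    except InvalidInputError as exc:
        raise ParseError(path, 1, str(exc)) from exc


# -- experiments ------------------------------------------------------------

MANIFEST_NAME = "manifest.txt"
_KNOWN_MANIFEST_KEYS = {"tsample_h", "reference"}


def write_experiment(exp: GrowthExperiment, directory) -> Path:
    """Write one curve file per channel plus a manifest; returns its path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    lines = [f"tsample_h = {exp.od_sample_interval!r}"]
    if "reference" in exp.metadata:
        lines.append(f"reference = {exp.metadata['reference']}")
    for label, curve in exp.channels.items():
        fname = f"{label}.csv"
        write_curve(curve, directory / fname)
        lines.append(f"channel.{label}.file = {fname}")
        lines.append(f"channel.{label}.kind = {curve.kind}")
        lines.append(f"channel.{label}.invert = {int(curve.invert)}")
    for key, val in exp.metadata.items():
        if key != "reference":
            lines.append(f"meta.{key} = {val}")
    manifest = directory / MANIFEST_NAME
    manifest.write_text("\n".join(lines) + "\n")
    return manifest


def read_experiment(manifest_path) -> GrowthExperiment:
    """Load an experiment from its manifest (or a directory containing one)."""
    manifest_path = Path(manifest_path)
    if manifest_path.is_dir():
        manifest_path = manifest_path / MANIFEST_NAME
    if not manifest_path.exists():
        raise ParseError(manifest_path, 1, "manifest file not found")
    base = manifest_path.parent
    tsample = 0.75
    metadata: dict = {}
    chan_attrs: dict[str, dict] = {}
    with open(manifest_path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ParseError(manifest_path, lineno,
                                 f"expected 'key = value', got {line!r}")
            key, _, val = (s.strip() for s in line.partition("="))
            if key == "tsample_h":
                tsample = float(val)
            elif key == "reference":
                metadata["reference"] = val
            elif key.startswith("channel."):
                parts = key.split(".")
                if len(parts) != 3:
                    raise ParseError(manifest_path, lineno,
                                     f"bad channel key {key!r}")
                _, label, attr = parts
                entry = chan_attrs.setdefault(label, {})
                if attr in entry:
                    raise ParseError(manifest_path, lineno,
                                     f"duplicate {attr!r} for channel {label!r}")
                entry[attr] = val
            elif key.startswith("meta."):
                metadata[key[5:]] = val
            else:
                warnings.warn(f"{manifest_path}:{lineno}: unknown manifest key "
                              f"{key!r} ignored", stacklevel=2)
    if not chan_attrs:
        raise ParseError(manifest_path, 1, "manifest defines no channels")
    channels: dict[str, GrowthCurve] = {}
    for label, attrs in chan_attrs.items():
        if "file" not in attrs:
            raise ParseError(manifest_path, 1,
                             f"channel {label!r} has no file entry")
        fpath = base / attrs["file"]
        if not fpath.exists():
            raise ParseError(manifest_path, 1,
                             f"channel {label!r} references missing file {fpath}")
        curve = read_curve(fpath)
        curve.channel = label
        if "kind" in attrs:
            if attrs["kind"] not in ("ncis", "od", "or"):
                raise ParseError(manifest_path, 1,
                                 f"channel {label!r} has unknown kind "
                                 f"{attrs['kind']!r}")
            curve.kind = attrs["kind"]
        if "invert" in attrs:
            curve.invert = bool(int(attrs["invert"]))
        channels[label] = curve
    return GrowthExperiment(channels=channels, od_sample_interval=tsample,
                            metadata=metadata)


# -- reports ----------------------------------------------------------------

def format_report(values: dict, title: str = "") -> str:
    """Flat machine-readable 'key = value' block (one entry per line)."""
    lines = [f"# {title}"] if title else []
    for key, val in values.items():
        if isinstance(val, float):
            lines.append(f"{key} = {val:.10g}")
        else:
            lines.append(f"{key} = {val}")
    return "\n".join(lines) + "\n"


def read_report(path) -> dict:
    out = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ParseError(path, lineno, f"expected 'key = value', got {line!r}")
            key, _, val = (s.strip() for s in line.partition("="))
            try:
                out[key] = float(val)
            except ValueError:
                out[key] = val
    return out
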