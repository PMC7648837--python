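"""Session container and feature-table I/O.

Two container layouts are supported:

* an HDF5 file with one group per trajectory and one subgroup per depth
  (``/central/d-03/samples`` …), sampling rate and units stored as
  attributes; and
* a plain-text fallback: a directory with one ``.txt`` file per site whose
  header lines carry ``fs``/``trajectory``/``depth_mm``, one sample per line.

Feature tables are CSV with the exact 19-parameter column roster plus the
``trajectory``/``depth_mm`` key columns; missing values are empty cells.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Dict, Mapping, Union

import h5py
import numpy as np
import pandas as pd

from .data_model import (
    FEATURE_NAMES,
    MerRecording,
    Session,
    SiteFeatures,
    SiteKey,
    ValidationError,
)

PathLike = Union[str, Path]

_DEPTH_FMT = "d{:+03d}"


def _depth_group_name(depth_mm: int) -> str:
    return _DEPTH_FMT.format(depth_mm)


def write_session(session: Session, path: PathLike) -> None:
    """Write a session to an HDF5 container (or a text directory).

    If ``path`` ends in ``.h5``/``.hdf5`` an HDF5 file is written,
    otherwise a plain-text per-site directory.
    """
    path = Path(path)
    if path.suffix.lower() in {".h5", ".hdf5"}:
        _write_session_h5(session, path)
    else:
        _write_session_text(session, path)


def read_session(path: PathLike) -> Session:
    """Read a session container written by :func:`write_session`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"session container not found: {path}")
    if path.is_dir():
        session = _read_session_text(path)
    else:
        session = _read_session_h5(path)
    session.validate()
    return session


def _write_session_h5(session: Session, path: Path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["hemisphere"] = session.hemisphere
        f.attrs["metadata"] = json.dumps(session.metadata)
        f.attrs["units"] = "uV"
        for (traj, depth), rec in session.recordings.items():
            grp = f.require_group(traj).create_group(_depth_group_name(depth))
            ds = grp.create_dataset("samples", data=rec.samples, dtype="f8")
            ds.attrs["units"] = "uV"
            grp.attrs["fs"] = rec.fs
            grp.attrs["trajectory"] = traj
            grp.attrs["depth_mm"] = depth


def _read_session_h5(path: Path) -> Session:
    session = Session()
    try:
        with h5py.File(path, "r") as f:
            session.hemisphere = str(f.attrs.get("hemisphere", "left"))
            session.metadata = json.loads(f.attrs.get("metadata", "{}"))
            for traj in f:
                for dname in f[traj]:
                    grp = f[traj][dname]
                    rec = MerRecording(
                        samples=grp["samples"][:],
                        fs=float(grp.attrs["fs"]),
                        trajectory=str(grp.attrs["trajectory"]),
                        depth_mm=int(grp.attrs["depth_mm"]),
                    )
                    session.add(rec)
    except OSError as exc:
        raise OSError(f"could not read session container {path}: {exc}") from exc
    return session


def _site_filename(traj: str, depth: int) -> str:
    return f"{traj}_{_depth_group_name(depth)}.txt"


def _write_session_text(session: Session, path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    meta = {"hemisphere": session.hemisphere, "metadata": session.metadata}
    (path / "session.json").write_text(json.dumps(meta, indent=1))
    for (traj, depth), rec in session.recordings.items():
        fname = path / _site_filename(traj, depth)
        with open(fname, "w") as fh:
            fh.write(f"# fs={rec.fs!r}\n")
            fh.write(f"# trajectory={traj}\n")
            fh.write(f"# depth_mm={depth}\n")
            fh.write("# units=uV\n")
            np.savetxt(fh, rec.samples, fmt="%.17g")  # lossless float round-trip


def _read_session_text(path: Path) -> Session:
    session = Session()
    meta_file = path / "session.json"
    if meta_file.exists():
        meta = json.loads(meta_file.read_text())
        session.hemisphere = meta.get("hemisphere", "left")
        session.metadata = meta.get("metadata", {})
    site_files = sorted(path.glob("*_d*.txt"))
    if not site_files:
        raise OSError(f"no site files found in {path}")
    for fname in site_files:
        header: Dict[str, str] = {}
        with open(fname) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                key, _, val = line[1:].strip().partition("=")
                header[key.strip()] = val.strip()
        samples = np.loadtxt(fname, comments="#")
        rec = MerRecording(
            samples=np.atleast_1d(samples),
            fs=float(header["fs"]),
            trajectory=header["trajectory"],
            depth_mm=int(header["depth_mm"]),
        )
        session.add(rec)
    return session


def write_feature_table(
    features: Mapping[SiteKey, SiteFeatures], path: PathLike
) -> pd.DataFrame:
    """Write one row per site, one column per parameter, as CSV.

    Missing values (NaN) render as empty cells. Returns the DataFrame that
    was written.
    """
    if not features:
        raise ValidationError("feature map is empty")
    rows = []
    for (traj, depth), feats in sorted(
        features.items(), key=lambda kv: (kv[0][0], kv[0][1])
    ):
        row = {"trajectory": traj, "depth_mm": depth}
        row.update(feats.as_dict())
        rows.append(row)
    df = pd.DataFrame(rows, columns=["trajectory", "depth_mm", *FEATURE_NAMES])
    df.to_csv(path, index=False, na_rep="")
    return df


def read_feature_table(path: PathLike) -> Dict[SiteKey, SiteFeatures]:
    """Read a feature CSV back into a site → :class:`SiteFeatures` map."""
    df = pd.read_csv(path)
    missing = set(FEATURE_NAMES) - set(df.columns)
    if missing:
        raise ValidationError(f"feature table missing columns: {sorted(missing)}")
    out: Dict[SiteKey, SiteFeatures] = {}
    for _, row in df.iterrows():
        key = (str(row["trajectory"]), int(row["depth_mm"]))
        vals = {
            name: (float(row[name]) if not pd.isna(row[name]) else math.nan)
            for name in FEATURE_NAMES
        }
        out[key] = SiteFeatures(**vals)
    return out
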