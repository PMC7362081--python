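"""CSV and JSON input/output.

File conventions: UTF-8 CSV with "." decimal separator and a mandatory
header row; times in hours everywhere; every file written by this package
starts with a comment line carrying the tool version and the configuration
hash.  Release-profile files have the exact columns

    formulation, replicate, time_h, value, value_type

with value_type either ``cumulative_fraction`` or ``conc_mg_per_ml``;
concentration inputs are converted to cumulative fractions through the
withdrawal/replacement mass-balance correction on load.
"""

from __future__ import annotations

import io
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .pipeline import correct_sampling
from .profiles import ReleaseProfile

__all__ = [
    "PROFILE_COLUMNS",
    "read_release_csv",
    "write_release_csv",
    "write_table_csv",
    "write_json",
    "hours_to_days",
    "days_to_hours",
]

PROFILE_COLUMNS = ["formulation", "replicate", "time_h", "value", "value_type"]
_VALUE_TYPES = {"cumulative_fraction", "conc_mg_per_ml"}


def hours_to_days(t_hours):
    return np.asarray(t_hours, dtype=float) / 24.0


def days_to_hours(t_days):
    return np.asarray(t_days, dtype=float) * 24.0


def _header_comment(config_hash: str | None) -> str:
    tag = config_hash if config_hash else "unset"
    return f"# mfrelease v{_pkg_version} config_hash={tag}\n"


def write_release_csv(
    profiles: list[ReleaseProfile],
    path,
    *,
    config_hash: str | None = None,
) -> None:
    """Write profiles in the canonical long format (cumulative fractions)."""
    rows = []
    for p in profiles:
        for t, v in zip(p.times, p.cumulative_fraction):
            rows.append((p.formulation_code, p.replicate_id, t, v, "cumulative_fraction"))
    df = pd.DataFrame(rows, columns=PROFILE_COLUMNS)
    with open(path, "w", newline="") as fh:
        fh.write(_header_comment(config_hash))
        df.to_csv(fh, index=False)


def read_release_csv(
    path,
    *,
    medium_ml: float = 10.0,
    sample_ml: float = 1.0,
    payload_mg: float = 50.0,
) -> list[ReleaseProfile]:
    """Read and validate release profiles.

    Order-insensitive: rows are sorted by (formulation, replicate, time_h)
    on load.  Raises ValueError listing the offending file line numbers for
    missing columns, duplicated (formulation, replicate, time) rows,
    negative values or non-monotone times within a replicate.  Profiles
    recorded as concentrations (mg/mL) are routed through the sampling
    correction and normalized by ``payload_mg``.
    """
    path = Path(path)
    with open(path) as fh:
        raw_lines = fh.readlines()
    n_comment = 0
    for line in raw_lines:
        if line.startswith("#"):
            n_comment += 1
        else:
            break
    body = "".join(l for l in raw_lines if not l.startswith("#"))
    df = pd.read_csv(io.StringIO(body))
    missing = [c for c in PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    # file line number of each row: header is line n_comment+1 (1-based)
    df["_line"] = df.index + n_comment + 2

    bad_type = df[~df["value_type"].isin(_VALUE_TYPES)]
    if len(bad_type):
        raise ValueError(
            f"{path}: invalid value_type on line(s) "
            f"{bad_type['_line'].tolist()}"
        )
    negative = df[(df["value"] < 0) | (df["time_h"] < 0)]
    if len(negative):
        raise ValueError(
            f"{path}: negative value/time on line(s) {negative['_line'].tolist()}"
        )
    dup = df.duplicated(subset=["formulation", "replicate", "time_h"], keep=False)
    if dup.any():
        raise ValueError(
            f"{path}: duplicated (formulation, replicate, time_h) on line(s) "
            f"{df.loc[dup, '_line'].tolist()}"
        )

    profiles = []
    for (form, rep), grp in sorted(
        df.groupby(["formulation", "replicate"], sort=True),
        key=lambda kv: (str(kv[0][0]), str(kv[0][1])),
    ):
        grp = grp.sort_values("time_h")
        vtypes = grp["value_type"].unique()
        if len(vtypes) != 1:
            raise ValueError(
                f"{path}: mixed value_type within ({form}, {rep}) on line(s) "
                f"{grp['_line'].tolist()}"
            )
        times = grp["time_h"].to_numpy(dtype=float)
        values = grp["value"].to_numpy(dtype=float)
        if np.any(np.diff(times) <= 0):
            raise ValueError(
                f"{path}: non-monotone time within ({form}, {rep}); "
                f"line(s) {grp['_line'].tolist()}"
            )
        if vtypes[0] == "conc_mg_per_ml":
            mass = correct_sampling(values, medium_ml=medium_ml, sample_ml=sample_ml)
            values = mass / payload_mg
        profiles.append(
            ReleaseProfile(
                formulation_code=str(form),
                replicate_id=str(rep),
                times=times,
                cumulative_fraction=np.minimum(values, 1.05),
            )
        )
    return profiles


def write_table_csv(df: pd.DataFrame, path, *, config_hash: str | None = None) -> None:
    """Write a result table with the version/hash header comment."""
    with open(path, "w", newline="") as fh:
        fh.write(_header_comment(config_hash))
        df.to_csv(fh, index=False)


def write_json(obj, path, *, config_hash: str | None = None) -> None:
    """Write a JSON document with version/hash stamped into the object."""
    doc = {
        "tool_version": _pkg_version,
        "config_hash": config_hash or "unset",
        **obj,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True, default=_jsonify)
        fh.write("\n")


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")
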