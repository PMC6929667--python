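"""Plain-text external interfaces for cohorts and configs.

All tabular artifacts are plain text: region time-series as tab-delimited
matrices (regions x timepoints, header row of region names), subject
metadata and exclusion reports as CSV, and configurations as documented
``key = value`` files.  NIfTI adapters for voxel data live in
:mod:`painconn.cohort`.
"""

from __future__ import annotations

import ast
from dataclasses import asdict, fields
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CohortConfig, SubjectRecord


def write_timeseries(record: SubjectRecord, path) -> None:
    """Tab-delimited regions x timepoints matrix with a region-name header."""
    n_regions = record.timeseries.shape[0]
    names = [f"region_{r:03d}" for r in range(n_regions)]
    with open(path, "w") as fh:
        fh.write("\t".join(names) + "\n")
        np.savetxt(fh, record.timeseries, delimiter="\t")


def read_timeseries(path):
    """Returns (region_names, regions x timepoints array)."""
    with open(path) as fh:
        names = fh.readline().rstrip("\n").split("\t")
        data = np.atleast_2d(np.loadtxt(fh, delimiter="\t"))
    if data.shape[0] != len(names):
        raise ValueError(f"{path}: header names {len(names)} != rows {data.shape[0]}")
    return names, data


def write_metadata(records, path) -> None:
    pd.DataFrame({
        "subject_id": [r.subject_id for r in records],
        "group": [r.group for r in records],
        "sex": [r.sex for r in records],
        "n_artifact_flags": [len(r.artifact_flags) for r in records],
    }).to_csv(path, index=False)


def read_metadata(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_exclusion_report(report, path) -> None:
    """``report`` rows are (subject_id, n_flags, excluded)."""
    pd.DataFrame(report, columns=["subject_id", "n_flags", "excluded"]).to_csv(
        path, index=False)


def write_config(config: CohortConfig, path) -> None:
    """Serialize a cohort configuration as a documented key = value file."""
    lines = ["# painconn cohort configuration (key = value, python literals)"]
    for key, value in asdict(config).items():
        if isinstance(value, frozenset):
            value = sorted(value)
        lines.append(f"{key} = {value!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_config(path) -> CohortConfig:
    kwargs = {}
    valid = {f.name for f in fields(CohortConfig)}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, raw = line.partition("=")
        key = key.strip()
        if key not in valid:
            raise ValueError(f"unknown configuration key {key!r}")
        value = ast.literal_eval(raw.strip())
        if key in ("affected_edges", "sex_effect_edges"):
            value = frozenset(tuple(e) for e in value)
        elif key in ("group_proportions", "sex_proportions"):
            value = tuple(value)
        kwargs[key] = value
    return CohortConfig(**kwargs)
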