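"""Readers/writers for the pipeline's plain-text and TIFF artifacts.

All tables are tab-separated; movies are multi-page 16-bit grayscale TIFF;
configs and condition panels are YAML with keys matching the parameter
field names.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .containers import FUnwoundEstimate, GroundTruth, MismatchProfile, SpotTable, TraceSet
from .params import ConditionSpec

__all__ = [
    "write_movie",
    "read_movie",
    "write_traces",
    "read_traces",
    "write_ground_truth",
    "write_spots",
    "write_estimates",
    "read_estimates",
    "write_condition_panel",
    "read_condition_panel",
    "write_yaml",
    "read_yaml",
]

_FLOAT_FMT = "%.6g"


def _write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_movie(stack: np.ndarray, path, frame_interval: float | None = None) -> None:
    """Write a (frame, row, col) uint16 stack as a multi-page TIFF."""
    meta = {"frame_interval_s": frame_interval} if frame_interval else None
    tifffile.imwrite(path, stack, photometric="minisblack", metadata=meta)


def read_movie(path) -> np.ndarray:
    return tifffile.imread(path)


def write_traces(traces: TraceSet, path) -> None:
    _write_tsv(traces.to_frame(), path)


def read_traces(path, frame_interval: float = 0.100) -> TraceSet:
    df = pd.read_csv(path, sep="\t")
    return TraceSet.from_frame(df, frame_interval=frame_interval, provenance={"source": str(path)})


def write_ground_truth(gt: GroundTruth, molecules_path, states_path) -> None:
    """Two TSVs: one row per molecule, and long-form per-frame states."""
    _write_tsv(gt.molecule_frame(), molecules_path)
    _write_tsv(gt.state_frame(), states_path)


def write_spots(spots: SpotTable, path) -> None:
    _write_tsv(spots.table, path)


def write_estimates(rows: Sequence[dict], path) -> None:
    """Estimates table: one row per condition x n_PD.

    Expected keys: label, grna, n_pd, f_unwound, sd, n_molecules, mean_e_low.
    """
    _write_tsv(pd.DataFrame(rows), path)


def read_estimates(path) -> list[MismatchProfile]:
    """Group an estimates TSV back into per-condition mismatch profiles."""
    df = pd.read_csv(path, sep="\t")
    profiles = []
    for (label, grna), grp in df.groupby(["label", "grna"], sort=False):
        estimates = {
            int(rec.n_pd): FUnwoundEstimate(
                f_unwound=float(rec.f_unwound),
                sd=float(rec.sd),
                n_molecules=int(rec.n_molecules),
                mean_e_low=float(rec.mean_e_low),
            )
            for rec in grp.itertuples(index=False)
        }
        profiles.append(MismatchProfile(label=str(label), grna=str(grna), estimates=estimates))
    return profiles


def write_condition_panel(panel: Sequence[ConditionSpec], path) -> None:
    payload = {"conditions": [c.to_dict() for c in panel]}
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def read_condition_panel(path) -> list[ConditionSpec]:
    payload = yaml.safe_load(Path(path).read_text())
    return [ConditionSpec.from_dict(d) for d in payload["conditions"]]


def write_yaml(obj, path) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=False))


def read_yaml(path):
    return yaml.safe_load(Path(path).read_text())
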