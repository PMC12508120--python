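"""File formats: trial-table TSV, trace/epoch HDF5 (with wide-TSV fallback).

Every artifact embeds the seed and configuration hash that produced it —
as ``# key=value`` comment lines in TSV headers and as HDF5 attributes —
so any output file can be traced back to its generating run.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from revdecode.alignment import EpochDefinition, EpochTensor
from revdecode.errors import ValidationError
from revdecode.task import TRIAL_TABLE_COLUMNS
from revdecode.traces import TraceMatrix

__all__ = [
    "config_hash",
    "read_trial_table",
    "write_trial_table",
    "validate_trial_table",
    "read_traces",
    "write_traces",
    "write_epoch_tensor",
    "read_epoch_tensor",
]

_TIME_COLS = ["t_init_cue", "t_init", "t_choice", "t_reward_cue", "t_retrieval"]


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def validate_trial_table(df: pd.DataFrame, block_length: int | None = None) -> None:
    """Check the structural invariants of a trial table; raise on violation."""
    missing = [c for c in TRIAL_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing column(s) {missing}")
    if len(df) == 0:
        raise ValidationError("empty trial table")
    idx = df["index"].to_numpy()
    if not np.array_equal(idx, np.arange(1, len(df) + 1)):
        raise ValidationError("column 'index' must be 1..N in order")
    for col in ("chosen_side", "better_side"):
        bad = ~df[col].isin(["L", "R"])
        if bad.any():
            row = int(df.loc[bad, "index"].iloc[0])
            raise ValidationError(f"row {row}: column {col!r} not in {{L, R}}")
    mism = df["better_chosen"] != (df["chosen_side"] == df["better_side"]).astype(int)
    if mism.any():
        row = int(df.loc[mism, "index"].iloc[0])
        raise ValidationError(f"row {row}: better_chosen inconsistent with sides")
    for a, b in (("t_init_cue", "t_init"), ("t_init", "t_choice")):
        bad = ~(df[a] < df[b])
        if bad.any():
            row = int(df.loc[bad, "index"].iloc[0])
            raise ValidationError(f"row {row}: need {a} < {b}")
    rewarded = df["rewarded"] == 1
    for a, b in (("t_choice", "t_reward_cue"), ("t_reward_cue", "t_retrieval")):
        bad = rewarded & ~(df[a] < df[b])
        if bad.any():
            row = int(df.loc[bad, "index"].iloc[0])
            raise ValidationError(f"row {row}: need {a} < {b} on rewarded trials")
    blocks = df["block"].to_numpy()
    if not set(np.unique(blocks)) <= {1, 2, 3}:
        raise ValidationError("column 'block' must take values in {1, 2, 3}")
    if block_length is not None:
        for b in (1, 2, 3):
            n = int((blocks == b).sum())
            if n != block_length:
                raise ValidationError(
                    f"block {b} has {n} trials; expected {block_length}"
                )
    # better side must reverse at block boundaries
    per_block = df.groupby("block")["better_side"].unique()
    for b, sides in per_block.items():
        if len(sides) != 1:
            raise ValidationError(f"block {b}: better_side not constant")
    order = [per_block[b][0] for b in sorted(per_block.index)]
    for i in range(len(order) - 1):
        if order[i] == order[i + 1]:
            raise ValidationError(
                f"better_side does not reverse between blocks {i + 1} and {i + 2}"
            )


def write_trial_table(
    df: pd.DataFrame, path: str | Path, meta: dict | None = None
) -> None:
    """Write a trial table as TSV with ``# key=value`` provenance comments."""
    path = Path(path)
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="nan")


def read_trial_table(
    path: str | Path, block_length: int | None = None
) -> pd.DataFrame:
    """Read and validate a trial-table TSV (raises :class:`ValidationError`)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    validate_trial_table(df, block_length=block_length)
    return df


def write_traces(
    traces: TraceMatrix, path: str | Path, meta: dict | None = None
) -> None:
    """Write traces as HDF5 (dataset ``traces``; attrs fps, t0) or wide TSV.

    The format is chosen by the file extension (``.h5``/``.hdf5`` vs
    ``.tsv``); the TSV fallback stores one row per cell with fps/t0 in
    header comments.
    """
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as fh:
            ds = fh.create_dataset("traces", data=traces.values)
            ds.attrs["fps"] = traces.fps
            ds.attrs["t0"] = traces.t0
            for k, v in (meta or {}).items():
                ds.attrs[k] = v
    else:
        with open(path, "w") as fh:
            fh.write(f"# fps={traces.fps}\n# t0={traces.t0}\n")
            for k, v in (meta or {}).items():
                fh.write(f"# {k}={v}\n")
            header = "\t".join(f"f{j}" for j in range(traces.n_frames))
            fh.write(f"cell\t{header}\n")
            for i in range(traces.n_cells):
                row = "\t".join(f"{v:.17g}" for v in traces.values[i])
                fh.write(f"{i}\t{row}\n")


def read_traces(path: str | Path) -> TraceMatrix:
    """Read a trace matrix written by :func:`write_traces`."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as fh:
            ds = fh["traces"]
            if "fps" not in ds.attrs:
                raise ValidationError(f"{path}: missing mandatory 'fps' attribute")
            return TraceMatrix(
                values=ds[()],
                fps=float(ds.attrs["fps"]),
                t0=float(ds.attrs.get("t0", 0.0)),
            )
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            k, _, v = line[1:].strip().partition("=")
            meta[k.strip()] = v
    if "fps" not in meta:
        raise ValidationError(f"{path}: missing mandatory 'fps' header")
    df = pd.read_csv(path, sep="\t", comment="#")
    values = df.drop(columns=["cell"]).to_numpy(float)
    return TraceMatrix(
        values=values, fps=float(meta["fps"]), t0=float(meta.get("t0", 0.0))
    )


def write_epoch_tensor(
    epoch: EpochTensor, path: str | Path, meta: dict | None = None
) -> None:
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("epoch", data=epoch.values)
        ds.attrs["name"] = epoch.epoch.name
        ds.attrs["anchor_event"] = epoch.epoch.anchor_event
        ds.attrs["window"] = list(epoch.epoch.window)
        ds.attrs["fps"] = epoch.fps
        ds.attrs["anchor_frame"] = epoch.anchor_frame
        fh.create_dataset("bin_centers", data=epoch.bin_centers)
        fh.create_dataset("trial_index_map", data=epoch.trial_index_map)
        for k, v in (meta or {}).items():
            ds.attrs[k] = v


def read_epoch_tensor(path: str | Path) -> EpochTensor:
    with h5py.File(path, "r") as fh:
        ds = fh["epoch"]
        epoch = EpochDefinition(
            name=str(ds.attrs["name"]),
            anchor_event=str(ds.attrs["anchor_event"]),
            window=tuple(float(w) for w in ds.attrs["window"]),
        )
        return EpochTensor(
            values=ds[()],
            bin_centers=fh["bin_centers"][()],
            epoch=epoch,
            anchor_frame=int(ds.attrs["anchor_frame"]),
            fps=float(ds.attrs["fps"]),
            trial_index_map=fh["trial_index_map"][()],
        )
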