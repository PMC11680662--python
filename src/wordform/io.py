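"""File containers: HDF5/NPZ epoch tensors, decoding results, result tables.

The epoch container holds one HDF5 group per subject (``subject_<id>``)
with datasets ``data`` (trials x channels x timepoints) and ``time`` (ms),
one dataset per trial-metadata column under ``trials/``, the channel map
under ``channels/``, and the processing-state flags as group attributes.
An NPZ fallback stores the same content flat.
"""

from __future__ import annotations

import json
from io import StringIO

import h5py
import numpy as np
import pandas as pd

from .cluster import ClusterRecord
from .connectivity import GCResult
from .decode import DecodingTimecourse
from .synth import EpochTensor

__all__ = [
    "save_epochs_h5", "load_epochs_h5",
    "save_epochs_npz", "load_epochs_npz",
    "save_decoding_h5", "load_decoding_h5",
    "clusters_to_frame", "gc_results_to_frame",
]

_STR = h5py.string_dtype(encoding="utf-8")


def _write_frame(grp: h5py.Group, df: pd.DataFrame) -> None:
    for col in df.columns:
        vals = df[col].to_numpy()
        if vals.dtype == object or vals.dtype.kind in "US":
            strs = np.array([str(x) for x in vals], dtype=object)
            grp.create_dataset(col, data=strs, dtype=_STR)
        else:
            grp.create_dataset(col, data=vals)
    grp.attrs["columns"] = json.dumps(list(df.columns))


def _read_frame(grp: h5py.Group) -> pd.DataFrame:
    cols = json.loads(grp.attrs["columns"])
    out = {}
    for col in cols:
        v = grp[col][()]
        if v.dtype.kind in ("O", "S"):
            v = np.array([x.decode() if isinstance(x, bytes) else x for x in v])
        out[col] = v
    return pd.DataFrame(out)


def save_epochs_h5(path, epochs_by_subject: dict[int, EpochTensor]) -> None:
    with h5py.File(path, "w") as f:
        for sid, ep in epochs_by_subject.items():
            g = f.create_group(f"subject_{sid}")
            g.create_dataset("data", data=ep.data)
            g.create_dataset("time", data=ep.times)
            _write_frame(g.create_group("trials"), ep.trials)
            _write_frame(g.create_group("channels"), ep.channel_map)
            g.attrs["subject_id"] = sid
            g.attrs["baseline_corrected"] = ep.baseline_corrected
            g.attrs["normalized"] = ep.normalized


def load_epochs_h5(path) -> dict[int, EpochTensor]:
    out = {}
    with h5py.File(path, "r") as f:
        for name in f:
            g = f[name]
            ep = EpochTensor(
                data=g["data"][()],
                times=g["time"][()],
                trials=_read_frame(g["trials"]),
                channel_map=_read_frame(g["channels"]),
                subject_id=int(g.attrs["subject_id"]),
                baseline_corrected=bool(g.attrs["baseline_corrected"]),
                normalized=bool(g.attrs["normalized"]),
            )
            out[ep.subject_id] = ep
    return out


def save_epochs_npz(path, epochs: EpochTensor) -> None:
    """Single-subject NPZ fallback container."""
    np.savez(
        path,
        data=epochs.data,
        time=epochs.times,
        trials_json=np.array(epochs.trials.to_json(orient="split")),
        channels_json=np.array(epochs.channel_map.to_json(orient="split")),
        subject_id=epochs.subject_id,
        baseline_corrected=epochs.baseline_corrected,
        normalized=epochs.normalized,
    )


def load_epochs_npz(path) -> EpochTensor:
    z = np.load(path, allow_pickle=False)
    return EpochTensor(
        data=z["data"],
        times=z["time"],
        trials=pd.read_json(StringIO(str(z["trials_json"])), orient="split"),
        channel_map=pd.read_json(StringIO(str(z["channels_json"])), orient="split"),
        subject_id=int(z["subject_id"]),
        baseline_corrected=bool(z["baseline_corrected"]),
        normalized=bool(z["normalized"]),
    )


def save_decoding_h5(path, dec: DecodingTimecourse) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("accuracy", data=dec.accuracy)
        f.create_dataset("time", data=dec.times)
        f.attrs["conditions"] = json.dumps(list(dec.conditions))
        f.attrs["subjects"] = json.dumps([int(s) for s in dec.subjects])
        f.attrs["chance"] = dec.chance
        f.attrs["provenance"] = json.dumps(dec.provenance)


def load_decoding_h5(path) -> DecodingTimecourse:
    with h5py.File(path, "r") as f:
        return DecodingTimecourse(
            accuracy=f["accuracy"][()],
            times=f["time"][()],
            conditions=tuple(json.loads(f.attrs["conditions"])),
            subjects=tuple(json.loads(f.attrs["subjects"])),
            chance=float(f.attrs["chance"]),
            provenance=json.loads(f.attrs["provenance"]),
        )


def clusters_to_frame(records: list[ClusterRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"roi": r.roi, "condition": r.condition, "start_ms": r.start_ms,
             "end_ms": r.end_ms, "size": r.size, "p_value": r.p_value,
             "significant": r.significant}
            for r in records
        ],
        columns=["roi", "condition", "start_ms", "end_ms", "size",
                 "p_value", "significant"],
    )


def gc_results_to_frame(results: list[GCResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"source_roi": r.source_roi, "target_roi": r.target_roi,
             "sig_count": r.sig_count, "window_len": r.window_len,
             "binomial_p": r.binomial_p, "fdr_significant": r.fdr_significant,
             "reciprocal": r.reciprocal}
            for r in results
        ],
        columns=["source_roi", "target_roi", "sig_count", "window_len",
                 "binomial_p", "fdr_significant", "reciprocal"],
    )
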