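"""Flat-binary + JSON-sidecar session storage and delimited feature tables."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .waveforms import MultichannelWaveform

__all__ = [
    "save_waveforms",
    "load_waveforms",
    "save_spike_trains",
    "load_spike_trains",
    "write_feature_table",
    "read_feature_table",
]

FEATURE_UNITS = {
    "tpw": "ms",
    "rep": "ms",
    "amplitude": "uV",
    "inv_v_below": "ms/um",
    "inv_v_above": "ms/um",
    "symmetry_index": "ms/um",
    "spread": "um",
    "depth": "um",
    "rate": "Hz",
}


def save_waveforms(waveforms: list[MultichannelWaveform], directory, seed=None) -> None:
    """Stacked float32 raw binary plus a JSON sidecar with geometry and rates."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stack = np.stack([w.samples for w in waveforms]).astype(np.float32)
    stack.tofile(directory / "waveforms.bin")
    sidecar = {
        "shape": list(stack.shape),
        "dtype": "float32",
        "sampling_rate": waveforms[0].sampling_rate,
        "channel_depths": waveforms[0].channel_depths.tolist(),
        "unit_ids": [w.unit_id for w in waveforms],
        "seed": seed,
    }
    (directory / "waveforms.json").write_text(json.dumps(sidecar, indent=1))


def load_waveforms(directory) -> list[MultichannelWaveform]:
    directory = Path(directory)
    sidecar = json.loads((directory / "waveforms.json").read_text())
    stack = np.fromfile(directory / "waveforms.bin", dtype=sidecar["dtype"]).reshape(
        sidecar["shape"]
    )
    depths = np.asarray(sidecar["channel_depths"])
    return [
        MultichannelWaveform(
            samples=stack[i].astype(float),
            sampling_rate=sidecar["sampling_rate"],
            channel_depths=depths,
            unit_id=uid,
        )
        for i, uid in enumerate(sidecar["unit_ids"])
    ]


def save_spike_trains(trains: dict, duration: float, directory) -> None:
    """``trains`` maps unit_id -> spike time array (s)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    payload = {
        "duration": duration,
        "trains": {str(k): np.round(np.asarray(v), 6).tolist() for k, v in trains.items()},
    }
    (directory / "spikes.json").write_text(json.dumps(payload))


def load_spike_trains(directory) -> tuple[dict, float]:
    payload = json.loads((Path(directory) / "spikes.json").read_text())
    trains = {k: np.asarray(v) for k, v in payload["trains"].items()}
    return trains, payload["duration"]


def write_feature_table(df: pd.DataFrame, path) -> None:
    """CSV with a '#' header naming the units of known columns."""
    units = ",".join(
        f"{c}[{FEATURE_UNITS[c]}]" for c in df.columns if c in FEATURE_UNITS
    )
    with open(path, "w") as fh:
        fh.write(f"# units: {units}\n")
        df.to_csv(fh, index=False, float_format="%.9g", lineterminator="\n")


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
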