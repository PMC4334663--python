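"""File formats: HDF5 epoch/evoked containers, record CSVs, JSON sidecars.

Volumes travel as NIfTI-1 through :mod:`megmyelin.qmri`; epoched and
evoked sensor data use a small documented HDF5 layout; hemisphere
records are plain CSV with columns ``hemisphere_id``, ``moment_nAm``
and one ``<map>_<roi>`` column per myelin cell; ground truth is a JSON
sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .forward import SensorArray
from .preprocess import EpochSet, EvokedField
from .stats import HemisphereRecord, frame_to_records, records_to_frame
from .synthgen import GroundTruth


def save_epochs(path, epochs: EpochSet, array: SensorArray | None = None) -> None:
    """HDF5 layout: /epochs/data (trials x channels x samples, T) with
    sfreq_hz, t0_s, transition_s attrs; optional /sensors/{positions_mm,
    orientations, baseline_mm}."""
    with h5py.File(path, "w") as f:
        g = f.create_group("epochs")
        g.create_dataset("data", data=epochs.data, compression="gzip")
        g.attrs["sfreq_hz"] = epochs.sfreq_hz
        g.attrs["t0_s"] = epochs.t0_s
        g.attrs["transition_s"] = epochs.transition_s
        if epochs.rejected is not None:
            g.create_dataset("rejected", data=epochs.rejected)
        if array is not None:
            s = f.create_group("sensors")
            s.create_dataset("positions_mm", data=array.positions_mm)
            s.create_dataset("orientations", data=array.orientations)
            s.attrs["baseline_mm"] = np.nan if array.baseline_mm is None else array.baseline_mm
            s.attrs["name"] = array.name


def load_epochs(path):
    """Returns (EpochSet, SensorArray or None)."""
    with h5py.File(path, "r") as f:
        g = f["epochs"]
        epochs = EpochSet(
            data=g["data"][()],
            sfreq_hz=float(g.attrs["sfreq_hz"]),
            t0_s=float(g.attrs["t0_s"]),
            transition_s=float(g.attrs["transition_s"]),
            rejected=g["rejected"][()] if "rejected" in g else None,
        )
        array = None
        if "sensors" in f:
            s = f["sensors"]
            bl = float(s.attrs["baseline_mm"])
            array = SensorArray(
                positions_mm=s["positions_mm"][()],
                orientations=s["orientations"][()],
                baseline_mm=None if np.isnan(bl) else bl,
                name=str(s.attrs.get("name", "loaded array")),
            )
    return epochs, array


def save_evoked(path, evoked: EvokedField) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("evoked")
        g.create_dataset("data", data=evoked.data, compression="gzip")
        g.attrs["sfreq_hz"] = evoked.sfreq_hz
        g.attrs["t0_s"] = evoked.t0_s
        g.attrs["transition_s"] = evoked.transition_s
        g.attrs["n_trials_used"] = evoked.n_trials_used
        g.attrs["processing"] = json.dumps(list(evoked.processing))


def load_evoked(path) -> EvokedField:
    with h5py.File(path, "r") as f:
        g = f["evoked"]
        return EvokedField(
            data=g["data"][()],
            sfreq_hz=float(g.attrs["sfreq_hz"]),
            t0_s=float(g.attrs["t0_s"]),
            transition_s=float(g.attrs["transition_s"]),
            n_trials_used=int(g.attrs["n_trials_used"]),
            processing=tuple(json.loads(g.attrs["processing"])),
        )


def save_records(path, records: list[HemisphereRecord]) -> None:
    records_to_frame(records).to_csv(path, index=False)


def load_records(path) -> list[HemisphereRecord]:
    return frame_to_records(pd.read_csv(path))


def save_ground_truth(path, truth: GroundTruth) -> None:
    payload = {
        "hemisphere_ids": truth.hemisphere_ids,
        "dipole_locations_mm": truth.dipole_locations_mm.tolist(),
        "dipole_moments_nAm": truth.dipole_moments_nAm.tolist(),
        "moment_magnitudes_nAm": truth.moment_magnitudes_nAm.tolist(),
        "roi_myelin": {f"{h}|{m}|{r}": v for (h, m, r), v in truth.roi_myelin.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def load_ground_truth(path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    myelin = {}
    for key, v in payload["roi_myelin"].items():
        h, m, r = key.split("|")
        myelin[(h, m, r)] = v
    return GroundTruth(
        dipole_locations_mm=np.array(payload["dipole_locations_mm"]),
        dipole_moments_nAm=np.array(payload["dipole_moments_nAm"]),
        roi_myelin=myelin,
        hemisphere_ids=list(payload["hemisphere_ids"]),
        moment_magnitudes_nAm=np.array(payload["moment_magnitudes_nAm"]),
    )
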