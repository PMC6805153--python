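"""Hierarchical array container (HDF5) for epochs, leadfields, contacts.

Layout::

    /epochs/<condition>/data        (subjects, trials, channels, time)
    /epochs/<condition>@sfreq,t0
    /leadfield/gain                 (m, 3n)
    /leadfield/positions            (n, 3) mm
    /leadfield/sensor_positions     (m, 3) mm
    /leadfield@spacing
    /contacts/<name>/trace          (trials, time)
    /contacts/<name>@sfreq,t0,region,mni,subject_id,condition
    /truth/...                      ground-truth arrays from the generator

All stage outputs that are tables go to CSV instead.
"""

from __future__ import annotations

import numpy as np
import h5py

from .grids import Leadfield, SourceGrid
from .simulate import ContactRecord, SensorEpochs

__all__ = [
    "save_epochs",
    "load_epochs",
    "save_leadfield",
    "load_leadfield",
    "save_contact",
    "load_contacts",
    "save_truth",
]


def save_epochs(path: str, epochs: SensorEpochs, mode: str = "a") -> None:
    with h5py.File(path, mode) as f:
        grp = f.require_group("epochs").create_group(epochs.condition)
        grp.create_dataset("data", data=epochs.data)
        grp.attrs["sfreq"] = epochs.sfreq
        grp.attrs["t0"] = epochs.t0


def load_epochs(path: str, condition: str) -> SensorEpochs:
    with h5py.File(path, "r") as f:
        grp = f["epochs"][condition]
        return SensorEpochs(
            data=grp["data"][()],
            sfreq=float(grp.attrs["sfreq"]),
            t0=float(grp.attrs["t0"]),
            condition=condition,
        )


def save_leadfield(path: str, lf: Leadfield, mode: str = "a") -> None:
    with h5py.File(path, mode) as f:
        grp = f.require_group("leadfield")
        grp.create_dataset("gain", data=lf.gain)
        grp.create_dataset("positions", data=lf.grid.positions)
        grp.create_dataset("sensor_positions", data=lf.sensor_positions)
        grp.attrs["spacing"] = lf.grid.spacing


def load_leadfield(path: str) -> Leadfield:
    with h5py.File(path, "r") as f:
        grp = f["leadfield"]
        grid = SourceGrid(grp["positions"][()], spacing=float(grp.attrs["spacing"]))
        return Leadfield(
            gain=grp["gain"][()],
            grid=grid,
            sensor_positions=grp["sensor_positions"][()],
        )


def save_contact(path: str, record: ContactRecord, name: str, mode: str = "a") -> None:
    with h5py.File(path, mode) as f:
        grp = f.require_group("contacts").create_group(name)
        grp.create_dataset("trace", data=record.trace)
        grp.create_dataset("trial_mask", data=record.trial_mask)
        grp.attrs["sfreq"] = record.sfreq
        grp.attrs["t0"] = record.t0
        grp.attrs["region"] = record.region
        grp.attrs["mni"] = np.asarray(record.mni, dtype=float)
        grp.attrs["subject_id"] = record.subject_id
        grp.attrs["condition"] = record.condition


def load_contacts(path: str) -> dict[str, ContactRecord]:
    out: dict[str, ContactRecord] = {}
    with h5py.File(path, "r") as f:
        if "contacts" not in f:
            return out
        for name, grp in f["contacts"].items():
            out[name] = ContactRecord(
                trace=grp["trace"][()],
                sfreq=float(grp.attrs["sfreq"]),
                region=str(grp.attrs["region"]),
                mni=tuple(grp.attrs["mni"]),
                subject_id=str(grp.attrs["subject_id"]),
                condition=str(grp.attrs["condition"]),
                t0=float(grp.attrs["t0"]),
                trial_mask=grp["trial_mask"][()],
            )
    return out


def save_truth(path: str, truth: dict, mode: str = "a") -> None:
    """Persist the generator's ground-truth arrays (for recovery tests)."""
    with h5py.File(path, mode) as f:
        grp = f.require_group("truth")
        grp.create_dataset("times", data=truth["times"])
        grp.create_dataset("orientations", data=truth["orientations"])
        grp.create_dataset("subject_gain", data=truth["subject_gain"])
        for kind in ("imagery", "stimulus"):
            kg = grp.create_group(kind)
            for j, src in enumerate(truth[kind]):
                sg = kg.create_group(str(j))
                sg.attrs["index"] = src["index"]
                sg.attrs["amplitude"] = src["amplitude"]
                sg.create_dataset("waveform", data=src["waveform"])
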