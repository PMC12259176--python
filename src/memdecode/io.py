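"""File formats: CSV image/trial tables, HDF5 spike counts, YAML configs."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .screen import Pseudopopulation
from .syndata import ChoiceSet, MemImage, SessionRecording, TrialSpec

__all__ = [
    "save_images", "load_images",
    "save_trials", "load_trials",
    "save_session", "load_session",
    "save_pseudopopulation", "load_pseudopopulation",
    "load_config", "save_json",
]


def save_images(images: list[MemImage], path) -> None:
    pd.DataFrame({"image_id": [im.image_id for im in images],
                  "memorability": [im.memorability for im in images]}
                 ).to_csv(path, index=False, float_format="%.17g")


def load_images(path) -> list[MemImage]:
    df = pd.read_csv(path, float_precision="round_trip")
    return [MemImage(str(r.image_id), float(r.memorability))
            for r in df.itertuples()]


def save_trials(trials: list[TrialSpec], path, choices: ChoiceSet | None = None) -> None:
    df = pd.DataFrame({
        "trial_index": [t.trial_index for t in trials],
        "image_id": [t.image_id for t in trials],
        "novelty": [t.novelty for t in trials],
        "n_back": [t.n_back if t.n_back is not None else -1 for t in trials],
        "on_target": [t.on_target if t.on_target is not None else False
                      for t in trials],
    })
    if choices is not None:
        df["choice"] = choices.choice
        df["correct"] = choices.correct
    df.to_csv(path, index=False)


def load_trials(path) -> tuple[list[TrialSpec], ChoiceSet | None]:
    df = pd.read_csv(path)
    trials = []
    for r in df.itertuples():
        rep = r.novelty == "repeated"
        trials.append(TrialSpec(int(r.trial_index), str(r.image_id), r.novelty,
                                n_back=int(r.n_back) if rep else None,
                                on_target=bool(r.on_target) if rep else None))
    choices = None
    if "choice" in df.columns:
        choices = ChoiceSet(choice=list(df["choice"]),
                            correct=df["correct"].to_numpy(dtype=bool))
    return trials, choices


def save_session(session: SessionRecording, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("counts", data=session.counts, compression="gzip")
        f.create_dataset("bin_edges", data=session.bin_edges)
        f.create_dataset("unit_ids",
                         data=np.array(session.unit_ids, dtype="S"))
        f.create_dataset("trial_index",
                         data=np.array([t.trial_index for t in session.trials]))
        f.attrs["trials_json"] = json.dumps(
            [{"trial_index": t.trial_index, "image_id": t.image_id,
              "novelty": t.novelty, "n_back": t.n_back,
              "on_target": t.on_target} for t in session.trials])
        f.attrs["memorability_json"] = json.dumps(session.memorability)
        f.attrs["n_clipped_rates"] = session.n_clipped_rates


def load_session(path) -> SessionRecording:
    with h5py.File(path, "r") as f:
        trials = [TrialSpec(**d) for d in json.loads(f.attrs["trials_json"])]
        return SessionRecording(
            unit_ids=[u.decode() for u in f["unit_ids"][()]],
            trials=trials,
            counts=f["counts"][()],
            bin_edges=f["bin_edges"][()],
            memorability=json.loads(f.attrs["memorability_json"]),
            n_clipped_rates=int(f.attrs["n_clipped_rates"]),
        )


def save_pseudopopulation(pop: Pseudopopulation, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("counts", data=pop.counts, compression="gzip")
        f.create_dataset("bin_edges", data=pop.bin_edges)
        f.create_dataset("unit_ids", data=np.array(pop.unit_ids, dtype="S"))
        f.create_dataset("memorability", data=pop.memorability)
        f.create_dataset("mb_bin", data=pop.mb_bin)
        f.create_dataset("n_back", data=pop.n_back)
        if pop.unit_session is not None:
            f.create_dataset("unit_session", data=pop.unit_session)


def load_pseudopopulation(path) -> Pseudopopulation:
    with h5py.File(path, "r") as f:
        return Pseudopopulation(
            unit_ids=[u.decode() for u in f["unit_ids"][()]],
            counts=f["counts"][()],
            bin_edges=f["bin_edges"][()],
            memorability=f["memorability"][()],
            mb_bin=f["mb_bin"][()],
            n_back=f["n_back"][()],
            unit_session=f["unit_session"][()] if "unit_session" in f else None,
        )


def load_config(path) -> dict:
    with open(path) as f:
        return yaml.safe_load(f)


def save_json(obj, path) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (np.bool_,)):
            return bool(o)
        raise TypeError(f"not serializable: {type(o)}")
    Path(path).write_text(json.dumps(obj, indent=2, default=default,
                                     sort_keys=True) + "\n")
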