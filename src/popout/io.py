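"""Disk formats: WAV audio, HDF5 session bundles, TSV tables."""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd
from scipy.io import wavfile

from .preprocessing import EEGEpoch
from .synthetic import (AudioStimulus, PupilTrace, SessionData,
                        design_to_frame)


def write_wav(path, stimulus: AudioStimulus) -> None:
    wavfile.write(path, int(stimulus.fs),
                  np.asarray(stimulus.samples, np.float32))


def read_wav(path, variant: str = "clear", sentence_id: int = -1) -> AudioStimulus:
    fs, data = wavfile.read(path)
    if data.dtype.kind == "i":
        data = data / float(np.iinfo(data.dtype).max)
    return AudioStimulus(samples=np.asarray(data, float), fs=float(fs),
                         variant=variant, sentence_id=sentence_id)


def save_session(path, session: SessionData) -> None:
    """Serialize a session to HDF5 (/training, /trials/<k>/<p>, /pupil, /design)."""
    with h5py.File(path, "w") as f:
        f.attrs["participant_index"] = session.participant_index
        f.attrs["seed"] = session.seed
        f.attrs["eeg_fs"] = 500.0
        tr = f.create_group("training")
        tr.create_dataset("eeg", data=session.training_eeg, compression="gzip")
        tr.create_dataset("envelope", data=session.training_envelope.samples)
        tr.attrs["envelope_fs"] = session.training_envelope.fs
        trials = f.create_group("trials")
        for (k, pres), epoch in session.trial_epochs.items():
            g = trials.require_group(str(k)).create_group(str(pres))
            g.create_dataset("data", data=epoch.data, compression="gzip")
            g.attrs["fs"] = epoch.fs
            g.attrs["t0"] = epoch.t0
            g.attrs["info"] = json.dumps(epoch.info)
        envs = f.create_group("envelopes")
        for sid, env in session.trial_envelopes.items():
            d = envs.create_dataset(str(sid), data=env.samples)
            d.attrs["fs"] = env.fs
        pup = f.create_group("pupil")
        for k, trace in session.pupil.items():
            g = pup.create_group(str(k))
            g.create_dataset("left", data=trace.left)
            g.create_dataset("right", data=trace.right)
            g.attrs["fs"] = trace.fs
            g.attrs["onset_1"] = trace.onset_1
            g.attrs["onset_2"] = trace.onset_2
        f.create_dataset("design",
                         data=design_to_frame(session.design)
                         .to_csv(sep="\t", index=False).encode())
        f["design"].attrs["format"] = "tsv"
        f.create_dataset("channels",
                         data="\n".join(session.layout.names).encode())


def load_design(path) -> pd.DataFrame:
    with h5py.File(path, "r") as f:
        raw = bytes(f["design"][()]).decode()
    from io import StringIO
    return pd.read_csv(StringIO(raw), sep="\t")


def load_trial_epoch(path, trial_index: int, presentation: int) -> EEGEpoch:
    with h5py.File(path, "r") as f:
        g = f["trials"][str(trial_index)][str(presentation)]
        channels = bytes(f["channels"][()]).decode().split("\n")
        return EEGEpoch(data=g["data"][()], fs=float(g.attrs["fs"]),
                        t0=float(g.attrs["t0"]), channels=tuple(channels),
                        info=json.loads(g.attrs["info"]))


def load_session_lite(path):
    """Design, training pair, envelopes, pupil — epochs are loaded lazily."""
    with h5py.File(path, "r") as f:
        design = load_design(path)
        training_eeg = f["training/eeg"][()]
        training_env = f["training/envelope"][()]
        env_fs = float(f["training"].attrs["envelope_fs"])
        envelopes = {int(k): (f["envelopes"][k][()],
                              float(f["envelopes"][k].attrs["fs"]))
                     for k in f["envelopes"]}
        pupil = {}
        for k in f["pupil"]:
            g = f["pupil"][k]
            pupil[int(k)] = PupilTrace(
                left=g["left"][()], right=g["right"][()],
                fs=float(g.attrs["fs"]), onset_1=float(g.attrs["onset_1"]),
                onset_2=float(g.attrs["onset_2"]), trial_index=int(k))
        trial_keys = [(int(k), int(p)) for k in f["trials"]
                      for p in f["trials"][k]]
    return {"design": design, "training_eeg": training_eeg,
            "training_envelope": (training_env, env_fs),
            "envelopes": envelopes, "pupil": pupil, "trial_keys": trial_keys}
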