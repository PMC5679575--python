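"""Readers and writers for the package's on-disk formats.

Event logs, markers, dose schedules, CE profiles, band series and
hemodynamics travel as TSV; fNIRS optical densities as long-format CSV
(time_s, channel, wavelength_nm, dod); EEG recordings as an .npz array
container with a JSON metadata sidecar.  BrainVision (.vhdr) and EDF
recordings are read through MNE.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .fnirs import FNIRSRecording, HemoSeries
from .markers import SessionLog, TransitionMarkers
from .pkpd import CEProfile, DoseSchedule
from .preprocess import EEGRecording

EVENT_KINDS = ("stimulus", "response", "bolus")


# ---- event logs --------------------------------------------------------------

def write_event_log(log: SessionLog, path: str | Path) -> None:
    rows = ([(t, "stimulus") for t in log.stimuli]
            + [(t, "response") for t in log.responses]
            + [(t, "bolus") for t in log.boluses])
    df = pd.DataFrame(sorted(rows), columns=["onset_s", "kind"])
    df.to_csv(path, sep="\t", index=False)


def read_event_log(path: str | Path, stage: str = "non_scaling") -> SessionLog:
    df = pd.read_csv(path, sep="\t")
    unknown = set(df["kind"]) - set(EVENT_KINDS)
    if unknown:
        raise ValueError(f"unknown event kinds in {path}: {sorted(unknown)}")

    def _of(kind: str) -> np.ndarray:
        return np.sort(df.loc[df["kind"] == kind, "onset_s"].to_numpy(float))

    return SessionLog(stimuli=_of("stimulus"), responses=_of("response"),
                      boluses=_of("bolus"), stage=stage)


# ---- markers -----------------------------------------------------------------

def write_markers(markers: TransitionMarkers, path: str | Path) -> None:
    markers.to_frame().to_csv(path, sep="\t", index=False)


def read_markers(path: str | Path) -> TransitionMarkers:
    df = pd.read_csv(path, sep="\t")
    return TransitionMarkers(kinds=list(df["kind"]),
                             times=df["time_s"].to_numpy(float),
                             stimulus_indices=df["stimulus_index"].to_numpy(int))


# ---- doses and CE ------------------------------------------------------------

def write_dose_schedule(doses: DoseSchedule, path: str | Path) -> None:
    df = pd.DataFrame(doses.events, columns=["start_s", "dose_mg", "duration_s"])
    df.to_csv(path, sep="\t", index=False)


def read_dose_schedule(path: str | Path, weight_kg: float) -> DoseSchedule:
    df = pd.read_csv(path, sep="\t")
    events = [tuple(r) for r in df[["start_s", "dose_mg", "duration_s"]]
              .to_numpy(float)]
    return DoseSchedule(events=events, weight_kg=weight_kg)


def write_ce_profile(profile: CEProfile, path: str | Path) -> None:
    profile.to_frame().to_csv(path, sep="\t", index=False)


# ---- EEG ---------------------------------------------------------------------

def write_eeg_npz(rec: EEGRecording, path: str | Path) -> None:
    """Portable array container + JSON sidecar (<path>.json)."""
    path = Path(path)
    np.savez_compressed(path, data=rec.data)
    meta = {"fs": rec.fs, "channel_labels": list(rec.channel_labels),
            "start_time_s": rec.start_time_s, "unit": "uV"}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def read_eeg_npz(path: str | Path) -> EEGRecording:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    with np.load(path) as z:
        data = z["data"]
    return EEGRecording(data=data, fs=meta["fs"],
                        channel_labels=meta["channel_labels"],
                        start_time_s=meta.get("start_time_s", 0.0))


def read_eeg_file(path: str | Path) -> EEGRecording:
    """Read BrainVision (.vhdr) or EDF (.edf) EEG via MNE; .npz natively."""
    path = Path(path)
    if path.suffix == ".npz":
        return read_eeg_npz(path)
    import mne  # deferred: heavy import only when file reading is needed

    if path.suffix == ".vhdr":
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    elif path.suffix == ".edf":
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    else:
        raise ValueError(f"unsupported EEG format {path.suffix!r}")
    data_uv = raw.get_data() * 1e6  # MNE works in volts
    return EEGRecording(data=data_uv, fs=float(raw.info["sfreq"]),
                        channel_labels=list(raw.ch_names),
                        start_time_s=float(raw.first_time))


def write_epochs_npz(epochs, path: str | Path) -> None:
    """EpochSet to a portable array container + JSON metadata sidecar."""
    path = Path(path)
    np.savez_compressed(path, data=epochs.data,
                        marker_times=epochs.marker_times)
    meta = {"fs": epochs.fs, "window": list(epochs.window),
            "alignment": epochs.alignment,
            "channel_labels": list(epochs.channel_labels), "unit": "uV"}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def read_epochs_npz(path: str | Path):
    from .preprocess import EpochSet

    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    with np.load(path) as z:
        data, marker_times = z["data"], z["marker_times"]
    return EpochSet(data=data, fs=meta["fs"], window=tuple(meta["window"]),
                    alignment=meta["alignment"], marker_times=marker_times,
                    channel_labels=meta["channel_labels"])


# ---- fNIRS -------------------------------------------------------------------

def write_fnirs_csv(rec: FNIRSRecording, path: str | Path) -> None:
    t = rec.times_s
    frames = []
    for c, label in enumerate(rec.channel_labels):
        for w, wl in enumerate(rec.wavelengths_nm):
            frames.append(pd.DataFrame({
                "time_s": t, "channel": label, "wavelength_nm": wl,
                "dod": rec.dod[c, w]}))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_fnirs_csv(path: str | Path, fs: float | None = None,
                   distances_cm: float | np.ndarray = 3.0) -> FNIRSRecording:
    df = pd.read_csv(path)
    channels = list(dict.fromkeys(df["channel"]))
    wavelengths = tuple(sorted(set(df["wavelength_nm"])))
    if len(wavelengths) != 2:
        raise ValueError("expected exactly two wavelengths")
    t = np.sort(df["time_s"].unique())
    if fs is None:
        fs = 1.0 / float(np.median(np.diff(t)))
    dod = np.empty((len(channels), 2, t.size))
    for c, ch in enumerate(channels):
        for w, wl in enumerate(wavelengths):
            sub = df[(df["channel"] == ch) & (df["wavelength_nm"] == wl)]
            dod[c, w] = sub.sort_values("time_s")["dod"].to_numpy()
    return FNIRSRecording(dod=dod, wavelengths_nm=wavelengths, fs=fs,
                          distances_cm=distances_cm,
                          channel_labels=channels, start_time_s=float(t[0]))


def write_fnirs_snirf(rec: FNIRSRecording, path: str | Path) -> None:
    """Write optical-density changes to a minimal SNIRF (HDF5) file.

    One data block with dataTypeLabel "dOD"; sources and detectors are laid
    out co-linearly at the recorded source-detector separations so readers
    can recover the channel geometry.
    """
    import h5py

    n_ch = rec.n_channels
    wl = list(rec.wavelengths_nm)
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs")
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(wl, dtype=float))
        src = np.zeros((n_ch, 3))
        det = np.zeros((n_ch, 3))
        src[:, 1] = np.arange(n_ch) * 10.0
        det[:, 1] = src[:, 1]
        det[:, 0] = rec.distances_cm
        probe.create_dataset("sourcePos3D", data=src)
        probe.create_dataset("detectorPos3D", data=det)
        data = nirs.create_group("data1")
        series = rec.dod.reshape(n_ch * 2, -1).T  # time x measurements
        data.create_dataset("dataTimeSeries", data=series)
        data.create_dataset("time", data=rec.times_s)
        k = 1
        for c in range(n_ch):
            for w in range(2):
                ml = data.create_group(f"measurementList{k}")
                ml.create_dataset("sourceIndex", data=c + 1)
                ml.create_dataset("detectorIndex", data=c + 1)
                ml.create_dataset("wavelengthIndex", data=w + 1)
                ml.create_dataset("dataType", data=99999)
                ml.create_dataset("dataTypeLabel", data="dOD")
                k += 1


def read_fnirs_snirf(path: str | Path) -> FNIRSRecording:
    """Read a SNIRF optical-density file (subset: one dOD data block)."""
    import h5py

    with h5py.File(path, "r") as f:
        nirs = f["nirs"]
        wavelengths = tuple(np.asarray(nirs["probe/wavelengths"][()],
                                       dtype=float))
        data = nirs["data1"]
        series = np.asarray(data["dataTimeSeries"][()])  # time x meas
        time = np.asarray(data["time"][()]).ravel()
        meas = []
        k = 1
        while f"measurementList{k}" in data:
            ml = data[f"measurementList{k}"]
            meas.append((int(ml["sourceIndex"][()]),
                         int(ml["detectorIndex"][()]),
                         int(ml["wavelengthIndex"][()])))
            k += 1
        src_pos = det_pos = None
        if "sourcePos3D" in nirs["probe"]:
            src_pos = np.asarray(nirs["probe/sourcePos3D"][()])
            det_pos = np.asarray(nirs["probe/detectorPos3D"][()])
    if len(wavelengths) != 2:
        raise ValueError("expected a two-wavelength recording")
    pairs = sorted({(s, d) for s, d, _ in meas})
    n_ch = len(pairs)
    dod = np.empty((n_ch, 2, time.size))
    for col, (s, d, w) in enumerate(meas):
        dod[pairs.index((s, d)), w - 1] = series[:, col]
    distances = 3.0
    if src_pos is not None:
        distances = np.array([
            np.linalg.norm(src_pos[s - 1] - det_pos[d - 1]) for s, d in pairs])
    fs = 1.0 / float(np.median(np.diff(time)))
    return FNIRSRecording(dod=dod, wavelengths_nm=wavelengths, fs=fs,
                          distances_cm=distances,
                          channel_labels=[f"S{s}-D{d}" for s, d in pairs],
                          start_time_s=float(time[0]))


def write_hemo_tsv(series: HemoSeries, path: str | Path) -> None:
    t = series.times_s
    frames = []
    for c, label in enumerate(series.channel_labels):
        frames.append(pd.DataFrame({
            "time_s": t, "channel": label,
            "hbo_um": series.hbo[c], "hbr_um": series.hbr[c]}))
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
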