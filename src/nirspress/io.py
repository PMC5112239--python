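"""File formats: a continuous-wave SNIRF subset, long-format CSV, tidy outputs.

SNIRF support is a documented subset of the HDF5-based standard: one
continuous-wave data block (``/nirs/data1``) with intensity time series and a
measurement list, probe wavelengths/positions, and stim blocks.  Long-format
CSV (columns ``time_s, channel, wavelength_nm, intensity``) is the canonical
text fallback.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .optics import HbSeries, RawIntensityRecording, SubjectMeta
from .protocol import ProbeLayout, StimulusProtocol


def write_snirf(recording: RawIntensityRecording, path: str | Path) -> None:
    layout = recording.layout
    n_ch, n_wl, n_t = recording.intensity.shape
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs")
        meta = nirs.create_group("metaDataTags")
        meta.create_dataset("SubjectID", data=recording.subject.id)
        meta.create_dataset("Group", data=recording.subject.group)
        meta.create_dataset("Age", data=float(recording.subject.age))
        meta.create_dataset("LengthUnit", data="mm")
        meta.create_dataset("TimeUnit", data="s")
        data1 = nirs.create_group("data1")
        # column order: (channel, wavelength) row-major
        flat = recording.intensity.reshape(n_ch * n_wl, n_t).T
        data1.create_dataset("dataTimeSeries", data=flat)
        data1.create_dataset("time", data=recording.time)
        k = 1
        for ci, cid in enumerate(layout.channel_ids):
            ch = layout.channel(cid)
            for wi in range(n_wl):
                ml = data1.create_group(f"measurementList{k}")
                ml.create_dataset("sourceIndex", data=ch.source)
                ml.create_dataset("detectorIndex", data=ch.detector)
                ml.create_dataset("wavelengthIndex", data=wi + 1)
                ml.create_dataset("dataType", data=1)  # CW amplitude
                ml.create_dataset("dataTypeIndex", data=1)
                ml.create_dataset("channelId", data=cid)
                k += 1
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(layout.wavelengths))
        # the layout carries no 3-D optode coordinates; store separations
        probe.create_dataset(
            "channelSeparations_mm",
            data=np.array([layout.channel(c).separation_mm
                           for c in layout.channel_ids]),
        )
        proto = recording.protocol
        if proto is not None and proto.sequence:
            for j, cond in enumerate(proto.conditions):
                stim = nirs.create_group(f"stim{j + 1}")
                stim.create_dataset("name", data=cond)
                onsets = [o for o, c in zip(proto.onsets(), proto.sequence)
                          if c == cond]
                stim.create_dataset(
                    "data",
                    data=np.column_stack([onsets,
                                          [proto.stimulus_s] * len(onsets),
                                          [1.0] * len(onsets)]),
                )


def read_snirf(path: str | Path, layout: ProbeLayout,
               protocol: StimulusProtocol | None = None) -> RawIntensityRecording:
    """Read the subset written by :func:`write_snirf`.

    The channel/wavelength structure must match ``layout``; stim blocks are
    reconciled into a protocol sequence when ``protocol`` is not given.
    """
    with h5py.File(path, "r") as f:
        if "nirs" not in f:
            raise ValueError(f"{path}: not a SNIRF file (missing /nirs)")
        nirs = f["nirs"]
        data1 = nirs["data1"]
        flat = np.asarray(data1["dataTimeSeries"])
        time = np.asarray(data1["time"])
        n_ch = len(layout.channels)
        n_wl = len(layout.wavelengths)
        if flat.shape[1] != n_ch * n_wl:
            raise ValueError(
                f"{path}: {flat.shape[1]} measurement columns, expected "
                f"{n_ch * n_wl} for the given layout"
            )
        intensity = flat.T.reshape(n_ch, n_wl, -1)
        meta = nirs["metaDataTags"]
        subject = SubjectMeta(
            id=_h5str(meta["SubjectID"]),
            group=_h5str(meta["Group"]) if "Group" in meta else "HC",
            age=float(meta["Age"][()]) if "Age" in meta else 30.0,
        )
        if protocol is None:
            protocol = _protocol_from_stim(nirs)
    return RawIntensityRecording(intensity=intensity, time=time, layout=layout,
                                 protocol=protocol, subject=subject)


def _h5str(ds) -> str:
    v = ds[()]
    return v.decode() if isinstance(v, bytes) else str(v)


def _protocol_from_stim(nirs) -> StimulusProtocol:
    events = []
    names = []
    for key in sorted(k for k in nirs.keys() if k.startswith("stim")):
        name = _h5str(nirs[key]["name"])
        names.append(name)
        for onset, dur, _ in np.asarray(nirs[key]["data"]):
            events.append((float(onset), float(dur), name))
    if not events:
        raise ValueError("SNIRF file has no stim blocks and no protocol given")
    events.sort()
    onsets = np.array([e[0] for e in events])
    stimulus_s = float(events[0][1])
    period = float(np.diff(onsets).min()) if len(onsets) > 1 else stimulus_s + 15.0
    proto = StimulusProtocol(
        baseline_s=float(onsets[0]),
        conditions=tuple(names),
        trials_per_condition=len(events) // len(names),
        stimulus_s=stimulus_s,
        isi_s=period - stimulus_s,
    )
    return proto.with_sequence([e[2] for e in events])


def write_intensity_csv(recording: RawIntensityRecording, path: str | Path) -> None:
    layout = recording.layout
    frames = []
    for ci, cid in enumerate(layout.channel_ids):
        for wi, wl in enumerate(layout.wavelengths):
            frames.append(pd.DataFrame({
                "time_s": recording.time,
                "channel": cid,
                "wavelength_nm": wl,
                "intensity": recording.intensity[ci, wi],
            }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_intensity_csv(path: str | Path, layout: ProbeLayout,
                       protocol: StimulusProtocol,
                       subject: SubjectMeta) -> RawIntensityRecording:
    df = pd.read_csv(path)
    required = {"time_s", "channel", "wavelength_nm", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    time = np.sort(df["time_s"].unique())
    n_t = time.size
    intensity = np.empty((len(layout.channels), len(layout.wavelengths), n_t))
    for ci, cid in enumerate(layout.channel_ids):
        for wi, wl in enumerate(layout.wavelengths):
            sub = df[(df["channel"] == cid) & (df["wavelength_nm"] == wl)]
            if len(sub) != n_t:
                raise ValueError(
                    f"{path}: channel {cid} @ {wl} nm has {len(sub)} samples, "
                    f"expected {n_t}"
                )
            intensity[ci, wi] = sub.sort_values("time_s")["intensity"].to_numpy()
    return RawIntensityRecording(intensity=intensity, time=time, layout=layout,
                                 protocol=protocol, subject=subject)


def write_hb_csv(series: HbSeries, path: str | Path) -> None:
    layout = series.layout
    frames = []
    for ci, cid in enumerate(layout.channel_ids):
        frames.append(pd.DataFrame({
            "time_s": series.time,
            "channel": cid,
            "o2hb_uM": series.o2hb[ci],
            "hhb_uM": series.hhb[ci],
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_epochs_csv(epoch_set, path: str | Path, subject_id: str = "") -> None:
    """Tidy per-sample epoch export."""
    layout = epoch_set.layout
    frames = []
    for e in epoch_set.epochs:
        t_rel = e.time_rel_onset()
        for ci, cid in enumerate(layout.channel_ids):
            frames.append(pd.DataFrame({
                "subject": subject_id,
                "condition": e.condition,
                "trial": e.trial_index,
                "channel": cid,
                "sample_index": np.arange(e.n_samples),
                "time_rel_onset_s": t_rel,
                "o2hb_uM": e.o2hb[ci],
                "hhb_uM": e.hhb[ci],
            }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_hr_csv(hr_series, path: str | Path) -> None:
    pd.DataFrame({"time_s": hr_series.time_s, "hr_bpm": hr_series.hr}).to_csv(
        path, index=False)


def read_hr_csv(path: str | Path, protocol: StimulusProtocol):
    from .behavior import HRSeries

    df = pd.read_csv(path)
    missing = {"time_s", "hr_bpm"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return HRSeries(time_s=df["time_s"].to_numpy(),
                    hr=df["hr_bpm"].to_numpy(), protocol=protocol)
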