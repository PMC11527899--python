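"""Session container I/O: SNIRF-layout HDF5 plus a JSON manifest.

A session directory holds ``session.h5`` — the two-wavelength fNIRS
intensity in SNIRF layout conventions (/nirs/data1) with the
accelerometer and respiration traces as auxiliary streams — and
``manifest.json`` carrying sample rates, montage, schedule, ground-truth
events, seeds and processing provenance.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .synthgen import (Channel, ChannelSet, HRFParams, NoiseParams,
                       ProtocolSpec, Schedule, Segment, SessionRecording)

__all__ = ["write_session", "read_session", "IntegrityError"]


class IntegrityError(RuntimeError):
    """Manifest and on-disk data disagree."""


def _channel_dict(ch: Channel) -> dict:
    return {"emitter": ch.emitter, "detector": ch.detector,
            "hemisphere": ch.hemisphere, "roi": ch.roi,
            "separation_cm": ch.separation_cm}


def _schedule_dict(s: Schedule) -> dict:
    return {
        "protocol": {
            "n_blocks": s.protocol.n_blocks,
            "positions": list(s.protocol.positions),
            "swallows_per_position_per_block":
                s.protocol.swallows_per_position_per_block,
            "inter_swallow_interval": s.protocol.inter_swallow_interval,
            "bolus_volume_ml": s.protocol.bolus_volume_ml,
            "bolus_duration_s": s.protocol.bolus_duration_s,
            "pump_rate_ml_min": s.protocol.pump_rate_ml_min,
            "inter_block_rest": s.protocol.inter_block_rest,
            "lead_in": s.protocol.lead_in,
            "lead_out": s.protocol.lead_out,
            "first_onset_offset": s.protocol.first_onset_offset,
        },
        "segments": [{"block": seg.block, "position": seg.position,
                      "start": seg.start, "end": seg.end,
                      "onsets": list(seg.onsets)} for seg in s.segments],
        "rests": [list(r) for r in s.rests],
        "duration": s.duration,
    }


def _schedule_from_dict(d: dict) -> Schedule:
    proto = ProtocolSpec(**{k: (tuple(v) if k == "positions" else v)
                            for k, v in d["protocol"].items()})
    segments = tuple(Segment(block=s["block"], position=s["position"],
                             start=s["start"], end=s["end"],
                             onsets=tuple(s["onsets"]))
                     for s in d["segments"])
    rests = tuple((r[0], r[1]) for r in d["rests"])
    return Schedule(protocol=proto, segments=segments, rests=rests,
                    duration=d["duration"])


def write_session(session: SessionRecording, outdir: str | Path) -> Path:
    """Write one session to a directory; returns the directory path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    n_wl, n_ch, n_t = session.intensity.shape
    fs = session.sample_rates

    with h5py.File(outdir / "session.h5", "w") as f:
        nirs = f.create_group("nirs")
        data1 = nirs.create_group("data1")
        # SNIRF convention: (time, measurement); measurement index runs
        # channel-major over (channel, wavelength)
        flat = session.intensity.transpose(1, 0, 2).reshape(n_ch * n_wl, n_t)
        data1.create_dataset("dataTimeSeries", data=flat.T)
        data1.create_dataset("time", data=np.arange(n_t) / fs["fnirs"])
        ml = data1.create_group("measurementList")
        chans = session.channels.all_channels
        ml.create_dataset("sourceIndex", data=np.repeat(
            [c.emitter for c in chans], n_wl))
        ml.create_dataset("detectorIndex", data=np.repeat(
            [c.detector for c in chans], n_wl))
        ml.create_dataset("wavelengthIndex", data=np.tile(
            np.arange(1, n_wl + 1), n_ch))
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths",
                             data=np.array(session.channels.wavelengths_nm))
        aux1 = nirs.create_group("aux1")
        aux1.create_dataset("name", data="accelerometer")
        aux1.create_dataset("dataTimeSeries", data=session.accel)
        aux1.create_dataset("samplingRate", data=fs["accel"])
        aux2 = nirs.create_group("aux2")
        aux2.create_dataset("name", data="respiration")
        aux2.create_dataset("dataTimeSeries", data=session.resp)
        aux2.create_dataset("samplingRate", data=fs["resp"])

    manifest = {
        "participant": session.participant,
        "sample_rates": fs,
        "seed": session.seed,
        "n_wavelengths": n_wl,
        "lengths": {"fnirs": n_t, "accel": len(session.accel),
                    "resp": len(session.resp)},
        "channels": {
            "long": [_channel_dict(c) for c in session.channels.long_channels],
            "short": [_channel_dict(c) for c in session.channels.short_channels],
            "wavelengths_nm": list(session.channels.wavelengths_nm),
        },
        "schedule": _schedule_dict(session.schedule),
        "truth_events": session.truth_events.to_dict(orient="records"),
        "truth_apneas": [list(a) for a in session.truth_apneas],
        "provenance": session.provenance,
        "files": {"signals": "session.h5"},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return outdir


def read_session(path: str | Path) -> SessionRecording:
    """Load a session directory, cross-checking lengths against the
    manifest; a mismatch raises :class:`IntegrityError`."""
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    schedule = _schedule_from_dict(manifest["schedule"])
    long_ch = tuple(Channel(**c) for c in manifest["channels"]["long"])
    short_ch = tuple(Channel(**c) for c in manifest["channels"]["short"])
    channels = ChannelSet(
        long_channels=long_ch, short_channels=short_ch,
        wavelengths_nm=tuple(manifest["channels"]["wavelengths_nm"]))
    if not short_ch:
        warnings.warn("session has no short-separation channels",
                      stacklevel=2)

    h5path = path / manifest["files"]["signals"]
    if not h5path.exists():
        raise IntegrityError(f"missing signal file {h5path}")
    with h5py.File(h5path, "r") as f:
        flat = f["nirs/data1/dataTimeSeries"][()].T
        accel = f["nirs/aux1/dataTimeSeries"][()]
        resp = f["nirs/aux2/dataTimeSeries"][()]

    n_wl = manifest["n_wavelengths"]
    n_ch = len(long_ch) + len(short_ch)
    lengths = manifest["lengths"]
    if flat.shape != (n_ch * n_wl, lengths["fnirs"]):
        raise IntegrityError(
            f"fNIRS data shape {flat.shape} does not match manifest "
            f"({n_ch * n_wl} measurements x {lengths['fnirs']} samples)")
    for name, sig in (("accel", accel), ("resp", resp)):
        if len(sig) != lengths[name]:
            raise IntegrityError(
                f"{name} stream has {len(sig)} samples, manifest declares "
                f"{lengths[name]}")
    intensity = flat.reshape(n_ch, n_wl, lengths["fnirs"]).transpose(1, 0, 2)

    return SessionRecording(
        participant=manifest["participant"], schedule=schedule,
        channels=channels, intensity=intensity, accel=accel, resp=resp,
        truth_events=pd.DataFrame(manifest["truth_events"]),
        truth_apneas=[tuple(a) for a in manifest["truth_apneas"]],
        sample_rates={k: float(v)
                      for k, v in manifest["sample_rates"].items()},
        seed=manifest["seed"], provenance=manifest["provenance"])
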