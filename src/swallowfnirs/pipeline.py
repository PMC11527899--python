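"""End-to-end driver: generate → detect → process → epoch → stats.

Single-session analysis and seeded multi-participant cohorts, all pure
functions of (config, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import hdr_epochs, nirs_core, physio_detect, stats_model, synthgen

log = logging.getLogger("swallowfnirs")


@dataclass
class SessionAnalysis:
    session: synthgen.SessionRecording
    events: list
    conc: synthgen.ConcentrationSeries
    epochs: hdr_epochs.EpochSet
    summary: pd.DataFrame            # participant x position x hemi x timing
    baselines: pd.DataFrame


def _build(section: dict | None, cls):
    return cls(**section) if section else cls()


def analyze_session(session: synthgen.SessionRecording,
                    config: dict | None = None) -> SessionAnalysis:
    """Run detection, processing and HDR summarisation on one session."""
    config = config or {}
    events = physio_detect.detect_swallows(session,
                                           **config.get("detect", {}))
    ev = physio_detect.events_frame(events)
    n_ok = int(ev["verified"].sum()) if len(ev) else 0
    log.info("detected %d onsets (%d assigned to position segments)",
             len(ev), n_ok)
    conc = nirs_core.process_session(session, **config.get("process", {}))
    epoch_cfg = config.get("epoch", {})
    epochs = hdr_epochs.extract_epochs(conc, ev,
                                       pre=epoch_cfg.get("pre", 10.0),
                                       post=epoch_cfg.get("post", 20.0))
    baselines = hdr_epochs.session_baselines(epochs, session.participant)
    epochs = hdr_epochs.baseline_normalize(epochs)
    scalars = hdr_epochs.median_hdr(
        epochs, window=tuple(epoch_cfg.get("window", (5.0, 20.0))))
    summary = hdr_epochs.aggregate(scalars, epochs.events, session.channels,
                                   session.participant)
    return SessionAnalysis(session=session, events=events, conc=conc,
                           epochs=epochs, summary=summary,
                           baselines=baselines)


def generate_cohort_session(participant_index: int, root_seed: int,
                            config: dict | None = None
                            ) -> synthgen.SessionRecording:
    config = config or {}
    seed = int(np.random.default_rng(
        [root_seed, participant_index]).integers(2**31))
    return synthgen.generate_session(
        participant=f"P{participant_index + 1:02d}",
        protocol=_build(config.get("protocol"), synthgen.ProtocolSpec),
        hrf=_build(config.get("hrf"), synthgen.HRFParams),
        noise=_build(config.get("noise"), synthgen.NoiseParams),
        seed=seed)


def run_all(config: dict | None = None, seed: int = 0,
            n_participants: int | None = None) -> dict:
    """Full signal-level pipeline over a cohort of synthetic sessions.

    Returns a dict with the pooled HDR summary, per-participant events,
    the baseline-consistency report (when >= 2 participants) and the
    backward-elimination model result (fitted on the first/last timing
    groups).
    """
    config = dict(config or {})
    if n_participants is None:
        n_participants = int(config.get("cohort", {}).get("n_participants", 1))
    summaries, baselines, all_events = [], [], {}
    for i in range(n_participants):
        session = generate_cohort_session(i, seed, config)
        out = analyze_session(session, config)
        summaries.append(out.summary)
        baselines.append(out.baselines)
        all_events[session.participant] = physio_detect.events_frame(
            out.events)
    summary = pd.concat(summaries, ignore_index=True)

    result: dict = {"hdr_summary": summary, "events": all_events}
    if n_participants >= 2:
        base = pd.concat(baselines, ignore_index=True)
        result["baseline_check"] = hdr_epochs.baseline_consistency_check(base)
        model_data = summary[summary["timing"].isin(["first", "last"])]
        spec = stats_model.ModelSpec(**config.get("stats", {}))
        result["model"] = stats_model.backward_eliminate(model_data, spec)
    return result


def model_report(model: stats_model.ModelResult) -> dict:
    """JSON-serialisable report of a fitted/eliminated model."""
    return {
        "retained_terms": model.retained_terms,
        "coefficients": [
            {"term": name, "estimate": float(row["estimate"]),
             "se": float(row["se"]), "p": float(row["p"])}
            for name, row in model.params.iterrows()],
        "elimination_path": [
            {k: (dict(v) if isinstance(v, dict) else v)
             for k, v in step.items()}
            for step in model.elimination_path],
        "contrasts": (model.contrasts.to_dict(orient="records")
                      if model.contrasts is not None else None),
        "fit_log": model.fit_log,
    }
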