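"""Event-related epoching and median hemodynamic-response summaries.

Epochs of ΔHbO are cut from −10 s to +20 s around each swallow onset,
baseline-normalised to the mean of the −10..0 s window, summarised as
the median over the 5..20 s response window, and aggregated per
participant × head position × hemisphere × timing group (first two /
last two / all swallows of each position segment).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .physio_detect import SwallowEvent
from .synthgen import ChannelSet, ConcentrationSeries, ConfigurationError

__all__ = [
    "EpochSet",
    "extract_epochs",
    "baseline_normalize",
    "median_hdr",
    "aggregate",
    "grand_average",
    "baseline_consistency_check",
]

TIMING_FIRST = (1, 2)
TIMING_LAST = (7, 8)


@dataclass
class EpochSet:
    """Event-locked ΔHbO epochs: (n_events, n_channels, n_samples)."""

    data: np.ndarray
    tau: np.ndarray                      # seconds relative to onset
    events: pd.DataFrame                 # onset, block, position, ordinal, ...
    channels: tuple
    sample_rate: float
    baseline_applied: bool = False

    def __post_init__(self) -> None:
        if self.data.shape != (len(self.events), len(self.channels),
                               len(self.tau)):
            raise ValueError("epoch array shape inconsistent with metadata")

    def __len__(self) -> int:
        return len(self.events)


def _events_to_frame(events) -> pd.DataFrame:
    if isinstance(events, pd.DataFrame):
        return events.reset_index(drop=True)
    return pd.DataFrame([{
        "onset": e.onset, "block": e.block, "position": e.position,
        "ordinal": e.ordinal, "verified": e.verified}
        for e in events])


def extract_epochs(conc: ConcentrationSeries, events,
                   pre: float = 10.0, post: float = 20.0) -> EpochSet:
    """Cut per-event windows [−pre, +post] from every long channel.

    Events whose window would run past either end of the record are
    dropped with a warning.  Unverified events (rest-period detections)
    are excluded.
    """
    ev = _events_to_frame(events)
    if "verified" in ev.columns:
        ev = ev[ev["verified"].fillna(True)].reset_index(drop=True)
    fs = conc.sample_rate
    n_pre, n_post = int(round(pre * fs)), int(round(post * fs))
    tau = np.arange(-n_pre, n_post + 1) / fs
    n_t = conc.hbo.shape[1]

    keep, slices = [], []
    for i, onset in enumerate(ev["onset"] if len(ev) else []):
        c = int(round(onset * fs))
        if c - n_pre < 0 or c + n_post >= n_t:
            continue
        keep.append(i)
        slices.append(conc.hbo[:, c - n_pre:c + n_post + 1])
    n_dropped = len(ev) - len(keep)
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} event(s) whose epoch window "
                      "exceeds the record bounds", stacklevel=2)
    data = (np.stack(slices) if slices
            else np.empty((0, conc.hbo.shape[0], len(tau))))
    return EpochSet(data=data, tau=tau,
                    events=ev.iloc[keep].reset_index(drop=True),
                    channels=conc.channels, sample_rate=fs)


def baseline_means(epochs: EpochSet) -> np.ndarray:
    """Mean over the baseline window τ ∈ [−pre, 0) per event × channel."""
    mask = epochs.tau < 0
    return epochs.data[:, :, mask].mean(axis=2)


def baseline_normalize(epochs: EpochSet) -> EpochSet:
    """Subtract each epoch/channel's mean over τ ∈ [−10, 0).

    The onset sample (τ = 0) is excluded from the baseline.  After
    normalisation the baseline-window mean is exactly zero.  Applying
    twice is an error.
    """
    if epochs.baseline_applied:
        raise ValueError("baseline normalisation already applied")
    base = baseline_means(epochs)
    return EpochSet(data=epochs.data - base[:, :, None], tau=epochs.tau,
                    events=epochs.events, channels=epochs.channels,
                    sample_rate=epochs.sample_rate, baseline_applied=True)


def median_hdr(epochs: EpochSet,
               window: tuple[float, float] = (5.0, 20.0)) -> np.ndarray:
    """Median ΔHbO over the response window, per event × channel (µM)."""
    if not epochs.baseline_applied:
        raise ValueError("baseline-normalise epochs before summarising")
    lo, hi = window
    if lo < epochs.tau[0] or hi > epochs.tau[-1] or lo >= hi:
        raise ConfigurationError(
            f"window {window} outside the epoch span "
            f"[{epochs.tau[0]}, {epochs.tau[-1]}]")
    mask = (epochs.tau >= lo) & (epochs.tau <= hi)
    return np.median(epochs.data[:, :, mask], axis=2)


def aggregate(scalars: np.ndarray, events: pd.DataFrame,
              channels: ChannelSet | tuple, participant: str) -> pd.DataFrame:
    """Per-event/channel medians → participant × position × hemisphere ×
    timing summary table.

    Each cell is the arithmetic mean of the per-channel median values
    over that hemisphere's channels and the events in the timing group:
    ``first`` = within-segment ordinals 1-2, ``last`` = 7-8, ``all`` =
    every swallow of the position segments.
    """
    ch_list = (channels.long_channels if isinstance(channels, ChannelSet)
               else tuple(channels))
    hemis = np.array([ch.hemisphere for ch in ch_list])
    if not set(hemis) <= {"L", "R"}:
        raise ValueError("every channel needs an L/R hemisphere label")
    if scalars.shape != (len(events), len(ch_list)):
        raise ValueError("scalar array shape inconsistent with events/channels")

    ords = events["ordinal"].to_numpy()
    groups = {"first": np.isin(ords, TIMING_FIRST),
              "last": np.isin(ords, TIMING_LAST),
              "all": np.ones(len(events), dtype=bool)}
    rows = []
    for pos in pd.unique(events["position"].dropna()):
        pos_mask = (events["position"] == pos).to_numpy()
        for hemi in ("L", "R"):
            cols = hemis == hemi
            for timing, tmask in groups.items():
                sel = pos_mask & tmask
                if not sel.any() or not cols.any():
                    continue
                rows.append({"participant": participant, "position": pos,
                             "hemisphere": hemi, "timing": timing,
                             "oxyhb": float(scalars[np.ix_(sel, cols)].mean())})
    return pd.DataFrame(rows)


def grand_average(epochs: EpochSet, by: str = "position") -> pd.DataFrame:
    """Pointwise mean time course (and SEM over events) per condition."""
    rows = []
    for level in pd.unique(epochs.events[by].dropna()):
        mask = (epochs.events[by] == level).to_numpy()
        traces = epochs.data[mask].mean(axis=1)      # mean over channels
        mean = traces.mean(axis=0)
        sem = (traces.std(axis=0, ddof=1) / np.sqrt(mask.sum())
               if mask.sum() > 1 else np.zeros_like(mean))
        for t, m, s in zip(epochs.tau, mean, sem):
            rows.append({by: level, "tau": t, "mean": m, "sem": s})
    return pd.DataFrame(rows)


def baseline_consistency_check(baselines: pd.DataFrame,
                               alpha: float = 0.05) -> pd.DataFrame:
    """Verify baselines do not drift from block start to block end.

    ``baselines`` is a tidy table (participant, position, timing,
    baseline) with timing in {first, last}; for each head position the
    participant-level first-vs-last baseline means are compared with a
    paired two-sided t-test.  Returns per-position p-values and a pass
    flag (p > alpha).  Identical baselines make the test degenerate and
    are reported as a pass.
    """
    if baselines["participant"].nunique() < 2:
        raise ValueError("need at least two participants")
    out = []
    for pos, grp in baselines.groupby("position", sort=False):
        wide = (grp.groupby(["participant", "timing"])["baseline"].mean()
                .unstack("timing"))
        if not {"first", "last"} <= set(wide.columns):
            raise ValueError(f"position {pos}: need both timing groups")
        diff = wide["last"] - wide["first"]
        if np.allclose(diff.std(ddof=1), 0.0) and np.allclose(diff.mean(), 0.0):
            p = 1.0       # no drift at all: degenerate test counts as pass
        else:
            p = float(stats.ttest_rel(wide["last"], wide["first"]).pvalue)
        out.append({"position": pos, "mean_drift": float(diff.mean()),
                    "p_value": p, "consistent": bool(p > alpha)})
    return pd.DataFrame(out)


def session_baselines(epochs: EpochSet, participant: str) -> pd.DataFrame:
    """Per-event baseline means labelled with timing group, for the
    baseline-consistency check (pre-normalisation epochs)."""
    base = baseline_means(epochs).mean(axis=1)       # mean over channels
    ords = epochs.events["ordinal"].to_numpy()
    timing = np.where(np.isin(ords, TIMING_FIRST), "first",
                      np.where(np.isin(ords, TIMING_LAST), "last", "mid"))
    df = pd.DataFrame({"participant": participant,
                       "position": epochs.events["position"],
                       "timing": timing, "baseline": base})
    return df[df["timing"] != "mid"].reset_index(drop=True)
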