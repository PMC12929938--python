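"""Threshold-based delay classifiers (moving-SD and spectral entropy).

Both rules operate on the tail region of an event (fractional position >=
``frac_position``, default 0.7) where probe-target delays occur:

* **MSD rule** — the min-max-normalized trace is split into ``total_bins``
  bins; an event is delayed iff some bin at fractional position >=
  ``frac_position`` starts a run of more than ``min_run_bins`` consecutive
  bins whose sample SD is below ``sigma_threshold``.
* **SE rule** — an event is delayed iff any spectrogram frame centered past
  ``frac_position`` has instantaneous spectral entropy below ``se_threshold``.

Each call also carries a continuous score (the regional minimum bin-SD or
frame-SE; lower = more delayed) so ROC curves can be computed for the rule
methods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, IndeterminateEventError
from .features import SpectrogramSpec, instantaneous_se, msd_profile, normalize_trace
from .sim import EventTrace

__all__ = [
    "MsdParams",
    "SeParams",
    "DelayCall",
    "classify_msd",
    "classify_se",
    "sweep_threshold",
    "dynamic_range",
    "calls_to_frame",
]


@dataclass(frozen=True)
class MsdParams:
    sigma_threshold: float = 0.003
    total_bins: int = 75
    min_run_bins: int = 10
    frac_position: float = 0.7
    # If True a qualifying run may begin before frac_position as long as it
    # reaches into the region; default requires the run to start inside it.
    run_may_straddle: bool = False

    def validate(self) -> None:
        if self.sigma_threshold <= 0:
            raise ConfigurationError("sigma_threshold must be > 0")
        if self.min_run_bins > self.total_bins:
            raise ConfigurationError("min_run_bins must be <= total_bins")
        if not (0.0 <= self.frac_position <= 1.0):
            raise ConfigurationError("frac_position must be in [0, 1]")


@dataclass(frozen=True)
class SeParams:
    se_threshold: float = 0.495
    frac_position: float = 0.7
    spec: SpectrogramSpec = field(default_factory=SpectrogramSpec)

    def validate(self) -> None:
        if not (0.0 < self.se_threshold < 1.0):
            raise ConfigurationError("se_threshold must be in (0, 1)")
        if not (0.0 <= self.frac_position <= 1.0):
            raise ConfigurationError("frac_position must be in [0, 1]")


@dataclass
class DelayCall:
    """Binary delay call with localization and a continuous evidence score."""

    event_id: str
    label: str  # 'delayed' | 'non_delayed'
    score: float  # lower = more delayed
    method: str  # 'msd' | 'se' | 'cnn'
    delay_start_frac: float | None = None
    run_length: int | None = None


def _run_lengths_from(below: np.ndarray) -> np.ndarray:
    """For each index, length of the run of True values starting there."""
    n = below.size
    run = np.zeros(n, dtype=int)
    for i in range(n - 1, -1, -1):
        if below[i]:
            run[i] = 1 + (run[i + 1] if i + 1 < n else 0)
    return run


def _msd_decide(
    sigma: np.ndarray, start_fracs: np.ndarray, p: MsdParams
) -> tuple[bool, float, float | None, int | None]:
    below = sigma < p.sigma_threshold
    runs = _run_lengths_from(below)
    in_region = start_fracs >= p.frac_position
    region_scores = sigma[in_region]
    score = float(region_scores.min()) if region_scores.size else float("nan")
    if p.run_may_straddle:
        # a run qualifies if any of its bins lies in the region
        qualifying = [
            i
            for i in np.flatnonzero(below & (runs > p.min_run_bins))
            if start_fracs[min(i + runs[i] - 1, sigma.size - 1)] >= p.frac_position
        ]
    else:
        qualifying = np.flatnonzero(in_region & below & (runs > p.min_run_bins))
    if len(qualifying) == 0:
        return False, score, None, None
    first = int(np.min(qualifying))
    return True, score, float(start_fracs[first]), int(runs[first])


def classify_msd(trace: EventTrace, p: MsdParams = MsdParams()) -> DelayCall:
    """Apply the moving-SD rule to one event."""
    p.validate()
    z = normalize_trace(trace)
    prof = msd_profile(z, p.total_bins)
    n = len(trace)
    start_fracs = np.array([a / n for a, _ in prof.bin_edges])
    delayed, score, start, run = _msd_decide(prof.sigma_bins, start_fracs, p)
    return DelayCall(
        event_id=trace.event_id,
        label="delayed" if delayed else "non_delayed",
        score=score,
        method="msd",
        delay_start_frac=start,
        run_length=run,
    )


def classify_se(trace: EventTrace, p: SeParams = SeParams()) -> DelayCall:
    """Apply the spectral-entropy rule to one event.

    Raises :class:`IndeterminateEventError` when no spectrogram frame lands
    past ``frac_position`` (events too short for the window carry a known
    length bias and are reported rather than silently called non-delayed).
    """
    p.validate()
    se = instantaneous_se(trace, p.spec)
    region = se.frame_fracs > p.frac_position
    if not np.any(region):
        raise IndeterminateEventError(
            f"{trace.event_id}: no spectrogram frame beyond frac {p.frac_position}"
        )
    vals = se.se_values[region]
    fracs = se.frame_fracs[region]
    score = float(vals.min())
    below = vals < p.se_threshold
    if not np.any(below):
        return DelayCall(trace.event_id, "non_delayed", score, "se")
    first = int(np.argmax(below))
    run = int(_run_lengths_from(below)[first])
    return DelayCall(
        trace.event_id,
        "delayed",
        score,
        "se",
        delay_start_frac=float(fracs[first]),
        run_length=run,
    )


def calls_to_frame(calls: Iterable[DelayCall]) -> pd.DataFrame:
    """Flatten calls into the TSV-ready table layout."""
    return pd.DataFrame(
        [
            {
                "event_id": c.event_id,
                "method": c.method,
                "label": c.label,
                "score": c.score,
                "delay_start_frac": c.delay_start_frac,
                "run_length": c.run_length,
            }
            for c in calls
        ]
    )


def _default_group(ev: EventTrace):
    return ev.meta.get("concentration", "all")


def sweep_threshold(
    events: Sequence[EventTrace],
    method: str,
    thresholds: Sequence[float],
    group_by: Callable[[EventTrace], object] = _default_group,
    msd_params: MsdParams = MsdParams(),
    se_params: SeParams = SeParams(),
) -> pd.DataFrame:
    """Percentage of events called delayed, per threshold and per group.

    The per-event bin profiles / SE traces are computed once and the rule is
    re-evaluated per threshold, so the sweep scales with the threshold grid
    only through the cheap decision step.  Columns: group, threshold,
    pct_delayed, n_events.  Both rules are monotone: a higher threshold can
    only add delayed calls.
    """
    if method not in ("msd", "se"):
        raise ConfigurationError("method must be 'msd' or 'se'")
    groups: dict[object, list[EventTrace]] = {}
    for ev in events:
        groups.setdefault(group_by(ev), []).append(ev)

    rows = []
    for gkey, evs in sorted(groups.items(), key=lambda kv: str(kv[0])):
        if not evs:
            warnings.warn(f"group {gkey!r} is empty; excluded from sweep")
            continue
        if method == "msd":
            cached = []
            for ev in evs:
                prof = msd_profile(normalize_trace(ev), msd_params.total_bins)
                fr = np.array([a / len(ev) for a, _ in prof.bin_edges])
                cached.append((prof.sigma_bins, fr))
            for thr in thresholds:
                p = MsdParams(
                    sigma_threshold=float(thr),
                    total_bins=msd_params.total_bins,
                    min_run_bins=msd_params.min_run_bins,
                    frac_position=msd_params.frac_position,
                    run_may_straddle=msd_params.run_may_straddle,
                )
                n_del = sum(_msd_decide(s, f, p)[0] for s, f in cached)
                rows.append(
                    {
                        "group": gkey,
                        "threshold": float(thr),
                        "pct_delayed": 100.0 * n_del / len(evs),
                        "n_events": len(evs),
                    }
                )
        else:
            mins = []
            for ev in evs:
                se = instantaneous_se(ev, se_params.spec)
                region = se.frame_fracs > se_params.frac_position
                if not np.any(region):
                    continue  # indeterminate: too short for the decision region
                mins.append(se.se_values[region].min())
            if not mins:
                warnings.warn(f"group {gkey!r} has no determinate events; excluded")
                continue
            mins_arr = np.array(mins)
            for thr in thresholds:
                rows.append(
                    {
                        "group": gkey,
                        "threshold": float(thr),
                        "pct_delayed": 100.0 * float(np.mean(mins_arr < thr)),
                        "n_events": int(mins_arr.size),
                    }
                )
    return pd.DataFrame(rows)


def dynamic_range(sweep: pd.DataFrame, high_group, low_group) -> pd.DataFrame:
    """Per-threshold difference in %% delayed between two groups.

    The paper-style selection criterion: the threshold window maximizing
    (%% delayed at the highest concentration − %% delayed at blank).
    """
    present = set(sweep["group"].unique())
    for g in (high_group, low_group):
        if g not in present:
            raise DataError(f"group {g!r} missing from sweep table")
    pivot = sweep.pivot_table(index="threshold", columns="group", values="pct_delayed")
    out = pd.DataFrame(
        {
            "threshold": pivot.index.to_numpy(),
            "dynamic_range": (pivot[high_group] - pivot[low_group]).to_numpy(),
        }
    )
    return out.reset_index(drop=True)
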