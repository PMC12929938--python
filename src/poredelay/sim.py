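"""Synthetic nanopore translocation-event generator.

Emulates the two signal classes produced by DNA-barcoded probes in a
solid-state/protein nanopore assay sampled at 5 kHz:

* **non-delayed** events — a piecewise-constant stepped background (the
  barcode's current levels) with broadband within-block noise, flanked by two
  short C3-spacer-like excursions that touch the extremes of the 200-700 pA
  acquisition band;
* **delayed** events — identical structure except for one contiguous
  low-variability plateau (the stalled probe-target duplex) starting at a
  fractional position >= 0.70.  The in-delay residual noise is modeled as a
  slow baseline wander (smoothed Gaussian noise), not white noise: a stalled
  complex suppresses the broadband translocation noise but leaves low-frequency
  drift, which is what gives real delays their low spectral entropy.

A parameterized "noisy delay" contaminant adds zero-mean broadband bursts
inside the delay segment while keeping its mean level, reproducing the failure
mode in which moving-standard-deviation thresholding misses true delays.

All generators are deterministic for a fixed seed and draw every random number
from one `numpy.random.Generator` per call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = [
    "SimConfig",
    "EventTrace",
    "CohortSpec",
    "generate_event",
    "generate_dataset",
    "generate_dose_response",
    "generate_reads",
    "hill_response",
]

LABELS = ("delayed", "non_delayed", "unknown")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the event simulator (currents in pA, lengths in samples)."""

    sampling_rate_hz: float = 5000.0
    base_level_pA: float = 450.0
    band_low_pA: float = 200.0
    band_high_pA: float = 700.0
    event_len_range: tuple[int, int] = (1500, 4000)
    step_block_len_range: tuple[int, int] = (150, 400)
    step_amp_sd_pA: float = 15.0
    noise_sd_pA: float = 12.0
    delay_onset_frac_range: tuple[float, float] = (0.70, 0.80)
    delay_len_frac_range: tuple[float, float] = (0.17, 0.25)
    delay_noise_sd_pA: float = 1.5
    delay_wander_len: int = 151
    noisy_delay_prob: float = 0.0
    noisy_delay_burst_sd_pA: float = 10.0
    spacer_len_range: tuple[int, int] = (8, 16)
    seed: int = 0

    def validate(self) -> None:
        if not (self.band_low_pA < self.base_level_pA < self.band_high_pA):
            raise ConfigurationError(
                "band_low_pA < base_level_pA < band_high_pA is required"
            )
        for name in ("event_len_range", "step_block_len_range", "spacer_len_range"):
            lo, hi = getattr(self, name)
            if lo >= hi:
                raise ConfigurationError(f"{name}: low >= high ({lo} >= {hi})")
        for name in ("delay_onset_frac_range", "delay_len_frac_range"):
            lo, hi = getattr(self, name)
            if not (0.0 <= lo < hi <= 1.0):
                raise ConfigurationError(f"{name} must satisfy 0 <= low < high <= 1")
        if self.delay_noise_sd_pA >= self.noise_sd_pA:
            raise ConfigurationError(
                "delay_noise_sd_pA must be below noise_sd_pA "
                "(the delay segment is quieter by construction)"
            )
        if not (0.0 <= self.noisy_delay_prob <= 1.0):
            raise ConfigurationError("noisy_delay_prob must be a probability")
        if min(self.noise_sd_pA, self.noisy_delay_burst_sd_pA, self.step_amp_sd_pA) < 0:
            raise ConfigurationError("noise standard deviations must be non-negative")
        if self.event_len_range[0] < 64:
            raise ConfigurationError("events must have at least 64 samples")


@dataclass
class EventTrace:
    """One translocation event: raw ionic current samples plus metadata."""

    event_id: str
    samples: np.ndarray
    sampling_rate_hz: float = 5000.0
    label: str = "unknown"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size < 64:
            raise ConfigurationError("EventTrace requires >= 64 samples")
        if self.label not in LABELS:
            raise ConfigurationError(f"label must be one of {LABELS}")
        if self.label == "delayed" and "true_onset_frac" not in self.meta:
            raise ConfigurationError("delayed events must carry meta['true_onset_frac']")

    def __len__(self) -> int:
        return int(self.samples.size)


def _smooth_noise(rng: np.random.Generator, m: int, sd: float, length: int) -> np.ndarray:
    """Zero-mean Gaussian noise low-passed by a moving average, rescaled to `sd`."""
    if sd == 0.0 or m == 0:
        return np.zeros(m)
    raw = rng.normal(0.0, 1.0, m + length - 1)
    smooth = np.convolve(raw, np.ones(length) / length, mode="valid")
    realized = smooth.std()
    if realized == 0.0:  # pathological short segment
        return np.zeros(m)
    return smooth * (sd / realized)


def generate_event(cfg: SimConfig, cls: str, seed: int) -> EventTrace:
    """Generate one labeled event of class ``cls`` ('delayed' or 'non_delayed')."""
    cfg.validate()
    if cls not in ("delayed", "non_delayed"):
        raise ConfigurationError(f"cls must be 'delayed' or 'non_delayed', got {cls!r}")
    rng = np.random.default_rng(seed)
    n = int(rng.integers(cfg.event_len_range[0], cfg.event_len_range[1] + 1))

    # stepped barcode-like background
    lens: list[int] = []
    levels: list[float] = []
    total = 0
    lo_b, hi_b = cfg.step_block_len_range
    while total < n:
        blk = int(rng.integers(lo_b, hi_b + 1))
        lens.append(blk)
        levels.append(cfg.base_level_pA + rng.normal(0.0, cfg.step_amp_sd_pA))
        total += blk
    level_track = np.repeat(levels, lens)[:n]
    x = level_track + rng.normal(0.0, cfg.noise_sd_pA, n)

    # C3-spacer-like excursions: one high spike near the start, one low dip
    # near the end of the event; they pin the per-event dynamic range.
    s_lo, s_hi = cfg.spacer_len_range
    p1 = int(n * rng.uniform(0.02, 0.05))
    w1 = int(rng.integers(s_lo, s_hi + 1))
    x[p1 : p1 + w1] = cfg.band_high_pA - 5.0 + rng.normal(0.0, 2.0, min(w1, n - p1))
    spacer2_frac = rng.uniform(0.97, 0.985)
    p2 = int(n * spacer2_frac)
    w2 = min(int(rng.integers(s_lo, s_hi + 1)), n - p2)
    x[p2 : p2 + w2] = cfg.band_low_pA + 5.0 + rng.normal(0.0, 2.0, w2)

    meta: dict = {"noisy_delay": False}
    if cls == "delayed":
        o_lo, o_hi = cfg.delay_onset_frac_range
        l_lo, l_hi = cfg.delay_len_frac_range
        len_frac = rng.uniform(l_lo, l_hi)
        # keep the whole delay ahead of the second spacer feature
        onset_hi = min(o_hi, spacer2_frac - 0.005 - len_frac)
        onset_frac = rng.uniform(o_lo, max(o_lo + 1e-9, onset_hi))
        start = int(onset_frac * n)
        end = min(start + int(len_frac * n), p2 - 1)
        end = max(end, start + 2)
        plateau = float(
            np.clip(level_track[start], cfg.band_low_pA + 10, cfg.band_high_pA - 10)
        )
        x[start:end] = plateau + _smooth_noise(
            rng, end - start, cfg.delay_noise_sd_pA, cfg.delay_wander_len
        )
        if rng.random() < cfg.noisy_delay_prob:
            meta["noisy_delay"] = True
            pos = start
            while pos < end:
                pos += int(rng.integers(30, 80))
                burst = int(rng.integers(20, 60))
                hi = min(pos + burst, end)
                if pos < end:
                    x[pos:hi] += rng.normal(0.0, cfg.noisy_delay_burst_sd_pA, hi - pos)
                pos = hi
        meta["true_onset_frac"] = start / n
        meta["true_len_frac"] = (end - start) / n

    np.clip(x, cfg.band_low_pA, cfg.band_high_pA, out=x)
    return EventTrace(
        event_id=f"ev-{seed}",
        samples=x,
        sampling_rate_hz=cfg.sampling_rate_hz,
        label=cls,
        meta=meta,
    )


def _child_seeds(seed: int, n: int) -> np.ndarray:
    """Deterministic per-event seeds (< 2**31) from one master seed."""
    return np.random.SeedSequence(seed).generate_state(n) % (2**31)


def generate_dataset(
    cfg: SimConfig, n_delayed: int, n_nondelayed: int, seed: int
) -> list[EventTrace]:
    """Labeled event list with exact class counts, shuffled deterministically."""
    if n_delayed < 0 or n_nondelayed < 0:
        raise ConfigurationError("class counts must be >= 0")
    total = n_delayed + n_nondelayed
    seeds = _child_seeds(seed, total + 1)
    events = []
    for i in range(total):
        cls = "delayed" if i < n_delayed else "non_delayed"
        ev = generate_event(cfg, cls, int(seeds[i]))
        ev.event_id = f"ev{i:05d}"
        events.append(ev)
    order = np.random.default_rng(int(seeds[-1])).permutation(total)
    return [events[i] for i in order]


def hill_response(conc: float, vmax: float, ke: float, nh: float) -> float:
    """Hill binding curve ``vmax * C**nh / (ke**nh + C**nh)`` (0 at C=0)."""
    if conc <= 0:
        return 0.0
    return vmax * conc**nh / (ke**nh + conc**nh)


@dataclass(frozen=True)
class CohortSpec:
    """Concentration cohort whose delayed fractions follow a Hill curve."""

    concentrations_nM: tuple[float, ...] = (0.0, 0.25, 1.0, 2.5, 10.0, 100.0)
    n_events_per_conc: int = 200
    n_replicates: int = 3
    hill_nh: float = 2.25
    hill_ke_nM: float = 1.19
    hill_vmax_pct: float = 36.59
    baseline_pct: float = 0.0

    def validate(self) -> None:
        if any(c < 0 for c in self.concentrations_nM):
            raise ConfigurationError("concentrations must be non-negative")
        if self.n_events_per_conc < 1 or self.n_replicates < 1:
            raise ConfigurationError("cohort sizes must be positive")
        if min(self.hill_nh, self.hill_ke_nM) <= 0 or self.hill_vmax_pct <= 0:
            raise ConfigurationError("Hill parameters must be positive")
        if self.baseline_pct < 0:
            raise ConfigurationError("baseline_pct must be non-negative")
        if self.expected_pct(max(self.concentrations_nM, default=0.0)) > 100.0:
            raise ConfigurationError("expected delayed fraction exceeds 100%")

    def expected_pct(self, conc: float) -> float:
        """Expected percentage of delayed events at concentration ``conc`` (nM)."""
        return self.baseline_pct + hill_response(
            conc, self.hill_vmax_pct, self.hill_ke_nM, self.hill_nh
        )


def generate_dose_response(
    cohort: CohortSpec, cfg: SimConfig, seed: int
) -> tuple[dict[tuple[float, int], list[EventTrace]], pd.DataFrame]:
    """Simulate a concentration cohort.

    Each event in the (concentration, replicate) cell is delayed with the
    Hill-given probability.  Returns the grouped events and a ground-truth
    table with columns conc_nM, replicate, n_events, n_delayed, expected_pct.
    """
    cohort.validate()
    cfg.validate()
    n_cells = len(cohort.concentrations_nM) * cohort.n_replicates
    cell_seeds = _child_seeds(seed, n_cells)
    groups: dict[tuple[float, int], list[EventTrace]] = {}
    rows = []
    k = 0
    for conc in cohort.concentrations_nM:
        p = cohort.expected_pct(conc) / 100.0
        for rep in range(1, cohort.n_replicates + 1):
            rng = np.random.default_rng(int(cell_seeds[k]))
            ev_seeds = _child_seeds(int(cell_seeds[k]) + 1, cohort.n_events_per_conc)
            k += 1
            cell = []
            n_del = 0
            for j in range(cohort.n_events_per_conc):
                cls = "delayed" if rng.random() < p else "non_delayed"
                n_del += cls == "delayed"
                ev = generate_event(cfg, cls, int(ev_seeds[j]))
                ev.event_id = f"c{conc:g}-r{rep}-ev{j:04d}"
                ev.meta.update(concentration=conc, replicate=rep)
                cell.append(ev)
            groups[(conc, rep)] = cell
            rows.append(
                {
                    "conc_nM": conc,
                    "replicate": rep,
                    "n_events": cohort.n_events_per_conc,
                    "n_delayed": n_del,
                    "expected_pct": cohort.expected_pct(conc),
                }
            )
    return groups, pd.DataFrame(rows)


_BASES = np.array(list("ACGT"))


def generate_reads(
    n: int,
    error_rate: float,
    seed: int,
    barcode: str | None = None,
    flank_len_range: tuple[int, int] = (20, 60),
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Simulate basecalled reads embedding the reference barcode.

    Substitutions hit each barcode base with probability ``error_rate``;
    insertions and deletions occur at a tenth of that rate per position.
    Returns ``[(read_id, sequence), ...]`` plus a per-read truth table of
    edit counts.
    """
    if not (0.0 <= error_rate < 0.5):
        raise ConfigurationError("error rate must be in [0, 0.5)")
    if barcode is None:
        from .barcode import BARCODE

        barcode = BARCODE
    rng = np.random.default_rng(seed)
    indel_rate = error_rate / 10.0
    reads = []
    rows = []
    for i in range(n):
        lflank = "".join(rng.choice(_BASES, int(rng.integers(*flank_len_range))))
        rflank = "".join(rng.choice(_BASES, int(rng.integers(*flank_len_range))))
        core = []
        n_sub = n_ins = n_del = 0
        for base in barcode:
            if rng.random() < indel_rate:
                n_del += 1
                continue
            if rng.random() < error_rate:
                n_sub += 1
                core.append(str(rng.choice(_BASES[_BASES != base])))
            else:
                core.append(base)
            if rng.random() < indel_rate:
                n_ins += 1
                core.append(str(rng.choice(_BASES)))
        reads.append((f"read{i:05d}", lflank + "".join(core) + rflank))
        rows.append(
            {"read_id": f"read{i:05d}", "n_sub": n_sub, "n_ins": n_ins, "n_del": n_del}
        )
    return reads, pd.DataFrame(rows)
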