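"""End-to-end orchestration.

``run_benchmark`` reproduces the three-way comparison protocol: simulate
disjoint train/validation/blind sets, train the CNN, classify the blind set
with all three methods and tabulate confusion matrices, metric sets and the
min-max radar table.  The blind set is generated independently of any
classifier output, and an event-id audit enforces that no blind event was
seen in training.

``run_dose_response`` classifies a simulated concentration cohort, computes
% delayed per (concentration, replicate), applies MAD outlier exclusion and
per-replicate baseline correction, and fits the Hill equation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .barcode import ScoringScheme
from .cnn import CLASS_NAMES, CnnSpec, ModelHandle, TrainConfig, predict, train
from .errors import ConfigurationError, DataError, IndeterminateEventError
from .features import SpectrogramSpec
from .images import render_dataset
from .rules import MsdParams, SeParams, classify_msd, classify_se
from .sim import CohortSpec, SimConfig, generate_dataset, generate_dose_response
from .stats import (
    ConfusionCounts,
    MetricSet,
    baseline_correct,
    compute_metrics,
    confusion,
    fit_hill,
    mad_filter,
    minmax_radar,
    summarize,
)

__all__ = ["RunConfig", "BenchmarkReport", "run_benchmark", "run_dose_response",
           "write_manifest"]


@dataclass
class RunConfig:
    """Fully serializable configuration of a benchmark/dose run."""

    sim: SimConfig = field(default_factory=SimConfig)
    msd: MsdParams = field(default_factory=MsdParams)
    se: SeParams = field(default_factory=SeParams)
    cnn: CnnSpec = field(default_factory=CnnSpec)
    train: TrainConfig = field(default_factory=TrainConfig)
    scoring: ScoringScheme = field(default_factory=ScoringScheme)
    n_train_per_class: int = 1000
    n_val_per_class: int = 250
    n_blind_per_class: int = 1000
    seed: int = 0

    def to_dict(self) -> dict:
        def clean(obj):
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            return obj

        return clean(asdict(self))

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        def tup(x):
            return tuple(x) if isinstance(x, list) else x

        def build(klass, sub, tuple_keys=()):
            sub = dict(sub or {})
            for k in tuple_keys:
                if k in sub:
                    sub[k] = tup(sub[k])
            return klass(**sub)

        se_raw = dict(d.get("se") or {})
        if "spec" in se_raw and isinstance(se_raw["spec"], dict):
            se_raw["spec"] = SpectrogramSpec(**se_raw["spec"])
        try:
            return cls(
                sim=build(SimConfig, d.get("sim"), (
                    "event_len_range", "step_block_len_range",
                    "delay_onset_frac_range", "delay_len_frac_range",
                    "spacer_len_range",
                )),
                msd=build(MsdParams, d.get("msd")),
                se=SeParams(**se_raw),
                cnn=build(CnnSpec, d.get("cnn"), ("conv_filters",)),
                train=build(TrainConfig, d.get("train")),
                scoring=build(ScoringScheme, d.get("scoring")),
                n_train_per_class=d.get("n_train_per_class", 1000),
                n_val_per_class=d.get("n_val_per_class", 250),
                n_blind_per_class=d.get("n_blind_per_class", 1000),
                seed=d.get("seed", 0),
            )
        except TypeError as exc:
            raise ConfigurationError(f"bad run config: {exc}") from exc

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


@dataclass
class BenchmarkReport:
    calls: pd.DataFrame  # event_id, true_label, method, label, score, indeterminate
    confusions: dict[str, ConfusionCounts]
    metrics: dict[str, MetricSet]
    radar: pd.DataFrame
    model: ModelHandle
    n_blind: int


def _derived_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def simulate_splits(cfg: RunConfig):
    """Disjoint train/val/blind event sets with audit-friendly id prefixes."""
    s_tr, s_va, s_bl = _derived_seeds(cfg.seed, 3)
    splits = {}
    for name, seed, n in (
        ("train", s_tr, cfg.n_train_per_class),
        ("val", s_va, cfg.n_val_per_class),
        ("blind", s_bl, cfg.n_blind_per_class),
    ):
        events = generate_dataset(cfg.sim, n, n, seed)
        for ev in events:
            ev.event_id = f"{name}-{ev.event_id}"
        splits[name] = events
    ids = [set(e.event_id for e in evs) for evs in splits.values()]
    assert not (ids[0] & ids[2]) and not (ids[1] & ids[2]), "blind set leakage"
    return splits["train"], splits["val"], splits["blind"]


def run_benchmark(cfg: RunConfig, model: ModelHandle | None = None) -> BenchmarkReport:
    """Simulate, train, and benchmark MSD / SE / CNN on a blind set."""
    cfg.sim.validate()
    train_ev, val_ev, blind_ev = simulate_splits(cfg)

    res = cfg.cnn.input_resolution
    if model is None:
        xtr, _ = render_dataset(train_ev, res)
        xva, _ = render_dataset(val_ev, res)
        model = train(
            xtr, [e.label for e in train_ev], xva, [e.label for e in val_ev],
            cfg.cnn, cfg.train,
        )
    xbl, _ = render_dataset(blind_ev, res)
    probs, classes = predict(model, xbl)

    rows = []
    for method in ("msd", "se", "cnn"):
        for i, ev in enumerate(blind_ev):
            indeterminate = False
            if method == "msd":
                call = classify_msd(ev, cfg.msd)
                label, score = call.label, -call.score  # higher = more delayed
            elif method == "se":
                try:
                    call = classify_se(ev, cfg.se)
                    label, score = call.label, -call.score
                except IndeterminateEventError:
                    label, score, indeterminate = None, np.nan, True
            else:
                label, score = CLASS_NAMES[classes[i]], float(probs[i, 0])
            rows.append(
                {
                    "event_id": ev.event_id,
                    "true_label": ev.label,
                    "method": method,
                    "label": label,
                    "score": score,
                    "indeterminate": indeterminate,
                }
            )
    calls = pd.DataFrame(rows)

    confusions: dict[str, ConfusionCounts] = {}
    metrics: dict[str, MetricSet] = {}
    for method in ("msd", "se", "cnn"):
        sub = calls[(calls["method"] == method) & (~calls["indeterminate"])]
        confusions[method] = confusion(sub["true_label"], sub["label"])
        metrics[method] = compute_metrics(
            confusions[method],
            scores=sub["score"].to_numpy(),
            score_labels=sub["true_label"].tolist(),
        )
    table = pd.DataFrame({m: metrics[m].to_dict() for m in metrics}).T
    radar, _ = minmax_radar(table)
    return BenchmarkReport(
        calls=calls,
        confusions=confusions,
        metrics=metrics,
        radar=radar,
        model=model,
        n_blind=len(blind_ev),
    )


def run_dose_response(
    cfg: RunConfig,
    cohort: CohortSpec,
    method: str = "msd",
    model: ModelHandle | None = None,
):
    """Concentration-response quantification with one classifier.

    ``method`` is one of 'msd', 'se', 'cnn' (requires a trained ``model``) or
    'truth' (oracle classifier using the simulator's ground-truth labels).
    Returns ``(dose_table, hill_fit, summary_table)``.
    """
    if method not in ("msd", "se", "cnn", "truth"):
        raise ConfigurationError(f"unknown method {method!r}")
    if method == "cnn" and model is None:
        raise ConfigurationError("method 'cnn' requires a trained model")
    groups, truth = generate_dose_response(cohort, cfg.sim, cfg.seed)

    rows = []
    for (conc, rep), events in groups.items():
        if method == "truth":
            n_del = sum(ev.label == "delayed" for ev in events)
            n_det = len(events)
        elif method == "cnn":
            imgs, _ = render_dataset(events, cfg.cnn.input_resolution)
            _, classes = predict(model, imgs)
            n_del = int((classes == 0).sum())
            n_det = len(events)
        else:
            n_del = n_det = 0
            for ev in events:
                try:
                    call = (
                        classify_msd(ev, cfg.msd)
                        if method == "msd"
                        else classify_se(ev, cfg.se)
                    )
                except IndeterminateEventError:
                    continue
                n_det += 1
                n_del += call.label == "delayed"
        if n_det == 0:
            raise DataError(f"no determinate events at {conc} nM, replicate {rep}")
        rows.append(
            {"conc_nM": conc, "replicate": rep, "pct_delay": 100.0 * n_del / n_det}
        )
    table = baseline_correct(pd.DataFrame(rows))

    # MAD outlier exclusion across replicates, then unweighted fit on means
    kept_frames = []
    for conc, sub in table.groupby("conc_nM"):
        kept, excluded = mad_filter(sub["corrected"].to_numpy())
        keep_idx = [i for i in range(len(sub)) if i not in excluded]
        kept_frames.append(sub.iloc[keep_idx])
    kept_table = pd.concat(kept_frames)
    means = summarize(kept_table, value_col="corrected")
    fit = fit_hill(means["conc_nM"], means["mean"])
    return table, fit, means


def write_manifest(outdir, entries: dict) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "manifest.json"
    path.write_text(json.dumps(entries, indent=2, default=str))
    return path
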