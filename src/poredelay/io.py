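"""Container I/O: events as JSON-lines, reads as FASTA/FASTQ, tables as CSV/TSV.

Malformed JSON-lines records are skipped with a warning and counted, so a
truncated file yields a partial load rather than a crash.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import DataError
from .sim import EventTrace

__all__ = [
    "write_events_jsonl",
    "read_events_jsonl",
    "write_fasta",
    "write_fastq",
]


def write_events_jsonl(events: Iterable[EventTrace], path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for ev in events:
            rec = {
                "event_id": ev.event_id,
                "sampling_rate_hz": ev.sampling_rate_hz,
                "samples": [float(v) for v in ev.samples],
                "label": ev.label,
                "meta": ev.meta,
            }
            fh.write(json.dumps(rec) + "\n")


def read_events_jsonl(path) -> tuple[list[EventTrace], int]:
    """Load events; returns (events, n_bad_lines)."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such events file: {path}")
    events = []
    n_bad = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
                events.append(
                    EventTrace(
                        event_id=rec["event_id"],
                        samples=np.asarray(rec["samples"], dtype=float),
                        sampling_rate_hz=rec["sampling_rate_hz"],
                        label=rec.get("label", "unknown"),
                        meta=rec.get("meta", {}),
                    )
                )
            except (json.JSONDecodeError, KeyError, TypeError) as exc:
                n_bad += 1
                warnings.warn(f"{path}:{lineno}: skipping malformed event line ({exc})")
    return events, n_bad


def write_fasta(reads: Sequence[tuple[str, str]], path) -> None:
    with Path(path).open("w") as fh:
        for read_id, seq in reads:
            fh.write(f">{read_id}\n{seq}\n")


def write_fastq(reads: Sequence[tuple[str, str]], path, quality: int = 20) -> None:
    qchar = chr(quality + 33)
    with Path(path).open("w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{qchar * len(seq)}\n")
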