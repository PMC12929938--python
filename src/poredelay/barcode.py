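"""Local alignment of basecalled reads to the reference barcode, plus the
four-rule read filter applied before delay classification.

The reference is the 38-nt barcode carried by the DNA probe.  Reads are
aligned with Smith-Waterman (linear gap penalty); a read passes the filter iff

1. at least 15 reference bases are matched exactly,
2. no more than 3 mismatches occur in the alignment,
3. the alignment starts at reference position 0 with the barcode's initial
   ``GGG`` motif aligned to read bases G,G,G, and
4. at most 3 mismatches fall within the first 10 reference bases.

``N`` bases score and count as mismatches (conservative filtering).  Gap
positions are counted separately from mismatches.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path
import pandas as pd

from .errors import ConfigurationError, DataError

__all__ = [
    "BARCODE",
    "ScoringScheme",
    "AlignmentResult",
    "FilterVerdict",
    "local_align",
    "apply_filters",
    "filter_batch",
]

BARCODE = "GGGATCGCTACGCCTTCGGCTCGTAATCATAGTCGAGT"

_ALPHABET = set("ACGTN")


@dataclass(frozen=True)
class ScoringScheme:
    match: int = 5
    mismatch: int = -4
    gap: int = -8  # linear, per gapped position

    def validate(self) -> None:
        if not (self.match > 0 > self.mismatch and self.gap < 0):
            raise ConfigurationError("require match > 0 > mismatch and gap < 0")


@dataclass
class AlignmentResult:
    score: int
    read_span: tuple[int, int]  # half-open, 0-based
    ref_span: tuple[int, int]
    n_match: int
    n_mismatch: int
    n_gap_positions: int
    aligned_pairs: list[tuple[int | None, int | None]]
    scheme: ScoringScheme = field(default_factory=ScoringScheme)


def _check_seq(seq: str, name: str) -> str:
    if not seq:
        raise DataError(f"{name} sequence is empty")
    s = seq.upper()
    bad = set(s) - _ALPHABET
    if bad:
        raise DataError(f"{name} contains non-ACGTN symbols: {sorted(bad)}")
    return s


def local_align(read: str, ref: str, scheme: ScoringScheme = ScoringScheme()) -> AlignmentResult:
    """Optimal Smith-Waterman local alignment with linear gap penalty.

    Deterministic traceback: the end cell is the first maximum in (read, ref)
    scan order; at score ties the diagonal move is preferred over gaps, which
    keeps gap positions minimal among co-optimal paths.
    """
    scheme.validate()
    r = _check_seq(read, "read")
    q = _check_seq(ref, "ref")
    n, m = len(r), len(q)

    def sub(a: str, b: str) -> int:
        return scheme.match if (a == b and a != "N") else scheme.mismatch

    H = [[0] * (m + 1) for _ in range(n + 1)]
    best, bi, bj = 0, 0, 0
    for i in range(1, n + 1):
        Hi, Hp = H[i], H[i - 1]
        ri = r[i - 1]
        for j in range(1, m + 1):
            h = max(
                0,
                Hp[j - 1] + sub(ri, q[j - 1]),
                Hp[j] + scheme.gap,
                Hi[j - 1] + scheme.gap,
            )
            Hi[j] = h
            if h > best:
                best, bi, bj = h, i, j

    pairs: list[tuple[int | None, int | None]] = []
    n_match = n_mismatch = n_gap = 0
    i, j = bi, bj
    while i > 0 and j > 0 and H[i][j] > 0:
        h = H[i][j]
        if h == H[i - 1][j - 1] + sub(r[i - 1], q[j - 1]):
            pairs.append((i - 1, j - 1))
            if r[i - 1] == q[j - 1] and r[i - 1] != "N":
                n_match += 1
            else:
                n_mismatch += 1
            i, j = i - 1, j - 1
        elif h == H[i - 1][j] + scheme.gap:
            pairs.append((i - 1, None))  # read base against a gap in ref
            n_gap += 1
            i -= 1
        else:
            pairs.append((None, j - 1))  # ref base against a gap in read
            n_gap += 1
            j -= 1
    pairs.reverse()

    if not pairs:
        return AlignmentResult(0, (0, 0), (0, 0), 0, 0, 0, [], scheme)
    read_idx = [p[0] for p in pairs if p[0] is not None]
    ref_idx = [p[1] for p in pairs if p[1] is not None]
    return AlignmentResult(
        score=int(best),
        read_span=(min(read_idx), max(read_idx) + 1),
        ref_span=(min(ref_idx), max(ref_idx) + 1),
        n_match=n_match,
        n_mismatch=n_mismatch,
        n_gap_positions=n_gap,
        aligned_pairs=pairs,
        scheme=scheme,
    )


@dataclass
class FilterVerdict:
    passed: bool
    reasons: set[str]


_REASONS = ("too_few_matches", "too_many_mismatches", "missing_GGG_start", "early_mismatches")


def apply_filters(a: AlignmentResult, read: str, ref: str) -> FilterVerdict:
    """Apply the four barcode read filters to one alignment."""
    s = a.scheme
    expected = s.match * a.n_match + s.mismatch * a.n_mismatch + s.gap * a.n_gap_positions
    if a.aligned_pairs and expected != a.score:
        raise DataError(
            f"inconsistent alignment: score {a.score} != {expected} from pair counts"
        )
    r = _check_seq(read, "read")
    reasons: set[str] = set()
    if a.n_match < 15:
        reasons.add("too_few_matches")
    if a.n_mismatch > 3:
        reasons.add("too_many_mismatches")

    by_ref = {p[1]: p[0] for p in a.aligned_pairs if p[1] is not None}
    ggg_ok = a.aligned_pairs and a.ref_span[0] == 0
    if ggg_ok:
        for k in (0, 1, 2):
            ri = by_ref.get(k)
            if ri is None or r[ri] != "G":
                ggg_ok = False
                break
    if not ggg_ok:
        reasons.add("missing_GGG_start")

    early_mm = 0
    for ri, qi in a.aligned_pairs:
        if ri is not None and qi is not None and qi < 10:
            if not (r[ri] == ref[qi].upper() and r[ri] != "N"):
                early_mm += 1
    if early_mm > 3:
        reasons.add("early_mismatches")

    return FilterVerdict(passed=not reasons, reasons=reasons)


def _iter_records(source, fmt: str | None):
    """Yield (read_id, sequence) from a FASTA/FASTQ path (gzip transparent)
    or from an iterable of (id, seq) pairs.  Malformed trailing records are
    skipped with a warning and counted via the generator's return value."""
    from Bio import SeqIO

    if isinstance(source, (str, Path)):
        path = Path(source)
        name = path.name.lower()
        if fmt is None:
            core = name[:-3] if name.endswith(".gz") else name
            fmt = "fastq" if core.endswith((".fastq", ".fq")) else "fasta"
        opener = gzip.open if name.endswith(".gz") else open
        with opener(path, "rt") as fh:
            it = SeqIO.parse(fh, fmt)
            while True:
                try:
                    rec = next(it)
                except StopIteration:
                    return 0
                except ValueError as exc:
                    warnings.warn(f"skipping malformed record(s) in {path}: {exc}")
                    return 1
                yield rec.id, str(rec.seq)
    else:
        for item in source:
            if hasattr(item, "seq"):
                yield item.id, str(item.seq)
            else:
                yield item
        return 0


def filter_batch(
    source,
    ref: str = BARCODE,
    scheme: ScoringScheme = ScoringScheme(),
    fmt: str | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Align and filter a batch of reads.

    Returns a per-read verdict table (read_id, score, n_match, n_mismatch,
    n_gap_positions, passed, reasons) and a summary dict with counts and the
    pass rate.
    """
    rows = []
    n_skipped = 0
    gen = _iter_records(source, fmt)
    while True:
        try:
            read_id, seq = next(gen)
        except StopIteration as stop:
            n_skipped = stop.value or 0
            break
        if not seq:
            warnings.warn(f"skipping empty read {read_id}")
            n_skipped += 1
            continue
        aln = local_align(seq, ref, scheme)
        verdict = apply_filters(aln, seq, ref)
        rows.append(
            {
                "read_id": read_id,
                "score": aln.score,
                "n_match": aln.n_match,
                "n_mismatch": aln.n_mismatch,
                "n_gap_positions": aln.n_gap_positions,
                "passed": verdict.passed,
                "reasons": ";".join(sorted(verdict.reasons)),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "read_id",
            "score",
            "n_match",
            "n_mismatch",
            "n_gap_positions",
            "passed",
            "reasons",
        ],
    )
    n = len(table)
    n_pass = int(table["passed"].sum()) if n else 0
    summary = {
        "n_reads": n,
        "n_passed": n_pass,
        "n_failed": n - n_pass,
        "n_skipped": n_skipped,
        "pass_rate": (n_pass / n) if n else 0.0,
    }
    return table, summary
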