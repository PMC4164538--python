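"""Read trimming and filtering for pyrosequencing/semiconductor reads.

Rules applied to each read, iterated jointly to a fixpoint:

* terminal runs of >= ``end_run_min`` N's, A's, or T's are trimmed from
  either end (poly-A/T tails and end N blocks);
* ends whose terminal ``window``-base mean Phred quality falls below
  ``mean_quality_floor`` are trimmed base by base;
* reads shorter than ``min_length_after`` after trimming are discarded;
* low-complexity reads are removed with the DUST triplet statistic.

Quality trimming with a floor of 0 is the identity; trimming never
lengthens a read and is idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["QcParams", "QcReport", "trim_read", "dust_score", "is_low_complexity", "filter_stream"]


@dataclass(frozen=True)
class QcParams:
    mean_quality_floor: float = 20.0
    end_run_min: int = 5
    min_length_after: int = 70
    dust_threshold: float = 7.0
    window: int = 10  # quality-trimming window
    dust_window: int = 64

    def __post_init__(self) -> None:
        for name in ("mean_quality_floor", "end_run_min", "min_length_after",
                     "dust_threshold", "window", "dust_window"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class QcReport:
    n_input: int = 0
    n_kept: int = 0
    n_discarded_length: int = 0
    n_discarded_complexity: int = 0
    n_bases_in: int = 0
    n_bases_out: int = 0

    @property
    def counts_conserved(self) -> bool:
        return self.n_input == self.n_kept + self.n_discarded_length + self.n_discarded_complexity

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("metric\tvalue\n")
            for key in ("n_input", "n_kept", "n_discarded_length",
                        "n_discarded_complexity", "n_bases_in", "n_bases_out"):
                fh.write(f"{key}\t{getattr(self, key)}\n")


def _trim_terminal_runs(seq: str, qual: Sequence[int], min_run: int):
    """Strip terminal runs (>= min_run) of N, A, or T from both ends once."""
    if min_run <= 0:
        return seq, qual
    changed = False
    for base in "NAT":
        n = 0
        while n < len(seq) and seq[n] == base:
            n += 1
        if n >= min_run:
            seq, qual, changed = seq[n:], qual[n:], True
        n = 0
        while n < len(seq) and seq[len(seq) - 1 - n] == base:
            n += 1
        if n >= min_run:
            seq, qual, changed = seq[: len(seq) - n], qual[: len(qual) - n], True
    return (seq, qual) if not changed else _trim_terminal_runs(seq, qual, min_run)


def _trim_quality_ends(seq: str, qual: Sequence[int], floor: float, window: int):
    if floor <= 0 or window <= 0:
        return seq, qual
    # 5' end
    while seq:
        w = qual[: min(window, len(qual))]
        if sum(w) / len(w) < floor:
            seq, qual = seq[1:], qual[1:]
        else:
            break
    # 3' end
    while seq:
        w = qual[max(0, len(qual) - window):]
        if sum(w) / len(w) < floor:
            seq, qual = seq[:-1], qual[:-1]
        else:
            break
    return seq, qual


def trim_read(seq: str, qual: Sequence[int], params: QcParams | None = None):
    """Apply end-run and quality trimming; return (seq, qual) or None (discard).

    Run trimming precedes quality trimming; the pair is iterated until
    neither changes the read, so the operator is idempotent.
    """
    params = params or QcParams()
    if len(seq) != len(qual):
        raise ValueError(f"sequence length {len(seq)} != quality length {len(qual)}")
    seq = seq.upper()
    qual = list(qual)
    while True:
        before = len(seq)
        seq, qual = _trim_terminal_runs(seq, qual, params.end_run_min)
        seq, qual = _trim_quality_ends(seq, qual, params.mean_quality_floor, params.window)
        if len(seq) == before:
            break
    if len(seq) < params.min_length_after:
        return None
    return seq, qual


def dust_score(seq: str, window: int = 64) -> float:
    """DUST low-complexity score: max over windows of sum c_t(c_t-1)/2 / (w-3).

    ``c_t`` are triplet counts within the window.  Homopolymers score
    (w-2)/2 (maximal for their window length); uniform-random sequence
    scores well below 1.
    """
    seq = seq.upper()
    n = len(seq)
    if n < 3:
        raise ValueError("dust_score requires a sequence of length >= 3")
    step = max(1, window // 2)
    best = 0.0
    starts = range(0, max(1, n - window + 1), step)
    for start in starts:
        sub = seq[start : start + window]
        w = len(sub)
        if w < 3:
            continue
        counts: dict[str, int] = {}
        for i in range(w - 2):
            t = sub[i : i + 3]
            counts[t] = counts.get(t, 0) + 1
        raw = sum(c * (c - 1) // 2 for c in counts.values())
        best = max(best, raw / max(w - 3, 1))
    # make sure the final window is always examined
    if n > window and (n - window) % step != 0:
        sub = seq[n - window :]
        counts = {}
        for i in range(len(sub) - 2):
            t = sub[i : i + 3]
            counts[t] = counts.get(t, 0) + 1
        raw = sum(c * (c - 1) // 2 for c in counts.values())
        best = max(best, raw / max(len(sub) - 3, 1))
    return best


def is_low_complexity(seq: str, params: QcParams | None = None) -> bool:
    params = params or QcParams()
    return dust_score(seq, params.dust_window) > params.dust_threshold


def filter_stream(records: Iterable[SeqRecord], params: QcParams | None = None):
    """Trim and filter an iterable of FASTQ records.

    Returns (kept_records, QcReport); kept + discarded(by reason) equals the
    input count, and running the filter on its own output is the identity.
    """
    params = params or QcParams()
    kept: list[SeqRecord] = []
    report = QcReport()
    for idx, rec in enumerate(records):
        seq = str(rec.seq)
        qual = rec.letter_annotations.get("phred_quality")
        if qual is None or len(qual) != len(seq):
            raise ValueError(f"record {idx} ({rec.id}): missing or mismatched qualities")
        report.n_input += 1
        report.n_bases_in += len(seq)
        trimmed = trim_read(seq, qual, params)
        if trimmed is None:
            report.n_discarded_length += 1
            continue
        tseq, tqual = trimmed
        if is_low_complexity(tseq, params):
            report.n_discarded_complexity += 1
            continue
        out = SeqRecord(Seq(tseq), id=rec.id, name=rec.name, description=rec.description)
        out.letter_annotations["phred_quality"] = list(tqual)
        kept.append(out)
        report.n_kept += 1
        report.n_bases_out += len(tseq)
    return kept, report


def filter_fastq(in_path, out_path, params: QcParams | None = None) -> QcReport:
    """File-level wrapper: FASTQ in, trimmed FASTQ out, report returned."""
    kept, report = filter_stream(SeqIO.parse(in_path, "fastq"), params)
    with open(out_path, "w") as fh:
        SeqIO.write(kept, fh, "fastq")
    return report
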