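"""Pairwise-hit tables, interval-union coverage, and best-hit selection.

The 12-column tab-separated hit table (qseqid sseqid pident length mismatch
gapopen qstart qend sstart send evalue bitscore) is the interface between
this package and external sequence-search tools.  Coordinates in tables are
1-based inclusive; ``s_start > s_end`` encodes a minus-strand subject
alignment.  All internal interval arithmetic is 0-based half-open, with
conversion only at the module boundary.

A naive exact-seed / ungapped x-drop extension aligner is included so that
synthetic end-to-end runs do not need an external search tool.  Its scores
are length-scaled match scores, not Karlin-Altschul bit scores, and are only
meaningful for relative ranking on synthetic data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "AlignmentHit",
    "CoverageResult",
    "parse_hit_table",
    "write_hit_table",
    "subject_coverage",
    "best_hit",
    "naive_align",
]

HIT_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


@dataclass(frozen=True)
class AlignmentHit:
    """One row of a 12-column tabular pairwise hit."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_len: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bit_score: float

    def __post_init__(self) -> None:
        if self.q_start > self.q_end:
            raise ValueError(f"q_start > q_end in hit {self.query_id}->{self.subject_id}")
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError(f"pct_identity {self.pct_identity} outside [0, 100]")
        if self.bit_score < 0:
            raise ValueError("negative bit score")

    @property
    def subject_strand(self) -> str:
        return "-" if self.s_start > self.s_end else "+"

    @property
    def subject_span(self) -> tuple[int, int]:
        """Subject interval as (start, end), 1-based inclusive, start <= end."""
        return (min(self.s_start, self.s_end), max(self.s_start, self.s_end))

    @property
    def query_span_len(self) -> int:
        return self.q_end - self.q_start + 1


@dataclass(frozen=True)
class CoverageResult:
    covered_bases: int
    target_len: int
    fraction: float
    intervals: tuple[tuple[int, int], ...]  # merged, 1-based inclusive


def parse_hit_table(path) -> list[AlignmentHit]:
    """Read an outfmt-6 style hit table; raises on a wrong column count."""
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, got {len(parts)}"
                )
            hits.append(
                AlignmentHit(
                    query_id=parts[0],
                    subject_id=parts[1],
                    pct_identity=float(parts[2]),
                    aln_len=int(parts[3]),
                    mismatches=int(parts[4]),
                    gap_opens=int(parts[5]),
                    q_start=int(parts[6]),
                    q_end=int(parts[7]),
                    s_start=int(parts[8]),
                    s_end=int(parts[9]),
                    evalue=float(parts[10]),
                    bit_score=float(parts[11]),
                )
            )
    return hits


def write_hit_table(hits: Iterable[AlignmentHit], path) -> None:
    """Write hits so that parse(write(h)) round-trips exactly."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        h.query_id,
                        h.subject_id,
                        h.pct_identity,
                        h.aln_len,
                        h.mismatches,
                        h.gap_opens,
                        h.q_start,
                        h.q_end,
                        h.s_start,
                        h.s_end,
                        h.evalue,
                        h.bit_score,
                    )
                )
                + "\n"
            )


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge 0-based half-open intervals into a disjoint sorted union."""
    ivs = sorted((s, e) for s, e in intervals if e > s)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def subject_coverage(
    hits: Sequence[AlignmentHit],
    cds_interval: tuple[int, int],
    subject_len: int | None = None,
    restrict_to_cds: bool = True,
) -> CoverageResult:
    """Union coverage of a subject's CDS span by a set of hits.

    ``cds_interval`` is 1-based inclusive on the subject.  Minus-strand hits
    are normalised before the interval union.  When ``restrict_to_cds`` the
    covered fraction is relative to the CDS span; otherwise to the whole
    subject (``subject_len`` required).
    """
    subjects = {h.subject_id for h in hits}
    if len(subjects) > 1:
        raise ValueError(f"hits span multiple subjects: {sorted(subjects)}")
    cds_lo, cds_hi = cds_interval
    if cds_lo < 1 or cds_hi < cds_lo:
        raise ValueError(f"invalid cds_interval {cds_interval}")
    if subject_len is not None:
        for h in hits:
            lo, hi = h.subject_span
            if lo < 1 or hi > subject_len:
                raise ValueError(
                    f"hit {h.query_id}->{h.subject_id} [{lo},{hi}] outside subject length {subject_len}"
                )
    if restrict_to_cds:
        lo0, hi0 = cds_lo - 1, cds_hi  # half-open window
        target_len = cds_hi - cds_lo + 1
    else:
        if subject_len is None:
            raise ValueError("subject_len required when restrict_to_cds is False")
        lo0, hi0 = 0, subject_len
        target_len = subject_len
    clipped = []
    for h in hits:
        s, e = h.subject_span
        s0, e0 = max(s - 1, lo0), min(e, hi0)
        if e0 > s0:
            clipped.append((s0, e0))
    merged = merge_intervals(clipped)
    covered = sum(e - s for s, e in merged)
    return CoverageResult(
        covered_bases=covered,
        target_len=target_len,
        fraction=covered / target_len,
        intervals=tuple((s + 1, e) for s, e in merged),
    )


def best_hit(hits: Iterable[AlignmentHit]) -> dict[str, AlignmentHit]:
    """Maximal-bit-score hit per query.

    Ties are broken by lower e-value, then lexicographic subject id, so the
    result is invariant to the input row order.
    """
    out: dict[str, AlignmentHit] = {}
    for h in hits:
        cur = out.get(h.query_id)
        if cur is None or _hit_rank(h) < _hit_rank(cur):
            out[h.query_id] = h
    return out


def _hit_rank(h: AlignmentHit) -> tuple:
    return (-h.bit_score, h.evalue, h.subject_id)


# ---------------------------------------------------------------------------
# Naive seed-and-extend aligner (synthetic-test stand-in)

_MATCH = 1
_MISMATCH = -2


def naive_align(
    query: str,
    subject: str,
    query_id: str = "query",
    subject_id: str = "subject",
    k: int = 11,
    min_len: int = 30,
    x_drop: int = 20,
) -> list[AlignmentHit]:
    """Exact k-mer seeding with ungapped two-way x-drop extension.

    Guaranteed to find the full-length hit whenever ``query`` is an exact
    substring of ``subject`` (or vice versa) of length >= k.  Plus strand
    only; gaps are not modelled.
    """
    if k < 8:
        raise ValueError(f"seed length k={k} too small (minimum 8)")
    query = query.upper()
    subject = subject.upper()
    index: dict[str, list[int]] = {}
    for i in range(len(subject) - k + 1):
        index.setdefault(subject[i : i + k], []).append(i)

    # diag -> query end (exclusive) already covered by an extension
    covered: dict[int, int] = {}
    raw: dict[tuple[int, int, int, int], int] = {}
    for qpos in range(len(query) - k + 1):
        seed = query[qpos : qpos + k]
        if "N" in seed:
            continue
        for spos in index.get(seed, ()):
            diag = spos - qpos
            if covered.get(diag, -1) >= qpos + k:
                continue
            qs, qe, ss, se, score = _extend(query, subject, qpos, spos, k, x_drop)
            covered[diag] = max(covered.get(diag, -1), qe)
            key = (qs, qe, ss, se)
            raw[key] = max(raw.get(key, -(10**9)), score)

    hits: list[AlignmentHit] = []
    for (qs, qe, ss, se), score in raw.items():
        aln_len = qe - qs
        if aln_len < min_len:
            continue
        matches = sum(1 for a, b in zip(query[qs:qe], subject[ss:se]) if a == b)
        mismatches = aln_len - matches
        hits.append(
            AlignmentHit(
                query_id=query_id,
                subject_id=subject_id,
                pct_identity=round(100.0 * matches / aln_len, 2),
                aln_len=aln_len,
                mismatches=mismatches,
                gap_opens=0,
                q_start=qs + 1,
                q_end=qe,
                s_start=ss + 1,
                s_end=se,
                evalue=0.0,
                bit_score=float(max(score, 0)),
            )
        )
    hits.sort(key=lambda h: (-h.bit_score, h.q_start, h.s_start))
    return hits


def _extend(q: str, s: str, qpos: int, spos: int, k: int, x_drop: int):
    """Ungapped extension of a seed in both directions with x-drop pruning."""
    score = k * _MATCH
    # rightwards
    best, best_q, cur = score, qpos + k, score
    qi, si = qpos + k, spos + k
    while qi < len(q) and si < len(s):
        cur += _MATCH if q[qi] == s[si] else _MISMATCH
        qi += 1
        si += 1
        if cur > best:
            best, best_q = cur, qi
        if best - cur > x_drop:
            break
    right_end = best_q
    score = best
    # leftwards
    best, best_q, cur = score, qpos, score
    qi, si = qpos - 1, spos - 1
    while qi >= 0 and si >= 0:
        cur += _MATCH if q[qi] == s[si] else _MISMATCH
        if cur > best:
            best, best_q = cur, qi
        if best - cur > x_drop:
            break
        qi -= 1
        si -= 1
    left_start = best_q
    diag = spos - qpos
    return left_start, right_end, left_start + diag, right_end + diag, best
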