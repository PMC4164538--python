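"""Codon-usage matrix construction and frame-pure ORF prediction.

A log-odds codon matrix is trained on in-frame coding sequences: the
foreground is the codon frequency in the training CDSs (with a pseudocount
so all 64 codons are finite) and the background is the codon probability
implied by the training set's mononucleotide composition.  Prediction
enumerates stop-to-stop spans in all six frames, takes the candidate CDS
from the first ATG of each span through its closing stop, scores it as the
sum of codon log-odds, and returns the highest-scoring candidate.

This is a deliberately frameshift-free procedure: indel-tolerant HMM
decoding (as in EST-oriented gene predictors) is out of scope, since the
downstream analyses consume only CDS spans, start/stop completeness flags,
and the translated protein.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

__all__ = ["CodonUsageMatrix", "OrfCall", "build_codon_matrix", "predict_orf", "translate", "revcomp"]

BASES = "ACGT"
ALL_CODONS = ["".join(p) for p in product(BASES, repeat=3)]
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(cds: str) -> str:
    """Translate an in-frame CDS with the standard genetic code.

    A single terminal stop codon is dropped from the protein; internal
    stops appear as ``*``; any codon containing an ambiguous base becomes
    ``X``.
    """
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    protein = str(Seq(cds.upper()).translate())
    if protein.endswith("*"):
        protein = protein[:-1]
    return protein


@dataclass(frozen=True)
class CodonUsageMatrix:
    log_odds: Mapping[str, float]
    frequency: Mapping[str, float]
    background: Mapping[str, float]
    pseudocount: float

    def score(self, cds: str) -> float:
        """Summed log-odds over in-frame codons; codons with N contribute 0."""
        cds = cds.upper()
        if len(cds) % 3 != 0:
            raise ValueError(f"CDS length {len(cds)} not divisible by 3")
        return sum(self.log_odds.get(cds[i : i + 3], 0.0) for i in range(0, len(cds), 3))

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("codon\tfrequency\tbackground\tlog_odds\n")
            for codon in ALL_CODONS:
                fh.write(
                    f"{codon}\t{self.frequency[codon]!r}\t{self.background[codon]!r}"
                    f"\t{self.log_odds[codon]!r}\n"
                )

    @classmethod
    def from_tsv(cls, path) -> "CodonUsageMatrix":
        freq, bg, lo = {}, {}, {}
        with open(path) as fh:
            header = fh.readline()
            for line in fh:
                codon, f, b, l = line.rstrip("\n").split("\t")
                freq[codon], bg[codon], lo[codon] = float(f), float(b), float(l)
        return cls(log_odds=lo, frequency=freq, background=bg, pseudocount=float("nan"))


def build_codon_matrix(training_cds: Sequence[str], pseudocount: float = 1.0) -> CodonUsageMatrix:
    """Train a codon-usage log-odds matrix from in-frame CDS sequences."""
    if not training_cds:
        raise ValueError("empty training set")
    counts = {c: 0 for c in ALL_CODONS}
    base_counts = {b: 0 for b in BASES}
    for idx, cds in enumerate(training_cds):
        cds = cds.upper()
        if len(cds) % 3 != 0:
            raise ValueError(f"training CDS #{idx} has length {len(cds)} not divisible by 3")
        for i in range(0, len(cds), 3):
            codon = cds[i : i + 3]
            if codon in counts:
                counts[codon] += 1
        for b in cds:
            if b in base_counts:
                base_counts[b] += 1
    total = sum(counts.values()) + pseudocount * 64
    if total <= 0:
        raise ValueError("no countable codons in training set")
    frequency = {c: (counts[c] + pseudocount) / total for c in ALL_CODONS}
    base_total = sum(base_counts.values())
    base_p = {b: (base_counts[b] + pseudocount) / (base_total + 4 * pseudocount) for b in BASES}
    background = {c: base_p[c[0]] * base_p[c[1]] * base_p[c[2]] for c in ALL_CODONS}
    log_odds = {c: math.log2(frequency[c] / background[c]) for c in ALL_CODONS}
    return CodonUsageMatrix(
        log_odds=log_odds, frequency=frequency, background=background, pseudocount=pseudocount
    )


@dataclass(frozen=True)
class OrfCall:
    contig_id: str
    strand: str  # '+' or '-'
    frame: int  # 0..2, offset on the oriented sequence
    cds_start: int  # 1-based inclusive on the forward contig axis
    cds_end: int
    has_start: bool
    has_stop: bool
    score: float
    protein: str

    @property
    def cds_len(self) -> int:
        return self.cds_end - self.cds_start + 1

    def utr_lengths(self, contig_len: int) -> tuple[int, int]:
        """(5'UTR, 3'UTR) lengths on the contig's sense strand."""
        if self.strand == "+":
            return self.cds_start - 1, contig_len - self.cds_end
        return contig_len - self.cds_end, self.cds_start - 1


def predict_orf(
    contig_id: str,
    seq: str,
    matrix: CodonUsageMatrix,
    min_codons: int = 30,
    require_start: bool = True,
    min_score: float = 0.0,
) -> OrfCall | None:
    """Best-scoring candidate CDS across all six frames, or None.

    Ties are broken by longer CDS, then plus strand, then lower frame
    index.  Coordinates are reported on the forward contig axis regardless
    of strand.
    """
    seq = seq.upper()
    n = len(seq)
    candidates: list[tuple[tuple, OrfCall]] = []
    for strand in "+-":
        oriented = seq if strand == "+" else revcomp(seq)
        for frame in range(3):
            codons = [oriented[i : i + 3] for i in range(frame, n - 2, 3)]
            if not codons:
                continue
            seg_start = 0
            for idx in range(len(codons) + 1):
                at_end = idx == len(codons)
                if not at_end and codons[idx] not in STOP_CODONS:
                    continue
                has_stop = not at_end
                seg = codons[seg_start:idx]
                start_idx = None
                for j, c in enumerate(seg):
                    if c == START_CODON:
                        start_idx = j
                        break
                if start_idx is None and require_start:
                    seg_start = idx + 1
                    continue
                first = 0 if start_idx is None else start_idx
                cand_codons = codons[seg_start + first : idx + (1 if has_stop else 0)]
                n_codons = len(cand_codons)
                if n_codons >= min_codons:
                    cds = "".join(cand_codons)
                    score = matrix.score(cds)
                    if score >= min_score:
                        o_start = frame + 3 * (seg_start + first)  # 0-based on oriented
                        o_end = o_start + 3 * n_codons - 1
                        if strand == "+":
                            cds_start, cds_end = o_start + 1, o_end + 1
                        else:
                            cds_start, cds_end = n - o_end, n - o_start
                        call = OrfCall(
                            contig_id=contig_id,
                            strand=strand,
                            frame=frame,
                            cds_start=cds_start,
                            cds_end=cds_end,
                            has_start=start_idx is not None,
                            has_stop=has_stop,
                            score=score,
                            protein=translate(cds),
                        )
                        rank = (score, 3 * n_codons, 1 if strand == "+" else 0, -frame)
                        candidates.append((rank, call))
                seg_start = idx + 1
    if not candidates:
        return None
    candidates.sort(key=lambda rc: rc[0], reverse=True)
    return candidates[0][1]


def write_orf_calls(calls: Iterable[OrfCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("contig_id\tstrand\tframe\tcds_start\tcds_end\thas_start\thas_stop\tscore\tprotein\n")
        for c in calls:
            fh.write(
                f"{c.contig_id}\t{c.strand}\t{c.frame}\t{c.cds_start}\t{c.cds_end}"
                f"\t{int(c.has_start)}\t{int(c.has_stop)}\t{c.score!r}\t{c.protein}\n"
            )
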