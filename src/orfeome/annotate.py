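"""Cross-species annotation transfer by best-hit and bidirectional hit rate.

Two strategies over pairwise hit tables:

* SBH (single-directional best hit): per contig, species are walked in a
  priority order; the first species holding a best hit with bit score
  strictly above the floor supplies the assignment.
* BBH with BHR: the bidirectional hit rate of a contig/gene pair is the
  product (or geometric mean) of the forward and reverse max-normalised
  bit-score ratios, x = bits(a->b)/max_b' bits(a->b') and
  y = bits(b->a)/max_a' bits(b->a'); pairs with BHR strictly above the
  threshold (default 0.95) and both directional scores above the floor are
  accepted, again honouring species priority.

Assigned contigs inherit every label class of their gene; contigs with no
assignment fall into the "specific" bucket.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .align import AlignmentHit, _hit_rank

__all__ = ["BhrAssignment", "sbh_annotate", "bhr", "bbh_annotate", "transfer_labels"]


@dataclass(frozen=True)
class BhrAssignment:
    contig_id: str
    gene_id: str
    species: str
    direction: str  # "SBH" | "BBH"
    forward_bits: float
    reverse_bits: float | None = None
    bhr: float | None = None

    def __post_init__(self) -> None:
        if (self.direction == "BBH") != (self.bhr is not None):
            raise ValueError("bhr must be present exactly for BBH assignments")


def _check_species(hits: Iterable[AlignmentHit], gene_species: Mapping[str, str],
                   species_order: Sequence[str]) -> None:
    known = set(species_order)
    for h in hits:
        sp = gene_species.get(h.subject_id)
        if sp is None:
            raise ValueError(f"hit subject {h.subject_id} has no species mapping")
        if sp not in known:
            raise ValueError(f"species {sp!r} not in the configured species order")


def _max_bits_per_query(hits: Iterable[AlignmentHit]) -> dict[str, float]:
    out: dict[str, float] = {}
    for h in hits:
        out[h.query_id] = max(out.get(h.query_id, 0.0), h.bit_score)
    return out


def _pair_bits(hits: Iterable[AlignmentHit]) -> dict[tuple[str, str], float]:
    out: dict[tuple[str, str], float] = {}
    for h in hits:
        key = (h.query_id, h.subject_id)
        out[key] = max(out.get(key, 0.0), h.bit_score)
    return out


def sbh_annotate(
    forward_hits: Sequence[AlignmentHit],
    gene_species: Mapping[str, str],
    species_order: Sequence[str],
    min_bitscore: float = 30.0,
) -> list[BhrAssignment]:
    """Single-directional best-hit assignment honouring species priority.

    Species order wins over raw score: a weaker hit in an earlier species
    beats a stronger hit in a later one.
    """
    _check_species(forward_hits, gene_species, species_order)
    by_contig: dict[str, dict[str, list[AlignmentHit]]] = {}
    for h in forward_hits:
        by_contig.setdefault(h.query_id, {}).setdefault(gene_species[h.subject_id], []).append(h)
    assignments = []
    for contig in sorted(by_contig):
        for species in species_order:
            sp_hits = by_contig[contig].get(species)
            if not sp_hits:
                continue
            best = min(sp_hits, key=_hit_rank)
            if best.bit_score > min_bitscore:
                assignments.append(
                    BhrAssignment(contig, best.subject_id, species, "SBH", best.bit_score)
                )
                break
    return assignments


def bhr(
    forward_hits: Sequence[AlignmentHit],
    reverse_hits: Sequence[AlignmentHit],
    a: str,
    b: str,
    combiner: str = "product",
) -> float:
    """Bidirectional hit rate of the pair (a, b) in [0, 1].

    Returns 0 when either direction lacks the pair hit; a zero maximal
    score in either direction is undefined and returns 0 with a warning.
    """
    fwd_pair = _pair_bits(forward_hits).get((a, b), 0.0)
    rev_pair = _pair_bits(reverse_hits).get((b, a), 0.0)
    if fwd_pair == 0.0 or rev_pair == 0.0:
        return 0.0
    fwd_max = max((h.bit_score for h in forward_hits if h.query_id == a), default=0.0)
    rev_max = max((h.bit_score for h in reverse_hits if h.query_id == b), default=0.0)
    if fwd_max <= 0.0 or rev_max <= 0.0:
        warnings.warn(f"zero maximal bit score for pair ({a}, {b}); BHR undefined, returning 0")
        return 0.0
    x = fwd_pair / fwd_max
    y = rev_pair / rev_max
    if combiner == "product":
        return x * y
    if combiner == "geometric_mean":
        return (x * y) ** 0.5
    raise ValueError(f"unknown combiner {combiner!r}")


def bbh_annotate(
    forward_hits: Sequence[AlignmentHit],
    reverse_hits: Sequence[AlignmentHit],
    gene_species: Mapping[str, str],
    species_order: Sequence[str],
    threshold: float = 0.95,
    min_bitscore: float = 30.0,
    combiner: str = "product",
) -> list[BhrAssignment]:
    """Bidirectional best-hit assignment with the BHR filter.

    Within each species (walked in priority order), candidate genes of a
    contig are screened by BHR > threshold and both directional bit scores
    > min_bitscore; the highest forward-bit candidate wins (ties by gene
    id).  The first species with a winner supplies the assignment.
    """
    _check_species(forward_hits, gene_species, species_order)
    fwd_pair = _pair_bits(forward_hits)
    rev_pair = _pair_bits(reverse_hits)
    fwd_max = _max_bits_per_query(forward_hits)
    rev_max = _max_bits_per_query(reverse_hits)
    by_contig: dict[str, dict[str, set[str]]] = {}
    for h in forward_hits:
        by_contig.setdefault(h.query_id, {}).setdefault(gene_species[h.subject_id], set()).add(
            h.subject_id
        )
    assignments = []
    for contig in sorted(by_contig):
        done = False
        for species in species_order:
            if done:
                break
            winners = []
            for gene in sorted(by_contig[contig].get(species, ())):
                f = fwd_pair.get((contig, gene), 0.0)
                r = rev_pair.get((gene, contig), 0.0)
                if f <= min_bitscore or r <= min_bitscore:
                    continue
                fm, rm = fwd_max.get(contig, 0.0), rev_max.get(gene, 0.0)
                if fm <= 0 or rm <= 0:
                    continue
                x, y = f / fm, r / rm
                rate = x * y if combiner == "product" else (x * y) ** 0.5
                if rate > threshold:
                    winners.append((-f, gene, rate, r))
            if winners:
                winners.sort()
                negf, gene, rate, r = winners[0]
                assignments.append(
                    BhrAssignment(contig, gene, species, "BBH", -negf, r, rate)
                )
                done = True
    return assignments


def transfer_labels(
    assignments: Sequence[BhrAssignment],
    label_table: pd.DataFrame,
    contig_universe: Iterable[str],
) -> pd.DataFrame:
    """Propagate gene labels to assigned contigs.

    ``label_table`` has columns (gene_id, label_class, label).  Unassigned
    contigs receive a single row with label_class ``annotation`` and label
    ``specific``.
    """
    known_genes = set(label_table["gene_id"])
    by_contig = {a.contig_id: a for a in assignments}
    for a in assignments:
        if a.gene_id not in known_genes:
            raise ValueError(f"assignment references unknown gene {a.gene_id}")
    grouped = {g: df for g, df in label_table.groupby("gene_id")}
    rows = []
    for contig in sorted(set(contig_universe)):
        a = by_contig.get(contig)
        if a is None:
            rows.append({"contig_id": contig, "gene_id": "", "label_class": "annotation",
                         "label": "specific"})
            continue
        for _, r in grouped[a.gene_id].iterrows():
            rows.append({"contig_id": contig, "gene_id": a.gene_id,
                         "label_class": r["label_class"], "label": r["label"]})
    return pd.DataFrame(rows, columns=["contig_id", "gene_id", "label_class", "label"])
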