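"""Three-stage full-length transcript classification and family uniqueness.

Contigs of a de novo assembly are classified against full-length grass
gene models in three sequential analyses:

* **Analysis I** — a single contig covers >= 95% of a reference CDS with
  identity >= 80% and at least 50% of the contig aligned.  Species are
  walked in a fixed priority order; qualifying contigs and their genes are
  consumed and excluded from everything downstream.
* **Analysis II** — two or more remaining contigs jointly (non-overlapping
  union) cover >= 95% of a remaining gene's CDS, each passing the identity
  and contig-coverage gates.
* **Analysis III** — remaining contigs with a complete predicted ORF
  (start and stop codons) whose CDS is strictly longer than the mean
  reference CDS length (1,030.85 bp for the six-grass default set).

Proteins of the resulting calls are clustered into families by
deterministic single-linkage (alleles/variants/paralogs collapse), and
unique full-length totals are counted per analysis after collapsing, each
family attributed to the first analysis in which it appears.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib
import pandas as pd

from .align import AlignmentHit, _hit_rank, subject_coverage
from .orf import OrfCall
from .synthetic import FULLLENGTH_SPECIES_ORDER, ReferenceGene

__all__ = [
    "FlThresholds",
    "FullLengthCall",
    "FamilyCluster",
    "mean_cds_length",
    "analysis_one",
    "analysis_two",
    "analysis_three",
    "cluster_families",
    "unique_fulllength",
]


@dataclass(frozen=True)
class FlThresholds:
    min_gene_cds_coverage: float = 0.95
    min_identity: float = 80.0  # percent
    min_contig_coverage: float = 0.50
    evalue_max: float = 1e-15
    species_order: tuple = FULLLENGTH_SPECIES_ORDER

    def __post_init__(self) -> None:
        if not (0 <= self.min_gene_cds_coverage <= 1 and 0 <= self.min_contig_coverage <= 1):
            raise ValueError("coverage thresholds must lie in [0, 1]")
        if not 0 <= self.min_identity <= 100:
            raise ValueError("identity threshold must lie in [0, 100]")


@dataclass(frozen=True)
class FullLengthCall:
    analysis: str  # "I" | "II" | "III"
    contig_ids: tuple
    gene_id: str | None
    species: str | None
    coverage_fraction: float
    mean_identity: float

    def __post_init__(self) -> None:
        if not self.contig_ids:
            raise ValueError("a call needs at least one contig")
        if self.analysis == "I" and (len(self.contig_ids) != 1 or self.gene_id is None):
            raise ValueError("Analysis I calls are single-contig with a gene")
        if self.analysis == "II" and len(self.contig_ids) < 2:
            raise ValueError("Analysis II calls need >= 2 contigs")
        if self.analysis == "III" and self.gene_id is not None:
            raise ValueError("Analysis III calls carry no reference gene")


@dataclass(frozen=True)
class FamilyCluster:
    cluster_id: str
    members: tuple
    representative: str  # longest member


class _GeneInfo:
    __slots__ = ("gene_id", "species", "cds_interval", "mrna_len")

    def __init__(self, gene_id, species, cds_interval, mrna_len):
        self.gene_id = gene_id
        self.species = species
        self.cds_interval = cds_interval
        self.mrna_len = mrna_len


def _gene_index(refset) -> dict[str, _GeneInfo]:
    """Accept either ReferenceGene objects or an annotation DataFrame."""
    out = {}
    if isinstance(refset, pd.DataFrame):
        for _, r in refset.iterrows():
            lo = int(r["utr5_len"]) + 1
            hi = lo + int(r["cds_len"]) - 1
            out[r["gene_id"]] = _GeneInfo(
                r["gene_id"], r["species"], (lo, hi),
                int(r["utr5_len"]) + int(r["cds_len"]) + int(r["utr3_len"]),
            )
    else:
        for g in refset:
            out[g.gene_id] = _GeneInfo(g.gene_id, g.species, g.cds_interval, len(g.mrna))
    return out


def mean_cds_length(refset) -> float:
    """Arithmetic mean CDS length (bp) of a reference gene set."""
    if isinstance(refset, pd.DataFrame):
        lengths = [int(v) for v in refset["cds_len"]]
    else:
        lengths = [len(g.cds_seq) for g in refset]
    if not lengths:
        raise ValueError("empty reference set")
    return sum(lengths) / len(lengths)


def _qualifying(h: AlignmentHit, contig_len: int, gene: _GeneInfo, th: FlThresholds) -> bool:
    if h.evalue > th.evalue_max or h.pct_identity < th.min_identity:
        return False
    if h.query_span_len / contig_len < th.min_contig_coverage:
        return False
    return True


def analysis_one(
    hits: Sequence[AlignmentHit],
    refset,
    contig_lens: Mapping[str, int],
    thresholds: FlThresholds | None = None,
):
    """Single-contig full-length calls with sequential species exclusion.

    Within a species, qualifying (contig, best-hit gene) pairs are consumed
    in descending bit-score order, so when several contigs fully cover the
    same gene the strongest claims it and the rest remain for the later
    analyses.  Returns (calls, consumed_contigs, consumed_genes).
    """
    th = thresholds or FlThresholds()
    genes = _gene_index(refset)
    for h in hits:
        if h.subject_id in genes and genes[h.subject_id].species not in th.species_order:
            raise ValueError(f"species {genes[h.subject_id].species!r} not in species order")
    hits = [h for h in hits if h.evalue <= th.evalue_max and h.subject_id in genes]
    by_contig: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        by_contig.setdefault(h.query_id, []).append(h)

    calls: list[FullLengthCall] = []
    consumed_contigs: set[str] = set()
    consumed_genes: set[str] = set()
    for species in th.species_order:
        candidates = []
        for contig in sorted(by_contig):
            if contig in consumed_contigs:
                continue
            # "first gene hit" semantics: the contig's best hit in this
            # species, whether or not the gene is later claimed elsewhere
            sp_hits = [h for h in by_contig[contig] if genes[h.subject_id].species == species]
            if not sp_hits:
                continue
            best = min(sp_hits, key=_hit_rank)
            gene = genes[best.subject_id]
            if not _qualifying(best, contig_lens[contig], gene, th):
                continue
            cov = subject_coverage([best], gene.cds_interval, subject_len=gene.mrna_len)
            if cov.fraction >= th.min_gene_cds_coverage:
                candidates.append((-best.bit_score, contig, best, cov.fraction))
        for _, contig, best, frac in sorted(candidates):
            if contig in consumed_contigs or best.subject_id in consumed_genes:
                continue
            calls.append(
                FullLengthCall("I", (contig,), best.subject_id, species, frac, best.pct_identity)
            )
            consumed_contigs.add(contig)
            consumed_genes.add(best.subject_id)
    return calls, consumed_contigs, consumed_genes


def analysis_two(
    hits: Sequence[AlignmentHit],
    refset,
    contig_lens: Mapping[str, int],
    consumed_contigs: set[str] = frozenset(),
    consumed_genes: set[str] = frozenset(),
    thresholds: FlThresholds | None = None,
):
    """Multi-contig union-coverage calls on the remainder of Analysis I.

    Per remaining gene, qualifying hits of remaining contigs are merged;
    the gene is called when the CDS union reaches the coverage gate with at
    least two contributing contigs.  Returns (calls, consumed_contigs,
    consumed_genes) including the input consumptions.
    """
    th = thresholds or FlThresholds()
    genes = _gene_index(refset)
    consumed_contigs = set(consumed_contigs)
    consumed_genes = set(consumed_genes)
    hits = [h for h in hits if h.evalue <= th.evalue_max and h.subject_id in genes]
    calls: list[FullLengthCall] = []
    for species in th.species_order:
        by_gene: dict[str, list[AlignmentHit]] = {}
        for h in hits:
            gene = genes[h.subject_id]
            if (
                gene.species == species
                and h.subject_id not in consumed_genes
                and h.query_id not in consumed_contigs
                and _qualifying(h, contig_lens[h.query_id], gene, th)
            ):
                by_gene.setdefault(h.subject_id, []).append(h)
        for gene_id in sorted(by_gene):
            gene = genes[gene_id]
            gh = by_gene[gene_id]
            contigs = sorted({h.query_id for h in gh})
            if len(contigs) < 2:
                continue
            cov = subject_coverage(gh, gene.cds_interval, subject_len=gene.mrna_len)
            if cov.fraction >= th.min_gene_cds_coverage:
                wsum = sum(h.pct_identity * h.aln_len for h in gh)
                calls.append(
                    FullLengthCall(
                        "II", tuple(contigs), gene_id, species, cov.fraction,
                        wsum / sum(h.aln_len for h in gh),
                    )
                )
                consumed_genes.add(gene_id)
                consumed_contigs.update(contigs)
    return calls, consumed_contigs, consumed_genes


def analysis_three(
    remaining_contigs: Iterable[str],
    orf_calls: Mapping[str, OrfCall | None],
    mean_cds: float,
) -> list[FullLengthCall]:
    """Complete-ORF calls: start and stop present, CDS strictly > mean_cds."""
    calls = []
    for contig in sorted(remaining_contigs):
        oc = orf_calls.get(contig)
        if oc is None:
            continue
        if oc.has_start and oc.has_stop and oc.cds_len > mean_cds:
            calls.append(FullLengthCall("III", (contig,), None, None, 1.0, 100.0))
    return calls


# ---------------------------------------------------------------------------
# Family clustering (uniqueness collapsing)


def _protein_similarity(a: str, b: str) -> float:
    """Global edit-distance identity, 1 - d/max(len)."""
    if not a or not b:
        return 0.0
    d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


def cluster_families(
    proteins: Mapping[str, str],
    overlap_cutoff: float = 0.5,
    score_cutoff: float = 0.7,
    score_fn=None,
) -> list[FamilyCluster]:
    """Single-linkage clustering of proteins into families.

    A link requires the shorter protein to span at least ``overlap_cutoff``
    of the longer (so the alignment overlap can reach that fraction of the
    pair) and global identity >= ``score_cutoff``.  Deterministic under
    input permutation; representatives are the longest members (ties by
    id).
    """
    if not proteins:
        raise ValueError("no proteins to cluster")
    sim = score_fn or _protein_similarity
    ids = sorted(proteins)
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    for i, a in enumerate(ids):
        pa = proteins[a]
        for b in ids[i + 1 :]:
            pb = proteins[b]
            if not pa or not pb:
                continue
            if min(len(pa), len(pb)) / max(len(pa), len(pb)) < overlap_cutoff:
                continue
            if sim(pa, pb) >= score_cutoff:
                union(a, b)

    groups: dict[str, list[str]] = {}
    for i in ids:
        groups.setdefault(find(i), []).append(i)
    clusters = []
    for n, root in enumerate(sorted(groups)):
        members = tuple(sorted(groups[root]))
        rep = max(members, key=lambda m: (len(proteins[m]), m))
        clusters.append(FamilyCluster(f"cluster_{n:05d}", members, rep))
    return clusters


def unique_fulllength(
    calls: Sequence[FullLengthCall],
    clusters: Sequence[FamilyCluster],
    call_protein_id=None,
) -> dict:
    """Table-5 style summary with family-collapsed unique counts.

    ``call_protein_id(call)`` maps a call to the protein id that was
    clustered (default: the gene for Analysis II, else the single contig).
    Per-analysis unique counts attribute each cluster to the first analysis
    (I, II, III) in which it appears; the grand total is their sum, equal
    to the number of distinct clusters represented.
    """
    if call_protein_id is None:
        def call_protein_id(c: FullLengthCall) -> str:
            return c.gene_id if c.analysis == "II" else c.contig_ids[0]

    member_cluster: dict[str, str] = {}
    for cl in clusters:
        for m in cl.members:
            member_cluster[m] = cl.cluster_id

    per_analysis_raw = {"I": 0, "II": 0, "III": 0}
    per_species: dict[str, dict[str, int]] = {}
    contigs_per_analysis = {"I": set(), "II": set(), "III": set()}
    seen_clusters: set[str] = set()
    unique_counts = {"I": 0, "II": 0, "III": 0}
    for analysis in ("I", "II", "III"):
        for call in calls:
            if call.analysis != analysis:
                continue
            per_analysis_raw[analysis] += 1
            contigs_per_analysis[analysis].update(call.contig_ids)
            if call.species:
                sp = per_species.setdefault(call.species, {"I_genes": 0, "I_contigs": 0,
                                                           "II_genes": 0, "II_contigs": 0})
                sp[f"{analysis}_genes"] += 1
                sp[f"{analysis}_contigs"] += len(call.contig_ids)
            pid = call_protein_id(call)
            if pid not in member_cluster:
                raise ValueError(f"call protein {pid} is not in any cluster")
            cl = member_cluster[pid]
            if cl not in seen_clusters:
                seen_clusters.add(cl)
                unique_counts[analysis] += 1
    total_unique = sum(unique_counts.values())
    return {
        "per_species": per_species,
        "raw_calls": per_analysis_raw,
        "contigs": {k: len(v) for k, v in contigs_per_analysis.items()},
        "total_contigs": len(set().union(*contigs_per_analysis.values())),
        "unique": unique_counts,
        "total_unique": total_unique,
    }


def summary_table(summary: dict) -> pd.DataFrame:
    rows = []
    for sp, d in sorted(summary["per_species"].items()):
        rows.append({"species": sp, **d})
    rows.append(
        {
            "species": "TOTAL",
            "I_genes": sum(d["I_genes"] for d in summary["per_species"].values()),
            "I_contigs": summary["contigs"]["I"],
            "II_genes": sum(d["II_genes"] for d in summary["per_species"].values()),
            "II_contigs": summary["contigs"]["II"],
        }
    )
    return pd.DataFrame(rows)
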