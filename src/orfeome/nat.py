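"""Strand-aware antisense transcript detection and pathway-activity scoring.

Reads from a strand-preserving protocol are classified against the sense
strand of their target: alignments shorter than 100 bp are ignored, reads
on the strand opposite the target's sense are antisense (NAT evidence).
Per-gene antisense intensities (reads-per-million by default) feed the
pathway-activity score

    PA(P, sample) = ( sum_{j in detected(P)} g_j ) / (N / M)

where ``g_j`` is the intensity of gene j in pathway P, N the number of
genes of P detected in the sample, and M the pathway size.  PA matrices
are log2-transformed, median-centred per pathway, and clustered
hierarchically (average linkage, Euclidean for pathways; Spearman
correlation distance for samples); the cluster count k is chosen by the
silhouette criterion over Euclidean dissimilarity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import silhouette_score

from .align import merge_intervals

__all__ = [
    "ReadAlignmentRecord",
    "PathwayActivityMatrix",
    "classify_orientation",
    "antisense_counts",
    "antisense_coverage",
    "pathway_activity",
    "normalize_cluster",
    "fulllength_nat_overlap",
    "SENSE",
    "ANTISENSE",
    "IGNORED",
]

SENSE, ANTISENSE, IGNORED = "SENSE", "ANTISENSE", "IGNORED"


@dataclass(frozen=True)
class ReadAlignmentRecord:
    read_id: str
    sample_id: str
    target_id: str
    strand: str  # strand of the target the read aligned to: '+' or '-'
    t_start: int  # 1-based inclusive
    t_end: int
    aln_len: int

    def __post_init__(self) -> None:
        if self.aln_len < 1:
            raise ValueError("aln_len must be >= 1")


def records_from_frame(df: pd.DataFrame) -> list[ReadAlignmentRecord]:
    return [
        ReadAlignmentRecord(r.read_id, r.sample_id, r.target_id, r.strand,
                            int(r.t_start), int(r.t_end), int(r.aln_len))
        for r in df.itertuples(index=False)
    ]


def classify_orientation(
    rec: ReadAlignmentRecord,
    reference_sense_strand: str,
    min_len: int = 100,
) -> str:
    """SENSE / ANTISENSE / IGNORED for one read-alignment record."""
    if reference_sense_strand not in "+-":
        raise ValueError(f"invalid reference strand {reference_sense_strand!r}")
    if rec.aln_len < min_len:
        return IGNORED
    return ANTISENSE if rec.strand != reference_sense_strand else SENSE


def antisense_counts(
    records: Iterable[ReadAlignmentRecord],
    reference_strands: Mapping[str, str],
    min_len: int = 100,
):
    """Per-sample x per-target sense/antisense counts.

    Returns (counts, overall_antisense_fraction) where ``counts`` is a
    DataFrame indexed by (sample_id, target_id) with columns sense and
    antisense.  The fraction is antisense over all non-ignored reads.
    """
    tally: dict[tuple[str, str], list[int]] = {}
    n_sense = n_anti = 0
    for rec in records:
        strand = reference_strands.get(rec.target_id)
        if strand is None:
            raise ValueError(f"record targets unknown reference {rec.target_id}")
        cls = classify_orientation(rec, strand, min_len)
        if cls == IGNORED:
            continue
        key = (rec.sample_id, rec.target_id)
        row = tally.setdefault(key, [0, 0])
        if cls == SENSE:
            row[0] += 1
            n_sense += 1
        else:
            row[1] += 1
            n_anti += 1
    idx = pd.MultiIndex.from_tuples(sorted(tally), names=["sample_id", "target_id"])
    counts = pd.DataFrame(
        [tally[k] for k in sorted(tally)], index=idx, columns=["sense", "antisense"], dtype=int
    )
    total = n_sense + n_anti
    return counts, (n_anti / total if total else 0.0)


def antisense_coverage(
    records: Iterable[ReadAlignmentRecord],
    reference_strands: Mapping[str, str],
    target_lens: Mapping[str, int],
    min_len: int = 100,
) -> dict[str, float]:
    """Percent of each target covered by merged antisense alignments."""
    by_target: dict[str, list[tuple[int, int]]] = {t: [] for t in target_lens}
    for rec in records:
        strand = reference_strands.get(rec.target_id)
        if strand is None:
            raise ValueError(f"record targets unknown reference {rec.target_id}")
        if classify_orientation(rec, strand, min_len) != ANTISENSE:
            continue
        tlen = target_lens[rec.target_id]
        if rec.t_start < 1 or rec.t_end > tlen:
            raise ValueError(
                f"record {rec.read_id} span [{rec.t_start},{rec.t_end}] outside target {rec.target_id}"
            )
        by_target[rec.target_id].append((rec.t_start - 1, rec.t_end))
    out = {}
    for target, ivs in by_target.items():
        covered = sum(e - s for s, e in merge_intervals(ivs))
        out[target] = 100.0 * covered / target_lens[target]
    return out


@dataclass
class PathwayActivityMatrix:
    scores: pd.DataFrame  # pathway x sample
    state: str  # "raw" | "log2" | "centered"
    n_detected: pd.DataFrame  # pathway x sample
    m_total: pd.Series  # pathway -> M


def pathway_activity(
    intensities: pd.DataFrame,
    membership: Mapping[str, set],
    detection_min: float = 0.0,
) -> PathwayActivityMatrix:
    """Raw PA scores from a gene x sample intensity matrix.

    A gene counts as detected in a sample when its intensity is strictly
    above ``detection_min`` (default: any positive signal).  Pathways with
    no detected gene in a sample are unscored there (NaN).
    """
    if (intensities.values < 0).any():
        raise ValueError("negative intensities")
    samples = list(intensities.columns)
    pathways = sorted(membership)
    scores = pd.DataFrame(np.nan, index=pathways, columns=samples)
    n_det = pd.DataFrame(0, index=pathways, columns=samples, dtype=int)
    m_tot = pd.Series({p: len(membership[p]) for p in pathways}, dtype=int)
    for p in pathways:
        genes = sorted(set(membership[p]) & set(intensities.index))
        M = m_tot[p]
        if M == 0:
            raise ValueError(f"pathway {p} has no member genes")
        for s in samples:
            col = intensities.loc[genes, s] if genes else pd.Series(dtype=float)
            detected = col[col > detection_min]
            N = len(detected)
            n_det.loc[p, s] = N
            if N > 0:
                scores.loc[p, s] = detected.sum() / (N / M)
    return PathwayActivityMatrix(scores=scores, state="raw", n_detected=n_det, m_total=m_tot)


def _linkage_to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    tree = hierarchy.to_tree(Z)

    def rec(node, parent_dist):
        length = max(parent_dist - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        return f"({rec(node.left, node.dist)},{rec(node.right, node.dist)}):{length:.6g}"

    return f"({rec(tree.left, tree.dist)},{rec(tree.right, tree.dist)});"


def normalize_cluster(pam: PathwayActivityMatrix, pseudo: float = 1.0) -> dict:
    """Log2 transform, median-centre, and cluster a raw PA matrix.

    Rows (pathways) with any unscored sample are dropped before
    clustering.  Returns a dict with the centred matrix, pathway/sample
    Newick dendrograms and linkages, the chosen k, and pathway cluster
    labels.  With fewer than two fully-scored pathways, clustering is
    skipped with a warning.
    """
    logm = np.log2(pam.scores + pseudo)
    centered = logm.sub(logm.median(axis=1), axis=0)
    complete = centered.dropna(axis=0)
    out = {
        "matrix": centered,
        "pathway_linkage": None,
        "sample_linkage": None,
        "pathway_newick": None,
        "sample_newick": None,
        "k": None,
        "pathway_clusters": None,
    }
    if complete.shape[0] < 2:
        warnings.warn("fewer than 2 fully scored pathways; clustering skipped")
        return out
    X = complete.values
    pz = hierarchy.linkage(pdist(X, metric="euclidean"), method="average")
    out["pathway_linkage"] = pz
    out["pathway_newick"] = _linkage_to_newick(pz, list(complete.index))
    if complete.shape[1] >= 2:
        rho = complete.corr(method="spearman").to_numpy()
        # undefined correlations (constant profiles) are treated as identical
        dist = np.clip(1.0 - np.nan_to_num(rho, nan=1.0), 0.0, None)
        np.fill_diagonal(dist, 0.0)
        sz = hierarchy.linkage(squareform(dist, checks=False), method="average")
        out["sample_linkage"] = sz
        out["sample_newick"] = _linkage_to_newick(sz, list(complete.columns))
    ks = range(2, min(10, complete.shape[0] - 1) + 1)
    best_k, best_score, best_labels = None, -np.inf, None
    for k in ks:
        labels = hierarchy.fcluster(pz, t=k, criterion="maxclust")
        if len(set(labels)) < 2:
            continue
        score = silhouette_score(X, labels, metric="euclidean")
        if score > best_score + 1e-12:
            best_k, best_score, best_labels = k, score, labels
    out["k"] = best_k
    if best_labels is not None:
        out["pathway_clusters"] = pd.Series(best_labels, index=complete.index)
    return out


def fulllength_nat_overlap(
    fulllength_contigs: Iterable[str],
    coverage_pct: Mapping[str, float],
) -> list[str]:
    """Full-length contigs whose antisense coverage is exactly 100%."""
    return sorted(c for c in fulllength_contigs if coverage_pct.get(c, 0.0) >= 100.0)
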