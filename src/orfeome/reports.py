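"""Pipeline orchestration, assembly statistics, and summary partitions.

``run_pipeline`` drives the whole synthetic study: reference generation,
contig/read simulation, read QC, hit tables, ORF prediction, SBH/BBH
annotation transfer, three-stage full-length classification with family
collapsing, NAT counting and pathway-activity clustering, TF
classification, and the partition/overlap summaries.  Every stage logs
its input/output record counts, and the whole run is deterministic under
a fixed seed.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import annotate, fulllength, nat, orf, qc, synthetic, tf
from .align import write_hit_table
from .synthetic import (
    ANNOTATION_SPECIES_ORDER,
    DEFAULT_SAMPLES,
    GENOTYPES,
    ContigProfile,
    LengthParams,
    SampleSpec,
)

log = logging.getLogger("orfeome")

__all__ = ["assembly_stats", "expression_partition", "database_overlap", "PipelineConfig", "run_pipeline"]


def assembly_stats(contig_lengths: Sequence[int]) -> dict:
    """Contig-length summary: n, total, extremes, >=1 kb count, mean/median/N50.

    N50 is the largest length L such that contigs of length >= L sum to at
    least half of the total assembly size.
    """
    if not len(contig_lengths):
        raise ValueError("empty length list")
    lens = sorted(int(x) for x in contig_lengths)
    total = sum(lens)
    half = total / 2
    acc = 0
    n50 = lens[-1]
    for L in reversed(lens):
        acc += L
        if acc >= half:
            n50 = L
            break
    n_1kb = sum(1 for L in lens if L >= 1000)
    return {
        "n_contigs": len(lens),
        "total_bases": total,
        "longest": lens[-1],
        "shortest": lens[0],
        "n_ge_1kb": n_1kb,
        "pct_ge_1kb": 100.0 * n_1kb / len(lens),
        "mean": total / len(lens),
        "median": float(np.median(lens)),
        "n50": n50,
    }


def expression_partition(
    counts: pd.DataFrame,
    genotype_of_sample: Mapping[str, str],
    presence_min: int = 1,
    genotypes: Sequence[str] = GENOTYPES,
) -> dict:
    """Partition expressed contigs by the set of genotypes they appear in.

    ``counts`` is contig x sample; a contig is present in a genotype when
    its summed counts over that genotype's samples reach ``presence_min``.
    Returns region -> sorted contig list over the 7 non-empty genotype
    subsets; regions partition all expressed contigs.
    """
    for s in counts.columns:
        if s not in genotype_of_sample:
            raise ValueError(f"sample {s} has no genotype")
        if genotype_of_sample[s] not in genotypes:
            raise ValueError(f"unknown genotype {genotype_of_sample[s]!r}")
    geno_cols: dict[str, list] = {g: [] for g in genotypes}
    for s in counts.columns:
        geno_cols[genotype_of_sample[s]].append(s)
    per_geno = pd.DataFrame(
        {g: counts[cols].sum(axis=1) if cols else 0 for g, cols in geno_cols.items()}
    )
    regions: dict[tuple, list] = {}
    for r in range(1, len(genotypes) + 1):
        for combo in itertools.combinations(genotypes, r):
            regions[combo] = []
    for contig, row in per_geno.iterrows():
        present = tuple(g for g in genotypes if row[g] >= presence_min)
        if present:
            regions[present].append(contig)
    return {"+".join(k): sorted(v) for k, v in regions.items()}


def database_overlap(
    hit_presence: Mapping[str, set],
    contig_universe: Sequence[str],
) -> pd.DataFrame:
    """Matched/unmatched counts per reference database.

    The returned frame carries one row per database plus a ``specific``
    row counting contigs unmatched everywhere.
    """
    universe = set(contig_universe)
    rows = []
    specific = set(universe)
    for db in sorted(hit_presence):
        matched = hit_presence[db] & universe
        specific -= matched
        rows.append({"database": db, "matched": len(matched),
                     "unmatched": len(universe - matched)})
    rows.append({"database": "specific", "matched": len(specific),
                 "unmatched": len(universe) - len(specific)})
    return pd.DataFrame(rows)


@dataclass
class PipelineConfig:
    out_dir: str = "orfeome_out"
    seed: int = 1
    n_species: int = 6
    genes_per_species: int = 50
    length_params: LengthParams = field(default_factory=LengthParams)
    profile: ContigProfile = field(default_factory=ContigProfile)
    samples: tuple = DEFAULT_SAMPLES
    run_qc: bool = True
    qc_params: qc.QcParams = field(default_factory=qc.QcParams)
    orf_min_codons: int = 30
    fl_thresholds: fulllength.FlThresholds = field(default_factory=fulllength.FlThresholds)
    annotation_species_order: tuple = ANNOTATION_SPECIES_ORDER
    bhr_threshold: float = 0.95
    min_bitscore: float = 30.0
    presence_min: int = 1
    nat_min_len: int = 100
    cluster_score_cutoff: float = 0.7
    cluster_overlap_cutoff: float = 0.5
    intensity_mode: str = "rpm"  # or "raw"


def _truncate1(x: float) -> float:
    """Truncate (not round) to one decimal, the paper-style percent format."""
    return int(x * 10) / 10


def run_pipeline(config: PipelineConfig) -> dict:
    """End-to-end synthetic run; writes every stage's tables, returns summary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.seed)
    summary: dict = {"seed": seed}

    # --- synthetic study ---------------------------------------------------
    genes = synthetic.generate_reference_set(
        n_species=config.n_species,
        genes_per_species=config.genes_per_species,
        length_params=config.length_params,
        seed=seed,
    )
    ann = synthetic.annotation_table(genes)
    ann.to_csv(out / "reference_annotation.tsv", sep="\t", index=False)
    synthetic.write_fasta({g.gene_id: g.mrna for g in genes}, out / "reference_mrna.fasta")
    synthetic.write_fasta({g.gene_id: g.cds_seq for g in genes}, out / "reference_cds.fasta")
    log.info("reference set: %d genes, %d species", len(genes), config.n_species)

    contigs, truth = synthetic.generate_contigs(
        genes, config.profile, seed=seed + 1,
        cds_coverage_gate=config.fl_thresholds.min_gene_cds_coverage,
    )
    synthetic.write_fasta(contigs, out / "contigs.fasta")
    synthetic.write_truth_table(truth, out / "truth.tsv")
    log.info("contigs: %d (truth records: %d)", len(contigs), len(truth))

    fastq, aln_records, truth = synthetic.generate_reads(
        contigs, truth, samples=config.samples, seed=seed + 2
    )
    for sample_id, recs in fastq.items():
        synthetic.write_fastq(recs, out / f"reads_{sample_id}.fastq")
    aln_records.to_csv(out / "read_alignments.tsv", sep="\t", index=False)

    # --- read QC -----------------------------------------------------------
    if config.run_qc:
        qc_reports = {}
        for sample_id in fastq:
            report = qc.filter_fastq(
                out / f"reads_{sample_id}.fastq", out / f"reads_{sample_id}.qc.fastq",
                config.qc_params,
            )
            if not report.counts_conserved:
                raise RuntimeError(f"QC count conservation violated for {sample_id}")
            qc_reports[sample_id] = report
        pd.DataFrame(
            {s: {"n_input": r.n_input, "n_kept": r.n_kept,
                 "n_discarded_length": r.n_discarded_length,
                 "n_discarded_complexity": r.n_discarded_complexity}
             for s, r in qc_reports.items()}
        ).T.to_csv(out / "qc_report.tsv", sep="\t")
        summary["qc_kept_fraction"] = (
            sum(r.n_kept for r in qc_reports.values())
            / max(1, sum(r.n_input for r in qc_reports.values()))
        )
        log.info("QC kept fraction: %.4f", summary["qc_kept_fraction"])

    # --- hit tables --------------------------------------------------------
    fwd_hits, rev_hits = synthetic.emit_truth_hit_tables(genes, contigs, truth)
    write_hit_table(fwd_hits, out / "hits_forward.tsv")
    write_hit_table(rev_hits, out / "hits_reverse.tsv")
    log.info("hit tables: %d forward, %d reverse", len(fwd_hits), len(rev_hits))

    # --- ORF prediction ----------------------------------------------------
    matrix = orf.build_codon_matrix([g.cds_seq for g in genes])
    matrix.to_tsv(out / "codon_matrix.tsv")
    orf_calls = {
        cid: orf.predict_orf(cid, seq, matrix, min_codons=config.orf_min_codons)
        for cid, seq in contigs.items()
    }
    orf.write_orf_calls([c for c in orf_calls.values() if c], out / "orf_calls.tsv")
    n_pred = sum(1 for c in orf_calls.values() if c)
    summary["orf_predicted_pct"] = 100.0 * n_pred / len(contigs)
    log.info("ORF calls: %d/%d contigs", n_pred, len(contigs))

    # --- annotation transfer ----------------------------------------------
    gene_species = {g.gene_id: g.species for g in genes}
    sbh = annotate.sbh_annotate(fwd_hits, gene_species, config.annotation_species_order,
                                config.min_bitscore)
    bbh = annotate.bbh_annotate(fwd_hits, rev_hits, gene_species,
                                config.annotation_species_order,
                                threshold=config.bhr_threshold,
                                min_bitscore=config.min_bitscore)
    label_rows = []
    for g in genes:
        label_rows.append({"gene_id": g.gene_id, "label_class": "annotation",
                           "label": g.annotation_label})
        for pw in sorted(g.pathway_ids):
            label_rows.append({"gene_id": g.gene_id, "label_class": "pathway", "label": pw})
        if g.tf_family:
            label_rows.append({"gene_id": g.gene_id, "label_class": "tf_family",
                               "label": g.tf_family})
    label_table = pd.DataFrame(label_rows)
    # Label transfer follows the SBH species-priority route; BBH assignments
    # (the stricter reciprocal test) are written alongside for GO-style use.
    contig_annotation = annotate.transfer_labels(sbh, label_table, contigs)
    contig_annotation.to_csv(out / "contig_annotation.tsv", sep="\t", index=False)
    pd.DataFrame([asdict(a) for a in bbh]).to_csv(out / "bbh_assignments.tsv", sep="\t", index=False)
    assigned = {a.contig_id for a in sbh}
    summary["annotated_pct"] = 100.0 * len(assigned) / len(contigs)
    summary["specific_pct"] = 100.0 * (len(contigs) - len(assigned)) / len(contigs)
    log.info("annotation: %d SBH, %d BBH of %d contigs", len(sbh), len(bbh), len(contigs))

    # --- full-length classification ----------------------------------------
    contig_lens = {c: len(s) for c, s in contigs.items()}
    th = config.fl_thresholds
    calls1, used_c, used_g = fulllength.analysis_one(fwd_hits, ann, contig_lens, th)
    calls2, used_c, used_g = fulllength.analysis_two(
        fwd_hits, ann, contig_lens, used_c, used_g, th
    )
    mean_cds = fulllength.mean_cds_length(ann)
    remaining = sorted(set(contigs) - used_c)
    calls3 = fulllength.analysis_three(remaining, orf_calls, mean_cds)
    calls = calls1 + calls2 + calls3
    log.info("full-length calls: I=%d II=%d III=%d (mean CDS %.2f bp)",
             len(calls1), len(calls2), len(calls3), mean_cds)

    gene_proteins = {g.gene_id: orf.translate(g.cds_seq) for g in genes}
    proteins: dict[str, str] = {}
    for call in calls:
        if call.analysis == "II":
            proteins[call.gene_id] = gene_proteins[call.gene_id]
        else:
            contig = call.contig_ids[0]
            oc = orf_calls.get(contig)
            if oc is not None:
                proteins[contig] = oc.protein
            elif call.gene_id is not None:
                proteins[contig] = gene_proteins[call.gene_id]
    clusters = fulllength.cluster_families(
        proteins, overlap_cutoff=config.cluster_overlap_cutoff,
        score_cutoff=config.cluster_score_cutoff,
    ) if proteins else []
    fl_summary = fulllength.unique_fulllength(calls, clusters) if clusters else None
    if fl_summary:
        fulllength.summary_table(fl_summary).to_csv(out / "fulllength_summary.tsv",
                                                    sep="\t", index=False)
        summary["fulllength"] = fl_summary
    summary["mean_cds_length"] = mean_cds

    # --- NAT detection and pathway activity ---------------------------------
    records = nat.records_from_frame(aln_records)
    contig_strands = {c: "+" for c in contigs}  # contigs are sense-oriented
    counts, anti_frac = nat.antisense_counts(records, contig_strands, config.nat_min_len)
    counts.to_csv(out / "strand_counts.tsv", sep="\t")
    summary["antisense_read_pct"] = _truncate1(100.0 * anti_frac)
    coverage = nat.antisense_coverage(records, contig_strands, contig_lens, config.nat_min_len)
    nat_contigs = [c for c, pct in coverage.items() if pct > 0]
    summary["nat_contig_pct"] = _truncate1(100.0 * len(nat_contigs) / len(contigs))
    fl_contigs = sorted({c for call in calls for c in call.contig_ids if c in contigs})
    summary["fulllength_nat_contigs"] = len(nat.fulllength_nat_overlap(fl_contigs, coverage))
    log.info("antisense fraction: %.3f%%; NAT contigs: %d",
             100 * anti_frac, len(nat_contigs))

    # antisense intensity per gene (via truth origin), RPM per sample
    truth_by_contig = {t.contig_id: t for t in truth}
    anti = counts["antisense"].unstack(level="sample_id").fillna(0) if len(counts) else pd.DataFrame()
    if not anti.empty:
        anti = anti.groupby(
            lambda c: truth_by_contig[c].origin_gene
        ).sum()
        anti = anti.drop(index="specific", errors="ignore")
        if config.intensity_mode == "rpm":
            lib_sizes = aln_records.groupby("sample_id").size()
            anti = anti.div(lib_sizes.reindex(anti.columns), axis=1) * 1e6
        membership: dict[str, set] = {}
        for g in genes:
            for pw in g.pathway_ids:
                membership.setdefault(pw, set()).add(g.gene_id)
        if membership:
            pam = nat.pathway_activity(anti, membership)
            pam.scores.to_csv(out / "pathway_activity_raw.tsv", sep="\t")
            clust = nat.normalize_cluster(pam)
            clust["matrix"].to_csv(out / "pathway_activity_centered.tsv", sep="\t")
            for key in ("pathway_newick", "sample_newick"):
                if clust[key]:
                    (out / f"{key}.nwk").write_text(clust[key] + "\n")
            summary["pa_cluster_k"] = clust["k"]
            n_scored = pam.scores.notna().all(axis=1).sum()
            summary["pa_pathways_scored_pct"] = _truncate1(
                100.0 * pam.scores.notna().any(axis=1).sum() / len(pam.scores)
            )
            log.info("PA matrix: %d pathways, k=%s", n_scored, clust["k"])

    # --- TF classification ---------------------------------------------------
    rules = tf.example_rules()
    domain_hits = synthetic.emit_domain_hits(genes, truth, rules, seed=seed + 3)
    domain_hits.to_csv(out / "domain_hits.tsv", sep="\t", index=False)
    domain_sets = tf.filter_domains(domain_hits)
    classifications = {pid: tf.classify_tf(doms, rules) for pid, doms in domain_sets.items()}
    tally = tf.tally_families(classifications, fl_contigs)
    tally.to_csv(out / "tf_families.tsv", sep="\t", index=False)
    summary["tf_contigs"] = int(sum(1 for v in classifications.values() if v))
    summary["tf_families"] = int(len(tally))
    log.info("TF classification: %d contigs in %d families",
             summary["tf_contigs"], summary["tf_families"])

    # --- partitions and statistics ------------------------------------------
    stats = assembly_stats(list(contig_lens.values()))
    pd.Series(stats).to_csv(out / "assembly_stats.tsv", sep="\t", header=False)
    summary["assembly"] = stats

    read_counts = (
        aln_records.groupby(["target_id", "sample_id"]).size().unstack(fill_value=0)
    )
    genotype_of_sample = {s.sample_id: s.genotype for s in config.samples}
    partition = expression_partition(read_counts, genotype_of_sample, config.presence_min)
    pd.DataFrame(
        [{"region": k, "n_contigs": len(v)} for k, v in partition.items()]
    ).to_csv(out / "genotype_partition.tsv", sep="\t", index=False)
    summary["genotype_partition"] = {k: len(v) for k, v in partition.items()}

    hit_presence: dict[str, set] = {}
    for h in fwd_hits:
        sp = gene_species[h.subject_id]
        hit_presence.setdefault(sp, set()).add(h.query_id)
    overlap = database_overlap(hit_presence, list(contigs))
    overlap.to_csv(out / "database_overlap.tsv", sep="\t", index=False)
    specific_n = int(overlap.loc[overlap["database"] == "specific", "matched"].iloc[0])
    summary["db_specific_pct"] = _truncate1(100.0 * specific_n / len(contigs))

    pd.Series({k: v for k, v in summary.items() if not isinstance(v, dict)}).to_csv(
        out / "summary.tsv", sep="\t", header=False
    )
    return summary
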