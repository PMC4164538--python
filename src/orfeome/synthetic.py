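"""Synthetic grass reference gene sets, derived contigs, and stranded reads.

Every downstream stage of the pipeline is testable against planted ground
truth generated here:

* ``generate_reference_set`` draws multi-species gene models with
  5'UTR + CDS + 3'UTR structure, pathway/TF/family labels, and an
  annotation table;
* ``generate_contigs`` derives an assembly from those genes: intact
  full-length contigs, genes fragmented into k pieces, lineage-specific
  contigs unrelated to any reference, and mutated paralog/allele variants;
* ``generate_reads`` draws strand-tagged reads per sample (the template
  strand is encoded in the read name suffix ``/s`` or ``/a``) together
  with the alignment records a strand-aware mapper would produce;
* ``emit_truth_hit_tables`` writes the pairwise hit tables the planted
  contigs would produce against their source genes, bypassing any aligner.

All generation is driven by ``numpy.random.default_rng`` so identical
seeds give byte-identical outputs.

Design notes.  CDS lengths default to the grass full-length mean of
1,030.85 bp.  5'UTRs are generated uORF-poor: the in-frame codon
immediately upstream of the start codon is a stop, so the true start is
the first ATG of its stop-to-stop span and ORF coordinates are
recoverable by frame-pure prediction.  Fragment cut points fall strictly
inside the CDS, at least (1 - cds_coverage_gate + 1%) of the CDS length
away from either CDS end, so no single fragment can pass the single-hit
full-length gate; fragments still partition the whole mRNA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .align import AlignmentHit
from .orf import STOP_CODONS, revcomp

__all__ = [
    "ReferenceGene",
    "LengthParams",
    "ContigProfile",
    "SampleSpec",
    "TruthRecord",
    "GENOTYPES",
    "FULLLENGTH_SPECIES_ORDER",
    "ANNOTATION_SPECIES_ORDER",
    "generate_reference_set",
    "generate_contigs",
    "generate_reads",
    "emit_truth_hit_tables",
    "emit_domain_hits",
    "annotation_table",
    "write_fasta",
    "write_fastq",
]

BASES = np.array(list("ACGT"))
_STOPS = sorted(STOP_CODONS)

# Species priority order used for full-length classification (most specific
# transcript hits first).
FULLLENGTH_SPECIES_ORDER = (
    "Sorghum bicolor",
    "Zea mays",
    "Panicum virgatum",
    "Setaria italica",
    "Oryza sativa",
    "Brachypodium distachyon",
)
# Species priority order used for cross-species annotation transfer.
ANNOTATION_SPECIES_ORDER = (
    "Sorghum bicolor",
    "Oryza sativa",
    "Zea mays",
    "Brachypodium distachyon",
    "Panicum virgatum",
    "Setaria italica",
)

GENOTYPES = ("SP803280", "S_officinarum", "S_spontaneum")

# Genotype-presence mixture for contigs: the hybrid expresses nearly
# everything; ancestor-specific transcripts are rare (sub-percent).
_PRESENCE_PATTERNS: list[tuple[frozenset, float]] = [
    (frozenset(GENOTYPES), 0.7828),
    (frozenset({"SP803280"}), 0.0500),
    (frozenset({"SP803280", "S_officinarum"}), 0.0800),
    (frozenset({"SP803280", "S_spontaneum"}), 0.0714),
    (frozenset({"S_officinarum"}), 0.0016),
    (frozenset({"S_spontaneum"}), 0.0069),
    (frozenset({"S_officinarum", "S_spontaneum"}), 0.0073),
]

_ANNOTATION_VOCAB = (
    "unknown",
    "NB-ARC domain",
    "protein kinase superfamily",
    "MYB transcription factor",
    "sucrose synthase",
    "cellulose synthase",
    "heat shock protein",
    "cytochrome P450",
    "ribosomal protein",
    "aquaporin",
)


@dataclass(frozen=True)
class ReferenceGene:
    gene_id: str
    species: str
    utr5_seq: str
    cds_seq: str
    utr3_seq: str
    strand: str = "+"
    annotation_label: str = "unknown"
    pathway_ids: frozenset = frozenset()
    tf_family: str | None = None
    family_id: str = ""

    def __post_init__(self) -> None:
        if len(self.cds_seq) % 3 != 0:
            raise ValueError(f"{self.gene_id}: CDS length not divisible by 3")
        if self.cds_seq[:3] != "ATG":
            raise ValueError(f"{self.gene_id}: CDS does not begin with ATG")
        if self.cds_seq[-3:] not in STOP_CODONS:
            raise ValueError(f"{self.gene_id}: CDS does not end with a stop codon")

    @property
    def mrna(self) -> str:
        return self.utr5_seq + self.cds_seq + self.utr3_seq

    @property
    def cds_interval(self) -> tuple[int, int]:
        """CDS span on the mRNA, 1-based inclusive."""
        lo = len(self.utr5_seq) + 1
        return lo, lo + len(self.cds_seq) - 1


@dataclass(frozen=True)
class LengthParams:
    """Normal length distributions (bp), truncated at the minima."""

    cds_mean: float = 1030.85
    cds_sd: float = 350.0
    utr5_mean: float = 150.0
    utr5_sd: float = 60.0
    utr3_mean: float = 250.0
    utr3_sd: float = 90.0
    min_cds_codons: int = 60
    min_utr: int = 20

    def __post_init__(self) -> None:
        if self.cds_mean <= 0 or self.cds_sd < 0:
            raise ValueError("invalid CDS length distribution")
        if self.utr5_mean < self.min_utr or self.utr3_mean < self.min_utr:
            raise ValueError("UTR mean below minimum UTR length")
        if self.min_cds_codons < 2:
            raise ValueError("min_cds_codons must be >= 2")


@dataclass(frozen=True)
class ContigProfile:
    frac_fulllength: float = 0.4
    frac_fragmented: float = 0.3
    frac_specific: float = 0.2
    frac_variant: float = 0.1
    pieces_range: tuple[int, int] = (2, 4)
    overlap: int = 0
    substitution_rate: float = 0.0
    variant_rate: float = 0.02
    n_variants_per_gene: int = 3
    min_piece: int = 40

    def __post_init__(self) -> None:
        fracs = (self.frac_fulllength, self.frac_fragmented, self.frac_specific, self.frac_variant)
        if any(f < 0 for f in fracs) or sum(fracs) > 1 + 1e-9:
            raise ValueError("class fractions must be non-negative and sum to <= 1")
        if self.pieces_range[0] < 2:
            raise ValueError("pieces_per_fragmented must be >= 2")
        if not 0 <= self.substitution_rate <= 0.2:
            raise ValueError("substitution_rate must lie in [0, 0.2]")
        if self.n_variants_per_gene < 1:
            raise ValueError("n_variants_per_gene must be >= 1")


@dataclass(frozen=True)
class SampleSpec:
    sample_id: str
    genotype: str
    n_reads: int
    antisense_fraction: float = 0.058

    def __post_init__(self) -> None:
        if self.n_reads <= 0:
            raise ValueError(f"{self.sample_id}: read depth must be positive")
        if not 0.0 <= self.antisense_fraction <= 1.0:
            raise ValueError(f"{self.sample_id}: antisense_fraction outside [0, 1]")


# The five libraries of the study design: three hybrid tissues plus one
# leaf library per ancestor genotype.
DEFAULT_SAMPLES = (
    SampleSpec("SP803280_leaf", "SP803280", 20000),
    SampleSpec("SP803280_internode1", "SP803280", 20000),
    SampleSpec("SP803280_internode5", "SP803280", 20000),
    SampleSpec("S_officinarum_leaf", "S_officinarum", 20000),
    SampleSpec("S_spontaneum_leaf", "S_spontaneum", 20000),
)


@dataclass
class TruthRecord:
    contig_id: str
    origin_gene: str  # gene_id or "specific"
    truth_class: str  # fulllength_single | fragment_i_of_k | specific | variant
    family_id: str
    genotypes: frozenset
    mrna_span: tuple[int, int] | None  # 1-based inclusive on the source mRNA
    mismatches: int
    read_counts: dict = field(default_factory=dict)  # sample -> {"sense": n, "antisense": n}


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


def _trunc_normal_int(rng: np.random.Generator, mean: float, sd: float, minimum: int) -> int:
    return max(minimum, int(round(rng.normal(mean, sd))))


# Fixed synthetic codon-usage bias shared by all generated species.  Real
# coding sequences show strong codon preferences (the signal a codon-usage
# matrix is trained on); drawing codons uniformly would leave the matrix
# uninformative.  The weights are lognormal with a fixed internal seed —
# they are part of the gene model, like a codon table, not of the sampling
# noise.
def _biased_codon_table() -> tuple[list[str], np.ndarray]:
    from .orf import ALL_CODONS

    codons = [c for c in ALL_CODONS if c not in STOP_CODONS]
    w = np.random.default_rng(777).lognormal(mean=0.0, sigma=0.8, size=len(codons))
    return codons, w / w.sum()


_BODY_CODONS, _BODY_WEIGHTS = _biased_codon_table()


def _make_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + (n-2) biased non-stop codons + random stop."""
    idx = rng.choice(len(_BODY_CODONS), size=n_codons - 2, p=_BODY_WEIGHTS)
    body = [_BODY_CODONS[i] for i in idx]
    stop = _STOPS[rng.integers(0, 3)]
    return "ATG" + "".join(body) + stop


def _make_utr5(rng: np.random.Generator, n: int) -> str:
    """Random leader whose final in-frame codon (relative to the CDS) is a stop.

    Emulates uORF-poor plant leaders: no upstream in-frame ATG can extend
    the true ORF past its start.
    """
    seq = _random_seq(rng, n)
    if n >= 3:
        seq = seq[: n - 3] + _STOPS[rng.integers(0, 3)]
    return seq


def generate_reference_set(
    n_species: int = 6,
    genes_per_species: int = 50,
    length_params: LengthParams | None = None,
    seed: int = 0,
    species_names: Sequence[str] | None = None,
    n_pathways: int = 20,
    tf_families: Sequence[str] | None = None,
    tf_fraction: float = 0.15,
) -> list[ReferenceGene]:
    """Draw a multi-species reference gene set with annotation labels."""
    if n_species < 1 or genes_per_species < 1:
        raise ValueError("n_species and genes_per_species must be >= 1")
    lp = length_params or LengthParams()
    if species_names is None:
        species_names = list(FULLLENGTH_SPECIES_ORDER[:n_species])
        species_names += [f"Species_{i}" for i in range(len(species_names), n_species)]
    if tf_families is None:
        from .tf import example_rules

        tf_families = [r.family for r in example_rules()]
    rng = np.random.default_rng(seed)
    genes: list[ReferenceGene] = []
    for sp_idx, species in enumerate(species_names[:n_species]):
        abbrev = "".join(w[0] for w in species.split()[:2])
        for g in range(genes_per_species):
            gene_id = f"{abbrev}{sp_idx}_g{g:04d}"
            n_codons = max(lp.min_cds_codons, int(round(rng.normal(lp.cds_mean, lp.cds_sd) / 3)))
            cds = _make_cds(rng, n_codons)
            utr5 = _make_utr5(rng, _trunc_normal_int(rng, lp.utr5_mean, lp.utr5_sd, lp.min_utr))
            utr3 = _random_seq(rng, _trunc_normal_int(rng, lp.utr3_mean, lp.utr3_sd, lp.min_utr))
            n_pw = int(rng.integers(0, 3))
            pathways = frozenset(
                f"pw{int(p):03d}" for p in rng.choice(n_pathways, size=n_pw, replace=False)
            )
            tf_family = None
            if tf_families and rng.random() < tf_fraction:
                tf_family = tf_families[int(rng.integers(0, len(tf_families)))]
            label = _ANNOTATION_VOCAB[int(rng.integers(0, len(_ANNOTATION_VOCAB)))]
            genes.append(
                ReferenceGene(
                    gene_id=gene_id,
                    species=species,
                    utr5_seq=utr5,
                    cds_seq=cds,
                    utr3_seq=utr3,
                    strand="+",
                    annotation_label=label,
                    pathway_ids=pathways,
                    tf_family=tf_family,
                    family_id=f"fam_{gene_id}",
                )
            )
    return genes


def annotation_table(genes: Sequence[ReferenceGene]) -> pd.DataFrame:
    """GFF3-like tab-separable annotation of a reference set."""
    rows = []
    for g in genes:
        rows.append(
            {
                "gene_id": g.gene_id,
                "species": g.species,
                "strand": g.strand,
                "utr5_len": len(g.utr5_seq),
                "cds_len": len(g.cds_seq),
                "utr3_len": len(g.utr3_seq),
                "annotation_label": g.annotation_label,
                "pathway_ids": ",".join(sorted(g.pathway_ids)),
                "tf_family": g.tf_family or "",
                "family_id": g.family_id,
            }
        )
    return pd.DataFrame(rows)


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> tuple[str, int]:
    if rate <= 0:
        return seq, 0
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hit:
        cur = arr[i].decode()
        choices = [b for b in "ACGT" if b != cur]
        arr[i] = choices[rng.integers(0, 3)].encode()
    return arr.tobytes().decode(), len(hit)


def _fragment_bounds(
    rng: np.random.Generator, gene: ReferenceGene, k: int, min_piece: int, cds_margin_frac: float
) -> list[tuple[int, int]]:
    """k half-open piece bounds partitioning the mRNA, cuts inside the CDS."""
    L = len(gene.mrna)
    cds_lo, cds_hi = gene.cds_interval  # 1-based inclusive
    margin = max(min_piece, int(np.ceil(cds_margin_frac * len(gene.cds_seq))))
    lo = cds_lo - 1 + margin  # 0-based cut window
    hi = cds_hi - margin
    if hi - lo < (k - 1) * min_piece:
        k = max(2, (hi - lo) // min_piece + 1)
    for _ in range(200):
        cuts = np.sort(rng.integers(lo, hi + 1, size=k - 1))
        if len(cuts) == 0:
            break
        gaps = np.diff(np.concatenate(([lo - margin], cuts, [hi + margin])))
        if (gaps >= min_piece).all() and len(np.unique(cuts)) == k - 1:
            break
    else:
        cuts = np.linspace(lo, hi, k + 1)[1:-1].round().astype(int)
    bounds = []
    prev = 0
    for c in list(cuts) + [L]:
        bounds.append((prev, int(c)))
        prev = int(c)
    return bounds


def _draw_presence(rng: np.random.Generator) -> frozenset:
    u = rng.random()
    acc = 0.0
    for pattern, p in _PRESENCE_PATTERNS:
        acc += p
        if u < acc:
            return pattern
    return frozenset(GENOTYPES)


def generate_contigs(
    genes: Sequence[ReferenceGene],
    profile: ContigProfile | None = None,
    seed: int = 0,
    cds_coverage_gate: float = 0.95,
) -> tuple[dict[str, str], list[TruthRecord]]:
    """Derive a synthetic assembly from a reference set.

    Gene slots are allocated to classes by exact counts (fractions of the
    gene number, rounded), shuffled deterministically.  Returns the contig
    dict and one truth record per contig.
    """
    profile = profile or ContigProfile()
    rng = np.random.default_rng(seed)
    genes = list(genes)
    n = len(genes)
    n_ff = int(round(profile.frac_fulllength * n))
    n_frag = int(round(profile.frac_fragmented * n))
    n_spec = int(round(profile.frac_specific * n))
    n_var = int(round(profile.frac_variant * n))
    order = rng.permutation(n)
    ff_genes = [genes[i] for i in order[:n_ff]]
    frag_genes = [genes[i] for i in order[n_ff : n_ff + n_frag]]
    var_genes = [genes[i] for i in order[n_ff + n_frag : n_ff + n_frag + n_var]]

    contigs: dict[str, str] = {}
    truth: list[TruthRecord] = []
    cid = 0

    def new_id() -> str:
        nonlocal cid
        cid += 1
        return f"contig_{cid:06d}"

    margin_frac = 1.0 - cds_coverage_gate + 0.01

    for g in ff_genes:
        seq, nm = _mutate(rng, g.mrna, profile.substitution_rate)
        c = new_id()
        contigs[c] = seq
        truth.append(
            TruthRecord(c, g.gene_id, "fulllength_single", g.family_id, _draw_presence(rng),
                        (1, len(g.mrna)), nm)
        )
    for g in frag_genes:
        k = int(rng.integers(profile.pieces_range[0], profile.pieces_range[1] + 1))
        bounds = _fragment_bounds(rng, g, k, profile.min_piece, margin_frac)
        presence = _draw_presence(rng)
        for i, (s, e) in enumerate(bounds):
            s2 = max(0, s - profile.overlap)
            e2 = min(len(g.mrna), e + profile.overlap)
            seq, nm = _mutate(rng, g.mrna[s2:e2], profile.substitution_rate)
            c = new_id()
            contigs[c] = seq
            truth.append(
                TruthRecord(c, g.gene_id, f"fragment_{i + 1}_of_{len(bounds)}", g.family_id,
                            presence, (s2 + 1, e2), nm)
            )
    for g in var_genes:
        seq, nm = _mutate(rng, g.mrna, profile.substitution_rate)
        c = new_id()
        contigs[c] = seq
        truth.append(
            TruthRecord(c, g.gene_id, "fulllength_single", g.family_id, _draw_presence(rng),
                        (1, len(g.mrna)), nm)
        )
        for _ in range(profile.n_variants_per_gene - 1):
            seq, nm = _mutate(rng, g.mrna, max(profile.variant_rate, profile.substitution_rate))
            c = new_id()
            contigs[c] = seq
            truth.append(
                TruthRecord(c, g.gene_id, "variant", g.family_id, _draw_presence(rng),
                            (1, len(g.mrna)), nm)
            )
    mean_len = int(np.mean([len(s) for s in contigs.values()])) if contigs else 1200
    for _ in range(n_spec):
        c = new_id()
        contigs[c] = _random_seq(rng, max(200, int(rng.normal(mean_len, mean_len / 4))))
        truth.append(
            TruthRecord(c, "specific", "specific", f"fam_{c}", _draw_presence(rng), None, 0)
        )
    return contigs, truth


def generate_reads(
    contigs: Mapping[str, str],
    truth: Sequence[TruthRecord],
    samples: Sequence[SampleSpec] = DEFAULT_SAMPLES,
    seed: int = 0,
    read_len_mean: float = 194.0,
    read_len_sd: float = 40.0,
    min_read_len: int = 40,
    mean_quality: float = 30.0,
    quality_sd: float = 3.0,
):
    """Draw strand-tagged reads per sample.

    Returns (fastq_records, aln_records, truth) where ``fastq_records`` maps
    sample -> list of (name, seq, qual_string) and ``aln_records`` is a
    DataFrame of the mapper records (read_id, sample_id, target_id, strand,
    t_start, t_end, aln_len).  Truth records get their per-sample
    sense/antisense counts filled in.
    """
    rng = np.random.default_rng(seed)
    by_contig = {t.contig_id: t for t in truth}
    ids = sorted(contigs)
    lens = np.array([len(contigs[c]) for c in ids], dtype=float)
    fastq: dict[str, list[tuple[str, str, str]]] = {}
    aln_rows = []
    for t in truth:
        t.read_counts = {s.sample_id: {"sense": 0, "antisense": 0} for s in samples}
    for spec in samples:
        eligible = np.array([i for i, c in enumerate(ids) if spec.genotype in by_contig[c].genotypes])
        if eligible.size == 0:
            raise ValueError(f"no contigs present in genotype {spec.genotype}")
        weights = lens[eligible]
        weights = weights / weights.sum()
        recs: list[tuple[str, str, str]] = []
        picks = rng.choice(eligible, size=spec.n_reads, p=weights)
        anti = rng.random(spec.n_reads) < spec.antisense_fraction
        for i in range(spec.n_reads):
            c = ids[int(picks[i])]
            cseq = contigs[c]
            L = len(cseq)
            rlen = min(L, max(min_read_len, int(round(rng.normal(read_len_mean, read_len_sd)))))
            start = int(rng.integers(0, L - rlen + 1))
            frag = cseq[start : start + rlen]
            is_anti = bool(anti[i])
            seq = revcomp(frag) if is_anti else frag
            tag = "a" if is_anti else "s"
            name = f"{spec.sample_id}_r{i:07d}/{tag}"
            quals = np.clip(rng.normal(mean_quality, quality_sd, size=rlen).round(), 2, 40)
            qual = "".join(chr(int(qv) + 33) for qv in quals)
            recs.append((name, seq, qual))
            by_contig[c].read_counts[spec.sample_id]["antisense" if is_anti else "sense"] += 1
            aln_rows.append(
                {
                    "read_id": name,
                    "sample_id": spec.sample_id,
                    "target_id": c,
                    "strand": "-" if is_anti else "+",
                    "t_start": start + 1,
                    "t_end": start + rlen,
                    "aln_len": rlen,
                }
            )
        fastq[spec.sample_id] = recs
    return fastq, pd.DataFrame(aln_rows), list(truth)


def _hamming_identity(a: str, b: str) -> tuple[float, int]:
    mism = sum(1 for x, y in zip(a, b) if x != y)
    return 100.0 * (len(a) - mism) / len(a), mism


def emit_truth_hit_tables(
    genes: Sequence[ReferenceGene],
    contigs: Mapping[str, str],
    truth: Sequence[TruthRecord],
) -> tuple[list[AlignmentHit], list[AlignmentHit]]:
    """Hit tables planted contigs would yield against their source mRNAs.

    Returns (forward, reverse): contig-vs-gene and gene-vs-contig.  Specific
    contigs produce no rows; noiseless contigs get identity 100 and exact
    coordinates.  Bit scores are length- and identity-scaled stand-ins.
    """
    missing = [t.contig_id for t in truth if t.contig_id not in contigs]
    if missing:
        raise ValueError(f"truth records without contigs: {missing[:3]}")
    by_gene = {g.gene_id: g for g in genes}
    forward: list[AlignmentHit] = []
    reverse: list[AlignmentHit] = []
    for t in truth:
        if t.origin_gene == "specific":
            continue
        gene = by_gene[t.origin_gene]
        s_lo, s_hi = t.mrna_span
        source = gene.mrna[s_lo - 1 : s_hi]
        cseq = contigs[t.contig_id]
        ident, mism = _hamming_identity(cseq, source)
        aln_len = len(cseq)
        bits = round(2.0 * aln_len * ident / 100.0, 1)
        forward.append(
            AlignmentHit(
                query_id=t.contig_id, subject_id=gene.gene_id, pct_identity=round(ident, 2),
                aln_len=aln_len, mismatches=mism, gap_opens=0,
                q_start=1, q_end=aln_len, s_start=s_lo, s_end=s_hi,
                evalue=1e-180, bit_score=bits,
            )
        )
        reverse.append(
            AlignmentHit(
                query_id=gene.gene_id, subject_id=t.contig_id, pct_identity=round(ident, 2),
                aln_len=aln_len, mismatches=mism, gap_opens=0,
                q_start=s_lo, q_end=s_hi, s_start=1, s_end=aln_len,
                evalue=1e-180, bit_score=bits,
            )
        )
    return forward, reverse


def emit_domain_hits(
    genes: Sequence[ReferenceGene],
    truth: Sequence[TruthRecord],
    rules,
    seed: int = 0,
) -> pd.DataFrame:
    """Domain-hit table for contig proteins, consistent with TF truth labels.

    Contigs derived from a gene carrying ``tf_family`` emit that family's
    required domains (strong e-values); all contigs additionally emit a
    random non-diagnostic domain at low rate to exercise the rule engine.
    """
    rng = np.random.default_rng(seed)
    rules_by_family = {r.family: r for r in rules}
    by_gene = {g.gene_id: g for g in genes}
    rows = []
    for t in truth:
        if t.origin_gene != "specific":
            gene = by_gene[t.origin_gene]
            if gene.tf_family and gene.tf_family in rules_by_family:
                for dom in sorted(rules_by_family[gene.tf_family].required):
                    rows.append(
                        {
                            "protein_id": t.contig_id,
                            "domain_id": dom,
                            "evalue": 10.0 ** float(rng.uniform(-30, -5)),
                            "score": float(np.round(rng.uniform(50, 300), 1)),
                            "env_start": 1,
                            "env_end": 100,
                        }
                    )
        if rng.random() < 0.05:
            rows.append(
                {
                    "protein_id": t.contig_id,
                    "domain_id": "Pkinase",
                    "evalue": 10.0 ** float(rng.uniform(-10, -4)),
                    "score": float(np.round(rng.uniform(20, 80), 1)),
                    "env_start": 1,
                    "env_end": 60,
                }
            )
    return pd.DataFrame(rows, columns=["protein_id", "domain_id", "evalue", "score", "env_start", "env_end"])


def write_fasta(seqs: Mapping[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def write_fastq(records: Iterable[tuple[str, str, str]], path) -> None:
    with open(path, "w") as fh:
        for name, seq, qual in records:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def write_truth_table(truth: Sequence[TruthRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("contig_id\torigin_gene\ttruth_class\tfamily_id\tgenotypes\tmrna_span\tmismatches\n")
        for t in truth:
            span = f"{t.mrna_span[0]}-{t.mrna_span[1]}" if t.mrna_span else ""
            fh.write(
                f"{t.contig_id}\t{t.origin_gene}\t{t.truth_class}\t{t.family_id}"
                f"\t{','.join(sorted(t.genotypes))}\t{span}\t{t.mismatches}\n"
            )
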