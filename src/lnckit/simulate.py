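"""Seeded synthetic-data generator with planted ground truth.

The generator emulates the inputs of a genome-wide lncRNA survey in a small
stress-treated plant: a toy multi-chromosome gene annotation, planted
lncRNAs of all four positional classes (intergenic, antisense, intronic,
sense), negative-binomial fragment counts over a tissues x conditions x
replicates design with planted condition effects, and 21-nt miRNAs with
target-mimic sites written into lncRNA sequences at exact mismatch / G:U
counts.  Every planted label is recorded in :class:`SimTruth`, so each
downstream stage can be tested against known answers.

Negative controls are planted alongside every positive rule: intergenic
lncRNAs whose nearest gene sits beyond the cis window, and mimic sites with
exactly three mismatches (one over the default acceptance threshold).

Sequence content is i.i.d. uniform over A/C/G/T except where a feature is
planted — the simplest null for scanner-specificity tests; coding
transcripts carry a long planted ORF, and lncRNA sequences are post-edited
(stop codons written into any long ORF) so that their longest ORF stays
below the coding cutoff.  Real genomes are messier in ways this generator
deliberately ignores: no isoforms, GC bias, batch effects or length bias.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as lio
from .identify import longest_orf_span
from .models import (
    CountMatrix,
    GenomicInterval,
    SequenceSet,
    TranscriptModel,
    ValidationError,
    revcomp,
)

FAR_MARGIN = 150_000  # nt kept clear on the far side of planted lincRNAs

SENSE_CODONS = [
    c for c in ("".join(p) for p in itertools.product("ACGT", repeat=3))
    if c not in ("TAA", "TAG", "TGA")
]


@dataclass(frozen=True)
class SimParams:
    """Knobs of the generator; defaults mirror the study design the package
    targets (24 samples = 2 tissues x 4 conditions x 3 replicates)."""

    seed: int = 1
    n_chrom: int = 2
    genes_per_chrom: int = 30
    lnc_per_class: int = 10  # genome-wide, per positional class
    # gene structure (nt)
    gene_exon_range: tuple[int, int] = (150, 300)
    gene_intron_range: tuple[int, int] = (200, 800)
    gene_exons_range: tuple[int, int] = (3, 5)
    long_intron_range: tuple[int, int] = (2000, 3000)
    # lncRNA structure (nt)
    lnc_exon_range: tuple[int, int] = (150, 400)
    lnc_intron_range: tuple[int, int] = (200, 600)
    intergenic_gap_range: tuple[int, int] = (3000, 15000)
    # cis geometry
    cis_window: int = 100_000
    linc_gap_range: tuple[int, int] = (5_000, 80_000)
    linc_far_gap_range: tuple[int, int] = (120_000, 140_000)
    linc_far_fraction: float = 0.25
    # counts model
    mean_log_mu: float = 5.0  # log-normal location of per-transcript means
    sd_log_mu: float = 1.0
    dispersion: float = 0.05  # NB alpha in Var = mu + alpha mu^2
    planted_log2fc: float = 3.0
    fraction_de: float = 0.3
    tissues: tuple[str, ...] = ("root", "shoot")
    conditions: tuple[str, ...] = ("CK", "LS", "SS", "R")
    replicates: int = 3
    de_conditions: tuple[str, str] = ("CK", "SS")
    # miRNA / mimicry
    n_mirna: int = 5
    mirna_len: int = 21
    mimic_plan: tuple[tuple[int, int], ...] = ((0, 0), (1, 0), (2, 0), (3, 0), (0, 2))
    max_orf_nt: int = 300  # planted lncRNAs keep their longest ORF below this
    chrom_length: int | None = None

    def __post_init__(self) -> None:
        if self.dispersion < 0 or self.sd_log_mu <= 0:
            raise ValidationError("counts parameters must be positive")
        if not (0 <= self.fraction_de <= 1):
            raise ValidationError("fraction_de must lie in [0, 1]")
        if self.replicates < 1:
            raise ValidationError("need >= 1 replicate")


@dataclass(frozen=True)
class MimicSite:
    lncrna_id: str
    mirna_id: str
    offset: int
    mismatches: int
    gu_pairs: int


@dataclass
class SimTruth:
    """Planted ground truth emitted alongside the synthetic data."""

    lncrna_classes: dict[str, str] = field(default_factory=dict)
    de_transcripts: dict[tuple[str, str], float] = field(default_factory=dict)
    mimic_sites: list[MimicSite] = field(default_factory=list)
    cis_pairs: list[tuple[str, str, int]] = field(default_factory=list)
    cis_negative_lincs: list[tuple[str, int]] = field(default_factory=list)


def _rng(params: SimParams, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([params.seed, stream]))


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def _suppress_orfs(seq: str, max_orf: int, keep: list[tuple[int, int]] | None = None
                   ) -> str:
    """Write TAA stops into the sequence until its longest ORF is < max_orf.

    Intervals in ``keep`` (e.g. planted mimic sites) are never edited; a
    codon-aligned position outside them always exists because any ORF of
    max_orf length far exceeds a planted site.
    """
    keep = keep or []
    s = list(seq)
    for _ in range(len(seq)):  # hard bound; each edit shortens some ORF
        start, end = longest_orf_span("".join(s))
        if end - start < max_orf:
            return "".join(s)
        placed = False
        # walk codon-aligned positions from the middle of the ORF outward
        n_codons = (end - start) // 3
        mid = n_codons // 2
        for delta in range(n_codons):
            for idx in {mid - delta, mid + delta}:
                if not 0 < idx < n_codons - 1:
                    continue
                pos = start + 3 * idx
                if any(pos < ke and ks < pos + 3 for ks, ke in keep):
                    continue
                s[pos : pos + 3] = "TAA"
                placed = True
                break
            if placed:
                break
        if not placed:
            raise ValidationError("cannot suppress ORF without touching a planted site")
    return "".join(s)


def _build_exons(chrom: str, strand: str, start: int, exon_lens: list[int],
                 intron_lens: list[int]) -> tuple[GenomicInterval, ...]:
    exons = []
    pos = start
    for i, el in enumerate(exon_lens):
        exons.append(GenomicInterval(chrom, pos, pos + el, strand))
        pos += el
        if i < len(intron_lens):
            pos += intron_lens[i]
    return tuple(exons)


def _make_gene(rng: np.random.Generator, params: SimParams, chrom: str,
               start: int, gid: str) -> TranscriptModel:
    n_ex = int(rng.integers(params.gene_exons_range[0], params.gene_exons_range[1] + 1))
    exon_lens = [int(rng.integers(*params.gene_exon_range)) for _ in range(n_ex)]
    intron_lens = [int(rng.integers(*params.gene_intron_range)) for _ in range(n_ex - 1)]
    # one guaranteed long intron so intronic lncRNAs always have a home
    long_i = int(rng.integers(0, n_ex - 1))
    intron_lens[long_i] = int(rng.integers(*params.long_intron_range))
    strand = "+" if rng.random() < 0.5 else "-"
    exons = _build_exons(chrom, strand, start, exon_lens, intron_lens)
    return TranscriptModel(
        transcript_id=f"{gid}.m1", gene_id=gid, exons=exons,
        class_code="=", biotype="coding",
    )


def _lnc_structure(rng: np.random.Generator, params: SimParams) -> tuple[list[int], list[int]]:
    n_ex = int(rng.integers(2, 4))  # 2-3 exons; never single-exon
    exon_lens = [int(rng.integers(*params.lnc_exon_range)) for _ in range(n_ex)]
    intron_lens = [int(rng.integers(*params.lnc_intron_range)) for _ in range(n_ex - 1)]
    return exon_lens, intron_lens


def simulate_genome(params: SimParams) -> tuple[list[TranscriptModel], SequenceSet, SimTruth]:
    """Generate the annotation (coding genes + planted lncRNAs), transcript
    sequences, and the planted truth.

    Genes are laid down sequentially per chromosome; intergenic lncRNAs get
    a dedicated intergenic slot whose near-side gap is the planted cis
    distance and whose far side is kept clear, so the planted nearest-gene
    distance is exact.  Antisense, intronic and sense lncRNAs are anchored
    on distinct host genes such that the positional classifier's precedence
    rules recover the planted class exactly.
    """
    rng = _rng(params, 0)
    n_linc = params.lnc_per_class
    n_far = int(round(n_linc * params.linc_far_fraction))
    truth = SimTruth()
    genes: list[TranscriptModel] = []
    lncs: list[TranscriptModel] = []

    # round-robin allocation of planted features to chromosomes
    chrom_of = lambda i: f"chr{(i % params.n_chrom) + 1}"
    per_chrom_genes = params.genes_per_chrom
    total_hosts_needed = 3 * params.lnc_per_class  # antisense + intronic + sense
    if total_hosts_needed + 1 > per_chrom_genes * params.n_chrom:
        raise ValidationError(
            "not enough genes to host the requested lncRNAs; increase "
            f"genes_per_chrom to >= {(total_hosts_needed + 1) // params.n_chrom + 1}"
        )

    lnc_counter = {"lincRNA": 0, "antisense": 0, "intronic": 0, "sense": 0}
    linc_slots: dict[str, list[tuple[str, int]]] = {}  # chrom -> [(linc_id, gap)]
    for i in range(n_linc):
        gap = (
            int(rng.integers(*params.linc_far_gap_range))
            if i < n_far
            else int(rng.integers(*params.linc_gap_range))
        )
        lid = f"lnc_linc_{i:03d}"
        linc_slots.setdefault(chrom_of(i), []).append((lid, gap))
        truth.lncrna_classes[lid] = "lincRNA"

    host_classes: list[str] = []
    for cls in ("antisense", "intronic", "sense"):
        host_classes += [cls] * params.lnc_per_class

    for c in range(params.n_chrom):
        chrom = f"chr{c + 1}"
        cursor = 2000  # room for lncRNAs extending upstream of the first gene
        slots = list(linc_slots.get(chrom, []))
        # hosts for anchored lncRNAs on this chromosome, spread over genes
        hosts = [h for h in range(len(host_classes)) if h % params.n_chrom == c]
        host_q = list(hosts)
        for j in range(per_chrom_genes):
            gid = f"gene_{chrom}_{j:03d}"
            gene = _make_gene(rng, params, chrom, cursor, gid)
            genes.append(gene)
            gspan = gene.span()

            if host_q and j % 2 == 0:  # anchor a lncRNA on every other gene
                h = host_q.pop(0)
                cls = host_classes[h]
                k = lnc_counter[cls]
                lnc_counter[cls] += 1
                lid = f"lnc_{cls[:4]}_{k:03d}"
                if cls == "antisense":
                    strand = "-" if gene.strand == "+" else "+"
                    e2 = GenomicInterval(chrom, gspan.start - 200, gspan.start + 150, strand)
                    e1_end = gspan.start - 200 - int(rng.integers(*params.lnc_intron_range))
                    e1 = GenomicInterval(
                        chrom, e1_end - int(rng.integers(*params.lnc_exon_range)),
                        e1_end, strand)
                    exons = (e1, e2)
                    code = "x"
                elif cls == "intronic":
                    intr = max(gene.introns(), key=len)
                    exon_lens = [250, 250]
                    intron_len = min(
                        int(rng.integers(*params.lnc_intron_range)),
                        len(intr) - sum(exon_lens) - 100,
                    )
                    exons = _build_exons(chrom, gene.strand, intr.start + 50,
                                         exon_lens, [max(intron_len, 60)])
                    if exons[-1].end > intr.end:
                        raise ValidationError(
                            "host intron too short for intronic lncRNA; "
                            "increase long_intron_range"
                        )
                    code = "i"
                else:  # sense: overlap the host's last exon by 80 nt
                    last = gene.exons[-1]
                    e1 = GenomicInterval(chrom, last.end - 80,
                                         last.end + int(rng.integers(150, 300)),
                                         gene.strand)
                    gap_i = int(rng.integers(*params.lnc_intron_range))
                    e2_start = e1.end + gap_i
                    e2 = GenomicInterval(chrom, e2_start,
                                         e2_start + int(rng.integers(*params.lnc_exon_range)),
                                         gene.strand)
                    exons = (e1, e2)
                    code = "o" if k % 2 == 0 else "e"
                lnc = TranscriptModel(transcript_id=lid, gene_id="",
                                      exons=exons, class_code=code,
                                      biotype="lncRNA")
                lncs.append(lnc)
                truth.lncrna_classes[lid] = cls
                truth.cis_pairs.append((lid, gene.transcript_id, 0))

            cursor = gspan.end + int(rng.integers(*params.intergenic_gap_range))
            # reserve the next intergenic slot for a planted lincRNA
            if slots and j % max(per_chrom_genes // (len(linc_slots.get(chrom, [])) + 1), 1) == 0 and j > 0:
                lid, gap = slots.pop(0)
                exon_lens, intron_lens = _lnc_structure(rng, params)
                exons = _build_exons(chrom, "+" if rng.random() < 0.5 else "-",
                                     gspan.end + gap, exon_lens, intron_lens)
                lnc = TranscriptModel(transcript_id=lid, gene_id="",
                                      exons=exons, class_code="u",
                                      biotype="lncRNA")
                lncs.append(lnc)
                if gap < params.cis_window:
                    truth.cis_pairs.append((lid, gene.transcript_id, gap))
                else:
                    truth.cis_negative_lincs.append((lid, gap))
                cursor = lnc.span().end + FAR_MARGIN
        if slots:
            raise ValidationError(
                "could not place all planted lincRNAs; increase genes_per_chrom"
            )
        if host_q:
            raise ValidationError(
                "not enough genes to anchor all planted lncRNAs; increase "
                "genes_per_chrom"
            )
        if params.chrom_length is not None and cursor > params.chrom_length:
            raise ValidationError(
                f"chromosome {chrom} too short ({params.chrom_length} nt); "
                f"needs >= {cursor} nt"
            )

    # transcript sequences
    seqs = SequenceSet()
    for gene in genes:
        L = gene.length
        utr = min(120, max(L - 330, 0))
        orf_nt = ((L - utr) // 3) * 3
        n_codons = orf_nt // 3 - 2
        body = rng.integers(0, len(SENSE_CODONS), size=n_codons)
        orf = "ATG" + "".join(SENSE_CODONS[int(b)] for b in body) + "TAA"
        head = _random_seq(rng, utr // 2)
        tail = _random_seq(rng, L - len(orf) - len(head))
        seqs.add(gene.transcript_id, head + orf + tail)
    mrna_seqs = {g.transcript_id: seqs[g.transcript_id] for g in genes}

    host_of = {}
    for lid, gid, gap in truth.cis_pairs:
        if gap == 0:
            host_of[lid] = gid
    for lnc in lncs:
        raw = _random_seq(rng, lnc.length)
        cls = truth.lncrna_classes[lnc.transcript_id]
        if cls == "antisense":
            # plant partial complementarity to the host mRNA so the
            # trans-target scan has true positives
            host = host_of.get(lnc.transcript_id)
            if host is not None:
                m = mrna_seqs[host]
                w = min(120, len(m), max(len(raw) - 10, 0))
                if w >= 20:
                    src_off = int(rng.integers(0, len(m) - w + 1))
                    dst_off = int(rng.integers(0, len(raw) - w + 1))
                    window = revcomp(m[src_off : src_off + w])
                    raw = raw[:dst_off] + window + raw[dst_off + w :]
        seqs.add(lnc.transcript_id, _suppress_orfs(raw, params.max_orf_nt))

    return genes + lncs, seqs, truth


def simulate_mirnas(params: SimParams) -> SequenceSet:
    """Random mature miRNAs (RNA alphabet, written back with U)."""
    rng = _rng(params, 1)
    out = SequenceSet()
    for i in range(params.n_mirna):
        seq = "".join(np.array(list("ACGU"))[rng.integers(0, 4, size=params.mirna_len)])
        out.add(f"mir_{i:03d}", seq)
    return out


def _site_for(rc: str, mm: int, gu: int, rng: np.random.Generator) -> str:
    """A site pairing the miRNA (given as its reverse complement ``rc``)
    with exactly ``mm`` mismatches and ``gu`` G:U wobble pairs."""
    if mm + gu > len(rc):
        raise ValidationError("requested edits exceed miRNA length")
    if mm >= len(rc):
        raise ValidationError("requested mismatches exceed miRNA length")
    site = list(rc)
    gu_able = [i for i, b in enumerate(rc) if b in "AC"]
    if len(gu_able) < gu:
        raise ValidationError("miRNA sequence cannot host the requested G:U pairs")
    gu_pos = list(rng.choice(gu_able, size=gu, replace=False)) if gu else []
    for i in gu_pos:
        site[i] = "G" if rc[i] == "A" else "T"
    rest = [i for i in range(len(rc)) if i not in set(gu_pos)]
    mm_pos = list(rng.choice(rest, size=mm, replace=False)) if mm else []
    mm_choices = {"A": "CT", "C": "AG", "G": "ACT", "T": "ACG"}
    for i in mm_pos:
        opts = mm_choices[rc[i]]
        site[i] = opts[int(rng.integers(0, len(opts)))]
    return "".join(site)


def plant_mimic_sites(
    lnc_seqs: SequenceSet,
    mirnas: SequenceSet,
    params: SimParams,
    truth: SimTruth | None = None,
) -> tuple[SequenceSet, SimTruth]:
    """Write mimic sites with exact (mismatch, G:U) counts into lncRNAs.

    Requests from ``params.mimic_plan`` are assigned round-robin over
    (lncRNA, miRNA) pairs; each planted offset is recorded in the truth and
    the edited sequence is re-checked so its longest ORF stays below the
    coding cutoff without touching the planted site.
    """
    rng = _rng(params, 2)
    truth = truth or SimTruth()
    lnc_ids = sorted(lnc_seqs.ids())
    mir_ids = sorted(mirnas.ids())
    if not lnc_ids or not mir_ids:
        raise ValidationError("need at least one lncRNA and one miRNA")
    edited = {lid: lnc_seqs[lid] for lid in lnc_ids}
    used: dict[str, list[tuple[int, int]]] = {lid: [] for lid in lnc_ids}
    for r, (mm, gu) in enumerate(params.mimic_plan):
        lid = lnc_ids[r % len(lnc_ids)]
        mid = mir_ids[r % len(mir_ids)]
        mir = mirnas[mid]
        if len(edited[lid]) < len(mir):
            raise ValidationError(f"{lid}: shorter than miRNA {mid}")
        site = _site_for(revcomp(mir), mm, gu, rng)
        # find a free, non-overlapping offset
        for _ in range(200):
            off = int(rng.integers(0, len(edited[lid]) - len(mir) + 1))
            if all(off + len(mir) <= s or e <= off for s, e in used[lid]):
                break
        else:
            raise ValidationError(f"{lid}: no room for another mimic site")
        seq = edited[lid]
        seq = seq[:off] + site + seq[off + len(site):]
        seq = _suppress_orfs(seq, 300, keep=used[lid] + [(off, off + len(site))])
        edited[lid] = seq
        used[lid].append((off, off + len(site)))
        truth.mimic_sites.append(MimicSite(lid, mid, off, mm, gu))
    out = SequenceSet({lid: edited[lid] for lid in lnc_ids})
    return out, truth


def simulate_counts(
    transcripts: list[TranscriptModel],
    params: SimParams,
    truth: SimTruth | None = None,
) -> tuple[CountMatrix, SimTruth]:
    """Negative-binomial counts over the full design with planted effects.

    Per-transcript means are log-normal; per-sample size factors are drawn
    uniformly in [0.5, 2]; a ``fraction_de`` subset of transcripts gets a
    planted +/- log2 fold change applied to the second condition of
    ``params.de_conditions`` (in both tissues); counts are NB with
    ``Var = mu + alpha mu^2``.
    """
    if params.replicates < 2:
        raise ValidationError("differential expression needs >= 2 replicates")
    rng = _rng(params, 3)
    truth = truth or SimTruth()
    tids = [t.transcript_id for t in transcripts]
    n = len(tids)
    mu = rng.lognormal(params.mean_log_mu, params.sd_log_mu, size=n)

    n_de = int(round(params.fraction_de * n))
    de_idx = rng.choice(n, size=n_de, replace=False) if n_de else np.array([], dtype=int)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    lfc = np.zeros(n)
    lfc[de_idx] = signs * params.planted_log2fc
    contrast = f"{params.de_conditions[0]}_vs_{params.de_conditions[1]}"
    for i, s in zip(de_idx, signs):
        truth.de_transcripts[(tids[int(i)], contrast)] = float(s * params.planted_log2fc)

    samples = []
    for tissue in params.tissues:
        for cond in params.conditions:
            for rep in range(1, params.replicates + 1):
                samples.append((f"{tissue}_{cond}_{rep}", tissue, cond, rep))
    sf = rng.uniform(0.5, 2.0, size=len(samples))

    counts = np.zeros((n, len(samples)), dtype=np.int64)
    alpha = params.dispersion
    for j, (sid, tissue, cond, rep) in enumerate(samples):
        m = mu * sf[j]
        if cond == params.de_conditions[1]:
            m = m * np.power(2.0, lfc)
        if alpha > 0:
            shape = 1.0 / alpha
            p = shape / (shape + m)
            counts[:, j] = rng.negative_binomial(shape, p)
        else:
            counts[:, j] = rng.poisson(m)
    cdf = pd.DataFrame(counts, index=tids, columns=[s[0] for s in samples])
    sheet = pd.DataFrame(
        [{"sample_id": s[0], "tissue": s[1], "condition": s[2], "replicate": s[3]}
         for s in samples]
    )
    return CountMatrix(cdf, sheet), truth


def simulate_all(params: SimParams, outdir: str | Path) -> SimTruth:
    """Run the full generator and write every artefact to ``outdir``.

    Files: ``annotation.gtf`` (genes + lncRNAs with class codes),
    ``reference.gff3`` (coding genes), ``transcripts.fa``, ``mirnas.fa``,
    ``counts.tsv`` + ``samples.tsv``, and truth tables
    (``truth_classes.tsv``, ``truth_de.tsv``, ``truth_mimics.tsv``,
    ``truth_cis.tsv``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    transcripts, seqs, truth = simulate_genome(params)
    genes = [t for t in transcripts if t.biotype == "coding"]
    lnc_ids = set(truth.lncrna_classes)
    mirnas = simulate_mirnas(params)
    lnc_seqs = SequenceSet({i: seqs[i] for i in sorted(lnc_ids) if i in seqs})
    lnc_seqs, truth = plant_mimic_sites(lnc_seqs, mirnas, params, truth)
    merged = SequenceSet()
    for sid, s in seqs.items():
        merged.add(sid, lnc_seqs[sid] if sid in lnc_seqs else s)
    cm, truth = simulate_counts(transcripts, params, truth)

    lio.write_gtf(transcripts, outdir / "annotation.gtf")
    lio.write_gff3(genes, outdir / "reference.gff3")
    lio.write_fasta(merged, outdir / "transcripts.fa")
    lio.write_fasta(mirnas, outdir / "mirnas.fa")
    lio.write_counts(cm, outdir / "counts.tsv", outdir / "samples.tsv")

    lio.write_table(
        pd.DataFrame(
            [{"transcript_id": t, "planted_class": c}
             for t, c in truth.lncrna_classes.items()],
            columns=["transcript_id", "planted_class"],
        ),
        outdir / "truth_classes.tsv",
    )
    lio.write_table(
        pd.DataFrame(
            [{"transcript_id": t, "contrast": c, "planted_log2fc": v}
             for (t, c), v in truth.de_transcripts.items()],
            columns=["transcript_id", "contrast", "planted_log2fc"],
        ),
        outdir / "truth_de.tsv",
    )
    lio.write_table(
        pd.DataFrame(
            [vars(m) for m in truth.mimic_sites],
            columns=["lncrna_id", "mirna_id", "offset", "mismatches", "gu_pairs"],
        ),
        outdir / "truth_mimics.tsv",
    )
    cis_rows = [
        {"lncrna_id": l, "gene_id": g, "gap_nt": gap, "is_positive": True}
        for l, g, gap in truth.cis_pairs
    ] + [
        {"lncrna_id": l, "gene_id": "", "gap_nt": gap, "is_positive": False}
        for l, gap in truth.cis_negative_lincs
    ]
    lio.write_table(
        pd.DataFrame(cis_rows,
                     columns=["lncrna_id", "gene_id", "gap_nt", "is_positive"]),
        outdir / "truth_cis.tsv",
    )
    return truth
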