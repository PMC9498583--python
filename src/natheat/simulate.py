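"""Synthetic heat-stress transcriptome generator with a machine-readable truth table.

Emulates the study design the analysis modules expect: both-strand
transcript architecture with controlled antisense overlap configurations,
log-normal TPM with planted heat fold-changes over 5 tissues x {0,1,5} h x 3
replicates, smRNA reads enriched over NAT overlap regions and NAT-gene TSS
windows, TSS-proximal histone peaks, context-specific cytosine methylation
with planted temporal shifts, and promoter sequences with planted heat-shock
elements.  Every planted structure is recorded in the truth table so each
pipeline stage can be tested without external data.

Determinism contract: identical config (including seed) gives byte-identical
outputs.  Each stage draws from its own generator seeded ``seed + stage
index`` so stages are independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chromatin import DEFAULT_MARKS, METH_CONTEXTS
from .expression import ExpressionMatrix, TISSUES, TREATED_TIMEPOINTS, make_design
from .genome import GenomeAnnotation, IntervalSet, TranscriptModel, tss_of, tss_window
from .smrna import SmallRnaRead

CONFIGS = ("enclosed", "convergent", "divergent")


class ConfigError(ValueError):
    pass


@dataclass
class SimulationConfig:
    seed: int = 0
    n_gene_loci: int = 200
    chrom_sizes: dict = field(default_factory=lambda: {"chr1": 1_500_000, "chr2": 1_500_000})
    frac_with_antisense: float = 0.5
    # enclosed share matches the study (64.5%); the convergent/divergent split
    # of the remainder is not reported and is fixed here once
    configuration_mix: dict = field(
        default_factory=lambda: {"enclosed": 0.645, "convergent": 0.20, "divergent": 0.155}
    )
    pair_type_mix: dict = field(
        default_factory=lambda: {"mRNA-mRNA": 0.034, "mRNA-lncRNA": 0.904, "lncRNA-lncRNA": 0.062}
    )
    frac_heat_responsive: float = 0.152
    planted_log2fc_range: tuple = (1.5, 4.0)
    replicate_cv: float = 0.2
    baseline_log_tpm_mean: float = 2.0  # natural-log scale
    baseline_log_tpm_sd: float = 1.0
    lnc_log_tpm_offset: float = -1.5  # lncRNAs sit lower than mRNAs
    frac_concordant: float = 0.81
    attenuation_5h: float = 1.0  # multiplier on planted log2FC at 5 h
    smrna_background_rate: float = 10.0  # reads per kb
    smrna_overlap_enrichment: float = 2.4
    smrna_24nt_weight: float = 0.0  # 0 = uniform 18-30 nt lengths
    frac_tss_marked: dict | float = 0.5  # per-mark proportion of marked genes
    methylation_context_means: dict = field(
        default_factory=lambda: {"CpG": 0.50, "CHH": 0.30, "CHG": 0.15}
    )
    meth_frac_down: float = 0.6
    meth_shift_magnitude: float = 0.05
    meth_beta_concentration: float = 30.0
    meth_cytosines_per_gene: int = 40
    # a transcript can only be observed as heat-repressed if it was expressed
    # in control samples; baselines of down-regulated truth members are drawn
    # from the log-normal truncated below at this TPM
    min_down_baseline_tpm: float = 5.0
    # decoy counts for the classification cascade
    n_lincrna: int = 20
    n_incrna: int = 10
    n_short_decoys: int = 10
    n_blacklist_decoys: int = 10
    n_coding_decoys: int = 10
    promoter_len: int = 300
    frac_promoter_hse: float = 0.5

    def __post_init__(self) -> None:
        for name in ("frac_with_antisense", "frac_heat_responsive", "frac_concordant",
                     "meth_frac_down", "frac_promoter_hse"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        for mix_name in ("configuration_mix", "pair_type_mix"):
            mix = getattr(self, mix_name)
            if abs(sum(mix.values()) - 1.0) > 1e-9 or any(v < 0 for v in mix.values()):
                raise ConfigError(f"{mix_name} must be non-negative and sum to 1")
        lo, hi = self.planted_log2fc_range
        if not (1.0 <= abs(lo) <= abs(hi)):
            raise ConfigError("planted |log2FC| must be >= 1 so effects exceed the 2-fold threshold")
        if self.replicate_cv < 0:
            raise ConfigError("replicate_cv must be >= 0")

    def marked_fraction(self, mark: str) -> float:
        if isinstance(self.frac_tss_marked, dict):
            return self.frac_tss_marked[mark]
        return float(self.frac_tss_marked)


@dataclass
class TruthTable:
    """Ground truth for every planted structure.

    transcripts: transcript_id, gene_id, true_class, expected_status,
    meth_direction, has_hse.  pairs: oriented truth pairs with configuration,
    pair type, responsiveness, concordance sign and smRNA-enrichment flag.
    effects: planted log2FC per (transcript, tissue, treated timepoint).
    labels: external coding-potential labels.  conservation: optional
    rice-homology scores for mRNA pair members.
    """

    transcripts: pd.DataFrame
    pairs: pd.DataFrame
    effects: pd.DataFrame
    labels: pd.DataFrame
    conservation: pd.DataFrame


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

_LEAD = 1600  # room reserved upstream/downstream of a primary gene for its partner


def _make_exons(rng: np.random.Generator, span: tuple[int, int], max_exons: int = 3) -> list:
    s, e = span
    n = int(rng.integers(1, max_exons + 1))
    if n == 1 or e - s < 1200:
        return [span]
    cuts = []
    # carve n-1 introns of 100-250 bp at interior positions
    interior = np.sort(rng.choice(np.arange(s + 300, e - 300, 10), size=n - 1, replace=False))
    exons = []
    prev = s
    ok = True
    for pos in interior:
        ilen = int(rng.integers(100, 251))
        if pos - prev < 100 or pos + ilen > e - 200:
            ok = False
            break
        exons.append((prev, int(pos)))
        prev = int(pos) + ilen
    if not ok:
        return [span]
    exons.append((prev, e))
    return exons


def generate_annotation(cfg: SimulationConfig) -> tuple[GenomeAnnotation, TruthTable, IntervalSet]:
    """Plant gene loci, NAT partners and classification decoys along the genome.

    Returns the annotation, the truth table and the structural-RNA blacklist.
    Raises ConfigError when the requested loci do not fit the chromosomes.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    ann = GenomeAnnotation(chrom_sizes=dict(cfg.chrom_sizes))
    blacklist = IntervalSet()

    chroms = sorted(cfg.chrom_sizes)
    cursors = {c: 1000 for c in chroms}

    tr_rows, pair_rows, label_rows, cons_rows = [], [], [], []

    def place(footprint: int) -> tuple[str, int]:
        chrom = min(chroms, key=lambda c: cursors[c] / cfg.chrom_sizes[c])
        base = cursors[chrom]
        gap = int(rng.integers(2300, 3200))
        if base + footprint + gap > cfg.chrom_sizes[chrom] - 1000:
            raise ConfigError(
                f"infeasible packing: loci do not fit chrom_sizes (stuck at {chrom}:{base})"
            )
        cursors[chrom] = base + footprint + gap
        return chrom, base

    def add_transcript(tid, gid, chrom, strand, span, biotype, true_class, expected, exons=None):
        t = TranscriptModel(tid, gid, chrom, strand, span, exons or [span], biotype)
        ann.add(t)
        tr_rows.append((tid, gid, chrom, true_class, expected))
        if biotype != "mRNA":
            label_rows.append((tid, "coding" if expected == "discarded_coding" else "noncoding"))
        return t

    config_names = sorted(cfg.configuration_mix)
    config_p = np.array([cfg.configuration_mix[c] for c in config_names])
    ptype_names = sorted(cfg.pair_type_mix)
    ptype_p = np.array([cfg.pair_type_mix[c] for c in ptype_names])

    for i in range(cfg.n_gene_loci):
        paired = rng.random() < cfg.frac_with_antisense
        L1 = int(rng.integers(1500, 3001))
        chrom, base = place(2 * _LEAD + L1)
        s1 = base + _LEAD
        e1 = s1 + L1
        strand1 = "+" if rng.random() < 0.5 else "-"
        gid = f"g{i:05d}"
        ptype = str(rng.choice(ptype_names, p=ptype_p)) if paired else None
        primary_is_mrna = ptype != "lncRNA-lncRNA"
        primary = add_transcript(
            f"TU{i:05d}A",
            gid + "a",
            chrom,
            strand1,
            (s1, e1),
            "mRNA" if primary_is_mrna else "lncRNA",
            "mRNA" if primary_is_mrna else "NAT_member",
            "annotated_mRNA" if primary_is_mrna else "lincRNA",
            _make_exons(rng, (s1, e1)),
        )
        if not paired:
            continue
        configuration = str(rng.choice(config_names, p=config_p))
        if configuration == "enclosed":
            L2 = int(rng.integers(250, max(251, min(L1 - 100, 2000))))
            o = int(rng.integers(50, L1 - L2 - 49))
            s2, e2 = s1 + o, s1 + o + L2
            overlap = (s2, e2)
        else:
            ov = int(rng.integers(100, min(601, L1 - 99)))
            ext = int(rng.integers(200, 1501))
            L2 = ov + ext
            # convergent: partner crosses the primary 3' end; divergent: the 5' end
            at_end = (configuration == "convergent") == (strand1 == "+")
            if at_end:
                s2, e2 = e1 - ov, e1 - ov + L2
                overlap = (s2, e1)
            else:
                s2, e2 = s1 + ov - L2, s1 + ov
                overlap = (s1, e2)
        strand2 = "-" if strand1 == "+" else "+"
        partner_is_mrna = ptype == "mRNA-mRNA"
        partner = add_transcript(
            f"TU{i:05d}B",
            gid + "b",
            chrom,
            strand2,
            (s2, e2),
            "mRNA" if partner_is_mrna else "lncRNA",
            "mRNA" if partner_is_mrna else "NAT_member",
            "annotated_mRNA" if partner_is_mrna else ("lincRNA" if not primary_is_mrna else "NAT_candidate"),
            _make_exons(rng, (s2, e2), max_exons=2),
        )
        if partner_is_mrna:
            cons_rows.append((primary.transcript_id, round(float(rng.uniform(0.6, 0.95)), 4)))
            cons_rows.append((partner.transcript_id, round(float(rng.uniform(0.1, 0.5)), 4)))
        responsive = rng.random() < cfg.frac_heat_responsive
        sign = 0
        if responsive:
            sign = 1 if rng.random() < cfg.frac_concordant else -1
        pair_rows.append(
            (
                primary.transcript_id,
                partner.transcript_id,
                chrom,
                overlap[0],
                overlap[1],
                configuration,
                ptype,
                responsive,
                sign,
                cfg.smrna_overlap_enrichment != 1.0,
            )
        )

    for j in range(cfg.n_lincrna):
        L = int(rng.integers(300, 1501))
        chrom, base = place(L + 200)
        strand = "+" if rng.random() < 0.5 else "-"
        add_transcript(
            f"LINC{j:04d}", f"linc{j:04d}", chrom, strand, (base, base + L),
            "lncRNA", "lincRNA", "lincRNA", _make_exons(rng, (base, base + L), max_exons=2),
        )

    for j in range(cfg.n_incrna):
        chrom, base = place(3000)
        strand = "+" if rng.random() < 0.5 else "-"
        host_span = (base, base + 2500)
        add_transcript(
            f"HOST{j:04d}", f"host{j:04d}", chrom, strand, host_span,
            "mRNA", "mRNA", "annotated_mRNA", [(base, base + 800), (base + 1700, base + 2500)],
        )
        L = int(rng.integers(250, 501))
        s = base + 850 + int(rng.integers(0, 800 - 50 - L))
        # same strand as host: an opposite-strand intronic transcript would be
        # (correctly) classified antisense, not intronic
        add_transcript(f"INC{j:04d}", f"inc{j:04d}", chrom, strand, (s, s + L), "lncRNA", "incRNA", "incRNA")

    for j in range(cfg.n_short_decoys):
        L = int(rng.integers(50, 200))
        chrom, base = place(L + 200)
        add_transcript(
            f"SHORT{j:04d}", f"short{j:04d}", chrom, "+", (base, base + L),
            "lncRNA", "short_decoy", "discarded_short",
        )

    for j in range(cfg.n_blacklist_decoys):
        chrom, base = place(800)
        blacklist.add(chrom, base, base + 200, None)
        add_transcript(
            f"BLK{j:04d}", f"blk{j:04d}", chrom, "-", (base + 150, base + 600),
            "lncRNA", "blacklist_decoy", "discarded_blacklist",
        )

    for j in range(cfg.n_coding_decoys):
        L = int(rng.integers(300, 1001))
        chrom, base = place(L + 200)
        add_transcript(
            f"CODY{j:04d}", f"cody{j:04d}", chrom, "+", (base, base + L),
            "lncRNA", "coding_decoy", "discarded_coding",
        )

    transcripts = pd.DataFrame(
        tr_rows, columns=["transcript_id", "gene_id", "chrom", "true_class", "expected_status"]
    )
    pairs = pd.DataFrame(
        pair_rows,
        columns=[
            "sense_id", "antisense_id", "chrom", "overlap_start", "overlap_end",
            "configuration", "pair_type", "responsive", "concordance_sign", "smrna_enriched",
        ],
    )
    effects = _plant_effects(rng, pairs, cfg)
    truth = TruthTable(
        transcripts=transcripts,
        pairs=pairs,
        effects=effects,
        labels=pd.DataFrame(label_rows, columns=["transcript_id", "label"]),
        conservation=pd.DataFrame(cons_rows, columns=["transcript_id", "score"]),
    )
    return ann, truth, blacklist


def _plant_effects(rng: np.random.Generator, pairs: pd.DataFrame, cfg: SimulationConfig) -> pd.DataFrame:
    lo, hi = cfg.planted_log2fc_range
    rows = []
    for p in pairs.itertuples(index=False):
        if not p.responsive:
            continue
        n_tissues = int(rng.integers(1, 3))
        tissues = rng.choice(TISSUES, size=n_tissues, replace=False)
        for member, member_sign in ((p.sense_id, 1), (p.antisense_id, p.concordance_sign)):
            mag = float(rng.uniform(lo, hi))
            for tissue in tissues:
                for tp in TREATED_TIMEPOINTS:
                    att = cfg.attenuation_5h if tp == 5 else 1.0
                    rows.append((member, tissue, tp, member_sign * mag * att))
    return pd.DataFrame(rows, columns=["transcript_id", "tissue", "timepoint_h", "log2fc"])


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def simulate_expression(
    annotation: GenomeAnnotation, truth: TruthTable, cfg: SimulationConfig
) -> ExpressionMatrix:
    """TPM = baseline x 2^(planted log2FC) x log-normal replicate noise.

    Baseline log TPM is normal per transcript (lncRNAs offset downward);
    noise has unit mean and CV ``replicate_cv`` (exactly 1 when CV = 0).
    Members carrying a planted negative log2FC draw their baseline from the
    same log-normal truncated below at ``min_down_baseline_tpm``: repression
    is only observable on transcripts expressed under control conditions.
    """
    from scipy.stats import norm

    rng = np.random.default_rng(cfg.seed + 2)
    design = make_design()
    ids = [t.transcript_id for t in annotation.sorted_transcripts()]
    is_mrna = np.array([annotation[i].biotype == "mRNA" for i in ids])
    base_mean = cfg.baseline_log_tpm_mean + np.where(is_mrna, 0.0, cfg.lnc_log_tpm_offset)
    sd = cfg.baseline_log_tpm_sd
    u = rng.random(len(ids))
    down_ids = (
        set(truth.effects.loc[truth.effects["log2fc"] < 0, "transcript_id"])
        if not truth.effects.empty
        else set()
    )
    is_down = np.array([i in down_ids for i in ids])
    lo_q = norm.cdf((np.log(cfg.min_down_baseline_tpm) - base_mean) / sd)
    u = np.where(is_down, lo_q + u * (1.0 - lo_q), u)  # truncated draw for repressed members
    baseline = np.exp(base_mean + sd * norm.ppf(u))

    lfc = np.zeros((len(ids), len(design)))
    if not truth.effects.empty:
        idx = {t: i for i, t in enumerate(ids)}
        for e in truth.effects.itertuples(index=False):
            i = idx[e.transcript_id]
            mask = (design["tissue"] == e.tissue) & (design["timepoint_h"] == e.timepoint_h)
            lfc[i, mask.to_numpy()] = e.log2fc

    tpm = baseline[:, None] * np.power(2.0, lfc)
    if cfg.replicate_cv > 0:
        sigma = np.sqrt(np.log1p(cfg.replicate_cv**2))
        noise = np.exp(rng.normal(-sigma**2 / 2.0, sigma, size=tpm.shape))
        tpm = tpm * noise
    frame = pd.DataFrame(tpm, index=pd.Index(ids, name="transcript_id"), columns=design["sample_id"])
    return ExpressionMatrix(tpm=frame, design=design)


# ---------------------------------------------------------------------------
# smRNA
# ---------------------------------------------------------------------------


def enriched_regions(annotation: GenomeAnnotation, truth: TruthTable, window: int = 1000) -> IntervalSet:
    """Union of NAT overlap regions and TSS windows of NAT-pair members."""
    regions = IntervalSet()
    for p in truth.pairs.itertuples(index=False):
        regions.add(p.chrom, int(p.overlap_start), int(p.overlap_end))
        for tid in (p.sense_id, p.antisense_id):
            t = annotation[tid]
            lo, hi = tss_window(t, window, annotation.chrom_sizes.get(t.chrom))
            regions.add(t.chrom, lo, hi)
    return regions


def simulate_smrna(
    annotation: GenomeAnnotation, truth: TruthTable, cfg: SimulationConfig
) -> list[SmallRnaRead]:
    """Poisson read starts: background rate genome-wide, rate x enrichment in NAT regions.

    Lengths are uniform on 18-30 nt unless ``smrna_24nt_weight`` adds excess
    mass at 24 nt; strands uniform.
    """
    rng = np.random.default_rng(cfg.seed + 3)
    rate = cfg.smrna_background_rate / 1000.0  # per bp
    reads: list[tuple[str, int]] = []
    max_len = 30
    for chrom in sorted(cfg.chrom_sizes):
        size = cfg.chrom_sizes[chrom]
        n = rng.poisson(rate * size)
        starts = rng.integers(0, size - max_len, size=n)
        reads.extend((chrom, int(s)) for s in np.sort(starts))
    extra = cfg.smrna_overlap_enrichment - 1.0
    if extra > 0:
        regions = enriched_regions(annotation, truth)
        merged: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e, _ in regions.intervals():
            merged.setdefault(chrom, []).append((s, e))
        for chrom in sorted(merged):
            flat: list[tuple[int, int]] = []
            for s, e in sorted(merged[chrom]):
                if flat and s <= flat[-1][1]:
                    flat[-1] = (flat[-1][0], max(flat[-1][1], e))
                else:
                    flat.append((s, e))
            for s, e in flat:
                n = rng.poisson(rate * extra * (e - s))
                starts = rng.integers(s, max(s + 1, e - max_len), size=n)
                reads.extend((chrom, int(x)) for x in np.sort(starts))

    lengths = np.arange(18, 31)
    w = np.ones(len(lengths))
    w[lengths == 24] += cfg.smrna_24nt_weight * len(lengths)
    w /= w.sum()
    out = []
    for chrom, start in sorted(reads):
        length = int(rng.choice(lengths, p=w))
        strand = "+" if rng.random() < 0.5 else "-"
        out.append(SmallRnaRead(chrom, start, start + length, strand))
    return out


# ---------------------------------------------------------------------------
# chromatin
# ---------------------------------------------------------------------------


def simulate_chromatin(
    annotation: GenomeAnnotation, truth: TruthTable, cfg: SimulationConfig
) -> tuple[dict[str, IntervalSet], pd.DataFrame]:
    """Per-mark TSS-proximal peaks and a per-cytosine methylation table.

    Each histone mark covers the TSS of a ``frac_tss_marked`` share of
    genes with a peak.  Methylation is planted on NAT-pair member genes:
    cytosine levels are Beta-distributed around per-context means at 0 h,
    then shifted down (for ``meth_frac_down`` of genes) or up by
    ``meth_shift_magnitude`` at 6/12/24 h.
    """
    rng = np.random.default_rng(cfg.seed + 4)
    genes = annotation.sorted_transcripts()
    peaks: dict[str, IntervalSet] = {}
    for mark in DEFAULT_MARKS:
        frac = cfg.marked_fraction(mark)
        ivs = IntervalSet()
        for g in genes:
            if rng.random() < frac:
                tss = tss_of(g)
                lo = max(0, tss - int(rng.integers(100, 801)))
                hi = min(annotation.chrom_sizes.get(g.chrom, tss + 801), tss + int(rng.integers(100, 801)))
                ivs.add(g.chrom, lo, hi)
        peaks[mark] = ivs

    member_ids = set(truth.pairs["sense_id"]) | set(truth.pairs["antisense_id"])
    contexts = np.array(METH_CONTEXTS)
    ctx_p = np.array([0.4, 0.3, 0.3])
    conc = cfg.meth_beta_concentration
    rows = []
    directions = {}
    for g in genes:
        if g.transcript_id not in member_ids:
            continue
        direction = -1 if rng.random() < cfg.meth_frac_down else 1
        directions[g.transcript_id] = direction
        lo = max(0, g.span[0] - 1000) if g.strand == "+" else g.span[0]
        hi = g.span[1] if g.strand == "+" else g.span[1] + 1000
        pos = np.sort(rng.integers(lo, hi, size=cfg.meth_cytosines_per_gene))
        ctx = rng.choice(contexts, p=ctx_p, size=cfg.meth_cytosines_per_gene)
        for tp in (0, 6, 12, 24):
            shift = 0.0 if tp == 0 else direction * cfg.meth_shift_magnitude
            for position, context in zip(pos, ctx):
                m = np.clip(cfg.methylation_context_means[context] + shift, 0.01, 0.99)
                level = float(rng.beta(m * conc, (1 - m) * conc))
                rows.append((g.chrom, int(position), context, round(level, 5), tp))
    meth = pd.DataFrame(rows, columns=["chrom", "pos", "context", "level", "timepoint_h"])
    truth.transcripts["meth_direction"] = [
        {1: "up", -1: "down"}.get(directions.get(t), "none")
        for t in truth.transcripts["transcript_id"]
    ]
    return peaks, meth


# ---------------------------------------------------------------------------
# promoters
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def _random_hse(rng: np.random.Generator) -> str:
    n = lambda: str(rng.choice(_BASES))
    return n() + "GAA" + n() + n() + "TTC" + n()


def simulate_promoters(
    annotation: GenomeAnnotation, truth: TruthTable, cfg: SimulationConfig
) -> dict[str, str]:
    """Random promoter sequences; a canonical double HSE is planted in a share of them."""
    rng = np.random.default_rng(cfg.seed + 5)
    member_ids = set(truth.pairs["sense_id"]) | set(truth.pairs["antisense_id"])
    promoters: dict[str, str] = {}
    planted = {}
    for t in annotation.sorted_transcripts():
        if t.transcript_id not in member_ids:
            continue
        seq = "".join(rng.choice(_BASES, size=cfg.promoter_len))
        has = rng.random() < cfg.frac_promoter_hse
        if has:
            motif = _random_hse(rng)
            at = int(rng.integers(0, cfg.promoter_len - len(motif)))
            seq = seq[:at] + motif + seq[at + len(motif):]
        promoters[t.transcript_id] = seq
        planted[t.transcript_id] = has
    truth.transcripts["has_hse"] = [
        planted.get(t, False) for t in truth.transcripts["transcript_id"]
    ]
    return promoters


# ---------------------------------------------------------------------------
# full dataset on disk
# ---------------------------------------------------------------------------


def write_dataset(cfg: SimulationConfig, outdir) -> dict:
    """Generate everything and write the on-disk toy dataset; returns the paths."""
    import os

    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    from .genome import write_bed, write_gtf, write_tsv, atomic_write_text

    os.makedirs(outdir, exist_ok=True)
    ann, truth, blacklist = generate_annotation(cfg)
    expr = simulate_expression(ann, truth, cfg)
    reads = simulate_smrna(ann, truth, cfg)
    peaks, meth = simulate_chromatin(ann, truth, cfg)
    promoters = simulate_promoters(ann, truth, cfg)

    p = lambda name: os.path.join(outdir, name)
    write_gtf(ann, p("annotation.gtf"))
    write_bed(blacklist, p("blacklist.bed"), name="rfam")
    write_tsv(truth.labels, p("coding_labels.tsv"))
    write_tsv(expr.tpm.reset_index(), p("expression_tpm.tsv"))
    write_tsv(expr.design, p("sample_design.tsv"))
    smrna_lines = [
        f"{r.chrom}\t{r.start}\t{r.end}\tsr{i}\t0\t{r.strand}" for i, r in enumerate(reads)
    ]
    atomic_write_text(p("smrna.bed"), "\n".join(smrna_lines) + ("\n" if smrna_lines else ""))
    for mark, ivs in peaks.items():
        write_bed(ivs, p(f"peaks_{mark}.bed"), name=mark)
    write_tsv(meth, p("methylation.tsv"))
    records = [
        SeqRecord(Seq(seq), id=tid, description="") for tid, seq in sorted(promoters.items())
    ]
    with open(p("promoters.fasta"), "w") as fh:
        SeqIO.write(records, fh, "fasta")
    write_tsv(truth.conservation, p("conservation.tsv"))
    write_tsv(truth.transcripts, p("truth_transcripts.tsv"))
    write_tsv(truth.pairs, p("truth_pairs.tsv"))
    write_tsv(truth.effects, p("truth_effects.tsv"))
    sizes = pd.DataFrame(sorted(cfg.chrom_sizes.items()), columns=["chrom", "size"])
    write_tsv(sizes, p("chrom_sizes.tsv"))
    return {
        "annotation": p("annotation.gtf"),
        "blacklist": p("blacklist.bed"),
        "coding_labels": p("coding_labels.tsv"),
        "expression": p("expression_tpm.tsv"),
        "design": p("sample_design.tsv"),
        "smrna": p("smrna.bed"),
        "peaks": {mark: p(f"peaks_{mark}.bed") for mark in peaks},
        "methylation": p("methylation.tsv"),
        "promoters": p("promoters.fasta"),
        "conservation": p("conservation.tsv"),
        "chrom_sizes": p("chrom_sizes.tsv"),
        "truth": {
            "transcripts": p("truth_transcripts.tsv"),
            "pairs": p("truth_pairs.tsv"),
            "effects": p("truth_effects.tsv"),
        },
    }
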