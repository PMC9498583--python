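"""End-to-end pipeline: classify -> discover -> respond -> smRNA -> chromatin -> summary.

Driven by a :class:`PipelineConfig` (YAML on disk); every threshold defaults
to the study's printed decision rules so a bare run reproduces them.  All
outputs are TSV (written atomically) plus a JSON summary whose percentages
recompute exactly from the counts in the same bundle.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field, asdict
from decimal import Decimal, ROUND_DOWN, ROUND_HALF_UP

import pandas as pd
import yaml

from . import chromatin, classify, expression, genome, pairs as pairs_mod, smrna

log = logging.getLogger("natheat")

STAGES = ("classify", "pairs", "respond", "smrna", "chromatin", "hse", "summary")


@dataclass
class PipelineConfig:
    annotation: str = ""
    blacklist: str = ""
    coding_labels: str = ""
    expression: str = ""
    design: str = ""
    smrna: str = ""
    peaks: dict = field(default_factory=dict)  # mark -> BED path
    methylation: str = ""
    promoters: str = ""
    conservation: str = ""  # optional
    chrom_sizes: str = ""  # optional TSV chrom\tsize
    outdir: str = "natheat_out"
    seed: int = 0
    # decision thresholds (study defaults)
    min_lnc_len: int = 200
    min_overlap: int = 50
    fc: float = 2.0
    p: float = 0.05
    tss_window: int = 1000
    promoter_window: int = 2000
    sirna_len: tuple = (20, 24)
    min_reads: int = 1
    detect_tpm: float = 1.0

    def __post_init__(self) -> None:
        for name in ("min_lnc_len", "min_overlap", "fc", "tss_window", "promoter_window", "min_reads"):
            if getattr(self, name) <= 0:
                raise chromatin.ConfigError(f"threshold {name} must be positive")
        if not 0 < self.p < 1:
            raise chromatin.ConfigError("p threshold must be in (0, 1)")
        self.sirna_len = tuple(self.sirna_len)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str) -> None:
        genome.atomic_write_text(path, yaml.safe_dump(asdict(self), sort_keys=True))


def compute_summary_percentages(
    counts: dict[str, int],
    whole: int | None = None,
    decimals: int = 1,
    mode: str = "round",
) -> pd.DataFrame:
    """Percentages for labeled counts against a common denominator.

    ``pct`` is full precision; ``pct_display`` renders at the requested
    precision with round-half-up (``mode="round"``) or truncation
    (``mode="truncate"``).  Zero denominator gives undefined (NaN/None).
    """
    if mode not in ("round", "truncate"):
        raise ValueError(f"mode must be round|truncate, got {mode!r}")
    whole = sum(counts.values()) if whole is None else whole
    q = Decimal(1).scaleb(-decimals)
    rounding = ROUND_HALF_UP if mode == "round" else ROUND_DOWN
    rows = []
    for label, n in counts.items():
        if whole > 0:
            pct = 100.0 * n / whole
            disp = float((Decimal(100) * Decimal(n) / Decimal(whole)).quantize(q, rounding=rounding))
        else:
            pct, disp = float("nan"), None
        rows.append((label, n, whole, pct, disp))
    return pd.DataFrame(rows, columns=["label", "count", "whole", "pct", "pct_display"])


def _setup_logging(outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    handlers = [logging.StreamHandler(), logging.FileHandler(os.path.join(outdir, "pipeline.log"), mode="w")]
    fmt = logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
    log.setLevel(logging.INFO)
    log.handlers.clear()
    for h in handlers:
        h.setFormatter(fmt)
        log.addHandler(h)
    log.propagate = False


def run_pipeline(cfg: PipelineConfig, upto: str | None = None) -> dict:
    """Run the configured stages; returns the summary bundle (also written to disk).

    ``upto`` stops after the named stage (one of STAGES).
    """
    if upto is not None and upto not in STAGES:
        raise chromatin.ConfigError(f"unknown stage {upto!r}; expected one of {STAGES}")
    stop = STAGES.index(upto) if upto else len(STAGES) - 1
    out = cfg.outdir
    _setup_logging(out)
    log.info("thresholds: %s", {k: v for k, v in asdict(cfg).items() if not isinstance(v, (dict,))})
    p = lambda name: os.path.join(out, name)
    summary: dict = {"seed": cfg.seed, "thresholds": {
        "min_lnc_len": cfg.min_lnc_len, "min_overlap": cfg.min_overlap, "fc": cfg.fc,
        "p": cfg.p, "tss_window": cfg.tss_window, "promoter_window": cfg.promoter_window,
        "sirna_len": list(cfg.sirna_len), "min_reads": cfg.min_reads, "detect_tpm": cfg.detect_tpm,
    }}

    # ---- stage: classify -------------------------------------------------
    ann = genome.read_gtf(cfg.annotation)
    if cfg.chrom_sizes and os.path.exists(cfg.chrom_sizes):
        sizes = genome.read_tsv(cfg.chrom_sizes)
        ann.chrom_sizes = dict(zip(sizes["chrom"].astype(str), sizes["size"].astype(int)))
    blacklist = genome.read_bed(cfg.blacklist) if cfg.blacklist else genome.IntervalSet()
    labels = genome.read_tsv(cfg.coding_labels)
    calls = classify.filter_candidates(ann, blacklist, labels, min_len=cfg.min_lnc_len)
    genome.write_tsv(classify.calls_to_frame(calls), p("lncrna_calls.tsv"))
    counts = classify.status_counts(calls)
    summary["lncrna_status_counts"] = counts
    log.info("classify: %d transcripts in, status counts %s", len(ann), counts)
    if stop < STAGES.index("pairs"):
        return _finish(summary, p)

    # ---- stage: pairs ----------------------------------------------------
    call_map = {c.transcript_id: c for c in calls}
    survivors = [
        c.transcript_id for c in calls
        if c.status in ("annotated_mRNA",) + classify.LNC_CLASSES
    ]
    sub = ann.subset(survivors)
    tpm_df = genome.read_tsv(cfg.expression).set_index("transcript_id")
    design = genome.read_tsv(cfg.design)
    expr = expression.ExpressionMatrix(tpm=tpm_df[list(design["sample_id"])], design=design)
    conservation = None
    if cfg.conservation and os.path.exists(cfg.conservation):
        cons_df = genome.read_tsv(cfg.conservation)
        conservation = dict(zip(cons_df["transcript_id"], cons_df["score"]))
    unoriented = pairs_mod.find_nat_pairs(sub, min_overlap=cfg.min_overlap)
    nat_pairs = pairs_mod.orient_pairs(
        sub, unoriented, call_map, expr.tpm, design, conservation, cfg.detect_tpm
    )
    genome.write_tsv(pairs_mod.pairs_to_frame(nat_pairs), p("nat_pairs.tsv"))
    type_counts = pairs_mod.pair_type_counts(nat_pairs)
    config_counts = pairs_mod.configuration_counts(nat_pairs)
    summary["pair_total"] = len(nat_pairs)
    summary["pair_type_counts"] = type_counts
    summary["pair_type_pct"] = _pct_map(type_counts)
    summary["configuration_counts"] = config_counts
    summary["configuration_pct"] = _pct_map(config_counts)
    log.info("pairs: %d cis-NAT pairs (%s; %s)", len(nat_pairs), type_counts, config_counts)
    if stop < STAGES.index("respond"):
        return _finish(summary, p)

    # ---- stage: respond --------------------------------------------------
    diff = expression.diff_test_all(expr, fc=cfg.fc, alpha=cfg.p)
    genome.write_tsv(diff, p("diff_expression.tsv"))
    responses = expression.call_responsive_pairs(nat_pairs, diff, fc=cfg.fc, alpha=cfg.p)
    genome.write_tsv(expression.responses_to_frame(responses), p("pair_responses.tsv"))
    conc = expression.concordance_counts(responses)
    spec_part = expression.tissue_specificity(responses)
    subset_df = pd.DataFrame(
        [(";".join(sorted(s)), c) for s, c in sorted(spec_part["subset_counts"].items(), key=lambda kv: sorted(kv[0]))],
        columns=["tissue_subset", "n_pairs"],
    )
    genome.write_tsv(subset_df, p("tissue_specificity.tsv"))
    n_resp = sum(r.responsive for r in responses)
    summary["responsive_total"] = n_resp
    summary["concordance_counts"] = conc
    summary["tissue_specific_total"] = spec_part["tissue_specific_total"]
    summary["tissue_specific_pct"] = spec_part["tissue_specific_pct"]
    de_up = {}
    de_down = {}
    for tissue, grp in diff.groupby("tissue"):
        de_up[tissue] = set(grp.loc[grp["status"] == "up", "transcript_id"])
        de_down[tissue] = set(grp.loc[grp["status"] == "down", "transcript_id"])
    summary["shared_up"] = expression.shared_de_fraction(de_up)
    summary["shared_down"] = expression.shared_de_fraction(de_down)
    log.info("respond: %d responsive pairs, concordance %s", n_resp, conc)
    if stop < STAGES.index("smrna"):
        return _finish(summary, p)

    # ---- stage: smRNA ----------------------------------------------------
    reads = smrna.reads_from_bed(genome.read_bed(cfg.smrna)) if cfg.smrna else []
    precursors = smrna.call_nat_sirna_precursors(
        nat_pairs, reads, min_reads=cfg.min_reads, sirna_len=cfg.sirna_len
    )
    genome.write_tsv(precursors, p("nat_sirna_precursors.tsv"))
    summary["precursor_pair_count"] = int(precursors["precursor"].sum())
    sense_ids = {q.sense_id for q in nat_pairs}
    anti_ids = {q.antisense_id for q in nat_pairs}
    member_ids = sense_ids | anti_ids
    classes = {
        "sense": [ann[i] for i in sorted(sense_ids)],
        "antisense": [ann[i] for i in sorted(anti_ids)],
        "non-NAT": [
            t for t in ann.sorted_transcripts()
            if t.biotype == "mRNA" and t.transcript_id not in member_ids
        ],
    }
    density, profile = smrna.tss_smrna_density(reads, classes, window=cfg.tss_window)
    genome.write_tsv(density, p("smrna_tss_density.tsv"))
    genome.write_tsv(profile, p("smrna_tss_profile.tsv"))
    overlap_regions = genome.IntervalSet()
    for q in nat_pairs:
        overlap_regions.add(q.chrom, q.overlap[0], q.overlap[1])
    lengths = smrna.length_distribution(reads, overlap_regions)
    genome.write_tsv(lengths.reset_index(), p("smrna_length_distribution.tsv"))
    summary["smrna_mean_reads_per_gene"] = dict(
        zip(density["class"], density["mean_reads_per_gene"])
    )
    log.info("smrna: %d reads, %d precursor pairs", len(reads), summary["precursor_pair_count"])
    if stop < STAGES.index("chromatin"):
        return _finish(summary, p)

    # ---- stage: chromatin ------------------------------------------------
    resp_ids = {r.pair_id for r in responses if r.responsive}
    resp_pairs = [q for q in nat_pairs if q.pair_id in resp_ids] or nat_pairs
    hm_classes = {
        "sense": [ann[q.sense_id] for q in resp_pairs],
        "antisense": [ann[q.antisense_id] for q in resp_pairs],
    }
    if cfg.peaks:
        peak_sets = {m: genome.read_bed(path) for m, path in sorted(cfg.peaks.items())}
        assoc = chromatin.peak_association(
            peak_sets, hm_classes, window=cfg.tss_window, chrom_sizes=ann.chrom_sizes
        )
        genome.write_tsv(assoc, p("histone_association.tsv"))
        profiles = []
        for mark, ivs in peak_sets.items():
            for cls, genes in hm_classes.items():
                prof = chromatin.tss_metaprofile(ivs, genes, cfg.tss_window, ann.chrom_sizes)
                prof.insert(0, "mark", mark)
                prof.insert(1, "class", cls)
                profiles.append(prof)
        genome.write_tsv(pd.concat(profiles, ignore_index=True), p("histone_tss_profiles.tsv"))
        summary["histone_association"] = {
            f"{row['mark']}:{row['class']}": row["fraction"] for _, row in assoc.iterrows()
        }
    if cfg.methylation and os.path.exists(cfg.methylation):
        meth = genome.read_tsv(cfg.methylation)
        fracs = []
        for tp in (6, 12, 24):
            if (meth["timepoint_h"] == tp).any():
                _, fr = chromatin.methylation_change(meth, hm_classes, tp)
                fracs.append(fr)
        if fracs:
            frac_df = pd.concat(fracs, ignore_index=True)
            genome.write_tsv(frac_df, p("methylation_change_fractions.tsv"))
            summary["methylation_change"] = [
                dict(zip(frac_df.columns, row)) for row in frac_df.itertuples(index=False)
            ]
        ctx = chromatin.methylation_profile(
            meth, hm_classes["sense"] + hm_classes["antisense"], window=cfg.tss_window
        )
        genome.write_tsv(ctx, p("methylation_context_means.tsv"))
        summary["methylation_context_means"] = dict(zip(ctx["context"], ctx["mean_level"]))
    if stop < STAGES.index("hse"):
        return _finish(summary, p)

    # ---- stage: HSE ------------------------------------------------------
    if cfg.promoters and os.path.exists(cfg.promoters):
        from Bio import SeqIO

        hits = {
            rec.id: chromatin.scan_hse(str(rec.seq))
            for rec in SeqIO.parse(cfg.promoters, "fasta")
        }
        genome.write_tsv(chromatin.hse_hits_to_frame(hits), p("hse_hits.tsv"))
        summary["promoters_with_hse"] = sum(1 for h in hits.values() if h)
        summary["promoters_scanned"] = len(hits)
        log.info("hse: %d/%d promoters carry a motif", summary["promoters_with_hse"], len(hits))

    return _finish(summary, p)


def _pct_map(counts: dict[str, int]) -> dict[str, float]:
    df = compute_summary_percentages(counts)
    return dict(zip(df["label"], df["pct_display"]))


def _finish(summary: dict, p) -> dict:
    genome.atomic_write_text(p("summary.json"), json.dumps(summary, indent=2, default=_json_default) + "\n")
    log.info("summary written")
    return summary


def _json_default(o):
    import numpy as np

    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
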