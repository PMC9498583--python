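"""Filter cascade and positional classification of candidate lncRNAs.

Candidate (unannotated) transcripts pass, in order, a minimum spliced-length
filter (200 nt, exactly 200 retained), a structural-RNA blacklist filter
(any exonic overlap, either strand) and a coding-potential filter (labels
supplied externally).  Survivors are classified by position relative to the
annotated gene set: antisense overlap beats intronic containment beats
intergenic.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .genome import (
    GenomeAnnotation,
    IntervalSet,
    TranscriptModel,
    ValidationError,
    overlap_length,
)

MIN_LNC_LEN = 200

STATUSES = (
    "discarded_short",
    "discarded_blacklist",
    "discarded_coding",
    "lincRNA",
    "incRNA",
    "NAT_candidate",
    "annotated_mRNA",
)

LNC_CLASSES = ("lincRNA", "incRNA", "NAT_candidate")


@dataclass
class LncRnaCall:
    transcript_id: str
    status: str
    reason: str = ""

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValidationError(f"unknown status {self.status!r}")


def classify_position(t: TranscriptModel, known: GenomeAnnotation) -> str:
    """Positional class of a surviving candidate relative to known genes.

    NAT_candidate: span overlaps a known gene's span on the opposite strand.
    incRNA: span fully inside an intron of a known gene (either strand).
    lincRNA: span overlaps no known gene.
    Precedence NAT_candidate > incRNA > lincRNA.
    """
    any_overlap = False
    intronic = False
    for g in known:
        if g.chrom != t.chrom or g.transcript_id == t.transcript_id:
            continue
        if overlap_length(t.span, g.span) == 0:
            continue
        any_overlap = True
        if g.strand != t.strand:
            return "NAT_candidate"
        for intron in g.introns:
            if intron[0] <= t.span[0] and t.span[1] <= intron[1]:
                intronic = True
                break
    if intronic:
        return "incRNA"
    if not any_overlap:
        return "lincRNA"
    # same-strand non-intronic overlap (e.g. an unannotated isoform fragment):
    # not antisense, not intronic — binned as lincRNA so the partition stays
    # exhaustive; such transcripts do not arise from the synthetic generator
    return "lincRNA"


def filter_candidates(
    annotation: GenomeAnnotation,
    blacklist: IntervalSet,
    coding_labels: dict[str, str] | pd.DataFrame,
    known: GenomeAnnotation | None = None,
    min_len: int = MIN_LNC_LEN,
) -> list[LncRnaCall]:
    """Apply the lncRNA filter cascade to every transcript.

    Annotated mRNAs (biotype ``mRNA``) are passed through untouched as
    ``annotated_mRNA``; everything else runs the cascade: spliced length
    < 200 nt, >= 1 bp exonic blacklist overlap (strand-blind), then the
    external coding-potential label.  Survivors get a positional class.

    ``coding_labels`` maps transcript_id -> ``coding``/``noncoding``; a
    DataFrame with columns transcript_id, label (and optionally score,
    where score > 0 forces coding) is also accepted.
    """
    labels = _normalize_labels(coding_labels)
    if known is None:
        known = GenomeAnnotation(
            transcripts={t.transcript_id: t for t in annotation if t.biotype == "mRNA"},
            chrom_sizes=dict(annotation.chrom_sizes),
        )
    missing = [
        t.transcript_id
        for t in annotation
        if t.biotype != "mRNA" and t.transcript_id not in labels
    ]
    if missing:
        raise ValidationError(
            f"missing coding labels for {len(missing)} transcripts: {sorted(missing)[:10]}"
        )

    calls: list[LncRnaCall] = []
    for t in annotation.sorted_transcripts():
        if t.biotype == "mRNA":
            calls.append(LncRnaCall(t.transcript_id, "annotated_mRNA", "reference annotation"))
            continue
        if t.exonic_length < min_len:
            calls.append(
                LncRnaCall(t.transcript_id, "discarded_short", f"exonic length {t.exonic_length} < {min_len}")
            )
            continue
        hit = next(
            (bl for ex in t.exons for bl in blacklist.overlapping(t.chrom, ex[0], ex[1])),
            None,
        )
        if hit is not None:
            calls.append(
                LncRnaCall(t.transcript_id, "discarded_blacklist", f"exon overlaps blacklist {hit[0]}-{hit[1]}")
            )
            continue
        if labels[t.transcript_id] == "coding":
            calls.append(LncRnaCall(t.transcript_id, "discarded_coding", "coding potential"))
            continue
        calls.append(LncRnaCall(t.transcript_id, classify_position(t, known), "survivor"))
    return calls


def _normalize_labels(coding_labels: dict[str, str] | pd.DataFrame) -> dict[str, str]:
    if isinstance(coding_labels, pd.DataFrame):
        labels = {}
        has_score = "score" in coding_labels.columns
        for row in coding_labels.itertuples(index=False):
            label = row.label
            if has_score and not pd.isna(row.score):
                label = "coding" if row.score > 0 else "noncoding"
            labels[row.transcript_id] = label
        return labels
    return dict(coding_labels)


def calls_to_frame(calls: list[LncRnaCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.transcript_id, c.status, c.reason) for c in calls],
        columns=["transcript_id", "status", "reason"],
    )


def status_counts(calls: list[LncRnaCall]) -> dict[str, int]:
    out = {s: 0 for s in STATUSES}
    for c in calls:
        out[c.status] += 1
    return out
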