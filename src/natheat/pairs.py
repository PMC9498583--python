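"""Cis-NAT pair discovery, orientation and classification.

A cis-NAT pair is two transcripts on opposite strands of the same
chromosome whose genomic spans overlap by at least ``MIN_OVERLAP`` bp.
The sense member is chosen by conservation score when available, else by
expression breadth, else lexicographically.  Each pair's overlap
configuration is one of:

* ``enclosed``   — one span contains the other;
* ``convergent`` — both 3' ends lie in the overlap (head-to-head 3' overlap);
* ``divergent``  — both 5' ends lie in the overlap (5' overlap, transcription
  pointing apart).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

from .classify import LncRnaCall
from .genome import GenomeAnnotation, TranscriptModel, ValidationError, overlap_length, tes_of, tss_of

MIN_OVERLAP = 50

CONFIGURATIONS = ("enclosed", "convergent", "divergent")
PAIR_TYPES = ("mRNA-mRNA", "mRNA-lncRNA", "lncRNA-lncRNA")


@dataclass
class NatPair:
    sense_id: str
    antisense_id: str
    chrom: str
    overlap: tuple[int, int]
    overlap_len: int
    configuration: str = ""
    pair_type: str = ""
    orientation_basis: str = ""

    @property
    def pair_id(self) -> str:
        return f"{self.sense_id}|{self.antisense_id}"

    @property
    def members(self) -> tuple[str, str]:
        return self.sense_id, self.antisense_id


def find_nat_pairs(
    annotation: GenomeAnnotation, min_overlap: int = MIN_OVERLAP
) -> list[tuple[str, str]]:
    """All unordered opposite-strand transcript pairs with span overlap >= min_overlap.

    Interval-tree query per transcript against the opposite strand,
    O(n log n + k); each pair reported once, ordered (id_a < id_b).
    """
    trees: dict[tuple[str, str], IntervalTree] = {}
    for t in annotation:
        trees.setdefault((t.chrom, t.strand), IntervalTree()).addi(
            t.span[0], t.span[1], t.transcript_id
        )
    pairs: set[tuple[str, str]] = set()
    for t in annotation:
        other = "-" if t.strand == "+" else "+"
        tree = trees.get((t.chrom, other))
        if tree is None:
            continue
        for iv in tree.overlap(t.span[0], t.span[1]):
            if min(t.span[1], iv.end) - max(t.span[0], iv.begin) >= min_overlap:
                pairs.add(tuple(sorted((t.transcript_id, iv.data))))
    return sorted(pairs)


def find_nat_pairs_bruteforce(
    annotation: GenomeAnnotation, min_overlap: int = MIN_OVERLAP
) -> list[tuple[str, str]]:
    """O(n^2) all-pairs reference used as the discovery oracle in tests."""
    ts = list(annotation)
    pairs = set()
    for i in range(len(ts)):
        for j in range(i + 1, len(ts)):
            a, b = ts[i], ts[j]
            if a.chrom != b.chrom or a.strand == b.strand:
                continue
            if overlap_length(a.span, b.span) >= min_overlap:
                pairs.add(tuple(sorted((a.transcript_id, b.transcript_id))))
    return sorted(pairs)


def detection_breadth(
    tpm: pd.DataFrame, design: pd.DataFrame, transcript_id: str, detect_tpm: float = 1.0
) -> int:
    """Number of samples whose condition-mean (over replicates) TPM >= detect_tpm."""
    if transcript_id not in tpm.index:
        raise ValidationError(f"{transcript_id} missing from expression matrix")
    vals = tpm.loc[transcript_id]
    cond = design.assign(tpm=vals.loc[design["sample_id"]].to_numpy())
    means = cond.groupby(["tissue", "timepoint_h"])["tpm"].transform("mean")
    return int((means >= detect_tpm).sum())


def assign_sense_antisense(
    a: TranscriptModel,
    b: TranscriptModel,
    tpm: pd.DataFrame | None = None,
    design: pd.DataFrame | None = None,
    conservation: dict[str, float] | None = None,
    detect_tpm: float = 1.0,
) -> NatPair:
    """Orient a discovered pair: conservation > expression breadth > id tie-break."""
    if a.chrom != b.chrom or a.strand == b.strand:
        raise ValidationError(f"{a.transcript_id}/{b.transcript_id}: not an opposite-strand pair")
    ov = (max(a.span[0], b.span[0]), min(a.span[1], b.span[1]))
    ov_len = ov[1] - ov[0]
    if ov_len <= 0:
        raise ValidationError(f"{a.transcript_id}/{b.transcript_id}: spans do not overlap")

    basis = None
    sense, anti = None, None
    if conservation is not None:
        sa, sb = conservation.get(a.transcript_id), conservation.get(b.transcript_id)
        if sa is not None and sb is not None and sa != sb:
            sense, anti = (a, b) if sa > sb else (b, a)
            basis = "conservation"
    if basis is None and tpm is not None and design is not None:
        na = detection_breadth(tpm, design, a.transcript_id, detect_tpm)
        nb = detection_breadth(tpm, design, b.transcript_id, detect_tpm)
        if na != nb:
            sense, anti = (a, b) if na > nb else (b, a)
            basis = "expression_breadth"
    if basis is None:
        sense, anti = (a, b) if a.transcript_id < b.transcript_id else (b, a)
        basis = "tie_break"
    pair = NatPair(
        sense_id=sense.transcript_id,
        antisense_id=anti.transcript_id,
        chrom=a.chrom,
        overlap=ov,
        overlap_len=ov_len,
        orientation_basis=basis,
    )
    pair.configuration = classify_configuration(sense, anti)
    return pair


def classify_configuration(a: TranscriptModel, b: TranscriptModel) -> str:
    """Overlap configuration of two opposite-strand overlapping transcripts.

    Orientation-independent: containment -> enclosed; otherwise both 3' ends
    in the overlap -> convergent, both 5' ends in the overlap -> divergent.
    For a partial overlap of opposite-strand spans exactly one of the two
    holds, so the classification is exhaustive.
    """
    (as_, ae), (bs, be) = a.span, b.span
    if (as_ <= bs and be <= ae) or (bs <= as_ and ae <= be):
        return "enclosed"
    lo, hi = max(as_, bs), min(ae, be)
    in_overlap = lambda pos: lo <= pos < hi
    if in_overlap(tes_of(a)) and in_overlap(tes_of(b)):
        return "convergent"
    if in_overlap(tss_of(a)) and in_overlap(tss_of(b)):
        return "divergent"
    raise ValidationError(
        f"{a.transcript_id}/{b.transcript_id}: unclassifiable geometry {a.span}/{b.span}"
    )


def classify_pair_type(pair: NatPair, calls: dict[str, LncRnaCall] | dict[str, str]) -> str:
    """Pair type from member biotypes: annotated_mRNA counts as mRNA, any lncRNA class as lncRNA."""
    kinds = []
    for tid in pair.members:
        call = calls.get(tid)
        if call is None:
            raise ValidationError(f"{tid}: no lncRNA call for pair member")
        status = call.status if isinstance(call, LncRnaCall) else call
        kinds.append("mRNA" if status == "annotated_mRNA" else "lncRNA")
    return "-".join(sorted(kinds, key=("mRNA", "lncRNA").index))


def orient_pairs(
    annotation: GenomeAnnotation,
    unoriented: list[tuple[str, str]],
    calls: dict[str, LncRnaCall] | None = None,
    tpm: pd.DataFrame | None = None,
    design: pd.DataFrame | None = None,
    conservation: dict[str, float] | None = None,
    detect_tpm: float = 1.0,
) -> list[NatPair]:
    out = []
    for ida, idb in unoriented:
        pair = assign_sense_antisense(
            annotation[ida], annotation[idb], tpm, design, conservation, detect_tpm
        )
        if calls is not None:
            pair.pair_type = classify_pair_type(pair, calls)
        out.append(pair)
    return out


def pairs_to_frame(pairs: list[NatPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                p.sense_id,
                p.antisense_id,
                p.chrom,
                p.overlap[0],
                p.overlap[1],
                p.overlap_len,
                p.configuration,
                p.pair_type,
                p.orientation_basis,
            )
            for p in pairs
        ],
        columns=[
            "sense_id",
            "antisense_id",
            "chrom",
            "overlap_start",
            "overlap_end",
            "overlap_len",
            "configuration",
            "pair_type",
            "orientation_basis",
        ],
    )


def configuration_counts(pairs: list[NatPair]) -> dict[str, int]:
    out = {c: 0 for c in CONFIGURATIONS}
    for p in pairs:
        out[p.configuration] += 1
    return out


def pair_type_counts(pairs: list[NatPair]) -> dict[str, int]:
    out = {c: 0 for c in PAIR_TYPES}
    for p in pairs:
        out[p.pair_type] += 1
    return out
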