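"""Core genomic data types, coordinate conventions and file I/O.

Internal convention is 0-based half-open intervals everywhere.  On disk,
GTF is 1-based inclusive and BED is 0-based half-open; the readers and
writers here do the conversion so no other module ever touches a 1-based
coordinate.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import pandas as pd
from intervaltree import IntervalTree

Interval = tuple[int, int]

STRANDS = ("+", "-")


class GtfParseError(ValueError):
    """A GTF line could not be parsed; carries the 1-based line number."""


class ValidationError(ValueError):
    """A domain object violates one of its invariants."""


def _check_interval(iv: Interval) -> None:
    s, e = iv
    if not (isinstance(s, int) and isinstance(e, int)) or s >= e or s < 0:
        raise ValidationError(f"invalid interval {iv!r}: need 0 <= start < end")


def overlap_length(a: Interval, b: Interval) -> int:
    """Length of the intersection of two half-open intervals (0 if disjoint)."""
    _check_interval(a)
    _check_interval(b)
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


@dataclass
class TranscriptModel:
    """A stranded genomic transcript with exons.

    ``span`` and ``exons`` are 0-based half-open.  Exons must be sorted,
    disjoint and contained in the span.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    span: Interval
    exons: list[Interval] = field(default_factory=list)
    biotype: str = "unknown"  # mRNA | lncRNA | unknown

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValidationError(f"{self.transcript_id}: strand must be + or -, got {self.strand!r}")
        _check_interval(self.span)
        if not self.exons:
            self.exons = [self.span]
        prev_end = None
        for ex in self.exons:
            _check_interval(ex)
            if ex[0] < self.span[0] or ex[1] > self.span[1]:
                raise ValidationError(f"{self.transcript_id}: exon {ex} outside span {self.span}")
            if prev_end is not None and ex[0] < prev_end:
                raise ValidationError(f"{self.transcript_id}: exons overlap or are unsorted at {ex}")
            prev_end = ex[1]

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def introns(self) -> list[Interval]:
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
            if self.exons[i + 1][0] > self.exons[i][1]
        ]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TranscriptModel):
            return NotImplemented
        return (
            self.transcript_id == other.transcript_id
            and self.gene_id == other.gene_id
            and self.chrom == other.chrom
            and self.strand == other.strand
            and self.span == other.span
            and self.exons == other.exons
            and self.biotype == other.biotype
        )


def tss_of(t: TranscriptModel) -> int:
    """The 5'-most transcribed base: span start on +, span end - 1 on -."""
    return t.span[0] if t.strand == "+" else t.span[1] - 1


def tes_of(t: TranscriptModel) -> int:
    """The 3'-most transcribed base (transcription end site)."""
    return t.span[1] - 1 if t.strand == "+" else t.span[0]


def tss_window(t: TranscriptModel, flank: int = 1000, chrom_size: int | None = None) -> Interval:
    """Half-open interval covering positions [TSS-flank, TSS+flank] inclusive.

    Clipped to the chromosome when its size is known.
    """
    tss = tss_of(t)
    lo, hi = tss - flank, tss + flank + 1
    lo = max(0, lo)
    if chrom_size is not None:
        hi = min(hi, chrom_size)
    return lo, hi


@dataclass
class GenomeAnnotation:
    """A collection of transcripts keyed by transcript_id."""

    transcripts: dict[str, TranscriptModel] = field(default_factory=dict)
    chrom_sizes: dict[str, int] = field(default_factory=dict)

    def add(self, t: TranscriptModel) -> None:
        if t.transcript_id in self.transcripts:
            raise ValidationError(f"duplicate transcript_id {t.transcript_id!r}")
        size = self.chrom_sizes.get(t.chrom)
        if size is not None and t.span[1] > size:
            raise ValidationError(
                f"{t.transcript_id}: span {t.span} exceeds {t.chrom} size {size}"
            )
        self.transcripts[t.transcript_id] = t

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self.transcripts.values())

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self.transcripts

    def __getitem__(self, transcript_id: str) -> TranscriptModel:
        return self.transcripts[transcript_id]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenomeAnnotation):
            return NotImplemented
        return self.transcripts == other.transcripts

    def sorted_transcripts(self) -> list[TranscriptModel]:
        return sorted(self, key=lambda t: (t.chrom, t.span[0], t.transcript_id))

    def subset(self, ids: Iterable[str]) -> "GenomeAnnotation":
        sub = GenomeAnnotation(chrom_sizes=dict(self.chrom_sizes))
        for tid in ids:
            sub.add(self.transcripts[tid])
        return sub


class IntervalSet:
    """Per-chromosome interval collection with optional strand, backed by interval trees."""

    def __init__(self) -> None:
        self._trees: dict[str, IntervalTree] = {}

    def add(self, chrom: str, start: int, end: int, strand: str | None = None) -> None:
        _check_interval((start, end))
        self._trees.setdefault(chrom, IntervalTree()).addi(start, end, strand)

    def overlapping(self, chrom: str, start: int, end: int) -> list[tuple[int, int, str | None]]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted((iv.begin, iv.end, iv.data) for iv in tree.overlap(start, end))

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree.overlap(start, end))

    def intervals(self) -> list[tuple[str, int, int, str | None]]:
        out = []
        for chrom in sorted(self._trees):
            for iv in sorted(self._trees[chrom]):
                out.append((chrom, iv.begin, iv.end, iv.data))
        return out

    def total_length(self) -> int:
        """Total bp covered, counting overlapping intervals once."""
        total = 0
        for chrom in self._trees:
            merged = self._trees[chrom].copy()
            merged.merge_overlaps()
            total += sum(iv.end - iv.begin for iv in merged)
        return total

    def __len__(self) -> int:
        return sum(len(t) for t in self._trees.values())


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

_GTF_COLS = 9


def _parse_gtf_attrs(attrs: str, lineno: int) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in attrs.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        try:
            key, val = part.split(" ", 1)
        except ValueError:
            raise GtfParseError(f"line {lineno}: malformed attribute {part!r}") from None
        out[key] = val.strip().strip('"')
    return out


def read_gtf(path: str | os.PathLike) -> GenomeAnnotation:
    """Read transcript and exon features from a GTF file.

    On-disk 1-based inclusive coordinates are converted to 0-based
    half-open.  Requires ``transcript_id`` and ``gene_id`` attributes.
    """
    spans: dict[str, dict] = {}
    exons: dict[str, list[Interval]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != _GTF_COLS:
                raise GtfParseError(f"line {lineno}: expected {_GTF_COLS} tab-separated fields, got {len(fields)}")
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise GtfParseError(f"line {lineno}: non-integer coordinates {start_s!r}/{end_s!r}") from None
            if strand not in STRANDS:
                raise GtfParseError(f"line {lineno}: strand must be + or -, got {strand!r}")
            attr = _parse_gtf_attrs(attrs, lineno)
            if "transcript_id" not in attr or "gene_id" not in attr:
                raise GtfParseError(f"line {lineno}: missing transcript_id/gene_id attribute")
            tid = attr["transcript_id"]
            iv = (start - 1, end)  # to 0-based half-open
            if feature == "transcript":
                spans[tid] = dict(
                    chrom=chrom,
                    strand=strand,
                    span=iv,
                    gene_id=attr["gene_id"],
                    biotype=attr.get("biotype", "unknown"),
                )
                order.append(tid)
            elif feature == "exon":
                exons.setdefault(tid, []).append(iv)
                if tid not in spans:
                    # exon before any transcript line: remember order anyway
                    order.append(tid)
                    spans[tid] = dict(
                        chrom=chrom, strand=strand, span=iv, gene_id=attr["gene_id"],
                        biotype=attr.get("biotype", "unknown"),
                    )
                    spans[tid]["_implied"] = True
    ann = GenomeAnnotation()
    seen = set()
    for tid in order:
        if tid in seen:
            continue
        seen.add(tid)
        info = spans[tid]
        ex = sorted(exons.get(tid, []))
        if info.pop("_implied", False) and ex:
            info["span"] = (min(s for s, _ in ex), max(e for _, e in ex))
        try:
            t = TranscriptModel(
                transcript_id=tid,
                gene_id=info["gene_id"],
                chrom=info["chrom"],
                strand=info["strand"],
                span=info["span"],
                exons=ex or [info["span"]],
                biotype=info["biotype"],
            )
        except ValidationError as err:
            raise ValidationError(f"while reading {path}: {err}") from err
        ann.add(t)
    return ann


def write_gtf(ann: GenomeAnnotation, path: str | os.PathLike) -> None:
    """Write transcripts as GTF (1-based inclusive), deterministically ordered."""
    lines = []
    for t in ann.sorted_transcripts():
        attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; biotype "{t.biotype}";'
        s, e = t.span
        lines.append(f"{t.chrom}\tnatheat\ttranscript\t{s + 1}\t{e}\t.\t{t.strand}\t.\t{attrs}")
        for xs, xe in t.exons:
            lines.append(f"{t.chrom}\tnatheat\texon\t{xs + 1}\t{xe}\t.\t{t.strand}\t.\t{attrs}")
    atomic_write_text(path, "\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def read_bed(path: str | os.PathLike) -> IntervalSet:
    """Read BED (3+ columns; strand taken from column 6 when present)."""
    ivs = IntervalSet()
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    if df.empty:
        return ivs
    for row in df.itertuples(index=False):
        strand = row[5] if len(row) > 5 and row[5] in STRANDS else None
        ivs.add(str(row[0]), int(row[1]), int(row[2]), strand)
    return ivs


def write_bed(ivs: IntervalSet, path: str | os.PathLike, name: str = ".") -> None:
    lines = []
    for i, (chrom, s, e, strand) in enumerate(ivs.intervals()):
        lines.append(f"{chrom}\t{s}\t{e}\t{name}{i}\t0\t{strand or '.'}")
    atomic_write_text(path, "\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# TSV / atomic writes
# ---------------------------------------------------------------------------


def read_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path: str | os.PathLike) -> None:
    atomic_write_text(path, df.to_csv(sep="\t", index=False))


def atomic_write_text(path: str | os.PathLike, text: str) -> None:
    """Write via a temporary file and rename, so partial output never lands."""
    path = os.fspath(path)
    d = os.path.dirname(path) or "."
    os.makedirs(d, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=d, prefix=".tmp-", text=True)
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def chrom_sizes_from_annotation(ann: GenomeAnnotation, pad: int = 0) -> Mapping[str, int]:
    sizes: dict[str, int] = {}
    for t in ann:
        sizes[t.chrom] = max(sizes.get(t.chrom, 0), t.span[1] + pad)
    return sizes
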