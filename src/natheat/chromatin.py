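"""Histone-mark association, TSS metaprofiles, DNA methylation and HSE scanning.

Histone marks arrive as peak interval sets (one per mark); association for a
gene means any bp of overlap between a peak and the strand-aware TSS +/- 1 kb
window.  Methylation arrives as per-cytosine levels in CpG / CHG / CHH
context at timepoints 0/6/12/24 h of heat.  Heat-shock elements (HSEs) are
inverted repeats of the 5-bp unit nGAAn / nTTCn scanned over promoter
sequences:

* canonical double  nGAAnnTTCn          (10 nt)
* canonical triple  nGAAnnTTCnnGAAn and its nTTCn-first phase (15 nt)
* non-canonical     nGAAnnnnTTCn        (12 nt)

The G of each nGAAn and the C of each nTTCn are invariant; across a motif at
most one conserved A (in the nGAAn units) and one conserved T (in the nTTCn
units) may be substituted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import (
    IntervalSet,
    TranscriptModel,
    ValidationError,
    tss_of,
    tss_window,
)

DEFAULT_MARKS = ("H3K27me2", "H3K27me3", "H3K36me2", "H3K4me1", "H3K4me2", "H3K4me3")

METH_CONTEXTS = ("CpG", "CHG", "CHH")
METH_TIMEPOINTS = (0, 6, 12, 24)


class ConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Histone peaks
# ---------------------------------------------------------------------------


def peak_association(
    peaks: dict[str, IntervalSet],
    classes: dict[str, list[TranscriptModel]],
    window: int = 1000,
    chrom_sizes: dict[str, int] | None = None,
    allowed_marks: tuple[str, ...] | None = DEFAULT_MARKS,
) -> pd.DataFrame:
    """Fraction of genes per (mark, class) whose TSS window overlaps >= 1 peak."""
    if allowed_marks is not None:
        unknown = sorted(set(peaks) - set(allowed_marks))
        if unknown:
            raise ConfigError(f"unknown mark name(s): {unknown}; expected {allowed_marks}")
    rows = []
    for mark, ivs in peaks.items():
        for cls, genes in classes.items():
            hit = 0
            for g in genes:
                size = (chrom_sizes or {}).get(g.chrom)
                lo, hi = tss_window(g, window, size)
                if ivs.overlaps(g.chrom, lo, hi):
                    hit += 1
            frac = hit / len(genes) if genes else np.nan
            rows.append((mark, cls, len(genes), hit, frac))
    return pd.DataFrame(rows, columns=["mark", "class", "n_genes", "n_associated", "fraction"])


def tss_metaprofile(
    track: IntervalSet | dict[str, np.ndarray],
    genes: list[TranscriptModel],
    window: int = 1000,
    chrom_sizes: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Mean signal per strand-oriented offset in [-window, window).

    ``track`` is either a peak IntervalSet (binary occupancy) or per-chrom
    per-bp score arrays.  Minus-strand genes are flipped so positive offsets
    are downstream of the TSS; positions clipped off the chromosome are
    excluded from both numerator and denominator.
    """
    offsets = np.arange(-window, window)
    total = np.zeros(2 * window)
    count = np.zeros(2 * window)
    for g in genes:
        size = (chrom_sizes or {}).get(g.chrom)
        tss = tss_of(g)
        pos = tss + offsets if g.strand == "+" else tss - offsets
        valid = pos >= 0
        if size is not None:
            valid &= pos < size
        sig = np.zeros(2 * window)
        if isinstance(track, IntervalSet):
            lo, hi = int(pos[valid].min()), int(pos[valid].max()) + 1
            cov = np.zeros(hi - lo, dtype=bool)
            for s, e, _ in track.overlapping(g.chrom, lo, hi):
                cov[max(s, lo) - lo : max(min(e, hi) - lo, 0)] = True
            sig[valid] = cov[pos[valid] - lo]
        else:
            arr = track.get(g.chrom)
            if arr is None:
                valid &= False
            else:
                valid &= pos < len(arr)
                sig[valid] = arr[pos[valid]]
        total += np.where(valid, sig, 0.0)
        count += valid
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return pd.DataFrame({"offset": offsets, "mean_signal": mean, "n_genes": count.astype(int)})


# ---------------------------------------------------------------------------
# Methylation
# ---------------------------------------------------------------------------


def _gene_region(g: TranscriptModel, promoter: int = 1000) -> tuple[int, int]:
    """Gene body plus 1-kb strand-aware promoter, clipped at 0."""
    s, e = g.span
    if g.strand == "+":
        return max(0, s - promoter), e
    return s, e + promoter


def methylation_change(
    meth: pd.DataFrame,
    classes: dict[str, list[TranscriptModel]],
    timepoint_h: int,
    promoter: int = 1000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene methylation change at ``timepoint_h`` vs 0 h, and up/down fractions per class.

    Delta = mean level(t) - mean level(0) over cytosines in gene body plus
    1-kb promoter.  up iff delta > 0, down iff delta < 0; exact ties and
    genes without cytosines at both timepoints are excluded.
    """
    if timepoint_h not in METH_TIMEPOINTS or timepoint_h == 0:
        raise ValidationError(f"timepoint_h must be a treated timepoint in {METH_TIMEPOINTS[1:]}")
    sub = meth[meth["timepoint_h"].isin([0, timepoint_h])]
    rows = []
    for cls, genes in classes.items():
        for g in genes:
            lo, hi = _gene_region(g, promoter)
            m = sub[(sub["chrom"] == g.chrom) & (sub["pos"] >= lo) & (sub["pos"] < hi)]
            m0 = m.loc[m["timepoint_h"] == 0, "level"]
            mt = m.loc[m["timepoint_h"] == timepoint_h, "level"]
            if m0.empty or mt.empty:
                continue
            delta = float(mt.mean() - m0.mean())
            direction = "up" if delta > 0 else ("down" if delta < 0 else "tie")
            rows.append((cls, g.transcript_id, delta, direction))
    per_gene = pd.DataFrame(rows, columns=["class", "transcript_id", "delta", "direction"])
    fr = []
    for cls, grp in per_gene[per_gene["direction"] != "tie"].groupby("class"):
        n = len(grp)
        up = int((grp["direction"] == "up").sum())
        fr.append((cls, timepoint_h, n, up / n, (n - up) / n))
    fractions = pd.DataFrame(
        fr, columns=["class", "timepoint_h", "n_classified", "up_fraction", "down_fraction"]
    )
    return per_gene, fractions


def methylation_profile(
    meth: pd.DataFrame,
    genes: list[TranscriptModel],
    window: int = 1000,
    timepoint_h: int = 0,
) -> pd.DataFrame:
    """Mean methylation level per context among cytosines in TSS +/- window."""
    sub = meth[meth["timepoint_h"] == timepoint_h]
    keep = np.zeros(len(sub), dtype=bool)
    pos = sub["pos"].to_numpy()
    chrom = sub["chrom"].to_numpy()
    for g in genes:
        tss = tss_of(g)
        keep |= (chrom == g.chrom) & (pos >= tss - window) & (pos <= tss + window)
    sel = sub[keep]
    rows = [
        (ctx, len(grp), float(grp["level"].mean()))
        for ctx, grp in sel.groupby("context")
    ]
    return pd.DataFrame(rows, columns=["context", "n_cytosines", "mean_level"])


# ---------------------------------------------------------------------------
# HSE scanning
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HseHit:
    position: int  # 0-based on the given promoter string
    strand: str
    kind: str  # canonical_double | canonical_triple | non_canonical
    n_mismatches: int


HSE_WIDTHS = {"canonical_double": 10, "canonical_triple": 15, "non_canonical": 12}

# each phase: (kind, strand label, [(unit offset, unit type), ...], width)
_PHASES = [
    ("canonical_double", "+", [(0, "GAA"), (5, "TTC")], 10),
    ("canonical_triple", "+", [(0, "GAA"), (5, "TTC"), (10, "GAA")], 15),
    ("canonical_triple", "-", [(0, "TTC"), (5, "GAA"), (10, "TTC")], 15),
    ("non_canonical", "+", [(0, "GAA"), (7, "TTC")], 12),
]

_VALID = set("ACGTN")


def _unit_mismatches(window: str, offset: int, unit: str) -> int | None:
    """Mismatch count at the conserved A/T positions, or None if G/C broken."""
    if unit == "GAA":
        if window[offset + 1] != "G":
            return None
        return (window[offset + 2] != "A") + (window[offset + 3] != "A")
    if window[offset + 3] != "C":
        return None
    return (window[offset + 1] != "T") + (window[offset + 2] != "T")


def scan_hse(promoter: str) -> list[HseHit]:
    """All HSE hits on a promoter sequence (both strands, overlaps reported).

    The double and non-canonical motif families are their own reverse
    complements, so each window is reported once (strand ``+``); the two
    triple phases are reported as ``+`` (nGAAn-first) and ``-``
    (nTTCn-first, i.e. nGAAn-first on the reverse strand).  At most one
    conserved A over all nGAAn units and one conserved T over all nTTCn
    units may mismatch; a triple hit suppresses the double hits it contains.
    """
    seq = promoter.upper()
    bad = set(seq) - _VALID
    if bad:
        raise ValidationError(f"invalid promoter characters: {sorted(bad)}")
    hits: list[HseHit] = []
    for kind, strand, units, width in _PHASES:
        for p in range(len(seq) - width + 1):
            win = seq[p : p + width]
            a_mm = t_mm = 0
            ok = True
            for off, unit in units:
                mm = _unit_mismatches(win, off, unit)
                if mm is None:
                    ok = False
                    break
                if unit == "GAA":
                    a_mm += mm
                else:
                    t_mm += mm
            if ok and a_mm <= 1 and t_mm <= 1:
                hits.append(HseHit(p, strand, kind, a_mm + t_mm))
    triples = [(h.position, h.position + HSE_WIDTHS[h.kind]) for h in hits if h.kind == "canonical_triple"]
    hits = [
        h
        for h in hits
        if not (
            h.kind == "canonical_double"
            and any(ts <= h.position and h.position + 10 <= te for ts, te in triples)
        )
    ]
    return sorted(hits, key=lambda h: (h.position, h.kind, h.strand))


def hse_hits_to_frame(hits_by_seq: dict[str, list[HseHit]]) -> pd.DataFrame:
    rows = [
        (name, h.position, h.strand, h.kind, h.n_mismatches)
        for name, hits in sorted(hits_by_seq.items())
        for h in hits
    ]
    return pd.DataFrame(rows, columns=["sequence", "position", "strand", "kind", "n_mismatches"])
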