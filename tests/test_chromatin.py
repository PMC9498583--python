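import itertools
import re

import numpy as np
import pandas as pd
import pytest

from natheat.chromatin import (
    ConfigError,
    HSE_WIDTHS,
    methylation_change,
    peak_association,
    scan_hse,
    tss_metaprofile,
)
from natheat.genome import IntervalSet, TranscriptModel, ValidationError


def _gene(tid, strand, span, chrom="chr1"):
    return TranscriptModel(tid, tid, chrom, strand, span)


# ---------------------------------------------------------------------------
# HSE oracle: regex sliding-window matcher, independent of the implementation
# ---------------------------------------------------------------------------

_GAA = {0: ".GAA.", 1: ".G(?:A[^A]|[^A]A)."}
_TTC = {0: ".TTC.", 1: ".(?:T[^T]|[^T]T)C."}
_ORACLE_PHASES = [
    ("canonical_double", "+", ("GAA", "TTC"), ""),
    ("canonical_triple", "+", ("GAA", "TTC", "GAA"), ""),
    ("canonical_triple", "-", ("TTC", "GAA", "TTC"), ""),
    ("non_canonical", "+", ("GAA", "TTC"), ".."),
]


def oracle_scan(seq):
    seq = seq.upper()
    hits = set()
    for kind, strand, units, spacer in _ORACLE_PHASES:
        width = 5 * len(units) + len(spacer)
        for alloc in itertools.product((0, 1), repeat=len(units)):
            a = sum(m for m, u in zip(alloc, units) if u == "GAA")
            t = sum(m for m, u in zip(alloc, units) if u == "TTC")
            if a > 1 or t > 1:
                continue
            parts = [(_GAA if u == "GAA" else _TTC)[m] for m, u in zip(alloc, units)]
            pat = parts[0] + spacer + "".join(parts[1:]) if spacer else "".join(parts)
            for m in re.finditer(rf"(?=({pat}))", seq):
                hits.add((m.start(), strand, kind, a + t))
    triples = [(p, p + 15) for p, _, k, _ in hits if k == "canonical_triple"]
    return {
        h
        for h in hits
        if not (h[2] == "canonical_double" and any(s <= h[0] and h[0] + 10 <= e for s, e in triples))
    }


def _revcomp(s):
    return s.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


class TestScanHse:
    def test_exact_canonical_double(self):
        hits = scan_hse("TGAACTTTCA")
        assert [(h.position, h.kind, h.n_mismatches) for h in hits] == [(0, "canonical_double", 0)]

    def test_one_exchanged_adenine(self):
        hits = scan_hse("TGTACTTTCA")
        assert [(h.position, h.kind, h.n_mismatches) for h in hits] == [(0, "canonical_double", 1)]

    def test_invariant_g_never_relaxed(self):
        assert scan_hse("TCAACTTTCA") == []  # G -> C breaks the motif

    def test_two_mismatches_in_one_unit_rejected(self):
        assert scan_hse("TGTTCTTTCA") == []  # both As exchanged

    def test_non_canonical_spacer(self):
        hits = scan_hse("TGAACATGTTCA")
        kinds = {h.kind for h in hits}
        assert "non_canonical" in kinds
        nc = next(h for h in hits if h.kind == "non_canonical")
        assert (nc.position, nc.n_mismatches) == (0, 0)

    def test_triple_suppresses_contained_double(self):
        seq = "TGAACTTTCATGAAC"  # nGAAnnTTCnnGAAn
        hits = scan_hse(seq)
        kinds = [h.kind for h in hits if h.position == 0]
        assert "canonical_triple" in kinds
        assert "canonical_double" not in [h.kind for h in hits]

    def test_lowercase_accepted_invalid_rejected(self):
        assert scan_hse("tgaactttca") == scan_hse("TGAACTTTCA")
        with pytest.raises(ValidationError):
            scan_hse("TGAACTTTCX")

    def test_reverse_complement_mirror(self):
        rng = np.random.default_rng(8)
        seq = "".join(rng.choice(list("ACGT"), size=400))
        seq = seq[:50] + "TGAACTTTCATGAAC" + seq[65:150] + "AGAACATGTTCT" + seq[162:]
        fwd = {(h.position, h.strand, h.kind, h.n_mismatches) for h in scan_hse(seq)}
        rev = {(h.position, h.strand, h.kind, h.n_mismatches) for h in scan_hse(_revcomp(seq))}
        flip = {"+": "-", "-": "+"}
        mirrored = {
            (len(seq) - p - HSE_WIDTHS[k], flip[s] if k == "canonical_triple" else s, k, m)
            for p, s, k, m in fwd
        }
        assert rev == mirrored

    def test_matches_bruteforce_oracle_with_planted_motifs(self):
        rng = np.random.default_rng(5)
        seq = list(rng.choice(list("ACGT"), size=2000))
        for at, motif in ((100, "TGAACTTTCA"), (500, "TGAACTTTCATGAAC"), (900, "AGAACGTACTTCT")):
            seq[at : at + len(motif)] = list(motif)
        seq = "".join(seq)
        got = {(h.position, h.strand, h.kind, h.n_mismatches) for h in scan_hse(seq)}
        assert got == oracle_scan(seq)
        # each planted motif is recovered by a hit covering at least its core
        # 10-mer (a planted double may be absorbed into an overlapping triple)
        for at in (100, 500, 900):
            assert any(p <= at + 1 and at + 9 <= p + HSE_WIDTHS[k] for p, _, k, _ in got)


class TestPeakAssociation:
    def test_saturation_and_empty(self):
        genes = {"sense": [_gene("g1", "+", (5000, 7000)), _gene("g2", "-", (20000, 21000))]}
        everywhere = IntervalSet()
        everywhere.add("chr1", 0, 100_000)
        marks = {"H3K4me3": everywhere, "H3K27me3": IntervalSet()}
        assoc = peak_association(marks, genes)
        by_mark = dict(zip(assoc["mark"], assoc["fraction"]))
        assert by_mark["H3K4me3"] == 1.0
        assert by_mark["H3K27me3"] == 0.0

    def test_window_boundary(self):
        g = _gene("g", "+", (5000, 7000))  # window [4000, 6001)
        touching = IntervalSet()
        touching.add("chr1", 3990, 4001)
        outside = IntervalSet()
        outside.add("chr1", 3000, 4000)
        marks = {"H3K4me1": touching, "H3K4me2": outside}
        assoc = peak_association(marks, {"c": [g]})
        by_mark = dict(zip(assoc["mark"], assoc["fraction"]))
        assert by_mark["H3K4me1"] == 1.0
        assert by_mark["H3K4me2"] == 0.0

    def test_unknown_mark_is_config_error(self):
        with pytest.raises(ConfigError, match="H2A"):
            peak_association({"H2A.Z": IntervalSet()}, {"c": []})


class TestTssMetaprofile:
    def test_uniform_coverage_is_flat(self):
        track = IntervalSet()
        track.add("chr1", 0, 100_000)
        prof = tss_metaprofile(track, [_gene("g", "+", (5000, 7000))])
        assert (prof["mean_signal"] == 1.0).all()

    def test_single_plus_gene_equals_raw_slice(self):
        arr = np.zeros(20_000)
        arr[4500:5500] = np.linspace(0, 1, 1000)
        prof = tss_metaprofile({"chr1": arr}, [_gene("g", "+", (5000, 7000))])
        assert np.allclose(prof["mean_signal"].to_numpy(), arr[4000:6000])

    def test_peak_at_tss_maximal_at_offset_zero(self):
        track = IntervalSet()
        genes = []
        for i, s in enumerate(range(10_000, 60_000, 10_000)):
            strand = "+" if i % 2 == 0 else "-"
            g = _gene(f"g{i}", strand, (s, s + 2000))
            genes.append(g)
            from natheat.genome import tss_of

            tss = tss_of(g)
            track.add("chr1", tss - 50, tss + 51)
        prof = tss_metaprofile(track, genes)
        assert prof.loc[prof["mean_signal"].idxmax(), "offset"] in range(-50, 51)
        assert prof.loc[prof["offset"] == 0, "mean_signal"].iloc[0] == 1.0

    def test_permutation_invariance(self):
        rng = np.random.default_rng(2)
        ivs = [(int(s), int(s) + int(rng.integers(50, 500))) for s in rng.integers(0, 50_000, 40)]
        genes = [_gene(f"g{i}", "+", (int(s), int(s) + 1000)) for i, s in enumerate(range(2000, 42_000, 2000))]
        t1, t2 = IntervalSet(), IntervalSet()
        for s, e in ivs:
            t1.add("chr1", s, e)
        for s, e in reversed(ivs):
            t2.add("chr1", s, e)
        assert tss_metaprofile(t1, genes).equals(tss_metaprofile(t2, genes))


class TestMethylationChange:
    def _meth(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "pos", "context", "level", "timepoint_h"])

    def test_identical_levels_all_ties(self):
        g = _gene("g", "+", (1000, 2000))
        rows = [("chr1", p, "CpG", 0.5, tp) for p in (1100, 1500) for tp in (0, 12)]
        per_gene, fractions = methylation_change(self._meth(rows), {"sense": [g]}, 12)
        assert (per_gene["direction"] == "tie").all()
        assert fractions.empty

    def test_signs_and_partition(self):
        g1, g2 = _gene("up", "+", (1000, 2000)), _gene("dn", "+", (10_000, 11_000))
        rows = (
            [("chr1", 1500, "CpG", 0.4, 0), ("chr1", 1500, "CpG", 0.6, 12)]
            + [("chr1", 10_500, "CHH", 0.6, 0), ("chr1", 10_500, "CHH", 0.3, 12)]
        )
        per_gene, fractions = methylation_change(self._meth(rows), {"sense": [g1, g2]}, 12)
        d = dict(zip(per_gene["transcript_id"], per_gene["direction"]))
        assert d == {"up": "up", "dn": "down"}
        assert fractions["up_fraction"].iloc[0] + fractions["down_fraction"].iloc[0] == 1.0

    def test_promoter_is_strand_aware(self):
        g = _gene("g", "-", (1000, 2000))  # promoter [2000, 3000)
        rows = [("chr1", 2500, "CpG", 0.2, 0), ("chr1", 2500, "CpG", 0.7, 6)]
        per_gene, _ = methylation_change(self._meth(rows), {"sense": [g]}, 6)
        assert per_gene["direction"].iloc[0] == "up"

    def test_gene_without_cytosines_excluded(self):
        g = _gene("g", "+", (1000, 2000))
        rows = [("chr1", 50_000, "CpG", 0.5, 0), ("chr1", 50_000, "CpG", 0.6, 6)]
        per_gene, _ = methylation_change(self._meth(rows), {"sense": [g]}, 6)
        assert per_gene.empty
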