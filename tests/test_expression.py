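import numpy as np
import pandas as pd
import pytest

from natheat.expression import (
    ExpressionMatrix,
    call_responsive_pairs,
    compute_tpm,
    concordance_counts,
    diff_test,
    make_design,
    shared_de_fraction,
    tissue_specificity,
)
from natheat.genome import TranscriptModel
from natheat.pairs import assign_sense_antisense


def _design_one_tissue():
    return make_design(tissues=("Root",), timepoints=(0, 1), n_replicates=3)


def _expr(control, treated, tissue="Root"):
    design = make_design(tissues=(tissue,), timepoints=(0, 1), n_replicates=3)
    tpm = pd.DataFrame(
        [list(control) + list(treated)],
        index=pd.Index(["t"], name="transcript_id"),
        columns=design["sample_id"],
    )
    return ExpressionMatrix(tpm=tpm, design=design)


class TestComputeTpm:
    def test_equal_rates_split_evenly(self):
        counts = pd.DataFrame({"s1": [10, 20]}, index=["a", "b"])
        lengths = pd.Series({"a": 1000, "b": 2000})
        tpm = compute_tpm(counts, lengths)
        assert tpm.loc["a", "s1"] == pytest.approx(500_000)
        assert tpm.loc["b", "s1"] == pytest.approx(500_000)

    def test_single_expressed_transcript_gets_million(self):
        counts = pd.DataFrame({"s1": [7, 0]}, index=["a", "b"])
        tpm = compute_tpm(counts, pd.Series({"a": 500, "b": 800}))
        assert tpm.loc["a", "s1"] == pytest.approx(1e6)

    def test_columns_conserve_a_million(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(rng.integers(1, 1000, size=(20, 6)))
        lengths = pd.Series(rng.integers(200, 5000, size=20))
        tpm = compute_tpm(counts, lengths)
        assert np.allclose(tpm.sum(axis=0), 1e6, atol=1e-6)

    def test_all_zero_column_stays_zero(self):
        counts = pd.DataFrame({"s1": [5, 5], "s2": [0, 0]}, index=["a", "b"])
        tpm = compute_tpm(counts, pd.Series({"a": 1000, "b": 1000}))
        assert (tpm["s2"] == 0).all()


def _welch_oracle(x, y):
    """Independent Welch t-test from the textbook formulas."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = len(x), len(y)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    from scipy.stats import t as tdist

    return 2 * tdist.sf(abs(t), df)


class TestDiffTest:
    def test_log2fc_and_welch_p_against_oracle(self):
        expr = _expr(control=(4, 5, 6), treated=(40, 50, 60))
        res = diff_test(expr, "Root", 1).iloc[0]
        assert res["log2fc"] == pytest.approx(np.log2(51 / 6))
        expected_p = _welch_oracle(np.log2(np.array([40, 50, 60]) + 1), np.log2(np.array([4, 5, 6]) + 1))
        assert res["p"] == pytest.approx(expected_p, rel=1e-10)
        assert res["status"] == "up"

    def test_identical_groups_are_ns(self):
        expr = _expr(control=(5, 6, 7), treated=(5, 6, 7))
        res = diff_test(expr, "Root", 1).iloc[0]
        assert res["log2fc"] == 0
        assert res["status"] == "ns"

    def test_constant_equal_groups_get_p_one(self):
        expr = _expr(control=(5, 5, 5), treated=(5, 5, 5))
        assert diff_test(expr, "Root", 1).iloc[0]["p"] == 1.0

    def test_swap_antisymmetry_and_relabel_invariance(self):
        c, t = (4, 5, 6), (40, 50, 60)
        fwd = diff_test(_expr(c, t), "Root", 1).iloc[0]
        rev = diff_test(_expr(t, c), "Root", 1).iloc[0]
        assert fwd["log2fc"] == pytest.approx(-rev["log2fc"])
        assert fwd["p"] == pytest.approx(rev["p"])
        shuffled = diff_test(_expr((6, 4, 5), (50, 60, 40)), "Root", 1).iloc[0]
        assert shuffled["p"] == pytest.approx(fwd["p"])
        assert shuffled["log2fc"] == pytest.approx(fwd["log2fc"])

    def test_missing_group_raises(self):
        expr = _expr((4, 5, 6), (40, 50, 60))
        with pytest.raises(Exception, match="5"):
            diff_test(expr, "Root", 5)


def _pair(sid="s", aid="a"):
    s = TranscriptModel(sid, sid, "chr1", "+", (100, 400))
    a = TranscriptModel(aid, aid, "chr1", "-", (150, 450))
    return assign_sense_antisense(s, a)


def _diff_frame(rows):
    return pd.DataFrame(rows, columns=["transcript_id", "tissue", "timepoint_h", "log2fc", "p", "status"])


class TestResponsivePairs:
    def test_shared_contrast_required(self):
        pair = _pair()
        both_root = _diff_frame(
            [
                ("s", "Root", 1, 2.0, 0.01, "up"),
                ("a", "Root", 1, 1.5, 0.02, "up"),
                ("s", "RL", 5, 0.0, 0.9, "ns"),
                ("a", "RL", 5, 0.0, 0.9, "ns"),
            ]
        )
        (resp,) = call_responsive_pairs([pair], both_root)
        assert resp.responsive and resp.qualifying == {("Root", 1)}

        disjoint = _diff_frame(
            [
                ("s", "Root", 1, 2.0, 0.01, "up"),
                ("a", "Root", 1, 0.2, 0.8, "ns"),
                ("s", "RL", 5, 0.1, 0.7, "ns"),
                ("a", "RL", 5, 2.0, 0.01, "up"),
            ]
        )
        (resp,) = call_responsive_pairs([pair], disjoint)
        assert not resp.responsive

    def test_concordance_signs(self):
        pair = _pair()
        rows = []
        sense_fc = [1.5, 2.0, 3.0]
        for i, (tissue, tp) in enumerate([("Root", 1), ("Root", 5), ("RL", 1)]):
            rows.append(("s", tissue, tp, sense_fc[i], 0.01, "up"))
            rows.append(("a", tissue, tp, 2 * sense_fc[i], 0.01, "up"))
        (resp,) = call_responsive_pairs([pair], _diff_frame(rows))
        assert resp.r == pytest.approx(1.0)
        assert resp.concordance == "concordant"

        rows = []
        for i, (tissue, tp) in enumerate([("Root", 1), ("Root", 5), ("RL", 1)]):
            rows.append(("s", tissue, tp, sense_fc[i], 0.01, "up"))
            rows.append(("a", tissue, tp, -sense_fc[i], 0.01, "down"))
        (resp,) = call_responsive_pairs([pair], _diff_frame(rows))
        assert resp.r == pytest.approx(-1.0)
        assert resp.concordance == "discordant"

    def test_zero_covariance_is_unclassified(self):
        # hand-computed: cov((1,0,2),(0,1,1)) = 0
        pair = _pair()
        rows = [
            ("s", "Root", 1, 1.0, 0.01, "up"),
            ("a", "Root", 1, 0.0, 0.9, "ns"),
            ("s", "Root", 5, 0.0, 0.9, "ns"),
            ("a", "Root", 5, 1.0, 0.01, "up"),
            ("s", "RL", 1, 2.0, 0.01, "up"),
            ("a", "RL", 1, 1.0, 0.01, "up"),
        ]
        (resp,) = call_responsive_pairs([pair], _diff_frame(rows))
        assert resp.responsive  # RL@1h qualifies for both
        assert resp.concordance == "unclassified"

    def test_zero_variance_is_unclassified(self):
        pair = _pair()
        rows = [
            ("s", "Root", 1, 1.5, 0.01, "up"),
            ("a", "Root", 1, 1.5, 0.01, "up"),
            ("s", "Root", 5, 1.5, 0.01, "up"),
            ("a", "Root", 5, 1.0, 0.01, "up"),
        ]
        (resp,) = call_responsive_pairs([pair], _diff_frame(rows))
        assert resp.responsive
        assert resp.r is None and resp.concordance == "unclassified"


class TestPartitions:
    def test_tissue_specificity_partition(self):
        pairs = [_pair("s1", "a1"), _pair("s2", "a2"), _pair("s3", "a3")]
        rows = []
        # pair 1: Root only; pair 2: Root@1h and OF@5h; pair 3: nothing
        for tid, contrasts in (
            ("s1", [("Root", 1)]), ("a1", [("Root", 1)]),
            ("s2", [("Root", 1), ("OF", 5)]), ("a2", [("Root", 1), ("OF", 5)]),
        ):
            for tissue, tp in contrasts:
                rows.append((tid, tissue, tp, 2.0, 0.01, "up"))
        for tid in ("s1", "a1", "s2", "a2", "s3", "a3"):
            rows.append((tid, "Shoot", 1, 0.0, 0.9, "ns"))
        responses = call_responsive_pairs(pairs, _diff_frame(rows))
        part = tissue_specificity(responses)
        assert part["n_responsive"] == 2
        assert part["subset_counts"][frozenset({"Root"})] == 1
        assert part["subset_counts"][frozenset({"Root", "OF"})] == 1
        assert part["tissue_specific_total"] == 1
        assert sum(part["subset_counts"].values()) == part["n_responsive"]
        conc = concordance_counts(responses)
        assert sum(conc.values()) == part["n_responsive"]

    def test_shared_de_fraction(self):
        same = {"Root": {"a", "b"}, "Shoot": {"a", "b"}}
        assert shared_de_fraction(same)["pct"] == 100.0
        disjoint = {"Root": {"a"}, "Shoot": {"b"}}
        assert shared_de_fraction(disjoint)["pct"] == 0.0
        empty = {"Root": set(), "Shoot": set()}
        assert shared_de_fraction(empty)["pct"] is None
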