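"""Expression quantification, heat-response calls and pair concordance.

The study design is 5 tissues (Shoot, Root, RL, Bud, OF), three heat-stress
timepoints (0 h control, 1 h, 5 h at 37 deg C) and 3 biological replicates,
i.e. 45 samples.  Per-transcript response at a (tissue, timepoint) contrast
requires a two-fold change (|log2 FC| >= 1, with a 1-TPM pseudo-count) and
Welch's t-test p < 0.05 on log2(TPM + 1) replicate values — fold change and
raw p, no multiple-testing correction.  A NAT pair is heat-responsive when
both members pass in the same contrast; responsive pairs split into
concordant / discordant by the sign of the Pearson correlation between the
two members' log2 FC vectors over all ten contrasts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genome import ValidationError
from .pairs import NatPair

log = logging.getLogger(__name__)

TISSUES = ("Shoot", "Root", "RL", "Bud", "OF")
TIMEPOINTS_H = (0, 1, 5)
TREATED_TIMEPOINTS = (1, 5)
N_REPLICATES = 3

FC_THRESHOLD = 2.0
P_THRESHOLD = 0.05
PSEUDOCOUNT = 1.0


def make_design(
    tissues: tuple[str, ...] = TISSUES,
    timepoints: tuple[int, ...] = TIMEPOINTS_H,
    n_replicates: int = N_REPLICATES,
) -> pd.DataFrame:
    """Standard sample sheet: one row per (tissue, timepoint, replicate)."""
    rows = [
        (f"{ti}_{tp}h_r{r}", ti, tp, r)
        for ti in tissues
        for tp in timepoints
        for r in range(1, n_replicates + 1)
    ]
    return pd.DataFrame(rows, columns=["sample_id", "tissue", "timepoint_h", "replicate"])


@dataclass
class ExpressionMatrix:
    """TPM by transcript x sample, with its sample design."""

    tpm: pd.DataFrame  # index: transcript_id, columns: sample_id
    design: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.tpm.columns) != list(self.design["sample_id"]):
            raise ValidationError("expression columns do not match design sample_ids")
        if (self.tpm.to_numpy() < 0).any():
            raise ValidationError("negative TPM values")

    def samples_for(self, tissue: str, timepoint_h: int) -> list[str]:
        m = (self.design["tissue"] == tissue) & (self.design["timepoint_h"] == timepoint_h)
        return list(self.design.loc[m, "sample_id"])


def compute_tpm(counts: pd.DataFrame, lengths: pd.Series, design: pd.DataFrame | None = None):
    """TPM from raw counts and exonic lengths (bp).

    TPM(t, s) = 1e6 * rate(t, s) / sum_u rate(u, s) with rate = count per kb
    of exonic length; columns with no reads stay all-zero (warning logged).
    """
    lengths = lengths.loc[counts.index]
    if (lengths <= 0).any():
        raise ValidationError("non-positive transcript lengths")
    rate = counts.div(lengths / 1000.0, axis=0)
    colsum = rate.sum(axis=0)
    zero_cols = colsum[colsum == 0].index
    if len(zero_cols):
        log.warning("all-zero count columns: %s", list(zero_cols))
        colsum = colsum.replace(0, np.nan)
    tpm = (rate.div(colsum, axis=1) * 1e6).fillna(0.0)
    if design is None:
        return tpm
    return ExpressionMatrix(tpm=tpm, design=design)


def diff_test(
    expr: ExpressionMatrix,
    tissue: str,
    timepoint_h: int,
    fc: float = FC_THRESHOLD,
    alpha: float = P_THRESHOLD,
) -> pd.DataFrame:
    """Per-transcript differential call for one (tissue, treated-timepoint) contrast.

    log2fc uses group means with a 1-TPM pseudo-count; p is Welch's
    two-sample t on log2(TPM + 1) replicate values.  status: up iff
    log2fc >= 1 and p < 0.05; down iff log2fc <= -1 and p < 0.05; else ns.
    """
    if timepoint_h not in TREATED_TIMEPOINTS:
        raise ValidationError(f"timepoint_h must be in {TREATED_TIMEPOINTS}, got {timepoint_h}")
    ctrl_cols = expr.samples_for(tissue, 0)
    trt_cols = expr.samples_for(tissue, timepoint_h)
    if len(ctrl_cols) < 2 or len(trt_cols) < 2:
        raise ValidationError(f"need >= 2 replicates in control and treated for ({tissue}, {timepoint_h})")
    ctrl = expr.tpm[ctrl_cols].to_numpy()
    trt = expr.tpm[trt_cols].to_numpy()

    log2fc = np.log2((trt.mean(axis=1) + PSEUDOCOUNT) / (ctrl.mean(axis=1) + PSEUDOCOUNT))
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(np.log2(trt + 1), np.log2(ctrl + 1), axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)

    sig = p < alpha
    status = np.where(
        (log2fc >= np.log2(fc)) & sig,
        "up",
        np.where((log2fc <= -np.log2(fc)) & sig, "down", "ns"),
    )
    return pd.DataFrame(
        {
            "transcript_id": expr.tpm.index,
            "tissue": tissue,
            "timepoint_h": timepoint_h,
            "log2fc": log2fc,
            "p": p,
            "status": status,
        }
    )


def diff_test_all(
    expr: ExpressionMatrix, fc: float = FC_THRESHOLD, alpha: float = P_THRESHOLD
) -> pd.DataFrame:
    """All tissue x treated-timepoint contrasts present in the design."""
    tissues = expr.design["tissue"].unique()
    frames = [
        diff_test(expr, ti, tp, fc, alpha)
        for ti in tissues
        for tp in TREATED_TIMEPOINTS
        if (expr.design["timepoint_h"] == tp).any()
    ]
    return pd.concat(frames, ignore_index=True)


@dataclass
class PairResponse:
    pair_id: str
    responsive: bool
    qualifying: set[tuple[str, int]] = field(default_factory=set)
    r: float | None = None
    concordance: str = "unclassified"  # concordant | discordant | unclassified


def call_responsive_pairs(
    pairs: list[NatPair],
    diff: pd.DataFrame,
    fc: float = FC_THRESHOLD,
    alpha: float = P_THRESHOLD,
) -> list[PairResponse]:
    """A pair is responsive iff some contrast has BOTH members at |log2fc| >= 1 and p < 0.05.

    The qualifying set records every such (tissue, timepoint).  The Pearson
    correlation between the members' log2fc vectors over all contrasts sets
    the concordance class by sign (undefined/zero -> unclassified).
    """
    qual = diff[(diff["log2fc"].abs() >= np.log2(fc)) & (diff["p"] < alpha)]
    qual_map: dict[str, set[tuple[str, int]]] = {}
    for row in qual.itertuples(index=False):
        qual_map.setdefault(row.transcript_id, set()).add((row.tissue, row.timepoint_h))
    fc = diff.pivot_table(
        index="transcript_id", columns=["tissue", "timepoint_h"], values="log2fc", sort=True
    )

    out = []
    for p in pairs:
        for tid in p.members:
            if tid not in fc.index:
                raise ValidationError(f"{tid}: pair member missing from differential results")
        shared = qual_map.get(p.sense_id, set()) & qual_map.get(p.antisense_id, set())
        resp = PairResponse(pair_id=p.pair_id, responsive=bool(shared), qualifying=shared)
        if resp.responsive:
            r = _pearson_or_none(fc.loc[p.sense_id].to_numpy(), fc.loc[p.antisense_id].to_numpy())
            resp.r = r
            if r is not None and r > 0:
                resp.concordance = "concordant"
            elif r is not None and r < 0:
                resp.concordance = "discordant"
        out.append(resp)
    return out


def _pearson_or_none(x: np.ndarray, y: np.ndarray) -> float | None:
    if np.std(x) == 0 or np.std(y) == 0:
        return None
    r = float(stats.pearsonr(x, y).statistic)
    if np.isnan(r):
        return None
    # exact zero covariance can round to +/-1e-17; keep it classifiable as 0
    return 0.0 if abs(r) < 1e-12 else r


def concordance_counts(responses: list[PairResponse]) -> dict[str, int]:
    out = {"concordant": 0, "discordant": 0, "unclassified": 0}
    for r in responses:
        if r.responsive:
            out[r.concordance] += 1
    return out


def tissue_specificity(responses: list[PairResponse]) -> dict:
    """Partition responsive pairs by the exact tissue set (union over timepoints) in which they qualify.

    Returns subset counts, the tissue-specific (singleton-subset) total and
    its percentage share of all responsive pairs.
    """
    counts: dict[frozenset, int] = {}
    n_resp = 0
    for r in responses:
        if not r.responsive:
            continue
        n_resp += 1
        subset = frozenset(t for t, _ in r.qualifying)
        counts[subset] = counts.get(subset, 0) + 1
    singleton = sum(c for s, c in counts.items() if len(s) == 1)
    return {
        "subset_counts": counts,
        "n_responsive": n_resp,
        "tissue_specific_total": singleton,
        "tissue_specific_pct": 100.0 * singleton / n_resp if n_resp else float("nan"),
    }


def shared_de_fraction(de_by_tissue: dict[str, set[str]]) -> dict:
    """Genes shared across all tissues, as 100 * |intersection| / |union|."""
    if len(de_by_tissue) < 2:
        raise ValidationError("need >= 2 tissues to compute a shared fraction")
    sets = list(de_by_tissue.values())
    inter = set.intersection(*sets)
    union = set.union(*sets)
    pct = 100.0 * len(inter) / len(union) if union else None
    return {"n_shared": len(inter), "n_union": len(union), "pct": pct}


def responses_to_frame(responses: list[PairResponse]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                r.pair_id,
                r.responsive,
                ";".join(sorted(f"{t}@{tp}h" for t, tp in r.qualifying)),
                r.r if r.r is not None else np.nan,
                r.concordance if r.responsive else "",
            )
            for r in responses
        ],
        columns=["pair_id", "responsive", "qualifying", "r", "concordance"],
    )
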