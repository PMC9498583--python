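"""Assemble the run's bookkeeping summary and check its internal identities.

Re-reads the stage tables, recomputes every percentage from the counts in
the same bundle and writes results/summary_tables.tsv.
"""

import os
import sys

sys.path.insert(0, os.path.dirname(os.path.abspath(__file__)))
import _common

import pandas as pd

from natheat import genome
from natheat.pipeline import compute_summary_percentages


def main() -> None:
    pairs = genome.read_tsv(os.path.join(_common.RESULTS, "nat_pairs.tsv"))
    resp = genome.read_tsv(os.path.join(_common.RESULTS, "pair_responses.tsv"))
    prec = genome.read_tsv(os.path.join(_common.RESULTS, "nat_sirna_precursors.tsv"))

    blocks = []
    total = len(pairs)
    for column in ("pair_type", "configuration"):
        counts = pairs[column].value_counts().to_dict()
        df = compute_summary_percentages(counts, whole=total)
        df.insert(0, "table", column)
        blocks.append(df)
        assert df["count"].sum() == total

    responsive = resp[resp["responsive"]]
    conc = responsive["concordance"].value_counts().to_dict()
    df = compute_summary_percentages(conc, whole=len(responsive))
    df.insert(0, "table", "concordance")
    blocks.append(df)
    assert df["count"].sum() == len(responsive)

    df = compute_summary_percentages(
        {"precursor_pairs": int(prec["precursor"].sum())}, whole=len(prec)
    )
    df.insert(0, "table", "nat_sirna")
    blocks.append(df)

    out = pd.concat(blocks, ignore_index=True)
    path = _common.save(out, "summary_tables.tsv")
    print(f"summary tables -> {path}")
    for row in out.itertuples(index=False):
        print(f"  {row.table:<13} {row.label:<16} {row.count:>5} / {row.whole:<5} = {row.pct_display}%")
    print("all partition identities verified (counts sum to their denominators)")


if __name__ == "__main__":
    main()
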