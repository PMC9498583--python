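"""Discover cis-NAT pairs, orient them and classify configuration and type.

Opposite-strand span overlaps of >= 50 bp define the pairs; orientation
uses rice-conservation scores where present, then expression breadth, then
a lexicographic tie-break.  Writes results/nat_pairs.tsv with one row per
oriented pair.
"""

import os
import sys

sys.path.insert(0, os.path.dirname(os.path.abspath(__file__)))
import _common

from natheat import genome
from natheat.classify import LNC_CLASSES, filter_candidates
from natheat.pairs import (
    configuration_counts,
    find_nat_pairs,
    orient_pairs,
    pair_type_counts,
    pairs_to_frame,
)
from natheat.pipeline import compute_summary_percentages


def main() -> None:
    ann = _common.load_annotation()
    blacklist = genome.read_bed(_common.dataset_path("blacklist.bed"))
    labels = genome.read_tsv(_common.dataset_path("coding_labels.tsv"))
    calls = {c.transcript_id: c for c in filter_candidates(ann, blacklist, labels)}
    survivors = ann.subset(
        tid for tid, c in calls.items() if c.status in ("annotated_mRNA",) + LNC_CLASSES
    )
    expr = _common.load_expression()
    cons = genome.read_tsv(_common.dataset_path("conservation.tsv"))
    conservation = dict(zip(cons["transcript_id"], cons["score"]))
    unoriented = find_nat_pairs(survivors)
    pairs = orient_pairs(survivors, unoriented, calls, expr.tpm, expr.design, conservation)
    path = _common.save(pairs_to_frame(pairs), "nat_pairs.tsv")
    print(f"{len(pairs)} cis-NAT pairs (span overlap >= 50 bp) -> {path}")
    for name, counts in (("type", pair_type_counts(pairs)), ("configuration", configuration_counts(pairs))):
        pcts = compute_summary_percentages(counts)
        for row in pcts.itertuples(index=False):
            print(f"  {name:<14} {row.label:<14} {row.count:>4}  ({row.pct_display}%)")
    truth = genome.read_tsv(_common.dataset_path("truth_pairs.tsv"))
    planted = {tuple(sorted(t)) for t in truth[["sense_id", "antisense_id"]].itertuples(index=False)}
    found = {tuple(sorted(p.members)) for p in pairs}
    print(f"planted-pair recovery: {len(planted & found)}/{len(planted)}")


if __name__ == "__main__":
    main()
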