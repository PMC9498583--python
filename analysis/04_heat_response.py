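"""Call heat-responsive NAT pairs and split them into concordant/discordant.

Per-transcript response needs a 2-fold change (1-TPM pseudo-count) with
Welch p < 0.05; a pair responds when both members pass in the same
tissue-by-timepoint contrast.  Writes the per-contrast DE table, per-pair
responses and the tissue-specificity partition under results/.
"""

import os
import sys

sys.path.insert(0, os.path.dirname(os.path.abspath(__file__)))
import _common

import pandas as pd

from natheat import genome
from natheat.expression import (
    call_responsive_pairs,
    concordance_counts,
    diff_test_all,
    responses_to_frame,
    shared_de_fraction,
    tissue_specificity,
)


def main() -> None:
    expr = _common.load_expression()
    pairs = _common.load_pairs()
    diff = diff_test_all(expr)
    _common.save(diff, "diff_expression.tsv")
    responses = call_responsive_pairs(pairs, diff)
    path = _common.save(responses_to_frame(responses), "pair_responses.tsv")
    n_resp = sum(r.responsive for r in responses)
    conc = concordance_counts(responses)
    print(f"{n_resp}/{len(pairs)} pairs heat-responsive -> {path}")
    print(f"  concordant {conc['concordant']}, discordant {conc['discordant']}, "
          f"unclassified {conc['unclassified']}")
    part = tissue_specificity(responses)
    subset_df = pd.DataFrame(
        [(";".join(sorted(s)), c) for s, c in sorted(part["subset_counts"].items(), key=lambda kv: sorted(kv[0]))],
        columns=["tissue_subset", "n_pairs"],
    )
    _common.save(subset_df, "tissue_specificity.tsv")
    print(f"  tissue-specific: {part['tissue_specific_total']}/{part['n_responsive']} "
          f"({part['tissue_specific_pct']:.2f}%)")
    up = {t: set(g.loc[g["status"] == "up", "transcript_id"]) for t, g in diff.groupby("tissue")}
    down = {t: set(g.loc[g["status"] == "down", "transcript_id"]) for t, g in diff.groupby("tissue")}
    for name, sets in (("up", up), ("down", down)):
        shared = shared_de_fraction(sets)
        pct = "undefined" if shared["pct"] is None else f"{shared['pct']:.1f}%"
        print(f"  shared {name}-regulated across tissues: "
              f"{shared['n_shared']}/{shared['n_union']} ({pct})")


if __name__ == "__main__":
    main()
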