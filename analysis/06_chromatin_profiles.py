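"""Chromatin around responsive NAT genes: histone marks, methylation, HSEs.

Computes per-mark TSS-window association fractions and metaprofiles for
sense/antisense genes of responsive pairs, methylation change fractions at
6/12/24 h with per-context means, and scans promoter sequences for
canonical and non-canonical heat-shock elements.
"""

import os
import sys

sys.path.insert(0, os.path.dirname(os.path.abspath(__file__)))
import _common

import pandas as pd
from Bio import SeqIO

from natheat import genome
from natheat.chromatin import (
    DEFAULT_MARKS,
    hse_hits_to_frame,
    methylation_change,
    methylation_profile,
    peak_association,
    scan_hse,
    tss_metaprofile,
)


def main() -> None:
    ann = _common.load_annotation()
    pairs = _common.load_pairs()
    resp = genome.read_tsv(os.path.join(_common.RESULTS, "pair_responses.tsv"))
    resp_ids = set(resp.loc[resp["responsive"], "pair_id"])
    rp = [p for p in pairs if p.pair_id in resp_ids] or pairs
    classes = {
        "sense": [ann[p.sense_id] for p in rp],
        "antisense": [ann[p.antisense_id] for p in rp],
    }
    peaks = {m: genome.read_bed(_common.dataset_path(f"peaks_{m}.bed")) for m in DEFAULT_MARKS}
    assoc = peak_association(peaks, classes, chrom_sizes=ann.chrom_sizes)
    _common.save(assoc, "histone_association.tsv")
    print(f"histone association over {len(rp)} responsive pairs:")
    for mark in DEFAULT_MARKS:
        sub = assoc[assoc["mark"] == mark]
        fr = dict(zip(sub["class"], sub["fraction"]))
        print(f"  {mark:<9} sense {fr['sense']:.2f}  antisense {fr['antisense']:.2f}")
    profiles = []
    for mark, ivs in peaks.items():
        for cls, genes in classes.items():
            prof = tss_metaprofile(ivs, genes, chrom_sizes=ann.chrom_sizes)
            prof.insert(0, "mark", mark)
            prof.insert(1, "class", cls)
            profiles.append(prof)
    _common.save(pd.concat(profiles, ignore_index=True), "histone_tss_profiles.tsv")

    meth = genome.read_tsv(_common.dataset_path("methylation.tsv"))
    fracs = []
    for tp in (6, 12, 24):
        _, fr = methylation_change(meth, classes, tp)
        fracs.append(fr)
    frac_df = pd.concat(fracs, ignore_index=True)
    _common.save(frac_df, "methylation_change_fractions.tsv")
    for row in frac_df[frac_df["class"] == "sense"].itertuples(index=False):
        print(f"  methylation at {row.timepoint_h:>2} h (sense): "
              f"{row.up_fraction:.0%} up vs {row.down_fraction:.0%} down")
    ctx = methylation_profile(meth, classes["sense"] + classes["antisense"])
    _common.save(ctx, "methylation_context_means.tsv")
    means = dict(zip(ctx["context"], ctx["mean_level"]))
    order = " > ".join(sorted(means, key=means.get, reverse=True))
    print(f"  context means: {means} (ordering {order})")

    hits = {
        rec.id: scan_hse(str(rec.seq))
        for rec in SeqIO.parse(_common.dataset_path("promoters.fasta"), "fasta")
    }
    _common.save(hse_hits_to_frame(hits), "hse_hits.tsv")
    with_hse = sum(1 for h in hits.values() if h)
    print(f"  HSE motifs found in {with_hse}/{len(hits)} NAT-gene promoters")


if __name__ == "__main__":
    main()
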