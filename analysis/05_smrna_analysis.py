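"""Small-RNA analysis: nat-siRNA precursor calling and TSS density by class.

A pair is a potential nat-siRNA precursor when its double-stranded overlap
fully contains at least one 20-24-nt read.  TSS density compares
sense-of-NAT, antisense-of-NAT and non-NAT genes over +/-1000 nt (and the
2000-bp promoter-window variant).  Writes precursor flags, per-class
densities, the start-position profile and the length histogram.
"""

import os
import sys

sys.path.insert(0, os.path.dirname(os.path.abspath(__file__)))
import _common

from natheat import genome
from natheat.smrna import (
    call_nat_sirna_precursors,
    length_distribution,
    reads_from_bed,
    tss_smrna_density,
)


def main() -> None:
    ann = _common.load_annotation()
    reads = reads_from_bed(genome.read_bed(_common.dataset_path("smrna.bed")))
    pairs = _common.load_pairs()
    precursors = call_nat_sirna_precursors(pairs, reads)
    path = _common.save(precursors, "nat_sirna_precursors.tsv")
    print(f"{int(precursors['precursor'].sum())}/{len(pairs)} pairs flagged as "
          f"potential nat-siRNA precursors -> {path}")

    sense = sorted({p.sense_id for p in pairs})
    anti = sorted({p.antisense_id for p in pairs})
    members = set(sense) | set(anti)
    classes = {
        "sense": [ann[i] for i in sense],
        "antisense": [ann[i] for i in anti],
        "non-NAT": [t for t in ann.sorted_transcripts()
                    if t.biotype == "mRNA" and t.transcript_id not in members],
    }
    for window, label in ((1000, "tss1000"), (2000, "tss2000")):
        density, profile = tss_smrna_density(reads, classes, window=window)
        _common.save(density, f"smrna_density_{label}.tsv")
        if window == 1000:
            _common.save(profile, "smrna_tss_profile.tsv")
        means = dict(zip(density["class"], density["mean_reads_per_gene"]))
        print(f"  mean reads/gene (+/-{window} nt): "
              + ", ".join(f"{c} {means[c]:.2f}" for c in ("sense", "antisense", "non-NAT")))

    overlaps = genome.IntervalSet()
    for p in pairs:
        overlaps.add(p.chrom, p.overlap[0], p.overlap[1])
    lengths = length_distribution(reads, overlaps)
    _common.save(lengths.reset_index(), "smrna_length_distribution.tsv")
    print(f"  reads inside overlap regions: {int(lengths.sum())} "
          f"(modal length {int(lengths.idxmax())} nt)")


if __name__ == "__main__":
    main()
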