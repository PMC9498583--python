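"""Generate the synthetic heat-stress transcriptome used by all later steps.

Writes annotation (GTF), blacklist (BED), coding labels, TPM matrix +
sample design, smRNA reads (BED), histone peaks (BED per mark), cytosine
methylation (TSV), promoters (FASTA) and the truth tables under
results/synthetic, then prints what was planted.
"""

import os
import sys

sys.path.insert(0, os.path.dirname(os.path.abspath(__file__)))
import _common

from natheat.simulate import SimulationConfig, write_dataset


def main() -> None:
    cfg = SimulationConfig(seed=_common.SEED)
    paths = write_dataset(cfg, _common.DATASET)
    from natheat import genome

    truth_pairs = genome.read_tsv(paths["truth"]["pairs"])
    truth_tr = genome.read_tsv(paths["truth"]["transcripts"])
    print(f"dataset written to {_common.DATASET}")
    print(f"  transcripts: {len(truth_tr)} "
          f"({(truth_tr['true_class'] == 'mRNA').sum()} mRNA, "
          f"{(truth_tr['true_class'] == 'NAT_member').sum()} NAT lncRNA members, "
          f"{truth_tr['true_class'].isin(['lincRNA', 'incRNA']).sum()} other lncRNA, "
          f"{truth_tr['true_class'].str.endswith('decoy').sum()} decoys)")
    config_counts = {k: int(v) for k, v in truth_pairs["configuration"].value_counts().items()}
    print(f"  planted cis-NAT pairs: {len(truth_pairs)} ({config_counts})")
    print(f"  heat-responsive pairs: {int(truth_pairs['responsive'].sum())} "
          f"(concordant {(truth_pairs['concordance_sign'] == 1).sum()}, "
          f"discordant {(truth_pairs['concordance_sign'] == -1).sum()})")
    print(f"  smRNA enrichment over NAT regions: {cfg.smrna_overlap_enrichment}x; "
          f"methylation down-shift in {cfg.meth_frac_down:.0%} of NAT genes")


if __name__ == "__main__":
    main()
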