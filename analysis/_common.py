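"""Shared paths and loaders for the numbered analysis scripts.

Every script operates on the synthetic dataset written by 01_simulate.py
into results/synthetic and writes its own tables into results/.
"""

import os

from natheat import genome
from natheat.expression import ExpressionMatrix

ROOT = os.path.dirname(os.path.dirname(os.path.abspath(__file__)))
RESULTS = os.path.join(ROOT, "results")
DATASET = os.path.join(RESULTS, "synthetic")
SEED = 1


def dataset_path(name: str) -> str:
    return os.path.join(DATASET, name)


def load_annotation():
    ann = genome.read_gtf(dataset_path("annotation.gtf"))
    sizes = genome.read_tsv(dataset_path("chrom_sizes.tsv"))
    ann.chrom_sizes = dict(zip(sizes["chrom"].astype(str), sizes["size"].astype(int)))
    return ann


def load_expression() -> ExpressionMatrix:
    tpm = genome.read_tsv(dataset_path("expression_tpm.tsv")).set_index("transcript_id")
    design = genome.read_tsv(dataset_path("sample_design.tsv"))
    return ExpressionMatrix(tpm=tpm[list(design["sample_id"])], design=design)


def load_pairs():
    import pandas as pd

    from natheat.pairs import NatPair

    df = genome.read_tsv(os.path.join(RESULTS, "nat_pairs.tsv"))
    return [
        NatPair(
            r.sense_id, r.antisense_id, r.chrom, (int(r.overlap_start), int(r.overlap_end)),
            int(r.overlap_len), r.configuration, r.pair_type, r.orientation_basis,
        )
        for r in df.itertuples(index=False)
    ]


def save(df, name: str) -> str:
    path = os.path.join(RESULTS, name)
    genome.write_tsv(df, path)
    return path
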