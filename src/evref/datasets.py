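"""Small bundled reference tables.

The only shipped dataset is the published list of the eleven rank-sum
ordered transcripts (RPKM ≥ 1000) shared by EVs from all twelve cell
sources, with their biotype classification — enough to run the biotype
filter at desk scale without any sequencing data.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .expression import GeneAnnotation


def shared_abundant_transcripts() -> pd.DataFrame:
    """The 11 robustly abundant transcripts shared across all 12 EV sources.

    Columns: rank_sum_order, gene_id (ENSEMBL), symbol, gene_name,
    classification (as printed: Protein-coding / Pseudogene / lncRNA /
    scRNA / Mitochondrial).
    """
    with resources.files("evref.data").joinpath(
            "shared_abundant_transcripts.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def shared_abundant_annotation() -> GeneAnnotation:
    """The same table as a :class:`GeneAnnotation` (canonical biotypes)."""
    df = shared_abundant_transcripts()
    table = pd.DataFrame({
        "symbol": df["symbol"].to_numpy(),
        "biotype": df["classification"].map(GeneAnnotation.normalize_biotype).to_numpy(),
        "length_bp": float("nan"),
    }, index=df["gene_id"])
    table.index.name = "gene_id"
    return GeneAnnotation(table)
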