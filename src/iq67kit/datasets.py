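"""Packaged reference tables."""

from __future__ import annotations

from importlib import resources

import pandas as pd


def load_sun_family_table() -> pd.DataFrame:
    """The published 24-member melon SUN family table.

    Columns: name, gene_id, chromosome, orf_bp, aa, mw_kd, pi — ORF length in
    bp (stop codon included), protein length in aa, molecular weight in kD,
    theoretical isoelectric point.
    """
    with resources.files("iq67kit.data").joinpath("sun_family_table.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
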