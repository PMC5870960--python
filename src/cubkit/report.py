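"""Tabular output helpers shared by the CLI.

All tables are TSV with a single header row; undefined values print as
``NA``. Codons print in the RNA alphabet by default (a flag switches the
CLI to DNA).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .genetic_code import to_rna

NA_REP = "NA"
FLOAT_FMT = "%.6g"


def write_tsv(df: pd.DataFrame, path: str | Path, index_label: str | None = None) -> None:
    df.to_csv(
        path,
        sep="\t",
        na_rep=NA_REP,
        float_format=FLOAT_FMT,
        index=index_label is not None,
        index_label=index_label,
    )


def codon_display(codon: str, alphabet: str = "rna") -> str:
    return to_rna(codon) if alphabet == "rna" else codon
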