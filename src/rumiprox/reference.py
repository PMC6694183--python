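"""Bundled reference tables from the published 42-animal cattle study
this package's analysis design follows.

Two small tables ship with the package: the per-trait gene-selection
tables (KO id, gene abbreviation, mean abundance, PLS estimate, VIP and
network cluster for FCR, ADG, RFI and DFI) and the per-factor
percent-variance table of the corresponding three-factor PLS models.
They serve as worked-example inputs: overlap analysis of the printed
selections and reconstruction of the cumulative variance columns."""

from __future__ import annotations

from importlib.resources import files

import pandas as pd

from .phenotypes import TRAITS


def reference_selections() -> pd.DataFrame:
    """Published per-trait gene-selection tables (one row per KO)."""
    path = files("rumiprox.data") / "reference_selections.tsv"
    return pd.read_csv(path, sep="\t", dtype={"trait": str, "ko": str, "gene": str,
                                              "cluster": str},
                       keep_default_na=False, na_values=[""])


def reference_gene_sets() -> dict[str, list[str]]:
    """Published selected-KO lists keyed by trait."""
    ref = reference_selections()
    return {t: ref.loc[ref["trait"] == t, "ko"].tolist() for t in TRAITS}


def reference_variance_table() -> pd.DataFrame:
    """Published per-factor percent-variance table (three factors per
    trait; current and cumulative columns for both blocks)."""
    path = files("rumiprox.data") / "reference_variance_table.tsv"
    return pd.read_csv(path, sep="\t")
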