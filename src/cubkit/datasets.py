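"""Bundled published datasets.

Per-species codon-usage statistics of the mammalian MMP-2 and MMP-9
coding sequences (seven species), as published: nucleotide composition,
codon-usage indices, and cross-species mean RSCU tables.  These serve as
desk-scale inputs for the correlation, ENC-plot and RSCU-identity
analyses without any sequence download.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_GENES = ("mmp2", "mmp9")


def _load(name: str) -> pd.DataFrame:
    with resources.files("cubkit.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def available_genes() -> tuple[str, ...]:
    return _GENES


def load_nucleotide_composition(gene: str) -> pd.DataFrame:
    """Per-species base composition (at/gc fractions, per-base X3s, GC3s, AT3s)."""
    if gene not in _GENES:
        raise KeyError(f"unknown gene {gene!r}; available: {_GENES}")
    return _load(f"{gene}_nucleotide_composition.tsv")


def load_codon_indices(gene: str) -> pd.DataFrame:
    """Per-species ENC/CAI/CBI/FOP and GC1s/GC2s/GC12 values."""
    if gene not in _GENES:
        raise KeyError(f"unknown gene {gene!r}; available: {_GENES}")
    return _load(f"{gene}_codon_indices.tsv")


def load_mean_rscu(gene: str) -> pd.DataFrame:
    """Cross-species mean RSCU table (amino_acid, codon, frequency, rscu)."""
    if gene not in _GENES:
        raise KeyError(f"unknown gene {gene!r}; available: {_GENES}")
    return _load(f"{gene}_mean_rscu.tsv")
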