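"""Positional nucleotide composition statistics of a coding sequence.

The "s" subscript statistics (GC3s, T3s, ..., GC1s, GC2s) are computed
over synonymous codons only: sense codons of amino-acid families with at
least two members, i.e. the 59-codon universe that excludes Met, Trp and
the stop codons.

Two conventions are offered for the per-base third-position statistics
(T3s/C3s/A3s/G3s):

``simple``
    fraction of synonymous third positions carrying the base; the four
    values partition 1.

``per_base_denominator`` (default)
    for base B the denominator is the number of synonymous codons whose
    family contains at least one synonym ending in B.  The four values may
    sum to more than 1.  This is the convention of classic codon-usage
    software, where each base is scored against the codons that *could*
    have ended in it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import pandas as pd

from .codonio import CodonCountTable, GeneticCode, STANDARD_CODE
from .errors import UndefinedStatisticError

X3sConvention = Literal["simple", "per_base_denominator"]
Gc12Universe = Literal["synonymous", "all"]

_COLUMNS = [
    "gene_id", "at_frac", "gc_frac", "t3s", "c3s", "a3s", "g3s",
    "gc3s", "at3s", "gc1s", "gc2s", "gc12", "n_syn_codons",
]


@dataclass(frozen=True)
class CompositionProfile:
    gene_id: str
    at_frac: float
    gc_frac: float
    t3s: float
    c3s: float
    a3s: float
    g3s: float
    gc3s: float
    at3s: float
    gc1s: float
    gc2s: float
    gc12: float
    n_syn_codons: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in _COLUMNS}


def synonymous_codon_set(
    counts: CodonCountTable, code: GeneticCode = STANDARD_CODE
) -> CodonCountTable:
    """Restrict a count table to synonymous codons (multi-codon sense families)."""
    return counts.restrict(code.synonymous_codons())


def composition_profile(
    counts: CodonCountTable,
    code: GeneticCode = STANDARD_CODE,
    x3s_convention: X3sConvention = "per_base_denominator",
    gc12_universe: Gc12Universe = "synonymous",
) -> CompositionProfile:
    """Compute the composition profile of one codon count table.

    ``at_frac``/``gc_frac`` cover all nucleotides of all counted codons
    (including Met, Trp and stops); every "s" statistic covers synonymous
    codons only.  ``gc12_universe`` switches the GC1s/GC2s denominator
    between the synonymous universe (default) and all counted codons.
    """
    if counts.n_codons == 0:
        raise UndefinedStatisticError(f"{counts.gene_id}: no counted codons")

    total_nt = 3 * counts.n_codons
    gc_nt = sum(
        n * sum(1 for b in codon if b in "GC")
        for codon, n in counts.counts.items()
    )
    gc_frac = gc_nt / total_nt
    at_frac = 1.0 - gc_frac

    syn = synonymous_codon_set(counts, code)
    n_syn = syn.n_codons
    if n_syn == 0:
        raise UndefinedStatisticError(
            f"{counts.gene_id}: no synonymous codons; profile undefined"
        )

    third = {"T": 0, "C": 0, "A": 0, "G": 0}
    for codon, n in syn.counts.items():
        third[codon[2]] += n
    gc3s = (third["G"] + third["C"]) / n_syn
    at3s = 1.0 - gc3s

    if x3s_convention == "simple":
        x3s = {b: third[b] / n_syn for b in "TCAG"}
    else:
        x3s = {}
        for b in "TCAG":
            denom = 0
            for codon, n in syn.counts.items():
                fam = code.family_of[code.codon_to_aa[codon]]
                if any(syn_codon[2] == b for syn_codon in fam):
                    denom += n
            x3s[b] = third[b] / denom if denom else 0.0

    universe = syn if gc12_universe == "synonymous" else counts
    n_univ = universe.n_codons
    gc1 = sum(n for codon, n in universe.counts.items() if codon[0] in "GC")
    gc2 = sum(n for codon, n in universe.counts.items() if codon[1] in "GC")
    gc1s = gc1 / n_univ
    gc2s = gc2 / n_univ
    gc12 = (gc1s + gc2s) / 2.0

    return CompositionProfile(
        gene_id=counts.gene_id,
        at_frac=at_frac, gc_frac=gc_frac,
        t3s=x3s["T"], c3s=x3s["C"], a3s=x3s["A"], g3s=x3s["G"],
        gc3s=gc3s, at3s=at3s,
        gc1s=gc1s, gc2s=gc2s, gc12=gc12,
        n_syn_codons=n_syn,
    )


def composition_table(
    tables: Iterable[CodonCountTable],
    code: GeneticCode = STANDARD_CODE,
    x3s_convention: X3sConvention = "per_base_denominator",
    gc12_universe: Gc12Universe = "synonymous",
) -> pd.DataFrame:
    """One composition-profile row per gene, in input order."""
    rows = [
        composition_profile(t, code, x3s_convention, gc12_universe).to_dict()
        for t in tables
    ]
    return pd.DataFrame(rows, columns=_COLUMNS)
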