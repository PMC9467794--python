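"""Codon usage bias statistics: RSCU, ENC, CAI, FOP and CBI.

RSCU for codon j of amino acid i with degeneracy n_i is
``X_ij * n_i / sum_j X_ij``; families with zero total are undefined
(reported as missing, never as zero).

ENC follows Wright's recipe: per-family homozygosity
``F = (n * sum(p_i^2) - 1) / (n - 1)`` averaged within degeneracy classes,
``ENC = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6``, with the 3-fold class imputed as
``(F2 + F4) / 2`` when unobservable and the result capped at 61.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .codonio import (
    CodonCountTable,
    GeneticCode,
    STANDARD_CODE,
    codon_sort_key,
    to_dna,
    to_rna,
)
from .errors import UndefinedStatisticError, ValidationError, FormatError

logger = logging.getLogger(__name__)

#: Flavour classes of amino acids (delicious / Strecker / branched-chain).
FLAVOUR_CLASSES: dict[str, frozenset[str]] = {
    "DAA": frozenset({"Glu", "Gly", "Ser", "Asp", "Arg", "Ile"}),
    "SAA": frozenset({"Phe", "Cys", "Ile", "Leu"}),
    "BCAA": frozenset({"Leu", "Ile", "Val"}),
}


def flavour_tags(amino_acid: str) -> tuple[str, ...]:
    return tuple(
        tag for tag in ("DAA", "SAA", "BCAA")
        if amino_acid in FLAVOUR_CLASSES[tag]
    )


def _preference(rscu: Optional[float]) -> str:
    if rscu is None:
        return "none"
    if rscu > 2:
        return "strong"
    if rscu > 1:
        return "preferred"
    return "none"


@dataclass(frozen=True)
class RSCURow:
    amino_acid: str
    codon: str  # RNA alphabet
    count: int
    rscu: Optional[float]  # None when the family was not observed
    preference: str = "none"
    flavour: tuple[str, ...] = ()


@dataclass
class RSCUTable:
    set_id: str
    rows: list[RSCURow] = field(default_factory=list)

    def rscu_of(self, codon: str) -> Optional[float]:
        codon = to_rna(to_dna(codon))
        for row in self.rows:
            if row.codon == codon:
                return row.rscu
        raise KeyError(codon)

    def count_of(self, codon: str) -> int:
        codon = to_rna(to_dna(codon))
        for row in self.rows:
            if row.codon == codon:
                return row.count
        raise KeyError(codon)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "set_id": self.set_id,
                "amino_acid": r.amino_acid,
                "codon": r.codon,
                "count": r.count,
                "rscu": r.rscu,
                "preference": r.preference,
                "flavour": ",".join(r.flavour),
            }
            for r in self.rows
        )


@dataclass(frozen=True)
class ReferenceWeights:
    """CAI relative-adaptiveness weights, one per sense codon of a
    multi-codon family; each family's maximum weight is 1."""

    weights: dict[str, float]
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        for codon, w in self.weights.items():
            if not 0 < w <= 1:
                raise ValidationError(
                    f"weight for {codon} is {w}; must be in (0, 1]"
                )


@dataclass(frozen=True)
class OptimalCodonSet:
    codons: frozenset[str]  # DNA alphabet
    provenance: str = "unspecified"

    @staticmethod
    def from_codons(codons: Iterable[str], provenance: str = "unspecified",
                    code: GeneticCode = STANDARD_CODE) -> "OptimalCodonSet":
        dna = frozenset(to_dna(c) for c in codons)
        syn = set(code.synonymous_codons())
        bad = dna - syn
        if bad:
            raise ValidationError(
                f"optimal codons must be sense codons of multi-codon "
                f"families; offending: {sorted(bad)}"
            )
        return OptimalCodonSet(dna, provenance)


def rscu(
    counts: CodonCountTable,
    code: GeneticCode = STANDARD_CODE,
    include_stops: bool = False,
) -> RSCUTable:
    """Relative synonymous codon usage of one gene (or pooled gene set)."""
    table = RSCUTable(set_id=counts.gene_id)
    for aa in code.amino_acids(include_stops=include_stops):
        fam = code.family_of[aa]
        fam_total = sum(counts.counts[c] for c in fam)
        for codon in fam:
            x = counts.counts[codon]
            value = x * len(fam) / fam_total if fam_total > 0 else None
            table.rows.append(
                RSCURow(
                    amino_acid=aa,
                    codon=to_rna(codon),
                    count=x,
                    rscu=value,
                    preference=_preference(value),
                    flavour=flavour_tags(aa),
                )
            )
    # canonical row order (families of Ser/Arg/Leu render as split blocks)
    table.rows.sort(key=lambda r: codon_sort_key(to_dna(r.codon)))
    return table


def mean_rscu(tables: Sequence[RSCUTable]) -> RSCUTable:
    """Cross-set RSCU: counts are summed; RSCU is the arithmetic mean of
    per-set values over the sets where the family was observed.

    Averaging per-set RSCU (rather than recomputing from pooled counts)
    preserves the family-sum-equals-degeneracy identity.
    """
    if not tables:
        raise ValidationError("mean_rscu requires at least one table")
    out = RSCUTable(set_id="mean")
    for i, template_row in enumerate(tables[0].rows):
        codon = template_row.codon
        count = 0
        values = []
        for t in tables:
            row = t.rows[i]
            if row.codon != codon:
                raise ValidationError("tables have mismatched codon layouts")
            count += row.count
            if row.rscu is not None:
                values.append(row.rscu)
        value = sum(values) / len(values) if values else None
        out.rows.append(
            RSCURow(
                amino_acid=template_row.amino_acid,
                codon=codon,
                count=count,
                rscu=value,
                preference=_preference(value),
                flavour=template_row.flavour,
            )
        )
    return out


def enc(counts: CodonCountTable, code: GeneticCode = STANDARD_CODE) -> float:
    """Wright's effective number of codons, capped at 61."""
    class_f: dict[int, list[float]] = {}
    class_sizes: dict[int, int] = {}
    for aa in code.amino_acids():
        fam = code.family_of[aa]
        k = len(fam)
        if k < 2:
            continue
        class_sizes[k] = class_sizes.get(k, 0) + 1
        n = sum(counts.counts[c] for c in fam)
        if n < 2:
            continue
        sum_p2 = sum((counts.counts[c] / n) ** 2 for c in fam)
        f = (n * sum_p2 - 1) / (n - 1)
        if f <= 0:
            continue
        class_f.setdefault(k, []).append(f)

    if not class_f:
        raise UndefinedStatisticError(
            f"{counts.gene_id}: no family has 2 or more codons counted"
        )

    f_bar: dict[int, float] = {
        k: sum(v) / len(v) for k, v in class_f.items()
    }
    if 3 not in f_bar and 2 in f_bar and 4 in f_bar:
        f_bar[3] = (f_bar[2] + f_bar[4]) / 2.0
    missing = [k for k in class_sizes if k not in f_bar]
    if missing:
        raise UndefinedStatisticError(
            f"{counts.gene_id}: degeneracy classes {missing} unobservable"
        )
    value = 2.0 + sum(class_sizes[k] / f_bar[k] for k in class_sizes)
    return min(value, 61.0)


def cai(
    counts: CodonCountTable,
    weights: ReferenceWeights,
    floor: float = 0.01,
) -> float:
    """Codon adaptation index: geometric mean of reference weights over all
    counted codons of multi-codon families (Met, Trp, stops excluded)."""
    code = STANDARD_CODE
    log_sum = 0.0
    n = 0
    floored = 0
    for codon in code.synonymous_codons():
        x = counts.counts[codon]
        if x == 0:
            continue
        w = weights.weights.get(codon)
        if w is None or w < floor:
            w = floor
            floored += x
        log_sum += x * math.log(w)
        n += x
    if n == 0:
        raise UndefinedStatisticError(f"{counts.gene_id}: no eligible codons for CAI")
    if floored:
        logger.info(
            "%s: CAI floor %.3g applied to %d codon occurrences",
            counts.gene_id, floor, floored,
        )
    return math.exp(log_sum / n)


def fop(counts: CodonCountTable, optimal: OptimalCodonSet,
        code: GeneticCode = STANDARD_CODE) -> float:
    """Frequency of optimal codons among synonymous codons."""
    n_syn = sum(counts.counts[c] for c in code.synonymous_codons())
    if n_syn == 0:
        raise UndefinedStatisticError(f"{counts.gene_id}: no synonymous codons")
    n_opt = sum(counts.counts[c] for c in optimal.codons)
    return n_opt / n_syn


def cbi(counts: CodonCountTable, optimal: OptimalCodonSet,
        code: GeneticCode = STANDARD_CODE) -> float:
    """Codon bias index: (N_opt - N_ran) / (N_tot - N_ran), where N_ran is
    the optimal-codon count expected under uniform synonymous usage."""
    n_tot = 0
    n_opt = 0
    n_ran = 0.0
    for aa in code.amino_acids():
        fam = code.family_of[aa]
        if len(fam) < 2:
            continue
        fam_count = sum(counts.counts[c] for c in fam)
        fam_opt = sum(1 for c in fam if c in optimal.codons)
        n_tot += fam_count
        n_opt += sum(counts.counts[c] for c in fam if c in optimal.codons)
        n_ran += fam_count * fam_opt / len(fam)
    if n_tot == 0 or math.isclose(n_tot, n_ran):
        raise UndefinedStatisticError(
            f"{counts.gene_id}: CBI denominator degenerate (N_tot == N_ran)"
        )
    return (n_opt - n_ran) / (n_tot - n_ran)


def derive_optimal_codons(
    tables: Sequence[RSCUTable],
    code: GeneticCode = STANDARD_CODE,
) -> OptimalCodonSet:
    """Per family, the codon with highest mean RSCU across the given tables;
    ties break toward the canonical codon order."""
    if not tables:
        raise ValidationError("derive_optimal_codons requires at least one table")
    means = mean_rscu(list(tables)) if len(tables) > 1 else tables[0]
    value_of = {row.codon: row.rscu for row in means.rows}
    chosen: set[str] = set()
    for aa in code.amino_acids():
        fam = code.family_of[aa]
        if len(fam) < 2:
            continue
        best, best_val = None, None
        for codon in fam:  # fam is already in canonical order
            v = value_of.get(to_rna(codon))
            if v is None:
                continue
            if best_val is None or v > best_val:
                best, best_val = codon, v
        if best is not None:
            chosen.add(best)
    return OptimalCodonSet.from_codons(chosen, provenance="derived:max-mean-rscu")


def weights_from_rscu(table: RSCUTable,
                      code: GeneticCode = STANDARD_CODE,
                      provenance: str = "derived:rscu-ratio") -> ReferenceWeights:
    """Relative adaptiveness w = RSCU / max(RSCU) within each family, built
    from a reference RSCU table (e.g. the pooled analysed set)."""
    value_of = {row.codon: row.rscu for row in table.rows}
    weights: dict[str, float] = {}
    for aa in code.amino_acids():
        fam = code.family_of[aa]
        if len(fam) < 2:
            continue
        vals = {c: value_of.get(to_rna(c)) for c in fam}
        observed = {c: v for c, v in vals.items() if v is not None}
        if not observed:
            continue
        vmax = max(observed.values())
        if vmax <= 0:
            continue
        for c, v in observed.items():
            if v > 0:
                weights[c] = v / vmax
    return ReferenceWeights(weights, provenance)


@dataclass(frozen=True)
class CUBIndexSet:
    gene_id: str
    enc: float
    cai: float
    cbi: float
    fop: float

    def to_dict(self) -> dict:
        return {
            "gene_id": self.gene_id, "enc": self.enc,
            "cai": self.cai, "cbi": self.cbi, "fop": self.fop,
        }


def cub_indices(
    counts: CodonCountTable,
    weights: ReferenceWeights,
    optimal: OptimalCodonSet,
    code: GeneticCode = STANDARD_CODE,
    cai_floor: float = 0.01,
) -> CUBIndexSet:
    """ENC/CAI/CBI/FOP bundle for one gene."""
    return CUBIndexSet(
        gene_id=counts.gene_id,
        enc=enc(counts, code),
        cai=cai(counts, weights, cai_floor),
        cbi=cbi(counts, optimal, code),
        fop=fop(counts, optimal, code),
    )


def read_codon_value_file(path: str | Path) -> dict[str, float]:
    """Two-column text file (codon, value); '#' comments and blank lines ignored."""
    out: dict[str, float] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise FormatError(f"{path}:{lineno}: expected 'codon value'")
        try:
            out[to_dna(parts[0])] = float(parts[1])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: bad value {parts[1]!r}") from exc
    return out


def write_codon_value_file(values: dict[str, float], path: str | Path) -> None:
    with open(path, "w") as fh:
        for codon in sorted(values, key=codon_sort_key):
            fh.write(f"{to_rna(codon)}\t{values[codon]:.6f}\n")
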