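"""Reading CDS FASTA files and tokenizing them into codon count tables.

Sequences are stored internally in the DNA alphabet (U is normalized to T
on input); codons are rendered in the RNA alphabet for user-facing tables.
The canonical codon ordering used in every output sorts by second base,
then first, then third (rank U < C < A < G) with stop codons last — the
classic layout of codon-usage tables, which keeps each amino-acid family
contiguous and makes outputs diffable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.SeqUtils import seq3

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGTN")
_BASE_RANK = {"T": 0, "C": 1, "A": 2, "G": 3}

FramePolicy = Literal["strict", "trim"]


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


@dataclass(frozen=True)
class CDSRecord:
    """One coding sequence; alphabet restricted to {A,C,G,T,N} after U→T."""

    id: str
    description: str
    sequence: str

    def __post_init__(self) -> None:
        norm = _normalize(self.sequence)
        object.__setattr__(self, "sequence", norm)
        if not norm:
            raise ValidationError(f"record {self.id!r}: empty sequence")
        bad = set(norm) - _VALID_BASES
        if bad:
            raise ValidationError(
                f"record {self.id!r}: invalid characters {sorted(bad)}"
            )

    @property
    def length_nt(self) -> int:
        return len(self.sequence)


class GeneticCode:
    """The standard genetic code with synonymous-family structure.

    Attributes
    ----------
    codon_to_aa : dict
        All 64 DNA codons -> three-letter amino acid name ("TER" for stops).
    family_of : dict
        Amino acid -> tuple of its codons in canonical order.
    degeneracy : dict
        Amino acid -> family size (1, 2, 3, 4 or 6 in the standard code).
    """

    def __init__(self, table_id: int = 1) -> None:
        table = CodonTable.unambiguous_dna_by_id[table_id]
        self.codon_to_aa: dict[str, str] = {}
        for codon, aa1 in table.forward_table.items():
            self.codon_to_aa[codon] = seq3(aa1)
        for codon in table.stop_codons:
            self.codon_to_aa[codon] = "TER"
        if len(self.codon_to_aa) != 64:
            raise ValidationError("genetic code must map exactly 64 codons")

        self.family_of: dict[str, tuple[str, ...]] = {}
        for codon in sorted(self.codon_to_aa, key=codon_sort_key):
            aa = self.codon_to_aa[codon]
            self.family_of.setdefault(aa, ())
            self.family_of[aa] += (codon,)
        self.degeneracy: dict[str, int] = {
            aa: len(fam) for aa, fam in self.family_of.items()
        }
        self.stop_codons: tuple[str, ...] = tuple(
            sorted(table.stop_codons, key=codon_sort_key)
        )
        self.sense_codons: tuple[str, ...] = tuple(
            c for c in sorted(self.codon_to_aa, key=codon_sort_key)
            if self.codon_to_aa[c] != "TER"
        )

    def is_stop(self, codon: str) -> bool:
        return self.codon_to_aa[codon] == "TER"

    def synonymous_codons(self) -> tuple[str, ...]:
        """Sense codons of families with >= 2 synonyms (59 in the standard code)."""
        return tuple(
            c for c in self.sense_codons
            if self.degeneracy[self.codon_to_aa[c]] >= 2
        )

    def amino_acids(self, include_stops: bool = False) -> tuple[str, ...]:
        seen: list[str] = []
        for codon in sorted(self.codon_to_aa, key=codon_sort_key):
            aa = self.codon_to_aa[codon]
            if aa == "TER" and not include_stops:
                continue
            if aa not in seen:
                seen.append(aa)
        return tuple(seen)


def codon_sort_key(codon: str) -> tuple[int, int, int, int]:
    """Canonical table order: stops last, then by 2nd, 1st, 3rd base (U<C<A<G)."""
    is_stop = 1 if codon in ("TAA", "TAG", "TGA") else 0
    return (is_stop, _BASE_RANK[codon[1]], _BASE_RANK[codon[0]], _BASE_RANK[codon[2]])


def to_rna(codon: str) -> str:
    return codon.replace("T", "U")


def to_dna(codon: str) -> str:
    return codon.upper().replace("U", "T")


STANDARD_CODE = GeneticCode()

#: All 64 DNA codons in canonical output order.
CANONICAL_CODON_ORDER: tuple[str, ...] = tuple(
    sorted(STANDARD_CODE.codon_to_aa, key=codon_sort_key)
)


@dataclass
class CodonCountTable:
    """Per-gene counts of all 64 codons.

    ``n_codons`` counts every counted triplet (including stops);
    ``n_skipped`` counts triplets that contained an N and were not counted.
    """

    gene_id: str
    counts: dict[str, int]
    n_codons: int = 0
    n_skipped: int = 0

    def __post_init__(self) -> None:
        full = {c: 0 for c in CANONICAL_CODON_ORDER}
        for codon, n in self.counts.items():
            codon = to_dna(codon)
            if codon not in full:
                raise ValidationError(f"unknown codon {codon!r}")
            if n < 0:
                raise ValidationError(f"negative count for codon {codon}")
            full[codon] = int(n)
        self.counts = full
        total = sum(full.values())
        if self.n_codons == 0 and total > 0:
            self.n_codons = total
        if total != self.n_codons:
            raise ValidationError(
                f"{self.gene_id}: counts sum to {total}, n_codons={self.n_codons}"
            )

    def total(self) -> int:
        return self.n_codons

    def restrict(self, codons: Iterable[str]) -> "CodonCountTable":
        keep = {to_dna(c) for c in codons}
        sub = {c: n for c, n in self.counts.items() if c in keep}
        return CodonCountTable(self.gene_id, sub, sum(sub.values()), 0)

    def scaled(self, k: int) -> "CodonCountTable":
        return CodonCountTable(
            self.gene_id, {c: n * k for c, n in self.counts.items()},
            self.n_codons * k, self.n_skipped,
        )

    def to_dataframe(self, code: GeneticCode = STANDARD_CODE) -> pd.DataFrame:
        rows = [
            {
                "gene_id": self.gene_id,
                "amino_acid": code.codon_to_aa[c],
                "codon": to_rna(c),
                "count": self.counts[c],
            }
            for c in CANONICAL_CODON_ORDER
        ]
        return pd.DataFrame(rows)


def read_cds_fasta(path: str | Path) -> list[CDSRecord]:
    """Read a multi-FASTA file of coding sequences.

    U is normalized to T; ids are the first whitespace-delimited header
    token; entry order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    with open(path) as handle:
        first = handle.readline()
        if not first.strip():
            raise FormatError(f"{path}: empty file")
        if not first.startswith(">"):
            raise FormatError(f"{path}: line 1 is not a FASTA header")
    records: list[CDSRecord] = []
    for seq_rec in SeqIO.parse(str(path), "fasta"):
        try:
            records.append(
                CDSRecord(
                    id=seq_rec.id,
                    description=seq_rec.description,
                    sequence=str(seq_rec.seq),
                )
            )
        except ValidationError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_cds_fasta(records: Iterable[CDSRecord], path: str | Path,
                    width: int = 70) -> None:
    with open(path, "w") as out:
        for rec in records:
            header = rec.id
            if rec.description and rec.description != rec.id:
                header = rec.description
            out.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                out.write(rec.sequence[i:i + width] + "\n")


def codon_counts(
    record: CDSRecord,
    code: GeneticCode = STANDARD_CODE,
    frame_policy: FramePolicy = "strict",
) -> CodonCountTable:
    """Split a CDS into consecutive triplets from position 0 and count them.

    Triplets containing N are skipped (counted in ``n_skipped``).  Internal
    stop codons are counted but logged as a warning.  Under the default
    ``strict`` policy a length not divisible by 3 is an error; ``trim``
    drops trailing 1-2 nt with a warning.
    """
    seq = record.sequence
    rem = len(seq) % 3
    if rem:
        if frame_policy == "strict":
            raise ValidationError(
                f"record {record.id!r}: length {len(seq)} is not a multiple of 3 "
                "(use frame_policy='trim' to drop trailing bases)"
            )
        logger.warning("record %s: trimming %d trailing nt", record.id, rem)
        seq = seq[: len(seq) - rem]

    counts = {c: 0 for c in CANONICAL_CODON_ORDER}
    n_skipped = 0
    n_codons = 0
    n_triplets = len(seq) // 3
    for i in range(n_triplets):
        codon = seq[3 * i: 3 * i + 3]
        if "N" in codon:
            n_skipped += 1
            continue
        if code.is_stop(codon) and i < n_triplets - 1:
            logger.warning(
                "record %s: internal stop codon %s at codon %d",
                record.id, to_rna(codon), i + 1,
            )
        counts[codon] += 1
        n_codons += 1
    return CodonCountTable(record.id, counts, n_codons, n_skipped)


def write_codon_counts(tables: Iterable[CodonCountTable], path: str | Path,
                       code: GeneticCode = STANDARD_CODE) -> None:
    df = pd.concat([t.to_dataframe(code) for t in tables], ignore_index=True)
    df.to_csv(path, sep="\t", index=False)
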