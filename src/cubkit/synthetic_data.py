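"""Synthetic CDS generation with controlled codon-usage structure.

The per-site model: an amino acid is drawn from ``aa_freqs``; its codon is
drawn within the synonymous family with probability proportional to
``m(c) * exp(s * 1[c in optimal_set])``, where the mutational factor
``m(c)`` puts total weight theta on the G/C-ending synonyms and
``1 - theta`` on the A/T-ending synonyms, split uniformly within each
class (families lacking one class fall back to uniform weights).  With
``s = 0`` this makes the empirical GC3s converge to theta, tying the
generator's no-selection limit to the expected-ENC reference curve.

Seeds are mandatory: identical spec + seed gives byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .codonio import CDSRecord, GeneticCode, STANDARD_CODE
from .clustering_phylo import TreeNode
from .cub_indices import OptimalCodonSet
from .errors import ValidationError

_BASES = np.array([b"A", b"C", b"G", b"T"], dtype="S1")


@dataclass(frozen=True)
class SyntheticSpec:
    n_genes: int
    n_codons: int
    seed: int
    aa_freqs: Optional[dict[str, float]] = None  # default: uniform over 20 AAs
    gc3_pressure: float = 0.5
    selection_strength: float = 0.0
    optimal_set: Optional[OptimalCodonSet] = None

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_codons < 1:
            raise ValidationError("n_genes and n_codons must be >= 1")
        if not 0.0 <= self.gc3_pressure <= 1.0:
            raise ValidationError("gc3_pressure must be in [0, 1]")
        if self.selection_strength < 0:
            raise ValidationError("selection_strength must be >= 0")
        if self.aa_freqs is not None:
            total = sum(self.aa_freqs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValidationError(f"aa_freqs sums to {total}, expected 1")
            if any(v < 0 for v in self.aa_freqs.values()):
                raise ValidationError("aa_freqs must be non-negative")


@dataclass(frozen=True)
class DivergenceSpec:
    n_species: int
    substitution_prob: float
    seed: int
    topology: Optional[TreeNode] = None

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValidationError("n_species must be >= 2")
        if not 0.0 <= self.substitution_prob < 1.0:
            raise ValidationError("substitution_prob must be in [0, 1)")


def _codon_probs(
    spec: SyntheticSpec, code: GeneticCode
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per amino acid: (codon array, sampling probabilities)."""
    theta = spec.gc3_pressure
    s = spec.selection_strength
    optimal = spec.optimal_set.codons if spec.optimal_set else frozenset()
    out = {}
    for aa in code.amino_acids():
        fam = code.family_of[aa]
        gc_class = [c for c in fam if c[2] in "GC"]
        at_class = [c for c in fam if c[2] in "AT"]
        weights = []
        for c in fam:
            if gc_class and at_class:
                w = theta / len(gc_class) if c in gc_class else (1 - theta) / len(at_class)
            else:
                w = 1.0 / len(fam)
            if c in optimal:
                w *= np.exp(s)
            weights.append(w)
        w = np.asarray(weights)
        total = w.sum()
        if total <= 0:
            # theta at an extreme and the family has only the excluded class
            w = np.full(len(fam), 1.0 / len(fam))
            total = 1.0
        out[aa] = (np.array(fam), w / total)
    return out


def generate_cds(
    spec: SyntheticSpec, code: GeneticCode = STANDARD_CODE
) -> list[CDSRecord]:
    """Generate ``n_genes`` coding sequences of ``n_codons`` body codons,
    plus a prepended ATG start and an appended stop codon."""
    rng = np.random.default_rng(spec.seed)
    aas = code.amino_acids()
    if spec.aa_freqs is None:
        aa_p = np.full(len(aas), 1.0 / len(aas))
    else:
        unknown = set(spec.aa_freqs) - set(aas)
        if unknown:
            raise ValidationError(f"unknown amino acids in aa_freqs: {sorted(unknown)}")
        aa_p = np.array([spec.aa_freqs.get(aa, 0.0) for aa in aas])
    codon_probs = _codon_probs(spec, code)
    stops = np.array(code.stop_codons)

    records = []
    for g in range(spec.n_genes):
        aa_idx = rng.choice(len(aas), size=spec.n_codons, p=aa_p)
        codons = np.empty(spec.n_codons, dtype="<U3")
        for k, aa in enumerate(aas):  # fixed iteration order keeps this deterministic
            mask = aa_idx == k
            cnt = int(mask.sum())
            if cnt:
                fam, p = codon_probs[aa]
                codons[mask] = rng.choice(fam, size=cnt, p=p)
        stop = rng.choice(stops)
        seq = "ATG" + "".join(codons) + str(stop)
        records.append(
            CDSRecord(
                id=f"gene{g + 1}",
                description=(
                    f"gene{g + 1} synthetic theta={spec.gc3_pressure} "
                    f"s={spec.selection_strength} seed={spec.seed}"
                ),
                sequence=seq,
            )
        )
    return records


def _mutate(sequence: str, prob: float, rng: np.random.Generator) -> str:
    """Substitute each site with probability ``prob`` (uniform among the
    other three bases); no indels, so the reading frame is preserved."""
    if prob == 0.0:
        return sequence
    arr = np.frombuffer(sequence.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(arr.size) < prob)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def _star_topology(n_species: int) -> TreeNode:
    root = TreeNode()
    for i in range(n_species):
        root.children.append((TreeNode(label=f"sp{i + 1}"), float("nan")))
    return root


def generate_species_set(
    spec: SyntheticSpec,
    div: DivergenceSpec,
    code: GeneticCode = STANDARD_CODE,
) -> list[CDSRecord]:
    """One ancestral CDS evolved along a topology (star by default).

    Per branch, each site mutates with the branch's substitution
    probability: the topology's branch length when given (and finite),
    otherwise ``div.substitution_prob``.  Equal lengths are guaranteed.
    """
    ancestor = generate_cds(replace(spec, n_genes=1), code)[0]
    topology = div.topology if div.topology is not None else _star_topology(div.n_species)
    n_leaves = len(topology.leaf_labels())
    if div.topology is not None and n_leaves != div.n_species:
        raise ValidationError(
            f"topology has {n_leaves} leaves but n_species={div.n_species}"
        )
    rng = np.random.default_rng(div.seed)
    records: list[CDSRecord] = []

    def walk(node: TreeNode, seq: str) -> None:
        for child, length in node.children:
            prob = length if length is not None and np.isfinite(length) else div.substitution_prob
            if not 0.0 <= prob < 1.0:
                raise ValidationError(f"branch substitution probability {prob} out of [0, 1)")
            child_seq = _mutate(seq, prob, rng)
            if child.is_leaf():
                records.append(
                    CDSRecord(
                        id=child.label,
                        description=f"{child.label} descendant of {ancestor.id}",
                        sequence=child_seq,
                    )
                )
            else:
                walk(child, child_seq)

    walk(topology, ancestor.sequence)
    return records
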