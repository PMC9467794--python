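"""Inference about the forces shaping codon usage.

Covers the expected-ENC reference curve and point classification, parity
rule 2 (PR2) coordinates, the GC12~GC3s neutrality analysis, and
per-codon RSCU~GC3s correlation matrices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .codonio import CodonCountTable, GeneticCode, STANDARD_CODE, to_rna
from .cub_indices import RSCUTable
from .errors import UndefinedStatisticError, ValidationError

PR2Mode = Literal["fourfold", "all3"]

#: Classification tolerance for on-curve points.
ON_CURVE_TOL = 1e-9


def expected_enc(gc3s: float) -> float:
    """Expected ENC under mutation only: ``2 + s + 29 / (s^2 + (1-s)^2)``."""
    if not 0.0 <= gc3s <= 1.0:
        raise ValidationError(f"gc3s must be in [0, 1], got {gc3s}")
    s = gc3s
    return 2.0 + s + 29.0 / (s * s + (1.0 - s) ** 2)


@dataclass(frozen=True)
class PR2Point:
    gene_id: str
    x: float  # G3 / (G3 + C3)
    y: float  # A3 / (A3 + T3)
    mode: PR2Mode


def fourfold_codons(code: GeneticCode = STANDARD_CODE) -> tuple[str, ...]:
    """Codons at fourfold-degenerate sites: all four codons sharing the
    first two bases encode the same amino acid (includes the fourfold
    halves of the Leu/Ser/Arg six-codon families)."""
    out = []
    for codon in code.sense_codons:
        quartet = [codon[:2] + b for b in "TCAG"]
        aas = {code.codon_to_aa[q] for q in quartet}
        if len(aas) == 1:
            out.append(codon)
    return tuple(out)


def pr2_point(
    counts: CodonCountTable,
    code: GeneticCode = STANDARD_CODE,
    mode: PR2Mode = "fourfold",
) -> PR2Point:
    """PR2 coordinates from third-position base tallies.

    Uses fourfold-degenerate sites by default; ``all3`` widens the tally
    to every synonymous codon.
    """
    if mode == "fourfold":
        universe = fourfold_codons(code)
    else:
        universe = code.synonymous_codons()
    third = {"T": 0, "C": 0, "A": 0, "G": 0}
    for codon in universe:
        third[codon[2]] += counts.counts[codon]
    if third["G"] + third["C"] == 0:
        raise UndefinedStatisticError(
            f"{counts.gene_id}: PR2 x-coordinate undefined (G3 + C3 = 0)"
        )
    if third["A"] + third["T"] == 0:
        raise UndefinedStatisticError(
            f"{counts.gene_id}: PR2 y-coordinate undefined (A3 + T3 = 0)"
        )
    return PR2Point(
        gene_id=counts.gene_id,
        x=third["G"] / (third["G"] + third["C"]),
        y=third["A"] / (third["A"] + third["T"]),
        mode=mode,
    )


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_two_sided: float
    n: int
    slope: float
    intercept: float

    def to_dict(self) -> dict:
        return {
            "r": self.r, "p_two_sided": self.p_two_sided, "n": self.n,
            "slope": self.slope, "intercept": self.intercept,
        }


def pearson(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson correlation with a two-sided t-test p-value (n-2 df) and the
    OLS slope/intercept of y on x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValidationError(f"need n >= 3 pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("correlation undefined for constant input")
    r, p = stats.pearsonr(x, y)
    reg = stats.linregress(x, y)
    return CorrelationResult(
        r=float(r), p_two_sided=float(p), n=int(n),
        slope=float(reg.slope), intercept=float(reg.intercept),
    )


def neutrality_analysis(
    gc12_values: Sequence[float], gc3s_values: Sequence[float]
) -> CorrelationResult:
    """Regression/correlation of GC12 on GC3s across genes.

    A strong correlation implicates mutational pressure; a weak one
    implicates selection.
    """
    return pearson(gc3s_values, gc12_values)


@dataclass(frozen=True)
class ENCPlotPoint:
    gene_id: str
    gc3s: float
    enc: float
    expected: float
    position: Literal["below", "above", "on"]


@dataclass(frozen=True)
class ENCPlotResult:
    points: tuple[ENCPlotPoint, ...]
    curve: tuple[tuple[float, float], ...]  # (gc3s, expected_enc) samples

    def points_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": p.gene_id, "gc3s": p.gc3s, "enc": p.enc,
                "expected_enc": p.expected, "position": p.position,
            }
            for p in self.points
        )

    def curve_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.curve, columns=["gc3s", "expected_enc"])


def classify_enc_point(gc3s: float, enc: float) -> ENCPlotPoint:
    exp = expected_enc(gc3s)
    delta = enc - exp
    if abs(delta) <= ON_CURVE_TOL:
        position = "on"
    elif delta < 0:
        position = "below"
    else:
        position = "above"
    return ENCPlotPoint("", gc3s, enc, exp, position)


def enc_plot(
    profiles: Sequence[tuple[str, float, float]],
    curve_step: float = 0.01,
) -> ENCPlotResult:
    """Classify (gene_id, gc3s, enc) points against the expected-ENC curve
    and sample the reference curve for plotting."""
    points = []
    for gene_id, gc3s, enc_value in profiles:
        p = classify_enc_point(gc3s, enc_value)
        points.append(ENCPlotPoint(gene_id, p.gc3s, p.enc, p.expected, p.position))
    grid = np.arange(0.0, 1.0 + curve_step / 2, curve_step)
    curve = tuple((float(s), expected_enc(float(s))) for s in grid)
    return ENCPlotResult(points=tuple(points), curve=curve)


def codon_gc3s_correlations(
    rscu_tables: Sequence[RSCUTable],
    gc3s_values: Sequence[float],
    code: GeneticCode = STANDARD_CODE,
) -> pd.DataFrame:
    """Per sense codon, the Pearson correlation of its RSCU across gene sets
    against GC3s.  Codons with fewer than 3 defined pairs or zero variance
    get a missing entry with a reason, never an error.
    """
    if len(rscu_tables) != len(gc3s_values):
        raise ValidationError("one RSCU table per gc3s value required")
    if len(rscu_tables) < 3:
        raise ValidationError("need at least 3 gene sets")
    gc3s_values = [float(v) for v in gc3s_values]
    rows = []
    for codon in code.sense_codons:
        rna = to_rna(codon)
        pairs = [
            (g, t.rscu_of(rna))
            for g, t in zip(gc3s_values, rscu_tables)
            if t.rscu_of(rna) is not None
        ]
        entry = {
            "codon": rna,
            "amino_acid": code.codon_to_aa[codon],
            "r": np.nan, "p_two_sided": np.nan,
            "n": len(pairs), "reason": "",
        }
        if len(pairs) < 3:
            entry["reason"] = "n<3"
        else:
            xs = [p[0] for p in pairs]
            ys = [p[1] for p in pairs]
            try:
                res = pearson(xs, ys)
            except UndefinedStatisticError:
                entry["reason"] = "zero variance"
            else:
                entry["r"] = res.r
                entry["p_two_sided"] = res.p_two_sided
        rows.append(entry)
    return pd.DataFrame(rows)
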