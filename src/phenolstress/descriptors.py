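"""Formula-level molecular indices and phenolic classification.

Implements the van Krevelen elemental ratios, a double-bond-equivalent
variant that additionally subtracts the divalent heteroatoms
(DBE = 1 + C - O - S - (N + H)/2, reported alongside the textbook
DBE = 1 + C - H/2 + N/2), the modified aromaticity index

    AImod = (1 + C - O/2 - S - (N + H)/2) / (C - O/2 - N - S)

with the usual FT-MS convention AImod = 0 when the denominator is
non-positive or the numerator negative, the nominal oxidation state of
carbon (NOSC), the Gini-Simpson abundance diversity over formulas, and the
intensity-weighted phenolic summary statistics.

A formula counts as phenolic when 0.6 < H/C < 1.5, 0.3 < O/C < 0.85 and
AImod < 0.67 (all inequalities strict).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .formulas import AssignedPeak, Formula

__all__ = [
    "MolecularIndices",
    "DiversityResult",
    "PhenolicSummary",
    "elemental_ratios",
    "dbe",
    "dbe_standard",
    "aimod",
    "nosc",
    "is_phenolic",
    "abundance_diversity",
    "weighted_mean",
    "summarize_phenolics",
    "compute_indices",
]


@dataclass(frozen=True)
class MolecularIndices:
    oc: float
    hc: float
    nc: float
    sc: float
    dbe: float
    dbe_standard: float
    aimod: float
    nosc: float


@dataclass(frozen=True)
class DiversityResult:
    """Gini-Simpson abundance diversity: DA = 1 - sum(p_i^2)."""

    da: float
    n_formulas: int


@dataclass
class PhenolicSummary:
    rel_intensity_pct: float
    n_phenolics: int
    mz_wa: float
    weighted: MolecularIndices | None
    da: DiversityResult


def elemental_ratios(f: Formula) -> tuple[float, float, float, float]:
    """(O/C, H/C, N/C, S/C); requires at least one carbon."""
    if f.c < 1:
        raise ValueError("elemental ratios undefined for a carbon-free formula")
    return (f.o / f.c, f.h / f.c, f.n / f.c, f.s / f.c)


def dbe(f: Formula) -> float:
    """Heteroatom-subtracting double-bond equivalent:
    1 + C - O - S - (N + H)/2. May be negative."""
    return 1.0 + f.c - f.o - f.s - 0.5 * (f.n + f.h)


def dbe_standard(f: Formula) -> float:
    """Textbook rings-plus-double-bonds: 1 + C - H/2 + N/2."""
    return 1.0 + f.c - 0.5 * f.h + 0.5 * f.n


def aimod(f: Formula) -> float:
    """Modified aromaticity index; 0 when denominator <= 0 or numerator < 0."""
    num = 1.0 + f.c - 0.5 * f.o - f.s - 0.5 * (f.n + f.h)
    den = f.c - 0.5 * f.o - f.n - f.s
    if den <= 0 or num < 0:
        return 0.0
    return num / den


def nosc(f: Formula) -> float:
    """Nominal oxidation state of carbon: 4 - (4C + H - 3N - 2O - 2S)/C."""
    if f.c < 1:
        raise ValueError("NOSC undefined for a carbon-free formula")
    return 4.0 - (4.0 * f.c + f.h - 3.0 * f.n - 2.0 * f.o - 2.0 * f.s) / f.c


def is_phenolic(f: Formula) -> bool:
    """Van Krevelen + aromaticity definition of a phenolic formula
    (0.6 < H/C < 1.5, 0.3 < O/C < 0.85, AImod < 0.67; strict bounds)."""
    if f.c < 1:
        return False
    oc, hc = f.o / f.c, f.h / f.c
    return 0.6 < hc < 1.5 and 0.3 < oc < 0.85 and aimod(f) < 0.67


def compute_indices(f: Formula) -> MolecularIndices:
    oc, hc, nc, sc = elemental_ratios(f)
    return MolecularIndices(oc=oc, hc=hc, nc=nc, sc=sc, dbe=dbe(f),
                            dbe_standard=dbe_standard(f), aimod=aimod(f), nosc=nosc(f))


def abundance_diversity(intensities: Sequence[float]) -> DiversityResult:
    """Gini-Simpson diversity of sum-normalized intensities.

    DA = 1 - sum p_i^2 with p_i = I_i / sum(I); ranges from 0 (one formula)
    to 1 - 1/N (N equally abundant formulas).
    """
    x = np.asarray(intensities, dtype=float)
    if x.size == 0:
        raise ValueError("abundance_diversity needs at least one intensity")
    if (x < 0).any() or not np.isfinite(x).all():
        raise ValueError("intensities must be finite and non-negative")
    total = x.sum()
    if total <= 0:
        raise ValueError("abundance_diversity needs positive total intensity")
    p = x / total
    return DiversityResult(da=float(1.0 - np.sum(p * p)), n_formulas=int(x.size))


def weighted_mean(values: Sequence[float], weights: Sequence[float]) -> float:
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.shape != w.shape:
        raise ValueError("values and weights must have the same length")
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    tot = w.sum()
    if tot <= 0:
        raise ValueError("weighted_mean needs positive total weight")
    return float(np.dot(v, w) / tot)


def flag_phenolics(assigned: Sequence[AssignedPeak]) -> list[AssignedPeak]:
    """Set ``is_phenolic`` on each assigned peak (False when unassigned)."""
    for a in assigned:
        a.is_phenolic = a.formula is not None and is_phenolic(a.formula)
    return list(assigned)


def summarize_phenolics(assigned: Sequence[AssignedPeak]) -> PhenolicSummary:
    """Intensity-weighted summary of the phenolic subset of an assignment.

    ``rel_intensity_pct`` is the phenolic share of the TOTAL processed-list
    intensity (assigned or not). Weighted ratios, DBE, AImod and the weighted
    average m/z use peak intensities as weights; the diversity index is
    computed over distinct formulas with peak intensities summed per formula.
    """
    if not assigned:
        raise ValueError("summarize_phenolics needs at least one assigned peak")
    flag_phenolics(assigned)
    total = sum(a.intensity for a in assigned)
    phen = [a for a in assigned if a.is_phenolic]
    if not phen:
        return PhenolicSummary(rel_intensity_pct=0.0, n_phenolics=0,
                               mz_wa=math.nan, weighted=None,
                               da=DiversityResult(da=math.nan, n_formulas=0))
    w = np.array([a.intensity for a in phen])
    rel = 100.0 * w.sum() / total if total > 0 else math.nan

    per_formula: dict[Formula, float] = {}
    for a in phen:
        per_formula[a.formula] = per_formula.get(a.formula, 0.0) + a.intensity
    div = abundance_diversity(list(per_formula.values()))

    mz_wa = weighted_mean([a.mz for a in phen], w)
    idx = [compute_indices(a.formula) for a in phen]
    wmean = lambda attr: weighted_mean([getattr(i, attr) for i in idx], w)
    weighted = MolecularIndices(oc=wmean("oc"), hc=wmean("hc"), nc=wmean("nc"),
                                sc=wmean("sc"), dbe=wmean("dbe"),
                                dbe_standard=wmean("dbe_standard"),
                                aimod=wmean("aimod"), nosc=wmean("nosc"))
    return PhenolicSummary(rel_intensity_pct=float(rel), n_phenolics=len(per_formula),
                           mz_wa=mz_wa, weighted=weighted, da=div)
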