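"""Mass-difference transformation networks.

Every observed m/z is a node; an edge connects two nodes whose exact mass
difference matches the monoisotopic mass of a known biochemical
transformation (amino-acid residue, nucleobase, sugar or small functional
increment) within a tolerance. The default tolerance is +-2 ppm referenced
to the larger member m/z of the pair — instrumental mass error scales with
the measured m/z and both members carry it; an absolute milli-Dalton mode
is available instead (``tol_mode="mda"``).

Transformations are grouped by heteroatom content: sulfur-containing
(group 1), nitrogen only (2), nitrogen and oxygen (3), oxygen only (4),
otherwise ungrouped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .formulas import Formula, monoisotopic_mass, parse_formula

logger = logging.getLogger(__name__)

__all__ = [
    "Transformation",
    "TransformationEdge",
    "NetworkSummary",
    "default_transformations",
    "load_transformations",
    "write_transformations",
    "build_network",
    "summarize_network",
    "to_networkx",
    "write_network_tables",
]

UNGROUPED = 0
GROUP_NAMES = {1: "sulfur", 2: "nitrogen", 3: "nitrogen+oxygen", 4: "oxygen"}


@dataclass(frozen=True)
class Transformation:
    name: str
    exact_mass: float
    formula: Formula | None = None
    hetero_group: int = UNGROUPED

    def __post_init__(self) -> None:
        if self.exact_mass <= 0:
            raise ValueError(f"transformation {self.name!r}: exact_mass must be positive")


@dataclass(frozen=True)
class TransformationEdge:
    node_lo: float
    node_hi: float
    transformation: str
    delta_observed: float
    match_error_ppm: float


@dataclass
class NetworkSummary:
    n_nodes: int
    n_edges: int
    n_distinct_transformations: int
    abundance: dict[str, float]
    group_totals: dict[int, float]


def hetero_group_of(f: Formula | None) -> int:
    """Heteroatom group from element content: S -> 1; N only -> 2;
    N and O -> 3; O only -> 4; none -> ungrouped."""
    if f is None:
        return UNGROUPED
    if f.s > 0:
        return 1
    if f.n > 0 and f.o > 0:
        return 3
    if f.n > 0:
        return 2
    if f.o > 0:
        return 4
    return UNGROUPED


# Common biochemical building blocks: amino-acid residues (condensation
# increments), nucleobases, sugar residues, small functional-group and
# metabolite increments. Masses are computed from the formulas at import.
_DEFAULT_FORMULAS: list[tuple[str, str]] = [
    ("glycine residue", "C2H3NO"),
    ("alanine residue", "C3H5NO"),
    ("serine residue", "C3H5NO2"),
    ("proline residue", "C5H7NO"),
    ("valine residue", "C5H9NO"),
    ("threonine residue", "C4H7NO2"),
    ("cysteine residue", "C3H5NOS"),
    ("leucine/isoleucine residue", "C6H11NO"),
    ("asparagine residue", "C4H6N2O2"),
    ("aspartate residue", "C4H5NO3"),
    ("glutamine residue", "C5H8N2O2"),
    ("lysine residue", "C6H12N2O"),
    ("glutamate residue", "C5H7NO3"),
    ("methionine residue", "C5H9NOS"),
    ("histidine residue", "C6H7N3O"),
    ("phenylalanine residue", "C9H9NO"),
    ("arginine residue", "C6H12N4O"),
    ("tyrosine residue", "C9H9NO2"),
    ("tryptophan residue", "C11H10N2O"),
    ("adenine", "C5H5N5"),
    ("guanine", "C5H5N5O"),
    ("cytosine", "C4H5N3O"),
    ("uracil", "C4H4N2O2"),
    ("thymine", "C5H6N2O2"),
    ("hexose residue", "C6H10O5"),
    ("pentose residue", "C5H8O4"),
    ("deoxyhexose residue", "C6H10O4"),
    ("glucuronic acid residue", "C6H8O6"),
    ("methylation", "CH2"),
    ("ethylation", "C2H4"),
    ("hydroxylation", "O"),
    ("water loss/gain", "H2O"),
    ("ammonia loss/gain", "NH3"),
    ("formaldehyde", "CH2O"),
    ("carbon monoxide", "CO"),
    ("carbon dioxide", "CO2"),
    ("acetylation", "C2H2O"),
    ("malonyl", "C3H2O3"),
    ("sulfonation", "SO3"),
    ("thiol increment", "H2S"),
    ("glyoxylate", "C2H2O3"),
    ("allantoin", "C4H6N4O3"),
    ("urea", "CH4N2O"),
]


def default_transformations() -> list[Transformation]:
    """The package's built-in transformation table (user-replaceable)."""
    out = []
    for name, fs in _DEFAULT_FORMULAS:
        f = parse_formula(fs)
        out.append(Transformation(name=name, exact_mass=monoisotopic_mass(f),
                                  formula=f, hetero_group=hetero_group_of(f)))
    return out


def load_transformations(path: str | Path) -> list[Transformation]:
    """Load a transformation table (columns: name, exact_mass; optional
    formula, group).

    When a formula is given, the stated mass is cross-checked against the
    computed monoisotopic mass within 1 mDa and the heteroatom group derived
    from it unless a group column overrides. Duplicate names and non-positive
    masses are rejected.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    if df.empty:
        raise ValueError(f"{path}: empty transformation table")
    for col in ("name", "exact_mass"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    names = df["name"].astype(str).str.strip()
    if names.duplicated().any():
        dups = sorted(names[names.duplicated()].unique())
        raise ValueError(f"{path}: duplicate transformation names {dups}")
    out = []
    for i, row in df.iterrows():
        mass = float(row["exact_mass"])
        if mass <= 0:
            raise ValueError(f"{path} row {i}: non-positive mass {mass}")
        f = None
        if "formula" in df.columns and isinstance(row.get("formula"), str) and row["formula"].strip():
            f = parse_formula(row["formula"])
            calc = monoisotopic_mass(f)
            if abs(calc - mass) > 1e-3:
                raise ValueError(
                    f"{path} row {i} ({row['name']}): stated mass {mass} differs from "
                    f"formula mass {calc:.5f} by more than 1 mDa")
        group = int(row["group"]) if "group" in df.columns and pd.notna(row.get("group")) \
            else hetero_group_of(f)
        out.append(Transformation(name=str(row["name"]).strip(), exact_mass=mass,
                                  formula=f, hetero_group=group))
    return out


def write_transformations(transformations: Sequence[Transformation],
                          path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({
        "name": [t.name for t in transformations],
        "exact_mass": [t.exact_mass for t in transformations],
        "formula": [t.formula.hill() if t.formula else "" for t in transformations],
        "group": [t.hetero_group for t in transformations],
    }).to_csv(path, index=False)


def build_network(
    mzs: Sequence[float],
    transformations: Sequence[Transformation],
    tol_ppm: float = 2.0,
    tol_mode: str = "ppm",
    tol_mda: float = 0.5,
) -> tuple[list[float], list[TransformationEdge]]:
    """Connect every m/z pair whose difference matches a transformation mass.

    In ``"ppm"`` mode (default) the window is ``tol_ppm * 1e-6 * mz_hi``; in
    ``"mda"`` mode it is ``tol_mda`` milli-Daltons, absolute. All qualifying
    (pair, transformation) combinations become edges — a pair matching two
    transformations yields two parallel edges.
    """
    nodes = sorted(float(m) for m in set(mzs))
    if len(nodes) < 2:
        raise ValueError("build_network needs at least 2 distinct nodes")
    if not transformations:
        raise ValueError("build_network needs at least one transformation")
    if tol_mode not in ("ppm", "mda"):
        raise ValueError(f"unknown tol_mode {tol_mode!r}")
    logger.info("network tolerance mode: %s (%s)", tol_mode,
                f"{tol_ppm} ppm of larger m/z" if tol_mode == "ppm" else f"{tol_mda} mDa")
    arr = np.asarray(nodes)
    tmass = np.array([t.exact_mass for t in transformations])
    edges: list[TransformationEdge] = []
    for i in range(len(arr) - 1):
        lo = arr[i]
        hi = arr[i + 1:]
        delta = hi - lo                        # > 0, sorted ascending
        diff = np.abs(delta[:, None] - tmass[None, :])
        if tol_mode == "ppm":
            window = tol_ppm * 1e-6 * hi[:, None]
        else:
            window = tol_mda * 1e-3
        jj, kk = np.nonzero(diff <= window)
        for j, k in zip(jj, kk):
            t = transformations[k]
            edges.append(TransformationEdge(
                node_lo=lo, node_hi=float(hi[j]), transformation=t.name,
                delta_observed=float(delta[j]),
                match_error_ppm=float((delta[j] - t.exact_mass) / hi[j] * 1e6)))
    edges.sort(key=lambda e: (e.node_lo, e.node_hi, e.transformation))
    return nodes, edges


def summarize_network(edges: Sequence[TransformationEdge],
                      transformations: Sequence[Transformation],
                      n_nodes: int = 0) -> NetworkSummary:
    """Per-transformation relative edge abundance and heteroatom group totals."""
    group_of = {t.name: t.hetero_group for t in transformations}
    counts: dict[str, int] = {}
    for e in edges:
        counts[e.transformation] = counts.get(e.transformation, 0) + 1
    n = len(edges)
    abundance = {name: c / n for name, c in counts.items()} if n else {}
    group_totals = {g: 0.0 for g in (1, 2, 3, 4)}
    for name, ab in abundance.items():
        g = group_of.get(name, UNGROUPED)
        if g in group_totals:
            group_totals[g] += ab
    return NetworkSummary(n_nodes=n_nodes, n_edges=n,
                          n_distinct_transformations=len(counts),
                          abundance=abundance, group_totals=group_totals)


def to_networkx(nodes: Sequence[float],
                edges: Sequence[TransformationEdge]) -> nx.MultiGraph:
    g = nx.MultiGraph()
    g.add_nodes_from(f"{m:.5f}" for m in nodes)
    for e in edges:
        g.add_edge(f"{e.node_lo:.5f}", f"{e.node_hi:.5f}",
                   transformation=e.transformation, error_ppm=e.match_error_ppm)
    return g


def write_network_tables(nodes: Sequence[float],
                         edges: Sequence[TransformationEdge],
                         prefix: str | Path) -> tuple[Path, Path]:
    """Write graph-viewer-importable node and edge tables; returns the paths."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    node_path = prefix.with_name(prefix.name + "_nodes.csv")
    edge_path = prefix.with_name(prefix.name + "_edges.csv")
    pd.DataFrame({"id": [f"{m:.5f}" for m in nodes], "mz": list(nodes)}).to_csv(
        node_path, index=False)
    pd.DataFrame({
        "source": [f"{e.node_lo:.5f}" for e in edges],
        "target": [f"{e.node_hi:.5f}" for e in edges],
        "transformation": [e.transformation for e in edges],
        "delta_observed": [e.delta_observed for e in edges],
        "error_ppm": [e.match_error_ppm for e in edges],
    }).to_csv(edge_path, index=False)
    return node_path, edge_path
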