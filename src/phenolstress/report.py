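"""Pipeline orchestration and between-treatment statistics.

Runs the full processing chain per treatment group — quality filter, blank
subtraction, technical-replicate consensus, fraction merge, formula
assignment, phenolic classification, summary statistics and the
mass-difference network — then compares groups with a Shapiro-Wilk
normality screen followed by pairwise two-sided Wilcoxon rank-sum tests
(exact null distribution at small n) and a compact letter display at
alpha = 0.05.

With only two or three biological replicates per group the exact rank-sum
test has almost no power (the smallest attainable two-sided p at n = 2 vs 2
is 1/3); letters are still reported but a warning is logged.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import descriptors, formulas, network as net
from .peaklist import (PeakList, filter_quality, merge_fractions, read_peaklist,
                       replicate_consensus, subtract_blank)

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineParams",
    "TreatmentComparison",
    "compare_groups",
    "compact_letters",
    "process_sample",
    "process_experiment",
    "run_pipeline",
    "load_config",
]

ALPHA = 0.05

_small_n_warned: set[tuple[str, int]] = set()


@dataclass
class PipelineParams:
    """All tunable tolerances of the processing chain."""

    snr_min: float = 4.0
    rel_intensity_min_pct: float = 0.1
    blank_tol_ppm: float = 5.0
    replicate_tol_ppm: float = 5.0
    fraction_tol_ppm: float = 5.0
    assign_tol_ppm: float = 10.0
    bounds: formulas.ElementBounds = field(default_factory=formulas.ElementBounds)
    network_tol_ppm: float = 2.0
    network_tol_mode: str = "ppm"
    network_tol_mda: float = 0.5


@dataclass
class TreatmentComparison:
    metric: str
    group_values: dict[str, list[float]]
    normality_p: dict[str, float]
    pairwise_p: dict[tuple[str, str], float]
    letters: dict[str, str]
    alpha: float = ALPHA


def compact_letters(groups: Sequence[str],
                    significant: set[tuple[str, str]]) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Groups sharing a letter are not significantly different; every
    significant pair shares no letter.
    """
    sets: list[set[str]] = [set(groups)]
    for a, b in significant:
        nxt: list[set[str]] = []
        for s in sets:
            if a in s and b in s:
                nxt.extend((s - {a}, s - {b}))
            else:
                nxt.append(s)
        # absorb proper subsets and duplicates
        nxt.sort(key=len, reverse=True)
        sets = []
        for s in nxt:
            if s and not any(s <= u for u in sets):
                sets.append(s)
    order = {g: i for i, g in enumerate(groups)}
    sets.sort(key=lambda s: min(order[g] for g in s))
    letters = {g: "" for g in groups}
    for letter, s in zip("abcdefghijklmnopqrstuvwxyz", sets):
        for g in groups:
            if g in s:
                letters[g] += letter
    return letters


def compare_groups(values: Mapping[str, Sequence[float]], metric: str = "",
                   alpha: float = ALPHA, holm: bool = False) -> TreatmentComparison:
    """Shapiro-Wilk screen + pairwise exact Wilcoxon rank-sum + letters.

    ``holm=True`` applies a Holm step-down adjustment to the pairwise
    p-values before thresholding (off by default).
    """
    groups = list(values)
    if len(groups) < 2:
        raise ValueError("compare_groups needs at least 2 groups")
    arrs = {g: np.asarray(v, dtype=float) for g, v in values.items()}
    for g, a in arrs.items():
        if len(a) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values")
        if len(a) <= 3 and (g, len(a)) not in _small_n_warned:
            _small_n_warned.add((g, len(a)))
            logger.warning("group %s has n=%d; rank-sum tests at this size "
                           "cannot reach p < %.2g", g, len(a), alpha)
    normality = {}
    for g, a in arrs.items():
        normality[g] = float(stats.shapiro(a).pvalue) if len(a) >= 3 and np.ptp(a) > 0 \
            else float("nan")
    pairs = list(itertools.combinations(groups, 2))
    pvals = {}
    for a, b in pairs:
        x, y = arrs[a], arrs[b]
        method = "exact" if max(len(x), len(y)) <= 10 else "asymptotic"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        pvals[(a, b)] = float(res.pvalue)
    thresholds = dict(pvals)
    if holm:
        ordered = sorted(pairs, key=lambda p: pvals[p])
        m = len(ordered)
        adj_prev = 0.0
        for i, p in enumerate(ordered):
            adj = max(adj_prev, min(1.0, (m - i) * pvals[p]))
            thresholds[p] = adj_prev = adj
    significant = {p for p in pairs if thresholds[p] < alpha}
    letters = compact_letters(groups, significant)
    return TreatmentComparison(metric=metric,
                               group_values={g: list(arrs[g]) for g in groups},
                               normality_p=normality, pairwise_p=pvals,
                               letters=letters, alpha=alpha)


def process_sample(
    fractions: Mapping[str, Sequence[PeakList]],
    blank: PeakList,
    params: PipelineParams | None = None,
) -> tuple[list[formulas.AssignedPeak], PeakList, dict]:
    """Process one biological sample: per fraction filter each technical
    replicate, subtract the blank, take the replicate consensus; then merge
    fractions, assign formulas and flag phenolics.

    Returns (assigned peaks, merged peak list, stage-count log).
    """
    params = params or PipelineParams()
    counts: dict[str, dict[str, int]] = {}
    merged_fracs = []
    for fname, reps in fractions.items():
        stage = {"raw": sum(len(r) for r in reps)}
        reps = [filter_quality(r, params.snr_min, params.rel_intensity_min_pct)
                for r in reps]
        stage["filtered"] = sum(len(r) for r in reps)
        reps = [subtract_blank(r, blank, params.blank_tol_ppm) for r in reps]
        stage["blank_subtracted"] = sum(len(r) for r in reps)
        cons = replicate_consensus(reps, params.replicate_tol_ppm)
        stage["consensus"] = len(cons)
        counts[fname] = stage
        merged_fracs.append(cons)
    merged = merge_fractions(merged_fracs, params.fraction_tol_ppm)
    counts["merged"] = {"peaks": len(merged)}
    assigned = formulas.assign(merged, tol_ppm=params.assign_tol_ppm,
                               bounds=params.bounds)
    descriptors.flag_phenolics(assigned)
    counts["assigned"] = {
        "with_formula": sum(a.formula is not None for a in assigned),
        "phenolic": sum(a.is_phenolic for a in assigned),
    }
    for fname, stage in counts.items():
        logger.info("sample %s / %s: %s", blank.sample_id.replace("_blank", ""),
                    fname, stage)
    return assigned, merged, counts


def _summary_row(group: str, bio_id: str,
                 summary: descriptors.PhenolicSummary) -> dict:
    row = {"group": group, "sample": bio_id,
           "rel_intensity_pct": summary.rel_intensity_pct,
           "n_phenolics": summary.n_phenolics,
           "mz_wa": summary.mz_wa, "da": summary.da.da}
    w = summary.weighted
    for name in ("oc", "hc", "nc", "sc", "dbe", "dbe_standard", "aimod", "nosc"):
        row[f"w_{name}"] = getattr(w, name) if w is not None else float("nan")
    return row


METRICS = ["rel_intensity_pct", "n_phenolics", "mz_wa", "da",
           "w_oc", "w_hc", "w_nc", "w_sc", "w_dbe", "w_aimod"]


def process_experiment(
    experiment: Mapping,
    params: PipelineParams | None = None,
    transformations: Sequence[net.Transformation] | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Run the whole pipeline over a multi-group experiment (the structure
    produced by :func:`phenolstress.synthetic.simulate_experiment` or by
    :func:`run_pipeline`'s file loader).

    Returns per-sample phenolic summaries, per-group network summaries,
    per-sample assignments and the between-group comparisons; writes CSV
    tables when ``out_dir`` is given.
    """
    params = params or PipelineParams()
    transformations = list(transformations or net.default_transformations())
    rows = []
    assignments: dict[str, list[formulas.AssignedPeak]] = {}
    group_networks: dict[str, net.NetworkSummary] = {}
    network_tables: dict[str, tuple[list[float], list[net.TransformationEdge]]] = {}
    for group, bios in experiment["groups"].items():
        phen_lists = []
        for bio_id, rec in bios.items():
            assigned, merged, _ = process_sample(rec["fractions"], rec["blank"], params)
            assignments[bio_id] = assigned
            rows.append(_summary_row(group, bio_id,
                                     descriptors.summarize_phenolics(assigned)))
            phen = [a for a in assigned if a.is_phenolic]
            if phen:
                phen_lists.append(PeakList(peaks=pd.DataFrame({
                    "mz": [a.mz for a in phen],
                    "intensity": [a.intensity for a in phen],
                    "snr": [1.0] * len(phen)}), sample_id=bio_id))
        if phen_lists:
            pooled = merge_fractions(phen_lists, params.fraction_tol_ppm)
            if len(pooled) >= 2:
                nodes, edges = net.build_network(
                    pooled.mz, transformations, tol_ppm=params.network_tol_ppm,
                    tol_mode=params.network_tol_mode, tol_mda=params.network_tol_mda)
                group_networks[group] = net.summarize_network(
                    edges, transformations, n_nodes=len(nodes))
                network_tables[group] = (nodes, edges)
    summaries = pd.DataFrame(rows)
    comparisons = {}
    groups = list(experiment["groups"])
    if len(groups) >= 2 and all(
            (summaries["group"] == g).sum() >= 2 for g in groups):
        for metric in METRICS:
            vals = {g: summaries.loc[summaries["group"] == g, metric].tolist()
                    for g in groups}
            comparisons[metric] = compare_groups(vals, metric=metric)

    result = {"summaries": summaries, "networks": group_networks,
              "network_tables": network_tables, "assignments": assignments,
              "comparisons": comparisons}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        summaries.to_csv(out_dir / "phenolic_summaries.csv", index=False)
        for bio_id, assigned in assignments.items():
            formulas.assignments_to_frame(assigned).to_csv(
                out_dir / f"assignments_{bio_id}.csv", index=False)
        for group, (nodes, edges) in network_tables.items():
            net.write_network_tables(nodes, edges, out_dir / f"network_{group}")
        net_rows = []
        for group, ns in group_networks.items():
            row = {"group": group, "n_nodes": ns.n_nodes, "n_edges": ns.n_edges,
                   "n_distinct_transformations": ns.n_distinct_transformations}
            for g in (1, 2, 3, 4):
                row[f"group{g}_total"] = ns.group_totals[g]
            net_rows.append(row)
        pd.DataFrame(net_rows).to_csv(out_dir / "network_summaries.csv", index=False)
        comp_rows = []
        for metric, comp in comparisons.items():
            for g in groups:
                comp_rows.append({"metric": metric, "group": g,
                                  "mean": float(np.mean(comp.group_values[g])),
                                  "letter": comp.letters[g]})
        pd.DataFrame(comp_rows).to_csv(out_dir / "comparisons.csv", index=False)
    return result


def load_config(path: str | Path) -> dict:
    """Load a run-configuration YAML file (see the worked example in the
    README for the layout)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "groups" not in cfg:
        raise ValueError(f"{path}: config must define a 'groups' mapping")
    return cfg


def _params_from_config(cfg: Mapping) -> PipelineParams:
    p = PipelineParams()
    for key in ("snr_min", "rel_intensity_min_pct", "blank_tol_ppm",
                "replicate_tol_ppm", "fraction_tol_ppm", "assign_tol_ppm",
                "network_tol_ppm", "network_tol_mode", "network_tol_mda"):
        if key in cfg:
            setattr(p, key, cfg[key])
    if "bounds" in cfg:
        b = {el: tuple(v) for el, v in cfg["bounds"].items()}
        p.bounds = formulas.ElementBounds(**b)
    return p


def run_pipeline(config: Mapping | str | Path) -> dict:
    """File-driven entry point: load every peak list named in the config,
    then hand off to :func:`process_experiment`.

    Config layout (YAML)::

        output_dir: results/run1
        snr_min: 4
        groups:
          control:
            control_bio1:
              blank: data/control_bio1_blank.csv
              fractions:
                F1: [data/control_bio1_F1_rep1.csv, data/control_bio1_F1_rep2.csv]

    Any stage failure aborts with the offending stage and sample named.
    """
    if not isinstance(config, Mapping):
        config = load_config(config)
    params = _params_from_config(config)
    transformations = (net.load_transformations(config["transformations"])
                       if config.get("transformations") else None)
    experiment: dict = {"groups": {}}
    for group, samples in config["groups"].items():
        experiment["groups"][group] = {}
        for bio_id, rec in samples.items():
            try:
                blank = read_peaklist(rec["blank"], sample_id=f"{bio_id}_blank")
                fracs = {fname: [read_peaklist(p, treatment=group, fraction=fname)
                                 for p in paths]
                         for fname, paths in rec["fractions"].items()}
            except Exception as exc:
                raise RuntimeError(f"loading sample {bio_id!r} of group "
                                   f"{group!r} failed: {exc}") from exc
            experiment["groups"][group][bio_id] = {"fractions": fracs, "blank": blank}
    return process_experiment(experiment, params=params,
                              transformations=transformations,
                              out_dir=config.get("output_dir"))
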