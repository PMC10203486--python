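"""Peak-list I/O and spectral cleaning.

Mirrors the standard direct-infusion workflow: S/N and relative-intensity
filtering, blank subtraction, duplicate-replicate consensus and
chromatographic-fraction merging. A peak list is a small dataclass wrapping
a pandas DataFrame with columns ``mz``, ``intensity``, ``snr``, kept sorted
by m/z.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PeakList",
    "read_peaklist",
    "write_peaklist",
    "filter_quality",
    "subtract_blank",
    "replicate_consensus",
    "merge_fractions",
]

_COLUMNS = ["mz", "intensity", "snr"]


@dataclass
class PeakList:
    """An ordered peak list for one sample/replicate/fraction."""

    peaks: pd.DataFrame
    sample_id: str = ""
    treatment: str = ""
    fraction: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.peaks.columns]
        if missing:
            raise ValueError(f"peak table missing columns: {missing}")
        df = self.peaks.loc[:, _COLUMNS].astype(float)
        if (df["mz"] <= 0).any() or not np.isfinite(df.to_numpy()).all():
            raise ValueError("peaks must have positive m/z and finite values")
        if (df["intensity"] < 0).any() or (df["snr"] < 0).any():
            raise ValueError("intensity and snr must be non-negative")
        self.peaks = df.sort_values("mz", kind="stable").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def mz(self) -> np.ndarray:
        return self.peaks["mz"].to_numpy()

    @property
    def intensity(self) -> np.ndarray:
        return self.peaks["intensity"].to_numpy()


def _make(pl: PeakList, df: pd.DataFrame, **meta) -> PeakList:
    return PeakList(peaks=df.reset_index(drop=True),
                    sample_id=meta.get("sample_id", pl.sample_id),
                    treatment=meta.get("treatment", pl.treatment),
                    fraction=meta.get("fraction", pl.fraction))


def read_peaklist(path: str | Path, sample_id: str = "", **meta) -> PeakList:
    """Read a delimited peak list (columns mz, intensity, snr).

    Malformed (non-numeric) rows are dropped with their 1-based row numbers
    logged; an empty or header-only file is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    raw = df.loc[:, _COLUMNS]
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    if bad.any():
        rows = [int(i) + 2 for i in numeric.index[bad]]  # +2: header + 1-based
        logger.warning("%s: rejected %d malformed row(s) at file line(s) %s",
                       path.name, bad.sum(), rows)
    numeric = numeric.loc[~bad]
    if numeric.empty:
        raise ValueError(f"{path}: empty peak list")
    return PeakList(peaks=numeric, sample_id=sample_id or path.stem,
                    treatment=meta.get("treatment", ""), fraction=meta.get("fraction", ""))


def write_peaklist(pl: PeakList, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pl.peaks.to_csv(path, index=False)


def filter_quality(pl: PeakList, snr_min: float = 4.0,
                   rel_intensity_min_pct: float = 0.1) -> PeakList:
    """Keep peaks with S/N strictly above ``snr_min`` and relative intensity
    (percent of the base peak) at or above ``rel_intensity_min_pct``.

    The base peak is the most intense peak of this list; it always survives
    the relative-intensity rule by construction. Idempotent.
    """
    if len(pl) == 0:
        raise ValueError("cannot filter an empty peak list")
    df = pl.peaks
    base = df["intensity"].max()
    keep = (df["snr"] > snr_min) & (100.0 * df["intensity"] / base >= rel_intensity_min_pct)
    out = df.loc[keep]
    if out.empty:
        logger.warning("filter_quality removed every peak of %s", pl.sample_id)
    return _make(pl, out)


def _ppm_match_any(mz: np.ndarray, targets: np.ndarray, tol_ppm: float) -> np.ndarray:
    """Boolean mask: does each mz lie within tol_ppm (of itself) of any target."""
    if len(targets) == 0:
        return np.zeros(len(mz), dtype=bool)
    idx = np.searchsorted(targets, mz)
    mask = np.zeros(len(mz), dtype=bool)
    for off in (-1, 0):
        j = np.clip(idx + off, 0, len(targets) - 1)
        mask |= np.abs(mz - targets[j]) <= tol_ppm * 1e-6 * mz
    return mask


def subtract_blank(pl: PeakList, blank: PeakList, tol_ppm: float = 5.0) -> PeakList:
    """Remove every sample peak whose m/z matches a blank m/z within ``tol_ppm``."""
    mask = _ppm_match_any(pl.mz, blank.mz, tol_ppm)
    return _make(pl, pl.peaks.loc[~mask])


def _greedy_pairs(a: np.ndarray, b: np.ndarray, tol_ppm: float) -> list[tuple[int, int]]:
    """Greedy nearest-first one-to-one matching of two sorted m/z arrays.

    Candidate pairs within tolerance are taken smallest |delta| first, ties
    toward the lower-m/z pair; each peak used at most once.
    """
    cands = []
    j0 = 0
    for i, mza in enumerate(a):
        tol = tol_ppm * 1e-6 * mza
        while j0 < len(b) and b[j0] < mza - tol:
            j0 += 1
        j = j0
        while j < len(b) and b[j] <= mza + tol:
            if abs(b[j] - mza) <= tol_ppm * 1e-6 * max(mza, b[j]):
                cands.append((abs(b[j] - mza), mza, i, j))
            j += 1
    cands.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for _, _, i, j in cands:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((i, j))
    return sorted(pairs)


def replicate_consensus(replicates: Sequence[PeakList], tol_ppm: float = 5.0) -> PeakList:
    """Keep only peaks present in ALL replicates (matched within ``tol_ppm``).

    Consensus m/z is the intensity-weighted mean of the matched m/z values,
    consensus intensity the arithmetic mean (so replicate count does not
    inflate abundance) and consensus S/N the mean S/N.
    """
    if len(replicates) < 2:
        raise ValueError("replicate_consensus needs at least 2 replicates")
    acc = replicates[0].peaks.copy()
    acc["_n"] = 1.0
    acc["_mzw"] = acc["mz"] * acc["intensity"]
    acc["_wsum"] = acc["intensity"]
    acc["_isum"] = acc["intensity"]
    acc["_ssum"] = acc["snr"]
    for rep in replicates[1:]:
        pairs = _greedy_pairs(acc["mz"].to_numpy(), rep.mz, tol_ppm)
        if not pairs:
            acc = acc.iloc[0:0]
            break
        ia = [p[0] for p in pairs]
        ib = [p[1] for p in pairs]
        nxt = acc.iloc[ia].reset_index(drop=True)
        other = rep.peaks.iloc[ib].reset_index(drop=True)
        nxt["_n"] += 1.0
        nxt["_mzw"] += other["mz"] * other["intensity"]
        nxt["_wsum"] += other["intensity"]
        nxt["_isum"] += other["intensity"]
        nxt["_ssum"] += other["snr"]
        acc = nxt
    if len(acc):
        acc["mz"] = acc["_mzw"] / acc["_wsum"]
        acc["intensity"] = acc["_isum"] / acc["_n"]
        acc["snr"] = acc["_ssum"] / acc["_n"]
    out = acc.loc[:, _COLUMNS]
    return _make(replicates[0], out, sample_id=replicates[0].sample_id + "_consensus")


def merge_fractions(fractions: Sequence[PeakList], tol_ppm: float = 5.0) -> PeakList:
    """Union of fraction peak lists; peaks matching within ``tol_ppm`` are
    combined by intensity sum with an intensity-weighted mean m/z, so total
    intensity is conserved."""
    if not fractions:
        raise ValueError("merge_fractions needs at least one peak list")
    if len(fractions) == 1:
        return _make(fractions[0], fractions[0].peaks, fraction="merged")
    rows = pd.concat([f.peaks for f in fractions], ignore_index=True)
    rows = rows.sort_values("mz", kind="stable").reset_index(drop=True)
    mz = rows["mz"].to_numpy()
    # cluster consecutive peaks within tolerance of the running cluster head
    cluster = np.zeros(len(rows), dtype=int)
    cid = 0
    head = mz[0]
    for i in range(1, len(rows)):
        if mz[i] - head <= tol_ppm * 1e-6 * mz[i]:
            cluster[i] = cid
        else:
            cid += 1
            cluster[i] = cid
            head = mz[i]
    rows["_c"] = cluster
    grp = rows.groupby("_c")
    w = grp.apply(lambda g: np.average(g["mz"], weights=g["intensity"])
                  if g["intensity"].sum() > 0 else g["mz"].mean(), include_groups=False)
    out = pd.DataFrame({
        "mz": w.to_numpy(),
        "intensity": grp["intensity"].sum().to_numpy(),
        "snr": grp["snr"].max().to_numpy(),
    })
    return _make(fractions[0], out, fraction="merged")
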