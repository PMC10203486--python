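"""Ground-truth-known synthetic data for every pipeline stage.

The generator emulates the statistical structure of negative-mode
direct-infusion peak lists: [M-H]- ions of a CHNOS formula library over
m/z 100-1000, Gaussian ppm-scale mass error applied multiplicatively,
heavy-tailed (lognormal) intensities with replicate-to-replicate jitter,
contaminant peaks shared at identical m/z between samples and blank (so
blank subtraction is exactly testable), and S/N proportional to intensity
over a constant noise floor. Dose-response tables follow a decreasing
logistic viability curve with multiplicative noise.

Everything is seed-deterministic: same seed, bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import descriptors
from .dose_response import DoseResponseTable
from .formulas import (DEFAULT_BOUNDS, AssignedPeak, ElementBounds, Formula,
                       ion_mz, monoisotopic_mass)
from .peaklist import PeakList

__all__ = [
    "GroundTruth",
    "generate_formula_library",
    "make_ground_truth",
    "generate_peaklists",
    "generate_dose_response",
    "simulate_experiment",
    "assignment_accuracy",
    "truth_table",
]

MZ_MIN, MZ_MAX = 100.0, 1000.0


#: Fraction of the mass-error VARIANCE that is systematic (a calibration
#: residual shared by every acquisition of a batch) rather than
#: per-acquisition noise. TOF calibration drifts slowly; within one
#: measurement sequence most of the ppm error at a given m/z repeats.
PPM_SYSTEMATIC_FRAC = 0.7


@dataclass
class GroundTruth:
    """True formulas, intensities and contaminants behind a synthetic sample.

    The total mass-error scale ``ppm_sigma`` splits into a systematic
    per-peak offset (``ppm_offsets``, drawn once per batch and shared by all
    acquisitions) and a per-acquisition random part; see
    :data:`PPM_SYSTEMATIC_FRAC`.
    """

    formulas: list[Formula]
    true_intensities: np.ndarray
    noise_mz: np.ndarray
    seed: int
    ppm_sigma: float = 2.0
    replicate_cv: float = 0.1
    noise_floor: float = 0.4
    noise_intensities: np.ndarray = field(default=None)  # type: ignore[assignment]
    ppm_offsets: np.ndarray = field(default=None)  # type: ignore[assignment]
    ppm_systematic_frac: float = PPM_SYSTEMATIC_FRAC

    def __post_init__(self) -> None:
        self.true_intensities = np.asarray(self.true_intensities, dtype=float)
        self.noise_mz = np.asarray(self.noise_mz, dtype=float)
        if len(self.formulas) != len(self.true_intensities):
            raise ValueError("formulas and true_intensities must align")
        if (self.true_intensities <= 0).any():
            raise ValueError("true intensities must be positive")
        if self.noise_intensities is None:
            # half the contaminants sit below the S/N=4 line, half well above
            k = len(self.noise_mz)
            vals = np.where(np.arange(k) % 2 == 0, 2.0, 10.0) * self.noise_floor
            self.noise_intensities = vals
        self.noise_intensities = np.asarray(self.noise_intensities, dtype=float)
        if self.ppm_offsets is None:
            sys_sigma = self.ppm_sigma * math.sqrt(self.ppm_systematic_frac)
            rng = np.random.default_rng((self.seed, 0xCA1))
            self.ppm_offsets = rng.normal(0.0, sys_sigma, len(self.formulas)) \
                if sys_sigma > 0 else np.zeros(len(self.formulas))
        self.ppm_offsets = np.asarray(self.ppm_offsets, dtype=float)

    @property
    def ppm_sigma_random(self) -> float:
        return self.ppm_sigma * math.sqrt(1.0 - self.ppm_systematic_frac)

    @property
    def ion_mzs(self) -> np.ndarray:
        return np.array([ion_mz(f) for f in self.formulas])


def _mz_in_range(f: Formula) -> bool:
    return MZ_MIN <= ion_mz(f) <= MZ_MAX


def _sample_phenolic(rng: np.random.Generator, bounds: ElementBounds) -> Formula | None:
    # c capped at 25: keeps ion m/z below ~650, the range where typical
    # plant/algal phenolics (flavonoids, phenolic acids, small glycosides) sit
    c = int(rng.integers(max(bounds.c[0], 7), min(bounds.c[1], 25) + 1))
    # H/C in (0.6, 1.5) with H + N even; O/C in (0.3, 0.85); N2/S2
    # compositions are left out: they are mass-degenerate with common
    # CHO compositions at sub-mDa splits and thus unassignable in principle
    s = int(rng.choice([0] * 9 + [1])) if bounds.s[1] >= 1 else bounds.s[0]
    s = min(max(s, bounds.s[0]), bounds.s[1])
    # N and S together (and O beyond ~15) produce compositions that are
    # mass-degenerate with CHNO alternatives at sub-mDa splits
    n = 0 if s > 0 else int(rng.choice([0, 0, 0, 0, 0, 0, 0, 1, 1, 1]))
    n = min(max(n, bounds.n[0]), bounds.n[1])
    h_lo = math.floor(0.6 * c) + 1
    h_hi = math.ceil(1.5 * c) - 1
    hs = [h for h in range(max(h_lo, bounds.h[0]), min(h_hi, bounds.h[1]) + 1)
          if (h + n) % 2 == 0 and 0.6 < h / c < 1.5]
    o_lo = math.floor(0.3 * c) + 1
    o_hi = min(math.ceil(0.85 * c) - 1, 13 if s > 0 else 15)
    os_ = [o for o in range(max(o_lo, bounds.o[0]), min(o_hi, bounds.o[1]) + 1)
           if 0.3 < o / c < 0.85]
    if not hs or not os_:
        return None
    f = Formula(c=c, h=int(rng.choice(hs)), n=n, o=int(rng.choice(os_)), s=s)
    from .formulas import rdbe
    if (rdbe(f) < 0 or not descriptors.is_phenolic(f)
            or not bounds.contains(f) or not _mz_in_range(f)):
        return None
    return f


def _sample_any(rng: np.random.Generator, bounds: ElementBounds) -> Formula | None:
    # biochemically plausible co-extracted compositions: O at most ~0.9 C,
    # H between ~0.4 C and saturation, sulfur rare
    c = int(rng.integers(max(bounds.c[0], 5), min(bounds.c[1], 28) + 1))
    n = int(rng.choice([0, 0, 0, 0, 0, 0, 0, 1, 1, 1]))
    n = min(max(n, bounds.n[0]), bounds.n[1])
    s = int(rng.choice([0] * 9 + [1]))
    s = min(max(s, bounds.s[0]), bounds.s[1])
    h_max = min(bounds.h[1], 2 * c + n + 2)
    h_min = max(bounds.h[0], math.ceil(0.4 * c))
    if h_max < h_min:
        return None
    h = int(rng.integers(h_min, h_max + 1))
    if (h + n) % 2 != 0:
        h += 1 if h < h_max else -1
    if not (h_min <= h <= h_max):
        return None
    o_max = min(bounds.o[1], max(2, round(0.9 * c)), 12)
    if o_max < bounds.o[0]:
        return None
    o = int(rng.integers(bounds.o[0], o_max + 1))
    f = Formula(c=c, h=h, n=n, o=o, s=s)
    from .formulas import rdbe
    if rdbe(f) < 0 or not bounds.contains(f) or not _mz_in_range(f):
        return None
    return f


def generate_formula_library(
    n: int,
    phenolic_fraction: float = 0.45,
    bounds: ElementBounds = DEFAULT_BOUNDS,
    seed: int = 0,
    min_spacing_ppm: float = 12.0,
) -> list[Formula]:
    """Draw ``n`` distinct in-bounds CHNOS formulas with [M-H]- m/z in
    [100, 1000], of which ``round(n * phenolic_fraction)`` are phenolic by
    construction (the rest are rejected if phenolic, so the split is exact).

    Accepted formulas keep a minimum mutual ion-m/z spacing
    (``min_spacing_ppm``): two species closer than the duplicate-merge
    tolerance are unresolvable by definition, so a resolvable library
    never contains such a pair.

    Raises when the request is unsatisfiable under the given bounds.
    """
    import bisect

    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= phenolic_fraction <= 1.0:
        raise ValueError("phenolic_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_phen = round(n * phenolic_fraction)
    lib: list[Formula] = []
    seen: set[Formula] = set()
    mzs: list[float] = []

    def accept(f: Formula | None) -> bool:
        if f is None or f in seen:
            return False
        mz = ion_mz(f)
        i = bisect.bisect_left(mzs, mz)
        for j in (i - 1, i):
            if 0 <= j < len(mzs) and abs(mzs[j] - mz) <= min_spacing_ppm * 1e-6 * mz:
                return False
        seen.add(f)
        bisect.insort(mzs, mz)
        lib.append(f)
        return True

    budget = 400 * n + 20000
    tries = 0
    while len(lib) < n_phen:
        tries += 1
        if tries > budget:
            raise ValueError(
                "cannot generate the requested phenolic formulas under these bounds "
                "(phenolic definition may be unsatisfiable, e.g. oxygen excluded)")
        accept(_sample_phenolic(rng, bounds))
    tries = 0
    while len(lib) < n:
        tries += 1
        if tries > budget:
            raise ValueError("cannot generate the requested non-phenolic formulas "
                             "under these bounds")
        f = _sample_any(rng, bounds)
        if f is not None and not descriptors.is_phenolic(f):
            accept(f)
    return lib


def plant_phenolic_share(
    intensities: np.ndarray,
    phenolic_mask: np.ndarray,
    target_pct: float,
    min_intensity: float,
) -> np.ndarray:
    """Rescale phenolic intensities so they carry ``target_pct`` percent of
    the total, never letting a peak fall below ``min_intensity``.

    The floor is enforced by alternating rescale/clip passes; when the floor
    does not bind the planted share is exact, otherwise slightly above
    target (monotonically in ``target_pct``, so planted orderings survive).
    """
    target = target_pct / 100.0
    if not 0 < target < 1:
        raise ValueError("target_pct must be in (0, 100)")
    x = intensities.astype(float).copy()
    if not phenolic_mask.any() or phenolic_mask.all():
        raise ValueError("share planting needs both phenolic and non-phenolic formulas")
    for _ in range(8):
        s_p = x[phenolic_mask].sum()
        s_o = x[~phenolic_mask].sum()
        x[phenolic_mask] *= target / (1 - target) * s_o / s_p
        x[phenolic_mask] = np.maximum(x[phenolic_mask], min_intensity)
    return x


def make_ground_truth(
    n_formulas: int = 400,
    phenolic_fraction: float = 0.45,
    phenolic_intensity_fraction: float | None = None,
    n_noise: int = 20,
    seed: int = 0,
    ppm_sigma: float = 2.0,
    replicate_cv: float = 0.1,
    intensity_mu: float = 6.0,
    intensity_sigma: float = 1.0,
    phenolic_sigma: float = 0.35,
    noise_floor: float = 0.4,
    bounds: ElementBounds = DEFAULT_BOUNDS,
) -> GroundTruth:
    """Build a complete ground truth: formula library, lognormal intensities
    (optionally rescaled so phenolics carry ``phenolic_intensity_fraction``
    percent of the total signal) and contaminant m/z shared with the blank.

    Non-phenolic intensities are lognormal(``intensity_mu``,
    ``intensity_sigma``) with the upper tail capped at mu + 2 sigma
    (detector-saturation-like); phenolics use the narrower
    ``phenolic_sigma`` so a small planted share still clears the
    relative-intensity and S/N cut-offs peak by peak.
    """
    rng = np.random.default_rng(seed)
    lib = generate_formula_library(n_formulas, phenolic_fraction, bounds,
                                   seed=int(rng.integers(2**31)))
    phen = np.array([descriptors.is_phenolic(f) for f in lib])
    inten = rng.lognormal(mean=intensity_mu, sigma=intensity_sigma, size=n_formulas)
    cap = math.exp(intensity_mu + 2.0 * intensity_sigma)
    inten = np.minimum(inten, cap)
    if phen.any():
        inten[phen] = rng.lognormal(mean=intensity_mu, sigma=phenolic_sigma,
                                    size=int(phen.sum()))
    # stay above the S/N=4 line and 0.1%-of-base-peak cut-off with margin
    min_allowed = max(8.0 * noise_floor, 1.3e-3 * inten.max())
    inten = np.maximum(inten, min_allowed)
    if phenolic_intensity_fraction is not None:
        inten = plant_phenolic_share(inten, phen, phenolic_intensity_fraction,
                                     min_allowed)
    noise_mz = np.sort(rng.uniform(MZ_MIN, MZ_MAX, size=n_noise))
    return GroundTruth(formulas=lib, true_intensities=inten, noise_mz=noise_mz,
                       seed=seed, ppm_sigma=ppm_sigma, replicate_cv=replicate_cv,
                       noise_floor=noise_floor)


def generate_peaklists(
    truth: GroundTruth,
    n_replicates: int = 2,
    sample_id: str = "synthetic",
) -> tuple[list[PeakList], PeakList]:
    """Technical-replicate peak lists plus the matching blank.

    Each replicate holds every true formula as an [M-H]- peak with
    multiplicative Gaussian ppm mass error and lognormal intensity jitter
    (CV ``truth.replicate_cv``), plus the contaminant peaks at m/z identical
    across replicates and blank. S/N = intensity / noise floor.
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 technical replicates")
    rng = np.random.default_rng(truth.seed)
    theo = truth.ion_mzs
    sig = math.sqrt(math.log(1.0 + truth.replicate_cv**2))
    sigma_rand = truth.ppm_sigma_random
    reps = []
    for r in range(n_replicates):
        err_ppm = truth.ppm_offsets + rng.normal(0.0, sigma_rand, len(theo))
        mz_obs = theo * (1.0 + err_ppm * 1e-6)
        jitter = (np.exp(rng.normal(0.0, sig, len(theo)) - sig**2 / 2.0)
                  if sig > 0 else np.ones(len(theo)))
        inten = truth.true_intensities * jitter
        mz = np.concatenate([mz_obs, truth.noise_mz])
        intensity = np.concatenate([inten, truth.noise_intensities])
        df = pd.DataFrame({"mz": mz, "intensity": intensity,
                           "snr": intensity / truth.noise_floor})
        reps.append(PeakList(peaks=df, sample_id=f"{sample_id}_rep{r + 1}"))
    blank = PeakList(peaks=pd.DataFrame({
        "mz": truth.noise_mz,
        "intensity": truth.noise_intensities,
        "snr": truth.noise_intensities / truth.noise_floor,
    }), sample_id=f"{sample_id}_blank")
    return reps, blank


def generate_dose_response(
    ec50: float,
    hill: float = 2.0,
    top: float = 1.0e6,
    n_doses: int = 8,
    noise_cv: float = 0.05,
    seed: int = 0,
    n_replicates: int = 2,
    span_decades: tuple[float, float] = (-3.0, 1.5),
) -> DoseResponseTable:
    """Logistic viability table: count = top / (1 + (dose/EC50)^hill) with
    multiplicative lognormal noise, doses log-spaced around EC50 and each
    dose measured in duplicate by default (the exposure-assay design)."""
    if ec50 <= 0:
        raise ValueError("ec50 must be positive")
    if n_doses < 4:
        raise ValueError("need at least 4 doses")
    rng = np.random.default_rng(seed)
    doses = ec50 * np.logspace(span_decades[0], span_decades[1], n_doses)
    doses = np.tile(doses, n_replicates)
    mean = top / (1.0 + (doses / ec50) ** hill)
    if noise_cv > 0:
        sig = math.sqrt(math.log(1.0 + noise_cv**2))
        mean = mean * np.exp(rng.normal(0.0, sig, len(doses)) - sig**2 / 2.0)
    rep = np.repeat(np.arange(1, n_replicates + 1), n_doses)
    return DoseResponseTable(doses=doses, responses=mean, replicate=rep)


def truth_table(truth: GroundTruth) -> pd.DataFrame:
    """Ground-truth table: theoretical ion m/z, Hill formula, true intensity,
    phenolic flag."""
    return pd.DataFrame({
        "mz_theoretical": truth.ion_mzs,
        "formula": [f.hill() for f in truth.formulas],
        "intensity_true": truth.true_intensities,
        "is_phenolic": [descriptors.is_phenolic(f) for f in truth.formulas],
    }).sort_values("mz_theoretical").reset_index(drop=True)


def assignment_accuracy(truth: GroundTruth, assigned: Sequence[AssignedPeak],
                        match_tol_ppm: float = 15.0) -> tuple[int, int]:
    """(n_correct, n_matched): of the assigned peaks that correspond to a true
    formula (nearest theoretical ion m/z within ``match_tol_ppm``), how many
    got exactly that formula."""
    theo = truth.ion_mzs
    order = np.argsort(theo)
    theo_sorted = theo[order]
    n_correct = n_matched = 0
    for a in assigned:
        j = int(np.searchsorted(theo_sorted, a.mz))
        best, best_d = None, np.inf
        for k in (j - 1, j):
            if 0 <= k < len(theo_sorted):
                d = abs(theo_sorted[k] - a.mz)
                if d < best_d:
                    best, best_d = k, d
        if best is None or best_d > match_tol_ppm * 1e-6 * a.mz:
            continue
        n_matched += 1
        if a.formula == truth.formulas[order[best]]:
            n_correct += 1
    return n_correct, n_matched


#: Planted phenolic intensity share (percent of total signal) per treatment.
DEFAULT_GROUP_FRACTIONS = {"control": 2.04, "Cd": 2.88, "Cu": 3.02, "Co": 2.95}
#: Biological replicates per treatment (triplicate control, duplicate metals).
DEFAULT_GROUP_SIZES = {"control": 3, "Cd": 2, "Cu": 2, "Co": 2}


def simulate_experiment(
    seed: int = 0,
    n_formulas: int = 400,
    phenolic_fraction: float = 0.45,
    group_fractions: dict[str, float] | None = None,
    group_sizes: dict[str, int] | None = None,
    n_fractions: int = 3,
    ppm_sigma: float = 2.0,
    replicate_cv: float = 0.05,
    n_noise: int = 20,
    out_dir: str | Path | None = None,
) -> dict:
    """Simulate the full multi-treatment study: a shared formula library,
    per-treatment planted phenolic intensity share (percent), biological
    replicates, chromatographic fractions (mass tertiles) each acquired as
    technical duplicates, and one shared blank.

    Returns a nested dict ``{group: {bio_id: {"fractions": {Fk: [PeakList x2]},
    "blank": PeakList, "truth": GroundTruth}}}`` plus the library metadata.
    When ``out_dir`` is given, every peak list, the blank and the ground-truth
    table are written as CSV.
    """
    group_fractions = dict(group_fractions or DEFAULT_GROUP_FRACTIONS)
    group_sizes = dict(group_sizes or DEFAULT_GROUP_SIZES)
    rng = np.random.default_rng(seed)
    base = make_ground_truth(n_formulas=n_formulas, phenolic_fraction=phenolic_fraction,
                             n_noise=n_noise, seed=int(rng.integers(2**31)),
                             ppm_sigma=ppm_sigma, replicate_cv=replicate_cv)
    phen = np.array([descriptors.is_phenolic(f) for f in base.formulas])
    masses = base.ion_mzs
    tertiles = np.quantile(masses, [1 / 3, 2 / 3])
    frac_of = np.digitize(masses, tertiles)          # 0,1,2 -> F1..F3
    frac_names = [f"F{k + 1}" for k in range(n_fractions)]

    min_allowed = max(8.0 * base.noise_floor, 1.3e-3 * base.true_intensities.max())
    out: dict = {"groups": {}, "library": base, "planted": group_fractions,
                 "planted_actual": {}}
    for group, pct in group_fractions.items():
        inten = plant_phenolic_share(base.true_intensities, phen, pct, min_allowed)
        out["planted_actual"][group] = float(100.0 * inten[phen].sum() / inten.sum())
        out["groups"][group] = {}
        for b in range(group_sizes[group]):
            bio_seed = int(rng.integers(2**31))
            bio_rng = np.random.default_rng(bio_seed)
            sig = math.sqrt(math.log(1.0 + 0.02**2))
            bio_inten = inten * np.exp(bio_rng.normal(0.0, sig, len(inten)) - sig**2 / 2)
            bio_id = f"{group}_bio{b + 1}"
            rec = {"fractions": {}, "truth": None}
            frac_truths = {}
            for k, fname in enumerate(frac_names):
                idx = np.nonzero(frac_of == k)[0]
                t = GroundTruth(formulas=[base.formulas[i] for i in idx],
                                true_intensities=bio_inten[idx],
                                noise_mz=base.noise_mz,
                                seed=int(bio_rng.integers(2**31)),
                                ppm_sigma=ppm_sigma, replicate_cv=replicate_cv,
                                noise_floor=base.noise_floor,
                                noise_intensities=base.noise_intensities,
                                ppm_offsets=base.ppm_offsets[idx])
                reps, blank = generate_peaklists(t, n_replicates=2,
                                                 sample_id=f"{bio_id}_{fname}")
                for r in reps:
                    r.treatment, r.fraction = group, fname
                rec["fractions"][fname] = reps
                rec["blank"] = blank
                frac_truths[fname] = t
            rec["truth"] = GroundTruth(formulas=base.formulas,
                                       true_intensities=bio_inten,
                                       noise_mz=base.noise_mz, seed=bio_seed,
                                       ppm_sigma=ppm_sigma, replicate_cv=replicate_cv,
                                       noise_floor=base.noise_floor,
                                       noise_intensities=base.noise_intensities,
                                       ppm_offsets=base.ppm_offsets)
            out["groups"][group][bio_id] = rec

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        from .peaklist import write_peaklist
        truth_table(base).to_csv(out_dir / "ground_truth.csv", index=False)
        for group, bios in out["groups"].items():
            for bio_id, rec in bios.items():
                for fname, reps in rec["fractions"].items():
                    for r in reps:
                        write_peaklist(r, out_dir / f"{r.sample_id}.csv")
                write_peaklist(rec["blank"], out_dir / f"{bio_id}_blank.csv")
    return out
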