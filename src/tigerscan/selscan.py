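"""Windowed Hudson FST, branch-time transform, four-population mPBS scan.

Per site, Hudson's estimator accumulates a numerator
``N = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)`` and denominator
``D = p1(1-p2) + p2(1-p1)``; a window's FST is the ratio of sums
``sum(N)/sum(D)`` (not a mean of per-site ratios).  FST converts to a
divergence time ``T = -ln(1 - FST)`` (negative FST clamped to zero), and
for four populations a, b, c, d the metapopulation branch statistic is

    mPBS_a = [2 (T_ab + T_ac + T_ad) - (T_bc + T_bd + T_cd)] / 6,

the mean of the three classic three-population PBS values with focal a.
This form is symmetric in the non-focal labels and recovers the terminal
branch length when T is additive; a literal asymmetric variant
(``2 T_ab + T_ac + T_ad`` in the numerator) is available for comparison
via ``literal=True``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coalsim import DemographicModel, simulate_window, window_seed
from .variants import GenotypeMatrix, Window

__all__ = [
    "PairwiseFstRecord",
    "hudson_fst",
    "fst_to_time",
    "mpbs",
    "mpbs_track",
    "null_mpbs_distribution",
    "outlier_windows",
    "window_mpbs",
]

DEFAULT_MIN_SITES = 10


@dataclass
class PairwiseFstRecord:
    window: Window
    population_pair: tuple[str, str]
    fst: float | None  # None when denominator zero or too few sites
    n_sites: int


def _site_components(gm: GenotypeMatrix, pop1: str, pop2: str):
    """Per-site Hudson numerator/denominator and usability mask."""
    a1, n1 = gm.allele_counts(pop1)
    a2, n2 = gm.allele_counts(pop2)
    ok = (n1 >= 2) & (n2 >= 2)
    n1f = np.maximum(n1, 2).astype(float)
    n2f = np.maximum(n2, 2).astype(float)
    p1 = a1 / n1f
    p2 = a2 / n2f
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1f - 1) - p2 * (1 - p2) / (n2f - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    used = ok & (den > 0)  # sites monomorphic across both pops contribute 0/0
    num = np.where(used, num, 0.0)
    den = np.where(used, den, 0.0)
    return num, den, used


def hudson_fst(
    gm: GenotypeMatrix,
    pair: tuple[str, str],
    window: Window | None = None,
    min_sites: int = DEFAULT_MIN_SITES,
) -> PairwiseFstRecord:
    """Ratio-of-sums Hudson FST for one window (or all sites)."""
    num, den, used = _site_components(gm, pair[0], pair[1])
    if window is None:
        sl = slice(None)
        window = Window("*", 0, max(int(gm.positions[-1]) + 1, 1) if gm.n_sites else 1)
    else:
        sl = gm.window_slice(window)
    n_used = int(used[sl].sum())
    dsum = float(den[sl].sum())
    if n_used < min_sites or dsum == 0.0:
        return PairwiseFstRecord(window, tuple(pair), None, n_used)
    return PairwiseFstRecord(window, tuple(pair), float(num[sl].sum()) / dsum, n_used)


def fst_to_time(fst):
    """Branch time T = -ln(1 - FST); negative FST clamps to 0, FST=1 -> inf."""
    f = np.asarray(fst, dtype=float)
    f = np.maximum(f, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = -np.log1p(-f)
    return float(t) if np.isscalar(fst) or f.ndim == 0 else t


def mpbs(
    t_values: dict[tuple[str, str], float],
    focal: str,
    populations: list[str] | None = None,
    literal: bool = False,
) -> float:
    """Metapopulation branch statistic for the focal population.

    ``t_values`` maps unordered population pairs to branch times; exactly
    four populations must be involved.
    """
    if populations is None:
        populations = sorted({p for pair in t_values for p in pair})
    if len(populations) != 4:
        raise ValueError("mPBS is defined for exactly four populations")
    if focal not in populations:
        raise ValueError(f"unknown focal population {focal!r}")

    def tv(i, j):
        if (i, j) in t_values:
            return t_values[(i, j)]
        return t_values[(j, i)]

    others = [p for p in populations if p != focal]
    b, c, d = others
    cross = tv(b, c) + tv(b, d) + tv(c, d)
    if literal:
        # the asymmetric rendering: 2*T_ab + T_ac + T_ad with b the first
        # non-focal label in population order
        num = 2 * tv(focal, b) + tv(focal, c) + tv(focal, d) - cross
    else:
        num = 2 * (tv(focal, b) + tv(focal, c) + tv(focal, d)) - cross
    return num / 6.0


def window_mpbs(
    gm: GenotypeMatrix,
    populations: list[str],
    window: Window | None = None,
    min_sites: int = DEFAULT_MIN_SITES,
    literal: bool = False,
):
    """Six FST -> six T -> four mPBS for one window.

    Returns (mpbs dict per population or None, fst dict, t dict, n_sites
    dict); all-None mpbs marks a missing window.
    """
    if len(populations) != 4:
        raise ValueError("the scan requires exactly four populations")
    pairs = list(itertools.combinations(populations, 2))
    fsts: dict[tuple[str, str], float | None] = {}
    ts: dict[tuple[str, str], float] = {}
    n_sites: dict[tuple[str, str], int] = {}
    ok = True
    for pair in pairs:
        rec = hudson_fst(gm, pair, window, min_sites)
        fsts[pair] = rec.fst
        n_sites[pair] = rec.n_sites
        if rec.fst is None or rec.fst >= 1.0:
            ok = False
            ts[pair] = math.nan
        else:
            ts[pair] = fst_to_time(rec.fst)
    if not ok:
        return None, fsts, ts, n_sites
    values = {p: mpbs(ts, p, populations, literal=literal) for p in populations}
    return values, fsts, ts, n_sites


def mpbs_track(
    gm: GenotypeMatrix,
    populations: list[str],
    windows: list[Window],
    min_sites: int = DEFAULT_MIN_SITES,
    literal: bool = False,
) -> pd.DataFrame:
    """Per-window scan: one row per window with six FST, six T, four mPBS.

    Windows with any missing component carry NaN in every statistic column.
    Vectorized: per-site Hudson components are computed once and summed per
    window via prefix sums.
    """
    if len(populations) != 4:
        raise ValueError("the scan requires exactly four populations")
    pairs = list(itertools.combinations(populations, 2))
    comp = {}
    for pair in pairs:
        num, den, used = _site_components(gm, *pair)
        comp[pair] = (
            np.concatenate([[0.0], np.cumsum(num)]),
            np.concatenate([[0.0], np.cumsum(den)]),
            np.concatenate([[0], np.cumsum(used.astype(np.int64))]),
        )
    scaffold_offsets: dict[str, tuple[int, np.ndarray]] = {}
    for scaffold in gm.scaffolds:
        sc = gm.scaffold_slice(scaffold)
        scaffold_offsets[scaffold] = (sc.start, gm.positions[sc])

    rows = []
    for w in windows:
        off, pos = scaffold_offsets.get(w.scaffold, (0, np.empty(0, np.int64)))
        lo = off + int(np.searchsorted(pos, w.start, side="left"))
        hi = off + int(np.searchsorted(pos, w.end, side="left"))
        row: dict = {
            "scaffold": w.scaffold,
            "start": w.start,
            "end": w.end,
            "partial": w.partial,
        }
        ts = {}
        ok = True
        for pair in pairs:
            cnum, cden, cused = comp[pair]
            n_used = int(cused[hi] - cused[lo])
            dsum = float(cden[hi] - cden[lo])
            key = f"{pair[0]}_{pair[1]}"
            row[f"n_sites_{key}"] = n_used
            if n_used < min_sites or dsum == 0.0:
                row[f"fst_{key}"] = math.nan
                row[f"T_{key}"] = math.nan
                ok = False
                continue
            fst = float(cnum[hi] - cnum[lo]) / dsum
            row[f"fst_{key}"] = fst
            if fst >= 1.0:
                row[f"T_{key}"] = math.nan
                ok = False
            else:
                t = fst_to_time(fst)
                row[f"T_{key}"] = t
                ts[pair] = t
        for p in populations:
            row[f"mpbs_{p}"] = (
                mpbs(ts, p, populations, literal=literal) if ok else math.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)


def null_mpbs_distribution(
    model: DemographicModel,
    n_windows: int,
    window_length: int,
    seed: int,
    min_sites: int = DEFAULT_MIN_SITES,
    literal: bool = False,
) -> dict[str, np.ndarray]:
    """Neutral per-population mPBS null from simulated windows.

    Each simulated window is scored exactly as an observed window (six
    ratio-of-sums FST over the whole window, T transform, mPBS); windows
    with any missing component are dropped.  Returns sorted value arrays.
    """
    if n_windows < 1:
        raise ValueError("n_windows must be >= 1")
    populations = [s.name for s in model.sampled()]
    if len(populations) != 4:
        raise ValueError("the scan requires exactly four sampled populations")
    values: dict[str, list[float]] = {p: [] for p in populations}
    for k in range(n_windows):
        sub = int(window_seed(seed, k).generate_state(1)[0] % (2**31))
        sw = simulate_window(model, window_length, sub)
        v, _, _, _ = window_mpbs(sw.genotypes, populations, None, min_sites, literal)
        if v is not None:
            for p in populations:
                values[p].append(v[p])
    return {p: np.sort(np.asarray(v)) for p, v in values.items()}


def null_quantiles(
    null: dict[str, np.ndarray], qs=(0.5, 0.9, 0.99, 0.999)
) -> pd.DataFrame:
    rows = []
    for pop, vals in null.items():
        row = {"population": pop, "n": len(vals)}
        for q in qs:
            row[f"q{q}"] = float(np.quantile(vals, q)) if len(vals) else math.nan
        rows.append(row)
    return pd.DataFrame(rows)


def outlier_windows(
    track: pd.DataFrame, population: str, top_fraction: float = 0.001
) -> list[Window]:
    """Highest-mPBS windows for one population (ties at the cut included).

    Takes the ``ceil(top_fraction * n_nonmissing)`` top windows; windows
    with missing mPBS count in neither numerator nor denominator.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    col = f"mpbs_{population}"
    if col not in track.columns:
        raise KeyError(f"track has no column {col}")
    ok = track[~track[col].isna()]
    if len(ok) == 0:
        return []
    k = math.ceil(top_fraction * len(ok))
    vals = np.sort(ok[col].to_numpy())[::-1]
    threshold = vals[k - 1]
    hits = ok[ok[col] >= threshold]
    return [
        Window(r.scaffold, int(r.start), int(r.end), bool(r.partial))
        for r in hits.itertuples()
    ]
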