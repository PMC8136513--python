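"""SFS computation and desk-scale composite-likelihood demographic fitting.

The observed joint site-frequency spectrum (folded to minor-allele counts
by default, since no outgroup polarization is assumed) is compared with a
Monte-Carlo expected spectrum obtained from the package's own coalescent
simulator.  The composite log-likelihood treats polymorphic SFS cells as
multinomial: ``CL = sum_i m_i ln p_i`` with observed counts ``m`` and
expected cell probabilities ``p`` renormalized over polymorphic cells.
Fitting maximizes CL by Nelder-Mead over a small number of free
parameters, using common random numbers (the same per-window seeds at
every evaluation) so the objective is deterministic given the master seed.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy.optimize import minimize

from .coalsim import DemographicModel, simulate_window, window_seed
from .variants import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)

__all__ = [
    "FoldedSFS",
    "CompositeFitResult",
    "sfs_from_genotypes",
    "expected_sfs",
    "composite_log_likelihood",
    "fit_parameters",
    "years_to_generations",
    "generations_to_years",
]


@dataclass
class FoldedSFS:
    """Joint SFS over one or more populations.

    ``counts`` has shape ``(n_1+1, ..., n_k+1)`` with ``n_i`` sampled
    alleles in population i.  When ``folded``, cells are minor-allele
    representatives: each site's count vector c is replaced by
    ``min(c, n - c)`` in total-count order (lexicographic tiebreak at
    half).  Monomorphic corners are kept in ``counts`` but excluded from
    the polymorphic cells used for likelihoods.
    """

    populations: list[str]
    sample_alleles: tuple[int, ...]
    counts: np.ndarray
    n_sites_total: int
    folded: bool = True

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        expect = tuple(n + 1 for n in self.sample_alleles)
        if self.counts.shape != expect:
            raise ValueError(f"counts shape {self.counts.shape} != {expect}")

    def polymorphic_mask(self) -> np.ndarray:
        mask = np.ones(self.counts.shape, dtype=bool)
        mask[(0,) * self.counts.ndim] = False
        mask[tuple(self.sample_alleles)] = False
        return mask

    def polymorphic_counts(self) -> np.ndarray:
        return np.where(self.polymorphic_mask(), self.counts, 0)

    @property
    def n_polymorphic(self) -> int:
        return int(self.polymorphic_counts().sum())

    def marginal(self, population: str) -> np.ndarray:
        """Marginal (re-folded) spectrum of one population."""
        axis = self.populations.index(population)
        other = tuple(i for i in range(self.counts.ndim) if i != axis)
        marg = self.polymorphic_counts().sum(axis=other).astype(np.int64)
        if not self.folded:
            return marg
        n = self.sample_alleles[axis]
        out = np.zeros(n // 2 + 1, dtype=np.int64)
        for c, m in enumerate(marg):
            out[min(c, n - c)] += m
        return out


def _fold_cell(cell: tuple[int, ...], sizes: tuple[int, ...]) -> tuple[int, ...]:
    flipped = tuple(n - c for c, n in zip(cell, sizes))
    tot, ftot = sum(cell), sum(flipped)
    if tot < ftot:
        return cell
    if ftot < tot:
        return flipped
    return min(cell, flipped)


def sfs_from_genotypes(
    gm: GenotypeMatrix, populations: list[str] | None = None, folded: bool = True
) -> FoldedSFS:
    """Joint SFS from a complete genotype matrix.

    Sites with missing genotypes in any counted population are not allowed
    (apply ``require_complete`` filtering upstream).
    """
    if populations is None:
        populations = gm.populations
    sizes = []
    cell_counts = []
    for pop in populations:
        idx = gm.sample_indices(pop)
        if idx.size == 0:
            raise ValueError(f"population {pop} has no samples")
        g = gm.genotypes[idx]
        if np.any(g == MISSING):
            raise ValueError("missing genotypes present; filter with require_complete")
        sizes.append(2 * len(idx))
        cell_counts.append(g.sum(axis=0).astype(np.int64))
    sizes = tuple(sizes)
    shape = tuple(n + 1 for n in sizes)
    counts = np.zeros(shape, dtype=np.int64)
    for j in range(gm.n_sites):
        cell = tuple(int(c[j]) for c in cell_counts)
        if folded:
            cell = _fold_cell(cell, sizes)
        counts[cell] += 1
    return FoldedSFS(
        populations=list(populations),
        sample_alleles=sizes,
        counts=counts,
        n_sites_total=gm.n_sites,
        folded=folded,
    )


def expected_sfs(
    model: DemographicModel,
    n_replicates: int,
    seed: int,
    window_length: int = 10_000,
    folded: bool = True,
    eps: float | None = None,
) -> np.ndarray:
    """Monte-Carlo expected polymorphic-cell probabilities.

    Simulates ``n_replicates`` windows, pools the joint SFS, and
    normalizes over polymorphic cells.  Cells with zero simulated mass are
    floored at ``eps`` (default 1/(10 * n_replicates)) and the result is
    renormalized, which stabilizes the composite likelihood.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    populations = [s.name for s in model.sampled()]
    sizes = tuple(2 * s.sample_size for s in model.sampled())
    shape = tuple(n + 1 for n in sizes)
    counts = np.zeros(shape, dtype=np.int64)
    for k in range(n_replicates):
        sub = int(window_seed(seed, k).generate_state(1)[0] % (2**31))
        sw = simulate_window(model, window_length, sub)
        gm = sw.genotypes
        cells = [gm.allele_counts(p)[0] for p in populations]
        for j in range(gm.n_sites):
            cell = tuple(int(c[j]) for c in cells)
            if folded:
                cell = _fold_cell(cell, sizes)
            counts[cell] += 1
    mask = np.ones(shape, dtype=bool)
    mask[(0,) * len(shape)] = False
    mask[tuple(sizes)] = False
    probs = counts.astype(float)
    probs[~mask] = 0.0
    total = probs.sum()
    if total == 0:
        raise ValueError("no polymorphic sites simulated; increase n_replicates")
    probs /= total
    if eps is None:
        eps = 1.0 / (10.0 * n_replicates)
    n_floored = int(np.sum(mask & (probs < eps)))
    if n_floored:
        log.debug("expected_sfs: flooring %d empty cells at eps=%g", n_floored, eps)
    probs[mask] = np.maximum(probs[mask], eps)
    probs[mask] /= probs[mask].sum()
    return probs


def composite_log_likelihood(
    obs: FoldedSFS, probs: np.ndarray, mask_singletons: bool = False
) -> float:
    """CL = sum_cells m_i ln p_i over polymorphic cells.

    ``probs`` is renormalized over the polymorphic cells first.  With
    ``mask_singletons``, cells whose total minor count is 1 are excluded
    from both counts and probabilities.
    """
    probs = np.asarray(probs, dtype=float)
    if probs.shape != obs.counts.shape:
        raise ValueError("probability array shape mismatch")
    mask = obs.polymorphic_mask()
    if mask_singletons:
        tot = np.zeros(obs.counts.shape, dtype=np.int64)
        for axis, n in enumerate(obs.sample_alleles):
            idx = np.arange(n + 1)
            sh = [1] * obs.counts.ndim
            sh[axis] = n + 1
            tot = tot + idx.reshape(sh)
        mask &= tot != 1
    m = np.where(mask, obs.counts, 0)
    p = np.where(mask, probs, 0.0)
    if p.sum() <= 0:
        raise ValueError("no probability mass on polymorphic cells")
    p = p / p.sum()
    bad = (m > 0) & (p == 0)
    if bad.any():
        raise ValueError(
            f"observed mass on {int(bad.sum())} zero-probability cells; "
            "raise eps or n_replicates"
        )
    nz = m > 0
    return float(np.sum(m[nz] * np.log(p[nz])))


@dataclass
class CompositeFitResult:
    parameter_estimates: dict[str, float]
    log_composite_likelihood: float
    n_evaluations: int
    hit_bounds: list[str]

    def report(self) -> str:
        lines = ["composite-likelihood fit", "-" * 32]
        for k, v in self.parameter_estimates.items():
            flag = "  [at bound]" if k in self.hit_bounds else ""
            lines.append(f"{k:32s} {v:.6g}{flag}")
        lines.append(f"{'log composite likelihood':32s} {self.log_composite_likelihood:.4f}")
        lines.append(f"{'objective evaluations':32s} {self.n_evaluations}")
        return "\n".join(lines)


def fit_parameters(
    obs: FoldedSFS,
    model_template: DemographicModel,
    free_parameters: list[str],
    bounds: list[tuple[float, float]],
    seed: int,
    n_replicates: int = 1_000,
    window_length: int = 10_000,
    n_restarts: int = 5,
    maxiter: int = 60,
    integer_parameters: set[str] | None = None,
) -> CompositeFitResult:
    """Maximize the composite likelihood over a few free parameters.

    Derivative-free Nelder-Mead with multiple restarts; every objective
    evaluation re-simulates the expected SFS with the same per-window
    seeds (common random numbers), so the fit is deterministic given the
    master seed.  Parameter names use
    :meth:`DemographicModel.with_param` addressing.  Supports the
    two-stage protocol by freezing previously fitted values into
    ``model_template``.
    """
    if len(free_parameters) != len(bounds):
        raise ValueError("free_parameters and bounds differ in length")
    for lo, hi in bounds:
        if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
            raise ValueError("bounds must be finite intervals")
    integer_parameters = integer_parameters or {
        n for n in free_parameters if "diploid_size" in n or "bottleneck_size" in n
    }
    n_eval = 0

    def build(theta: np.ndarray) -> DemographicModel:
        m = model_template
        for name, value in zip(free_parameters, theta):
            if name in integer_parameters:
                value = max(1, int(round(value)))
            m = m.with_param(name, float(value) if name not in integer_parameters else value)
        return m

    def objective(theta: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        theta = np.clip(theta, [lo for lo, _ in bounds], [hi for _, hi in bounds])
        model = build(theta)
        probs = expected_sfs(model, n_replicates, seed, window_length, obs.folded)
        try:
            return -composite_log_likelihood(obs, probs)
        except ValueError:
            return math.inf

    if not free_parameters:
        probs = expected_sfs(
            model_template, n_replicates, seed, window_length, obs.folded
        )
        return CompositeFitResult(
            {}, composite_log_likelihood(obs, probs), 1, []
        )

    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0xF17,)))
    best = None
    for r in range(max(1, n_restarts)):
        x0 = np.array(
            [lo + (hi - lo) * rng.uniform(0.2, 0.8) for lo, hi in bounds]
        )
        res = minimize(
            objective,
            x0,
            method="Nelder-Mead",
            bounds=bounds,
            options={"maxiter": maxiter, "xatol": 1e-3, "fatol": 1e-3},
        )
        if not math.isfinite(res.fun):
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise ValueError("non-finite composite likelihood in every restart")
    theta = np.clip(best.x, [lo for lo, _ in bounds], [hi for _, hi in bounds])
    hit = [
        name
        for name, v, (lo, hi) in zip(free_parameters, theta, bounds)
        if math.isclose(v, lo, rel_tol=1e-6, abs_tol=1e-9)
        or math.isclose(v, hi, rel_tol=1e-6, abs_tol=1e-9)
    ]
    if hit:
        log.warning("fit hit bounds for: %s", ", ".join(hit))
    estimates = {}
    for name, v in zip(free_parameters, theta):
        estimates[name] = float(max(1, round(v))) if name in integer_parameters else float(v)
    return CompositeFitResult(
        parameter_estimates=estimates,
        log_composite_likelihood=-float(best.fun),
        n_evaluations=n_eval,
        hit_bounds=hit,
    )


def years_to_generations(years, generation_time):
    """Exact rational conversion where inputs are integers."""
    if years < 0:
        raise ValueError("years must be >= 0")
    if generation_time <= 0:
        raise ValueError("generation_time must be > 0")
    if isinstance(years, int) and isinstance(generation_time, int):
        out = Fraction(years, generation_time)
        return int(out) if out.denominator == 1 else out
    return years / generation_time


def generations_to_years(generations, generation_time):
    if generations < 0:
        raise ValueError("generations must be >= 0")
    if generation_time <= 0:
        raise ValueError("generation_time must be > 0")
    if isinstance(generations, int) and isinstance(generation_time, int):
        out = Fraction(generations) * generation_time
        return int(out) if out.denominator == 1 else out
    return generations * generation_time


def sfs_to_frame(sfs: FoldedSFS):
    """Serialize the joint SFS as a tidy table (cell indices + count)."""
    import pandas as pd

    rows = []
    for cell in itertools.product(*(range(n + 1) for n in sfs.sample_alleles)):
        c = int(sfs.counts[cell])
        if c:
            row = {f"minor_{p}": k for p, k in zip(sfs.populations, cell)}
            row["count"] = c
            rows.append(row)
    return pd.DataFrame(rows)
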