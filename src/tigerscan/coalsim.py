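"""Structured-coalescent simulator for hierarchical continent-island demographies.

The model is a set of demes: sampled populations that each diverged from a
(possibly nested) metapopulation at some time in the past and that keep
receiving lineages from it (backward in time) at a constant per-generation
migration rate.  Any deme can pass through bottleneck epochs of constant
reduced size; bottleneck intensity follows the t/2N convention (epoch
duration over twice the bottleneck size).

Coalescence is simulated in continuous time with exponential waiting times
(rate k(k-1)/2 * 1/(2N) per deme), mutations fall on branches as a Poisson
process with rate ``mutation_rate * branch_length * window_length`` under an
infinite-sites model on an integer coordinate grid (position collisions are
redrawn).  Intra-window recombination is off by default; a uniform rate can
be configured, in which case an ancestral-recombination-graph variant of the
same algorithm is used.

A discrete-generation Wright-Fisher forward simulator of the same model
class (:func:`forward_wf_oracle`) is provided purely as an independent
distributional check for small models; it treats sites as freely
recombining, which leaves single-site summaries (segregating sites, FST)
unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .variants import GenotypeMatrix

__all__ = [
    "PopulationSpec",
    "BottleneckEvent",
    "DemographicModel",
    "SimulatedWindow",
    "simulate_window",
    "simulate_null_windows",
    "simulate_genealogy",
    "forward_wf_oracle",
    "load_model",
    "save_model",
    "scale_population",
]


@dataclass(frozen=True)
class PopulationSpec:
    """One deme: a sampled population or a metapopulation level.

    ``divergence_time`` is the time (generations before present) at which
    the deme's lineages join its parent; ``migration_rate`` is the
    backward-in-time per-generation probability that a lineage in this deme
    derives from the parent.  ``parent`` defaults to the first
    metapopulation level for sampled populations and to the next level up
    for metapopulations (the last level is the root and never merges).
    """

    name: str
    diploid_size: int
    sample_size: int = 0
    divergence_time: float = 0.0
    migration_rate: float = 0.0
    parent: str | None = None

    def __post_init__(self) -> None:
        if self.diploid_size < 1:
            raise ValueError(f"{self.name}: diploid_size must be >= 1")
        if self.sample_size < 0 or self.divergence_time < 0:
            raise ValueError(f"{self.name}: negative sample size or divergence time")
        if not 0 <= self.migration_rate <= 1:
            raise ValueError(f"{self.name}: migration_rate must be in [0, 1]")


@dataclass(frozen=True)
class BottleneckEvent:
    """Epoch of reduced constant size for one deme.

    The epoch spans [start_time, start_time + duration) backward in time;
    ``intensity`` is duration / (2 * bottleneck_size).
    """

    population: str
    start_time: float
    duration: float
    bottleneck_size: int

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("bottleneck duration must be > 0")
        if self.bottleneck_size < 1:
            raise ValueError("bottleneck_size must be >= 1")
        if self.start_time < 0:
            raise ValueError("bottleneck start_time must be >= 0")

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration

    @property
    def intensity(self) -> float:
        return self.duration / (2.0 * self.bottleneck_size)


@dataclass
class DemographicModel:
    """Populations plus nested metapopulation levels, bottlenecks and rates.

    ``metapopulations`` are ordered leafward to rootward; the last entry is
    the root deme, which persists indefinitely.  With no metapopulations the
    populations themselves must form a tree through their ``parent`` fields
    (a single population is its own root).
    """

    populations: list[PopulationSpec]
    metapopulations: list[PopulationSpec] = field(default_factory=list)
    bottlenecks: list[BottleneckEvent] = field(default_factory=list)
    mutation_rate: float = 0.35e-8
    generation_time: float = 5.0
    recombination_rate: float = 0.0

    def __post_init__(self) -> None:
        self.validate()

    # -- resolution ------------------------------------------------------

    def demes(self) -> dict[str, PopulationSpec]:
        out = {}
        for spec in list(self.populations) + list(self.metapopulations):
            if spec.name in out:
                raise ValueError(f"duplicate deme name {spec.name!r}")
            out[spec.name] = spec
        return out

    def resolved_parents(self) -> dict[str, str | None]:
        metas = self.metapopulations
        parents: dict[str, str | None] = {}
        for spec in self.populations:
            if spec.parent is not None:
                parents[spec.name] = spec.parent
            elif metas:
                parents[spec.name] = metas[0].name
            else:
                parents[spec.name] = None
        for k, spec in enumerate(metas):
            if spec.parent is not None:
                parents[spec.name] = spec.parent
            else:
                parents[spec.name] = metas[k + 1].name if k + 1 < len(metas) else None
        return parents

    def root(self) -> str:
        roots = [n for n, p in self.resolved_parents().items() if p is None]
        if len(roots) != 1:
            raise ValueError(
                f"model must have exactly one root deme, found {roots}"
            )
        return roots[0]

    def validate(self) -> None:
        if self.mutation_rate <= 0:
            raise ValueError("mutation_rate must be > 0")
        if self.generation_time <= 0:
            raise ValueError("generation_time must be > 0")
        if self.recombination_rate < 0:
            raise ValueError("recombination_rate must be >= 0")
        demes = self.demes()
        parents = self.resolved_parents()
        root = self.root()
        for name, parent in parents.items():
            if parent is None:
                continue
            if parent not in demes:
                raise ValueError(f"{name}: unknown parent deme {parent!r}")
            # walk up to guard against cycles / unreachable root
            seen = {name}
            cur = parent
            while cur is not None:
                if cur in seen:
                    raise ValueError(f"parent cycle involving {cur!r}")
                seen.add(cur)
                cur = parents[cur]
            if root not in seen:
                raise ValueError(f"{name} cannot reach the root deme")
            if parent != root:
                if demes[name].divergence_time > demes[parent].divergence_time:
                    raise ValueError(
                        f"{name} diverges after its parent {parent} merges"
                    )
        for b in self.bottlenecks:
            if b.population not in demes:
                raise ValueError(f"bottleneck on unknown deme {b.population!r}")
        byp: dict[str, list[BottleneckEvent]] = {}
        for b in self.bottlenecks:
            byp.setdefault(b.population, []).append(b)
        for name, events in byp.items():
            events = sorted(events, key=lambda b: b.start_time)
            for a, b in zip(events, events[1:]):
                if b.start_time < a.end_time:
                    raise ValueError(f"overlapping bottlenecks on {name}")

    # -- convenience -----------------------------------------------------

    def sampled(self) -> list[PopulationSpec]:
        return [
            s
            for s in list(self.populations) + list(self.metapopulations)
            if s.sample_size > 0
        ]

    def n_haploids(self) -> int:
        return 2 * sum(s.sample_size for s in self.sampled())

    def size_at(self, deme: str, t: float) -> int:
        for b in self.bottlenecks:
            if b.population == deme and b.start_time <= t < b.end_time:
                return b.bottleneck_size
        return self.demes()[deme].diploid_size

    def with_param(self, name: str, value) -> "DemographicModel":
        """Copy with one parameter replaced.

        ``name`` is either a model-level field (``mutation_rate``), a deme
        field ``"<deme>.<field>"``, or a bottleneck field
        ``"bottleneck:<deme>:<k>.<field>"`` (k-th bottleneck of that deme in
        list order).
        """
        if "." not in name:
            return replace(self, **{name: value})
        head, fld = name.rsplit(".", 1)
        if head.startswith("bottleneck:"):
            _, deme, k = head.split(":")
            k = int(k)
            hits = [i for i, b in enumerate(self.bottlenecks) if b.population == deme]
            idx = hits[k]
            new_b = list(self.bottlenecks)
            new_b[idx] = replace(new_b[idx], **{fld: value})
            return replace(self, bottlenecks=new_b)
        def upd(specs):
            return [
                replace(s, **{fld: value}) if s.name == head else s for s in specs
            ]
        if head not in self.demes():
            raise KeyError(f"no deme named {head!r}")
        return replace(
            self, populations=upd(self.populations), metapopulations=upd(self.metapopulations)
        )


def scale_population(model: DemographicModel, name: str, factor: float) -> DemographicModel:
    """Scale one deme's size (and its bottleneck sizes) by ``factor``.

    Used to emulate locally elevated drift (a selection-like signal) in a
    focal population.
    """
    if factor <= 0:
        raise ValueError("factor must be > 0")
    demes = model.demes()
    if name not in demes:
        raise KeyError(f"no deme named {name!r}")
    pops = [
        replace(s, diploid_size=max(1, round(s.diploid_size * factor)))
        if s.name == name
        else s
        for s in model.populations
    ]
    metas = [
        replace(s, diploid_size=max(1, round(s.diploid_size * factor)))
        if s.name == name
        else s
        for s in model.metapopulations
    ]
    bots = [
        replace(b, bottleneck_size=max(1, round(b.bottleneck_size * factor)))
        if b.population == name
        else b
        for b in model.bottlenecks
    ]
    return replace(model, populations=pops, metapopulations=metas, bottlenecks=bots)


@dataclass
class SimulatedWindow:
    """Genotypes for one simulated locus."""

    genotypes: GenotypeMatrix
    window_length: int
    seed: int


@dataclass
class Genealogy:
    """Branches of one realized coalescent tree (root branch excluded).

    Each branch is (descendant haploid bitmask, length in generations).
    """

    branches: list[tuple[int, float]]
    tmrca: float
    n_haploids: int

    @property
    def total_branch_length(self) -> float:
        return float(sum(ln for _, ln in self.branches))


# -- sample layout -------------------------------------------------------


def _sample_layout(model: DemographicModel):
    """(sample_ids, population_labels, per-deme haploid index ranges)."""
    ids: list[str] = []
    pops: list[str] = []
    ranges: dict[str, tuple[int, int]] = {}
    h = 0
    for spec in model.sampled():
        ranges[spec.name] = (h, h + 2 * spec.sample_size)
        for k in range(spec.sample_size):
            ids.append(f"{spec.name}_{k + 1}")
            pops.append(spec.name)
        h += 2 * spec.sample_size
    return ids, pops, ranges


def _epoch_boundaries(model: DemographicModel) -> list[float]:
    root = model.root()
    demes = model.demes()
    parents = model.resolved_parents()
    times = set()
    for name, parent in parents.items():
        if parent is not None:
            times.add(float(demes[name].divergence_time))
    for b in model.bottlenecks:
        times.add(float(b.start_time))
        times.add(float(b.end_time))
    return sorted(t for t in times if t > 0)


# -- continuous-time coalescent (no recombination) -----------------------


def simulate_genealogy(model: DemographicModel, rng: np.random.Generator) -> Genealogy:
    """Simulate one coalescent genealogy for the configured samples."""
    if model.n_haploids() < 2:
        raise ValueError("need at least one diploid sample (two lineages)")
    demes = model.demes()
    parents = model.resolved_parents()
    root = model.root()
    _, _, ranges = _sample_layout(model)

    # lineages[deme] -> list of [mask, birth_time]
    lineages: dict[str, list[list]] = {name: [] for name in demes}
    for name, (lo, hi) in ranges.items():
        for h in range(lo, hi):
            lineages[name].append([1 << h, 0.0])
    active = {name: (name == root or demes[name].divergence_time > 0) for name in demes}
    for name in demes:
        if not active[name] and lineages[name]:
            # zero divergence time: lineages start in the nearest active ancestor
            target = parents[name]
            while not active[target]:
                target = parents[target]
            lineages[target].extend(lineages[name])
            lineages[name] = []

    branches: list[tuple[int, float]] = []
    boundaries = _epoch_boundaries(model) + [math.inf]
    total = sum(len(v) for v in lineages.values())
    t = 0.0
    tmrca = 0.0
    b_idx = 0
    order = list(demes)

    while total > 1:
        t_next = boundaries[b_idx] if b_idx < len(boundaries) else math.inf
        while t_next <= t:
            b_idx += 1
            t_next = boundaries[b_idx] if b_idx < len(boundaries) else math.inf
        sizes = {name: model.size_at(name, t) for name in order if active[name]}
        while total > 1:
            coal_rates = []
            mig_rates = []
            for name in order:
                if not active[name]:
                    coal_rates.append(0.0)
                    mig_rates.append(0.0)
                    continue
                k = len(lineages[name])
                coal_rates.append(k * (k - 1) / (4.0 * sizes[name]))
                m = demes[name].migration_rate if parents[name] is not None else 0.0
                mig_rates.append(k * m)
            rate = sum(coal_rates) + sum(mig_rates)
            if rate == 0.0:
                if math.isinf(t_next):  # pragma: no cover - guarded by validate()
                    raise ValueError("non-coalescing configuration")
                break
            dt = rng.exponential(1.0 / rate)
            if t + dt >= t_next:
                break
            t += dt
            u = rng.uniform(0.0, rate)
            acc = 0.0
            for i, name in enumerate(order):
                acc += coal_rates[i]
                if u < acc:
                    group = lineages[name]
                    ia, ib = rng.choice(len(group), size=2, replace=False)
                    a, b = group[ia], group[ib]
                    branches.append((a[0], t - a[1]))
                    branches.append((b[0], t - b[1]))
                    merged = [a[0] | b[0], t]
                    for j in sorted((int(ia), int(ib)), reverse=True):
                        group.pop(j)
                    group.append(merged)
                    total -= 1
                    tmrca = t
                    break
                acc += mig_rates[i]
                if u < acc:
                    group = lineages[name]
                    j = int(rng.integers(len(group)))
                    lineages[parents[name]].append(group.pop(j))
                    break
        else:
            break
        if total <= 1:
            break
        if math.isinf(t_next):  # pragma: no cover - guarded by validate()
            raise ValueError("non-coalescing configuration")
        t = t_next
        merging = {
            name
            for name in order
            if active[name]
            and parents[name] is not None
            and demes[name].divergence_time == t_next
        }
        for name in merging:
            active[name] = False
        for name in merging:
            target = parents[name]
            while not active[target]:
                target = parents[target]
            lineages[target].extend(lineages[name])
            lineages[name] = []
    return Genealogy(branches=branches, tmrca=tmrca, n_haploids=model.n_haploids())


def _place_mutations(
    gen: Genealogy, mu: float, window_length: int, rng: np.random.Generator
):
    """Poisson mutations on branches; infinite sites on an integer grid."""
    if not gen.branches:
        return np.empty(0, np.int64), []
    lens = np.array([ln for _, ln in gen.branches], dtype=float)
    total = float(lens.sum())
    n_mut = int(rng.poisson(mu * window_length * total))
    if n_mut == 0:
        return np.empty(0, np.int64), []
    if n_mut > window_length:
        raise ValueError("more mutations than sites on the coordinate grid")
    which = rng.choice(len(lens), size=n_mut, p=lens / total)
    used: set[int] = set()
    positions = np.empty(n_mut, dtype=np.int64)
    for i in range(n_mut):
        pos = int(rng.integers(window_length))
        while pos in used:
            pos = int(rng.integers(window_length))
        used.add(pos)
        positions[i] = pos
    order = np.argsort(positions)
    masks = [gen.branches[int(which[i])][0] for i in order]
    return positions[order], masks


def _genotypes_from_masks(
    model: DemographicModel,
    positions: np.ndarray,
    masks: list[int],
    window_length: int,
    scaffold: str,
) -> GenotypeMatrix:
    ids, pops, _ = _sample_layout(model)
    n_dip = len(ids)
    g = np.zeros((n_dip, len(positions)), dtype=np.int8)
    for j, mask in enumerate(masks):
        for i in range(n_dip):
            g[i, j] = ((mask >> (2 * i)) & 1) + ((mask >> (2 * i + 1)) & 1)
    return GenotypeMatrix(
        sample_ids=ids,
        population_labels=pops,
        scaffolds={scaffold: window_length},
        site_scaffolds=np.array([scaffold] * len(positions), dtype=object),
        positions=positions,
        genotypes=g,
    )


def simulate_window(
    model: DemographicModel,
    window_length: int,
    seed: int,
    scaffold: str = "sim0",
) -> SimulatedWindow:
    """Simulate genotypes for one window; deterministic given the seed."""
    if window_length < 1:
        raise ValueError("window_length must be >= 1")
    model.validate()
    if model.n_haploids() < 2:
        raise ValueError("need at least one diploid sample (two lineages)")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if model.recombination_rate > 0:
        positions, masks = _simulate_arg_window(model, window_length, rng)
    else:
        gen = simulate_genealogy(model, rng)
        positions, masks = _place_mutations(gen, model.mutation_rate, window_length, rng)
    gm = _genotypes_from_masks(model, positions, masks, window_length, scaffold)
    return SimulatedWindow(genotypes=gm, window_length=window_length, seed=seed)


def window_seed(master_seed: int, index) -> np.random.SeedSequence:
    """Counter-based per-window seed: order-independent in ``index``."""
    key = (index,) if isinstance(index, int) else tuple(index)
    return np.random.SeedSequence(entropy=master_seed, spawn_key=key)


def simulate_null_windows(
    model: DemographicModel, n_windows: int, window_length: int, seed: int
) -> list[SimulatedWindow]:
    """Independent neutral replicates with per-window derived seeds."""
    if n_windows < 1:
        raise ValueError("n_windows must be >= 1")
    out = []
    for k in range(n_windows):
        ss = window_seed(seed, k)
        sub = int(ss.generate_state(1)[0] % (2**31))
        out.append(simulate_window(model, window_length, sub, scaffold=f"sim{k}"))
    return out


# -- ancestral recombination graph variant -------------------------------


def _simulate_arg_window(model: DemographicModel, L: int, rng: np.random.Generator):
    """Hudson-style ARG for one window with uniform recombination.

    Lineages carry lists of (left, right, mask) ancestral segments; pieces
    whose mask reaches the full sample are done and dropped.  Dead lineages
    record (duration, segments) for mutation placement.
    """
    demes = model.demes()
    parents = model.resolved_parents()
    root = model.root()
    _, _, ranges = _sample_layout(model)
    full_mask = (1 << model.n_haploids()) - 1
    r_rate = model.recombination_rate

    class Lin:
        __slots__ = ("segs", "birth", "deme")

        def __init__(self, segs, birth, deme):
            self.segs = segs
            self.birth = birth
            self.deme = deme

        def span(self):
            return self.segs[-1][1] - self.segs[0][0]

    active = {
        name: (name == root or demes[name].divergence_time > 0) for name in demes
    }
    lineages: list[Lin] = []
    for name, (lo, hi) in ranges.items():
        target = name
        while not active[target]:
            target = parents[target]
        for h in range(lo, hi):
            lineages.append(Lin([(0.0, float(L), 1 << h)], 0.0, target))
    dead: list[tuple[float, list]] = []

    def retire(lin: Lin, t: float):
        if lin.segs:
            dead.append((t - lin.birth, lin.segs))

    boundaries = _epoch_boundaries(model) + [math.inf]
    t = 0.0
    b_idx = 0
    while lineages:
        t_next = boundaries[b_idx] if b_idx < len(boundaries) else math.inf
        while t_next <= t:
            b_idx += 1
            t_next = boundaries[b_idx] if b_idx < len(boundaries) else math.inf
        sizes = {name: model.size_at(name, t) for name in demes if active[name]}
        while lineages:
            by_deme: dict[str, list[int]] = {}
            for i, lin in enumerate(lineages):
                by_deme.setdefault(lin.deme, []).append(i)
            coal = {
                d: len(ix) * (len(ix) - 1) / (4.0 * sizes[d])
                for d, ix in by_deme.items()
            }
            mig = {
                d: len(ix) * (demes[d].migration_rate if parents[d] else 0.0)
                for d, ix in by_deme.items()
            }
            rec_w = [r_rate * lin.span() for lin in lineages]
            rate = sum(coal.values()) + sum(mig.values()) + sum(rec_w)
            if rate == 0.0:
                break
            dt = rng.exponential(1.0 / rate)
            if t + dt >= t_next:
                break
            t += dt
            u = rng.uniform(0.0, rate)
            acc = 0.0
            done = False
            for d, ix in by_deme.items():
                acc += coal[d]
                if u < acc:
                    ia, ib = rng.choice(len(ix), size=2, replace=False)
                    a, b = lineages[ix[ia]], lineages[ix[ib]]
                    retire(a, t)
                    retire(b, t)
                    merged = _merge_segments(a.segs, b.segs, full_mask)
                    for j in sorted((ix[ia], ix[ib]), reverse=True):
                        lineages.pop(j)
                    if merged:
                        lineages.append(Lin(merged, t, d))
                    done = True
                    break
                acc += mig[d]
                if u < acc:
                    j = ix[int(rng.integers(len(ix)))]
                    lineages[j].deme = parents[d]
                    done = True
                    break
            if not done:
                for j, w in enumerate(rec_w):
                    acc += w
                    if u < acc:
                        lin = lineages[j]
                        x = rng.uniform(lin.segs[0][0], lin.segs[-1][1])
                        left, right = _split_segments(lin.segs, x)
                        if left and right:
                            retire(lin, t)
                            lineages.pop(j)
                            lineages.append(Lin(left, t, lin.deme))
                            lineages.append(Lin(right, t, lin.deme))
                        break
        if not lineages:
            break
        if math.isinf(t_next):
            if len(lineages) > 1:  # pragma: no cover - guarded by validate()
                raise ValueError("non-coalescing configuration")
            break
        t = t_next
        merging = {
            name
            for name in demes
            if active[name]
            and parents[name] is not None
            and demes[name].divergence_time == t_next
        }
        for name in merging:
            active[name] = False
        for name in merging:
            target = parents[name]
            while not active[target]:
                target = parents[target]
            for lin in lineages:
                if lin.deme == name:
                    lin.deme = target

    # mutations over recorded branches
    weights = []
    for dur, segs in dead:
        length = sum(r - l for l, r, _ in segs)
        weights.append(dur * length)
    weights = np.asarray(weights, dtype=float)
    total = float(weights.sum())
    if total == 0.0:
        return np.empty(0, np.int64), []
    n_mut = int(rng.poisson(model.mutation_rate * total))
    used: set[int] = set()
    positions: list[int] = []
    masks: list[int] = []
    for _ in range(n_mut):
        b = int(rng.choice(len(weights), p=weights / total))
        _, segs = dead[b]
        counts = [max(0, math.ceil(r) - math.ceil(l)) for l, r, _ in segs]
        tot = sum(counts)
        if tot == 0:
            continue
        pos = None
        for _try in range(200):
            k = int(rng.integers(tot))
            for (l, r, mask), c in zip(segs, counts):
                if k < c:
                    cand = math.ceil(l) + k
                    break
                k -= c
            if cand not in used:
                pos = cand
                break
        if pos is None:
            continue
        used.add(pos)
        positions.append(pos)
        masks.append(mask)
    order = np.argsort(positions)
    return (
        np.asarray(positions, np.int64)[order],
        [masks[int(i)] for i in order],
    )


def _merge_segments(a: list, b: list, full_mask: int) -> list:
    """Coalesce two segment lists; pieces reaching the full mask are dropped."""
    cuts = sorted({x for l, r, _ in a + b for x in (l, r)})
    out = []
    for lo, hi in zip(cuts, cuts[1:]):
        mid = (lo + hi) / 2.0
        ma = next((m for l, r, m in a if l <= mid < r), 0)
        mb = next((m for l, r, m in b if l <= mid < r), 0)
        m = ma | mb
        if m == 0 or m == full_mask:
            continue
        if out and out[-1][1] == lo and out[-1][2] == m:
            out[-1] = (out[-1][0], hi, m)
        else:
            out.append((lo, hi, m))
    return out


def _split_segments(segs: list, x: float):
    left, right = [], []
    for l, r, m in segs:
        if r <= x:
            left.append((l, r, m))
        elif l >= x:
            right.append((l, r, m))
        else:
            left.append((l, x, m))
            right.append((x, r, m))
    return left, right


# -- forward Wright-Fisher oracle ----------------------------------------

_WF_MAX_N = 500
_WF_MAX_T = 5_000


def forward_wf_oracle(
    model: DemographicModel,
    window_length: int,
    seed: int,
    burn_in: int | None = None,
    scaffold: str = "wf0",
) -> SimulatedWindow:
    """Discrete-generation Wright-Fisher forward simulation of the model.

    Tracks per-site allele counts in every deme forward in time (new
    mutations arise Poisson(2N mu L) per deme per generation); demes are
    founded from their parent at their divergence time, receive migrant
    genes each generation with probability ``migration_rate``, and pass
    through the same bottleneck epochs.  Sites are unlinked, so only
    single-site summaries are comparable with the coalescent simulator.

    Refuses models too large for forward simulation (N > 500 or event
    times > 5,000 generations).
    """
    model.validate()
    demes = model.demes()
    parents = model.resolved_parents()
    root = model.root()
    all_sizes = [s.diploid_size for s in demes.values()] + [
        b.bottleneck_size for b in model.bottlenecks
    ]
    t_max = max(
        [demes[n].divergence_time for n in demes if parents[n] is not None]
        + [b.end_time for b in model.bottlenecks]
        + [0.0]
    )
    if max(all_sizes) > _WF_MAX_N or t_max > _WF_MAX_T:
        raise ValueError("model too large for forward simulation")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if burn_in is None:
        burn_in = 20 * demes[root].diploid_size
    t0 = int(math.ceil(t_max)) + int(burn_in)

    order = list(demes)
    counts: dict[str, np.ndarray] = {root: np.empty(0, np.int64)}
    mu_l = model.mutation_rate * window_length
    for t in range(t0, 0, -1):
        t_new = t - 1
        newly = [
            n
            for n in order
            if n not in counts
            and parents[n] is not None
            and t_new < demes[n].divergence_time <= t
            and parents[n] in counts
        ]
        n_sites = len(counts[root])
        prev_p = {
            d: c / (2.0 * model.size_at(d, t)) if n_sites else c.astype(float)
            for d, c in counts.items()
        }
        for d in list(counts):
            n2 = 2 * model.size_at(d, t_new)
            par = parents[d]
            m = demes[d].migration_rate if (par is not None and par in prev_p) else 0.0
            p_eff = (1.0 - m) * prev_p[d] + (m * prev_p[par] if m > 0 else 0.0)
            counts[d] = rng.binomial(n2, p_eff) if n_sites else counts[d]
        for d in newly:
            n2 = 2 * model.size_at(d, t_new)
            counts[d] = rng.binomial(n2, prev_p[parents[d]]) if n_sites else np.empty(0, np.int64)
        # new mutations, one copy each
        fresh = {d: int(rng.poisson(2 * model.size_at(d, t_new) * mu_l)) for d in counts}
        n_new = sum(fresh.values())
        if n_new:
            for d in counts:
                add = np.zeros(n_new, dtype=np.int64)
                counts[d] = np.concatenate([counts[d], add])
            off = len(counts[root]) - n_new
            k = off
            for d, c in fresh.items():
                counts[d][k : k + c] = 1
                k += c
        # prune sites lost or fixed everywhere
        if len(counts[root]):
            lost = np.ones(len(counts[root]), dtype=bool)
            fixed = np.ones(len(counts[root]), dtype=bool)
            for d, c in counts.items():
                lost &= c == 0
                fixed &= c == 2 * model.size_at(d, t_new)
            keep = ~(lost | fixed)
            if not keep.all():
                for d in counts:
                    counts[d] = counts[d][keep]

    # sample diploids at the present
    ids, pops, ranges = _sample_layout(model)
    n_sites = len(counts[root])
    samp: dict[str, np.ndarray] = {}
    for spec in model.sampled():
        d = spec.name
        if d not in counts:
            raise ValueError(f"sampled deme {d} never became active")
        n2 = 2 * model.size_at(d, 0)
        k = 2 * spec.sample_size
        if n_sites:
            samp[d] = rng.hypergeometric(counts[d], n2 - counts[d], k)
        else:
            samp[d] = np.empty(0, np.int64)
    if n_sites:
        tot = sum(samp.values())
        n_alleles = sum(2 * s.sample_size for s in model.sampled())
        seg = (tot > 0) & (tot < n_alleles)
        for d in samp:
            samp[d] = samp[d][seg]
        n_sites = int(seg.sum())
    positions = np.sort(rng.choice(window_length, size=n_sites, replace=False))
    g = np.zeros((len(ids), n_sites), dtype=np.int8)
    hap_of = np.repeat(np.arange(len(ids)), 2)
    for spec in model.sampled():
        lo, hi = ranges[spec.name]
        k = hi - lo
        for j in range(n_sites):
            c = int(samp[spec.name][j])
            if c:
                hit = rng.choice(k, size=c, replace=False)
                for h in hit:
                    g[hap_of[lo + h], j] += 1
    gm = GenotypeMatrix(
        sample_ids=ids,
        population_labels=pops,
        scaffolds={scaffold: window_length},
        site_scaffolds=np.array([scaffold] * n_sites, dtype=object),
        positions=positions,
        genotypes=g,
    )
    return SimulatedWindow(genotypes=gm, window_length=window_length, seed=seed)


# -- model config I/O ----------------------------------------------------


def _spec_to_dict(spec: PopulationSpec) -> dict:
    d = {
        "name": spec.name,
        "diploid_size": spec.diploid_size,
        "sample_size": spec.sample_size,
        "divergence_time": spec.divergence_time,
        "migration_rate": spec.migration_rate,
    }
    if spec.parent is not None:
        d["parent"] = spec.parent
    return d


def save_model(model: DemographicModel, path) -> None:
    doc = {
        "mutation_rate": float(model.mutation_rate),
        "generation_time": float(model.generation_time),
        "recombination_rate": float(model.recombination_rate),
        "metapopulations": [_spec_to_dict(s) for s in model.metapopulations],
        "populations": [_spec_to_dict(s) for s in model.populations],
        "bottlenecks": [
            {
                "population": b.population,
                "start_time": float(b.start_time),
                "duration": float(b.duration),
                "bottleneck_size": b.bottleneck_size,
            }
            for b in model.bottlenecks
        ],
    }
    with open(str(path), "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_model(path) -> DemographicModel:
    """Read a demographic model from its YAML description.

    Schema: top-level scalars ``mutation_rate`` (per site per generation),
    ``generation_time`` (years), ``recombination_rate`` (per site per
    generation, default 0); ``metapopulations`` — a list ordered leafward
    to rootward — and ``populations``, both lists of blocks with ``name``,
    ``diploid_size``, and optional ``sample_size``, ``divergence_time``
    (generations), ``migration_rate`` (backward, per generation) and
    ``parent`` (defaults: first metapopulation for populations, next level
    up for metapopulations); ``bottlenecks`` — a list of blocks with
    ``population``, ``start_time``, ``duration`` (generations) and
    ``bottleneck_size`` (diploids).  See ``data/stage1_tigers.yaml`` for a
    complete example.
    """
    with open(str(path)) as fh:
        doc = yaml.safe_load(fh)
    return model_from_dict(doc)


def model_from_dict(doc: dict) -> DemographicModel:
    def spec(d: dict) -> PopulationSpec:
        return PopulationSpec(
            name=str(d["name"]),
            diploid_size=int(d["diploid_size"]),
            sample_size=int(d.get("sample_size", 0)),
            divergence_time=float(d.get("divergence_time", 0.0)),
            migration_rate=float(d.get("migration_rate", 0.0)),
            parent=d.get("parent"),
        )

    return DemographicModel(
        populations=[spec(d) for d in doc.get("populations", [])],
        metapopulations=[spec(d) for d in doc.get("metapopulations", [])],
        bottlenecks=[
            BottleneckEvent(
                population=str(b["population"]),
                start_time=float(b["start_time"]),
                duration=float(b["duration"]),
                bottleneck_size=int(b["bottleneck_size"]),
            )
            for b in doc.get("bottlenecks", [])
        ],
        mutation_rate=float(doc.get("mutation_rate", 0.35e-8)),
        generation_time=float(doc.get("generation_time", 5.0)),
        recombination_rate=float(doc.get("recombination_rate", 0.0)),
    )


def bundled_model_path(name: str = "stage1_tigers") -> str:
    """Path of a bundled example model config."""
    from importlib.resources import files

    return str(files("tigerscan.data") / f"{name}.yaml")


def load_bundled_model(name: str = "stage1_tigers") -> DemographicModel:
    return load_model(bundled_model_path(name))
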