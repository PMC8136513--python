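"""Seeded synthetic datasets with the statistical structure the scan assumes.

A fixture is a bundle of files (VCF, scaffold table, population map, gene
BED, GO map, ground-truth manifest) built from non-overlapping simulated
blocks under a hierarchical continent-island demography.  A configurable
number of blocks is "injected": simulated under the same model with the
focal population's size multiplied by ``injection_factor`` (< 1), which
emulates a selective sweep's locally elevated drift while keeping the
block a valid coalescent sample.  One gene is placed inside every injected
block and a designated GO term is assigned to all genes overlapping
injected blocks plus a small random fraction of background genes, so
outlier-window recovery and enrichment ranking can be scored against the
manifest alone.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from .coalsim import (
    DemographicModel,
    load_bundled_model,
    save_model,
    scale_population,
    simulate_window,
)
from .enrichment import GeneAnnotation, map_windows_to_genes, write_genes_bed, write_term_map
from .variants import GenotypeMatrix, Window, write_scaffold_lengths, write_vcf

__all__ = ["FixtureSpec", "generate_fixture", "generate_annotation", "simulate_chunked_window"]


@dataclass
class FixtureSpec:
    """Recipe for one synthetic dataset.

    Defaults mirror the high-coverage demographic subset of the bundled
    stage-1 model (3 SUM, 3 BEN, 4 MAL, 3 AMU diploids) over ten 10-Mb
    scaffolds (~10,000 sliding 50-kb windows at a 10-kb step), with five
    injected high-drift windows in the Amur population at a 0.1 size
    factor.
    """

    model: DemographicModel = field(default_factory=load_bundled_model)
    n_scaffolds: int = 10
    scaffold_length: int = 10_000_000
    block_length: int = 50_000
    n_injected_windows: int = 5
    injection_factor: float = 0.1
    focal_population: str = "AMU"
    chunks_per_window: int = 50
    annotation_density: float = 20.0  # genes per Mb
    n_terms: int = 30
    background_term_fraction: float = 0.01
    designated_term: str = "GO:0000001"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.injection_factor <= 1:
            raise ValueError("injection_factor must be in (0, 1]")
        if self.n_injected_windows < 0:
            raise ValueError("n_injected_windows must be >= 0")
        if self.scaffold_length < self.block_length:
            raise ValueError("scaffold_length must be >= block (window) length")
        if self.focal_population not in self.model.demes():
            raise ValueError(f"unknown focal population {self.focal_population!r}")

    @property
    def scaffold_names(self) -> list[str]:
        return [f"scaffold_{k + 1:02d}" for k in range(self.n_scaffolds)]

    @property
    def scaffolds(self) -> dict[str, int]:
        return {name: self.scaffold_length for name in self.scaffold_names}


def simulate_chunked_window(
    model: DemographicModel,
    window_length: int,
    n_chunks: int,
    seed: int,
    seed_key: tuple = (),
    scaffold: str = "sim0",
) -> GenotypeMatrix:
    """One window composed of independently simulated chunks.

    Chunks emulate loosely linked loci: free recombination between chunks,
    none within.  Real genomes sit between this and a single genealogy per
    window; the chunk count controls how strongly window statistics
    average over genealogical noise.
    """
    chunk_len = window_length // n_chunks
    if chunk_len < 1:
        raise ValueError("window too short for the requested chunk count")
    parts = []
    for c in range(n_chunks):
        ss = np.random.SeedSequence(entropy=seed, spawn_key=tuple(seed_key) + (c,))
        sub = int(ss.generate_state(1)[0] % (2**31))
        length = chunk_len if c < n_chunks - 1 else window_length - chunk_len * (n_chunks - 1)
        gm = simulate_window(model, length, sub, scaffold=scaffold).genotypes
        gm.positions = gm.positions + c * chunk_len
        gm.scaffolds = {scaffold: window_length}
        parts.append(gm)
    return GenotypeMatrix.concatenate(parts)


def _choose_injected_blocks(spec: FixtureSpec, rng: np.random.Generator):
    """(scaffold index, block index) pairs: away from edges, >=2 blocks apart."""
    per = spec.scaffold_length // spec.block_length
    eligible = [
        (si, bi)
        for si in range(spec.n_scaffolds)
        for bi in range(1, per - 1)
    ]
    if spec.n_injected_windows == 0:
        return []
    if spec.n_injected_windows > len(eligible) // 3 + 1:
        raise ValueError("injected windows exceed scaffold capacity")
    for _ in range(1000):
        idx = rng.choice(len(eligible), size=spec.n_injected_windows, replace=False)
        chosen = sorted(eligible[int(i)] for i in idx)
        ok = all(
            not (a[0] == b[0] and abs(a[1] - b[1]) < 3)
            for a, b in zip(chosen, chosen[1:])
        )
        if ok:
            return chosen
    raise ValueError("could not place injected windows with required spacing")


def generate_annotation(
    scaffolds: dict[str, int],
    injected_windows: list[Window],
    seed: int,
    annotation_density: float = 20.0,
    n_terms: int = 30,
    background_term_fraction: float = 0.01,
    designated_term: str = "GO:0000001",
):
    """Random gene annotation plus GO map with a designated enriched term.

    Genes are placed uniformly (5-30 kb long, random strand); one extra
    gene is placed inside each injected window so the designated term is
    guaranteed representation among true positives.  The designated term
    is assigned to every gene overlapping an injected window plus a
    ``background_term_fraction`` random draw of the remaining genes; all
    other terms are assigned Poisson(1.5) per gene at random.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(2,)))
    names = list(scaffolds)
    lengths = np.array([scaffolds[n] for n in names], dtype=float)
    total_mb = lengths.sum() / 1e6
    n_genes = int(round(annotation_density * total_mb))
    genes: list[GeneAnnotation] = []
    k = 0
    for _ in range(n_genes):
        si = int(rng.choice(len(names), p=lengths / lengths.sum()))
        glen = int(rng.integers(5_000, 30_000))
        start = int(rng.integers(0, scaffolds[names[si]] - glen))
        k += 1
        genes.append(
            GeneAnnotation(
                gene_id=f"g{k:05d}",
                scaffold=names[si],
                start=start,
                end=start + glen,
                strand="+" if rng.random() < 0.5 else "-",
            )
        )
    for w in injected_windows:
        glen = min(20_000, w.length)
        start = w.start + (w.length - glen) // 2
        k += 1
        genes.append(
            GeneAnnotation(
                gene_id=f"g{k:05d}",
                scaffold=w.scaffold,
                start=start,
                end=start + glen,
                strand="+" if rng.random() < 0.5 else "-",
            )
        )
    genes.sort(key=lambda g: (g.scaffold, g.start, g.end))

    terms = [f"GO:{i:07d}" for i in range(2, n_terms + 2)]
    term_map: dict[str, set[str]] = {t: set() for t in terms}
    term_map[designated_term] = set()
    hit = map_windows_to_genes(injected_windows, genes, flank=0)
    for g in genes:
        for _ in range(int(rng.poisson(1.5))):
            term_map[terms[int(rng.integers(len(terms)))]].add(g.gene_id)
        if g.gene_id in hit:
            term_map[designated_term].add(g.gene_id)
        elif rng.random() < background_term_fraction:
            term_map[designated_term].add(g.gene_id)
    term_map = {t: m for t, m in term_map.items() if m}
    return genes, term_map


def generate_fixture(spec: FixtureSpec, out_dir) -> dict:
    """Build the full file bundle; returns the ground-truth manifest."""
    os.makedirs(str(out_dir), exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=spec.seed, spawn_key=(0,)))
    chosen = _choose_injected_blocks(spec, rng)
    injected = {
        (si, bi): Window(
            spec.scaffold_names[si],
            bi * spec.block_length,
            (bi + 1) * spec.block_length,
        )
        for si, bi in chosen
    }
    perturbed = (
        scale_population(spec.model, spec.focal_population, spec.injection_factor)
        if injected
        else spec.model
    )

    per = spec.scaffold_length // spec.block_length
    parts: list[GenotypeMatrix] = []
    for si, scaffold in enumerate(spec.scaffold_names):
        for bi in range(per):
            model = perturbed if (si, bi) in injected else spec.model
            gm = simulate_chunked_window(
                model,
                spec.block_length,
                spec.chunks_per_window,
                seed=spec.seed,
                seed_key=(1, si, bi),
                scaffold=scaffold,
            )
            gm.positions = gm.positions + bi * spec.block_length
            gm.scaffolds = {scaffold: spec.scaffold_length}
            parts.append(gm)
    gm = GenotypeMatrix.concatenate(parts)
    gm.scaffolds = dict(spec.scaffolds)

    genes, term_map = generate_annotation(
        spec.scaffolds,
        list(injected.values()),
        spec.seed,
        spec.annotation_density,
        spec.n_terms,
        spec.background_term_fraction,
        spec.designated_term,
    )

    paths = {
        "vcf": os.path.join(str(out_dir), "fixture.vcf"),
        "scaffolds": os.path.join(str(out_dir), "scaffolds.tsv"),
        "popmap": os.path.join(str(out_dir), "popmap.tsv"),
        "genes": os.path.join(str(out_dir), "genes.bed"),
        "go_map": os.path.join(str(out_dir), "go_map.tsv"),
        "model": os.path.join(str(out_dir), "model.yaml"),
        "manifest": os.path.join(str(out_dir), "manifest.yaml"),
    }
    write_vcf(gm, paths["vcf"])
    write_scaffold_lengths(spec.scaffolds, paths["scaffolds"])
    with open(paths["popmap"], "w") as fh:
        for sid, pop in zip(gm.sample_ids, gm.population_labels):
            fh.write(f"{sid}\t{pop}\n")
    write_genes_bed(genes, paths["genes"])
    write_term_map(term_map, paths["go_map"])
    save_model(spec.model, paths["model"])

    manifest = {
        "seed": spec.seed,
        "focal_population": spec.focal_population,
        "injection_factor": spec.injection_factor,
        "designated_term": spec.designated_term,
        "block_length": spec.block_length,
        "n_scaffolds": spec.n_scaffolds,
        "scaffold_length": spec.scaffold_length,
        "n_sites": int(gm.n_sites),
        "injected_windows": [
            {"scaffold": w.scaffold, "start": w.start, "end": w.end}
            for w in injected.values()
        ],
        "files": {k: os.path.basename(v) for k, v in paths.items() if k != "manifest"},
    }
    with open(paths["manifest"], "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest
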