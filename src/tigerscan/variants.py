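"""Genotype data model, VCF ingestion, site/genotype filters, window tiling and PCA.

The central container is :class:`GenotypeMatrix`: diploid allele counts
(0, 1, 2, or -1 for missing) for every sample at every biallelic SNP,
grouped by scaffold with strictly increasing positions.  All coordinates
are 0-based half-open internally; VCF I/O converts at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

log = logging.getLogger(__name__)

MISSING = -1


@dataclass
class Window:
    """Genomic interval, 0-based half-open."""

    scaffold: str
    start: int
    end: int
    partial: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid window [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenotypeMatrix:
    """Diploid genotypes for samples x sites, with population labels.

    ``genotypes[i, j]`` is the alternate-allele count of sample ``i`` at
    site ``j`` (0/1/2) or -1 when missing.  Sites are stored sorted by
    (scaffold, position); ``scaffolds`` maps scaffold name to length and
    fixes the scaffold order.
    """

    sample_ids: list[str]
    population_labels: list[str]
    scaffolds: dict[str, int]
    site_scaffolds: np.ndarray  # per-site scaffold name, object dtype
    positions: np.ndarray  # per-site 0-based position, int64
    genotypes: np.ndarray  # (n_samples, n_sites) int8
    depth: np.ndarray | None = None  # (n_samples, n_sites) int32, -1 unknown
    gq: np.ndarray | None = None  # (n_samples, n_sites) int32, -1 unknown
    _pop_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.site_scaffolds = np.asarray(self.site_scaffolds, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if len(self.sample_ids) != len(self.population_labels):
            raise ValueError("sample_ids and population_labels differ in length")
        if self.genotypes.shape != (len(self.sample_ids), len(self.positions)):
            raise ValueError("genotype matrix shape mismatch")
        order = {name: k for k, name in enumerate(self.scaffolds)}
        codes = np.array([order[s] for s in self.site_scaffolds], dtype=np.int64)
        if np.any(np.diff(codes) < 0):
            raise ValueError("sites not sorted by scaffold order")
        same = np.diff(codes) == 0
        if np.any(np.diff(self.positions)[same] <= 0):
            raise ValueError("positions not strictly increasing within scaffold")

    # -- basic accessors -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.population_labels:
            seen.setdefault(p)
        return list(seen)

    def sample_indices(self, population: str) -> np.ndarray:
        if population not in self._pop_cache:
            idx = np.array(
                [i for i, p in enumerate(self.population_labels) if p == population],
                dtype=np.int64,
            )
            if idx.size == 0:
                raise KeyError(f"no samples with population label {population!r}")
            self._pop_cache[population] = idx
        return self._pop_cache[population]

    def scaffold_slice(self, scaffold: str) -> slice:
        """Index range of the sites on one scaffold."""
        hits = np.flatnonzero(self.site_scaffolds == scaffold)
        if hits.size == 0:
            return slice(0, 0)
        return slice(int(hits[0]), int(hits[-1]) + 1)

    def window_slice(self, window: Window) -> slice:
        sc = self.scaffold_slice(window.scaffold)
        pos = self.positions[sc]
        lo = int(np.searchsorted(pos, window.start, side="left"))
        hi = int(np.searchsorted(pos, window.end, side="left"))
        return slice(sc.start + lo, sc.start + hi)

    def allele_counts(self, population: str, sites: slice | np.ndarray = slice(None)):
        """(alt allele count, total non-missing allele count) per site."""
        g = self.genotypes[self.sample_indices(population)][:, sites]
        ok = g != MISSING
        alt = np.where(ok, g, 0).sum(axis=0)
        return alt.astype(np.int64), 2 * ok.sum(axis=0).astype(np.int64)

    # -- subsetting / combining ------------------------------------------

    def subset_sites(self, keep: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            sample_ids=self.sample_ids,
            population_labels=self.population_labels,
            scaffolds=dict(self.scaffolds),
            site_scaffolds=self.site_scaffolds[keep],
            positions=self.positions[keep],
            genotypes=self.genotypes[:, keep],
            depth=None if self.depth is None else self.depth[:, keep],
            gq=None if self.gq is None else self.gq[:, keep],
        )

    @staticmethod
    def concatenate(parts: list["GenotypeMatrix"]) -> "GenotypeMatrix":
        """Concatenate site-wise; all parts must share the sample layout."""
        if not parts:
            raise ValueError("nothing to concatenate")
        head = parts[0]
        for p in parts[1:]:
            if p.sample_ids != head.sample_ids:
                raise ValueError("sample layouts differ")
        scaffolds: dict[str, int] = {}
        for p in parts:
            for name, length in p.scaffolds.items():
                if scaffolds.setdefault(name, length) != length:
                    raise ValueError(f"conflicting lengths for scaffold {name}")
        has_dp = all(p.depth is not None for p in parts)
        has_gq = all(p.gq is not None for p in parts)
        return GenotypeMatrix(
            sample_ids=head.sample_ids,
            population_labels=head.population_labels,
            scaffolds=scaffolds,
            site_scaffolds=np.concatenate([p.site_scaffolds for p in parts]),
            positions=np.concatenate([p.positions for p in parts]),
            genotypes=np.concatenate([p.genotypes for p in parts], axis=1),
            depth=np.concatenate([p.depth for p in parts], axis=1) if has_dp else None,
            gq=np.concatenate([p.gq for p in parts], axis=1) if has_gq else None,
        )


@dataclass
class FilterConfig:
    """Site/genotype filter thresholds.

    Defaults follow the scan conventions for high-coverage resequencing
    panels: genotypes below DP 10 or GQ 30 are set missing, sites below
    minor-allele frequency 0.025 or above 5% missingness are dropped, and
    scaffolds shorter than 1 Mb are excluded.
    """

    min_gq: int = 30
    min_dp: int = 10
    min_maf: float = 0.025
    max_missing_fraction: float = 0.05
    min_scaffold_length: int = 1_000_000
    require_complete: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.max_missing_fraction <= 1:
            raise ValueError("max_missing_fraction must be in [0, 1]")
        for name in ("min_gq", "min_dp", "min_maf", "min_scaffold_length"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def apply_filters(gm: GenotypeMatrix, cfg: FilterConfig) -> GenotypeMatrix:
    """Apply filters in the fixed order genotype -> site -> scaffold.

    1. genotype level: calls with DP < min_dp or GQ < min_gq become missing;
    2. site level: MAF (on non-missing alleles) then missingness, then the
       optional require_complete rule;
    3. scaffold level: scaffolds shorter than min_scaffold_length dropped.
    """
    g = gm.genotypes.copy()
    n_masked = 0
    if cfg.min_dp > 0 and gm.depth is not None:
        bad = (gm.depth >= 0) & (gm.depth < cfg.min_dp)
        n_masked += int(np.sum(bad & (g != MISSING)))
        g[bad] = MISSING
    if cfg.min_gq > 0 and gm.gq is not None:
        bad = (gm.gq >= 0) & (gm.gq < cfg.min_gq)
        n_masked += int(np.sum(bad & (g != MISSING)))
        g[bad] = MISSING
    work = replace(gm, genotypes=g, _pop_cache={})

    ok = g != MISSING
    n_alleles = 2 * ok.sum(axis=0)
    alt = np.where(ok, g, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), 0.0)
    maf = np.minimum(p, 1.0 - p)
    keep = np.ones(gm.n_sites, dtype=bool)
    keep &= n_alleles > 0
    if cfg.min_maf > 0:
        keep &= maf >= cfg.min_maf
    n_maf = int(np.sum(~keep))
    n_missing = gm.n_samples - ok.sum(axis=0)
    # integer-count comparison avoids float boundary artifacts at e.g. 1/20
    keep_miss = n_missing <= cfg.max_missing_fraction * gm.n_samples + 1e-9
    if cfg.require_complete:
        keep_miss &= n_missing == 0
    n_miss = int(np.sum(keep & ~keep_miss))
    keep &= keep_miss

    short = {s for s, ln in gm.scaffolds.items() if ln < cfg.min_scaffold_length}
    if short:
        on_short = np.array([s in short for s in gm.site_scaffolds])
        n_scaf = int(np.sum(keep & on_short))
        keep &= ~on_short
    else:
        n_scaf = 0

    out = work.subset_sites(np.flatnonzero(keep))
    out.scaffolds = {
        s: ln for s, ln in gm.scaffolds.items() if ln >= cfg.min_scaffold_length
    }
    log.info(
        "filters: %d genotypes masked (DP/GQ); sites dropped: %d MAF, "
        "%d missingness, %d short-scaffold; %d of %d sites retained",
        n_masked, n_maf, n_miss, n_scaf, out.n_sites, gm.n_sites,
    )
    if out.n_sites == 0:
        log.warning("all sites removed by filtering")
    return out


def tile_windows(
    scaffold_lengths: dict[str, int], window_size: int = 50_000, step: int = 10_000
) -> list[Window]:
    """Sliding windows per scaffold: starts at 0, step, 2*step, ...

    Full windows only, plus one terminal partial window when it is at least
    half a window long (flagged ``partial``).  A scaffold shorter than one
    window yields a single window covering the whole scaffold.
    """
    if not (window_size >= step >= 1):
        raise ValueError("require window_size >= step >= 1")
    out: list[Window] = []
    for scaffold, length in scaffold_lengths.items():
        if length <= 0:
            raise ValueError(f"scaffold {scaffold} has non-positive length")
        if length < window_size:
            out.append(Window(scaffold, 0, length, partial=length < window_size))
            continue
        n_full = (length - window_size) // step + 1
        for k in range(n_full):
            out.append(Window(scaffold, k * step, k * step + window_size))
        tail_start = n_full * step
        tail = length - tail_start
        last_full_end = (n_full - 1) * step + window_size
        needed_for_coverage = length > last_full_end
        if 0 < tail < window_size and (
            tail >= (window_size + 1) // 2 or needed_for_coverage
        ):
            out.append(Window(scaffold, tail_start, length, partial=True))
    return out


def genotype_pca(gm: GenotypeMatrix, n_components: int = 10):
    """Variance-standardized genotype PCA (plink-style).

    Each site is centered by twice its allele frequency and scaled by
    ``sqrt(2 p (1-p))``; missing calls are mean-imputed (with a warning).
    Returns (coordinates, explained variance fractions).
    """
    from sklearn.decomposition import PCA

    if gm.n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    g = gm.genotypes.astype(float)
    miss = g == MISSING
    if miss.any():
        log.warning("PCA input has %d missing calls; mean-imputing", int(miss.sum()))
        g[miss] = np.nan
        col_mean = np.nanmean(g, axis=0)
        g = np.where(np.isnan(g), col_mean, g)
    p = g.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("no polymorphic sites for PCA")
    g = g[:, poly]
    p = p[poly]
    z = (g - 2 * p) / np.sqrt(2 * p * (1 - p))
    n_components = min(n_components, gm.n_samples - 1, z.shape[1])
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(z)
    return coords, pca.explained_variance_ratio_


# -- VCF / TSV I/O -------------------------------------------------------


def read_population_map(path) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sample, pop = line.split("\t")[:2]
            out[sample] = pop
    return out


def read_scaffold_lengths(path) -> dict[str, int]:
    out: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, length = line.split("\t")[:2]
            out[name] = int(length)
    return out


def write_scaffold_lengths(scaffolds: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for name, length in scaffolds.items():
            fh.write(f"{name}\t{length}\n")


def read_vcf(
    path, population_map: dict[str, str], scaffold_lengths: dict[str, int] | None = None
) -> GenotypeMatrix:
    """Load biallelic SNPs from a VCF into a :class:`GenotypeMatrix`.

    Indels and multiallelic records are skipped (counted in the log).  VCF
    1-based positions become 0-based.  Scaffold lengths come from the
    contig header unless ``scaffold_lengths`` overrides them.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    missing_pop = [s for s in samples if s not in population_map]
    if missing_pop:
        raise ValueError(f"samples absent from population map: {missing_pop}")
    if scaffold_lengths is None:
        scaffold_lengths = dict(zip(vcf.seqnames, vcf.seqlens))

    scafs: list[str] = []
    poss: list[int] = []
    gts: list[np.ndarray] = []
    dps: list[np.ndarray] = []
    gqs: list[np.ndarray] = []
    n_skipped = 0
    header_fmt = {
        h.info().get("ID")
        for h in vcf.header_iter()
        if h.type == "FORMAT"
    }
    has_dp = "DP" in header_fmt
    has_gq = "GQ" in header_fmt
    bases = {"A", "C", "G", "T"}
    for v in vcf:
        if len(v.ALT) != 1 or v.REF not in bases or v.ALT[0] not in bases:
            n_skipped += 1
            continue
        scafs.append(v.CHROM)
        poss.append(v.POS - 1)
        gt = v.gt_types.astype(np.int8)  # 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        gt[gt == 3] = MISSING
        gts.append(gt)
        if has_dp:
            dp = v.format("DP")
            if dp is None:
                has_dp = False
            else:
                dp = dp.reshape(-1).astype(np.int32)
                dp[dp < 0] = -1
                dps.append(dp)
        if has_gq:
            gq = v.format("GQ")
            if gq is None:
                has_gq = False
            else:
                gq = gq.reshape(-1).astype(np.int32)
                gq[gq < 0] = -1
                gqs.append(gq)
    if n_skipped:
        log.info("read_vcf: skipped %d non-biallelic-SNP records", n_skipped)

    seen = {s: None for s in scafs}
    scaffolds = {s: int(scaffold_lengths[s]) for s in seen}
    return GenotypeMatrix(
        sample_ids=samples,
        population_labels=[population_map[s] for s in samples],
        scaffolds=scaffolds,
        site_scaffolds=np.array(scafs, dtype=object),
        positions=np.array(poss, dtype=np.int64),
        genotypes=np.array(gts, dtype=np.int8).T
        if gts
        else np.zeros((len(samples), 0), np.int8),
        depth=np.array(dps, np.int32).T if (has_dp and dps) else None,
        gq=np.array(gqs, np.int32).T if (has_gq and gqs) else None,
    )


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a minimal VCF 4.2 (synthetic REF=A / ALT=T alleles)."""
    with open(str(path), "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=tigerscan\n")
        for name, length in gm.scaffolds.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fmt = "GT"
        if gm.depth is not None:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
            fmt += ":DP"
        if gm.gq is not None:
            fh.write(
                '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n'
            )
            fmt += ":GQ"
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.sample_ids)
            + "\n"
        )
        for j in range(gm.n_sites):
            cells = []
            for i in range(gm.n_samples):
                cell = _GT_STR[int(gm.genotypes[i, j])]
                if gm.depth is not None:
                    cell += f":{gm.depth[i, j]}" if gm.depth[i, j] >= 0 else ":."
                if gm.gq is not None:
                    cell += f":{gm.gq[i, j]}" if gm.gq[i, j] >= 0 else ":."
                cells.append(cell)
            fh.write(
                f"{gm.site_scaffolds[j]}\t{gm.positions[j] + 1}\t.\tA\tT\t.\tPASS\t.\t{fmt}\t"
                + "\t".join(cells)
                + "\n"
            )
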