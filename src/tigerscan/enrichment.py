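"""Candidate-gene mapping and GO-term over-representation tests.

Outlier windows map to genes whose span, extended by flanking sequence
(50 kb by default, clipped at scaffold bounds), intersects any outlier
window.  Homolog annotations are deduplicated first: within a scaffold and
strand, records are taken in coordinate order and any record overlapping
its predecessor is ignored, and only the first record of each homolog
group is kept.  Per GO term a one-sided (over-representation) Fisher's
exact test is run on the 2x2 table (candidate/term membership) against the
full post-dedup gene list as background, with Benjamini-Hochberg
adjustment across tested terms.  GO hierarchy propagation is NOT
performed; the term map is taken as given.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .variants import Window

__all__ = [
    "GeneAnnotation",
    "EnrichmentResult",
    "dedup_annotation",
    "map_windows_to_genes",
    "fisher_enrichment",
    "read_genes_bed",
    "write_genes_bed",
    "read_term_map",
]


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    scaffold: str
    start: int  # 0-based half-open
    end: int
    strand: str = "+"
    homolog_group: str | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"{self.gene_id}: end must exceed start")
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")

    @property
    def group(self) -> str:
        return self.homolog_group or self.gene_id


@dataclass
class EnrichmentResult:
    term_id: str
    candidate_hits: int
    candidate_size: int
    background_hits: int
    background_size: int
    p_value: float
    adjusted_p: float = float("nan")


def dedup_annotation(genes: list[GeneAnnotation]) -> list[GeneAnnotation]:
    """One record per homolog group; overlap chains collapse to their first.

    Records are processed in coordinate order per (scaffold, strand); a
    record overlapping the previous record in that order is dropped even
    if the previous record was itself dropped (so an overlap chain leaves
    exactly one survivor).
    """
    kept: list[GeneAnnotation] = []
    seen_groups: set[str] = set()
    by_key: dict[tuple[str, str], list[GeneAnnotation]] = {}
    for g in genes:
        by_key.setdefault((g.scaffold, g.strand), []).append(g)
    for key in sorted(by_key):
        group = sorted(by_key[key], key=lambda g: (g.start, g.end, g.gene_id))
        prev_end = -1
        for g in group:
            overlaps_prev = g.start < prev_end
            prev_end = max(prev_end, g.end)
            if overlaps_prev:
                continue
            if g.group in seen_groups:
                continue
            seen_groups.add(g.group)
            kept.append(g)
    kept.sort(key=lambda g: (g.scaffold, g.start, g.end))
    return kept


def map_windows_to_genes(
    windows: list[Window],
    genes: list[GeneAnnotation],
    flank: int = 50_000,
    scaffold_lengths: dict[str, int] | None = None,
) -> set[str]:
    """Gene ids whose flank-extended span intersects any outlier window."""
    trees: dict[str, IntervalTree] = {}
    for w in windows:
        trees.setdefault(w.scaffold, IntervalTree()).addi(w.start, w.end)
    out: set[str] = set()
    for g in genes:
        tree = trees.get(g.scaffold)
        if tree is None:
            continue
        lo = max(0, g.start - flank)
        hi = g.end + flank
        if scaffold_lengths and g.scaffold in scaffold_lengths:
            hi = min(hi, scaffold_lengths[g.scaffold])
        if tree.overlap(lo, hi):
            out.add(g.gene_id)
    return out


def fisher_enrichment(
    candidates: set[str],
    background: set[str],
    term_map: dict[str, set[str]],
    min_term_size: int = 1,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """One-sided Fisher over-representation test per term, BH-adjusted.

    ``term_map`` maps term id -> gene ids; genes without terms still count
    in the totals.  Terms with fewer than ``min_term_size`` background
    genes are skipped.  Results are sorted by raw p-value.
    """
    stray = candidates - background
    if stray:
        raise ValueError(f"candidate genes absent from background: {sorted(stray)[:5]}")
    if not candidates:
        return []
    n_bg = len(background)
    n_cand = len(candidates)
    results: list[EnrichmentResult] = []
    for term in sorted(term_map):
        members = term_map[term] & background
        bg_hits = len(members)
        if bg_hits < min_term_size:
            continue
        cand_hits = len(members & candidates)
        table = [
            [cand_hits, n_cand - cand_hits],
            [bg_hits - cand_hits, (n_bg - n_cand) - (bg_hits - cand_hits)],
        ]
        _, p = fisher_exact(table, alternative="greater")
        results.append(
            EnrichmentResult(term, cand_hits, n_cand, bg_hits, n_bg, float(p))
        )
    if results:
        _, adj, _, _ = multipletests([r.p_value for r in results], alpha=alpha, method="fdr_bh")
        for r, a in zip(results, adj):
            r.adjusted_p = float(a)
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return results


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term_id": r.term_id,
                "candidate_hits": r.candidate_hits,
                "candidate_size": r.candidate_size,
                "background_hits": r.background_hits,
                "background_size": r.background_size,
                "p_value": r.p_value,
                "adjusted_p": r.adjusted_p,
            }
            for r in results
        ]
    )


# -- I/O -----------------------------------------------------------------


def read_genes_bed(path) -> list[GeneAnnotation]:
    """BED6(+1): scaffold, start, end, gene_id, score, strand[, homolog_group]."""
    out = []
    with open(str(path)) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            out.append(
                GeneAnnotation(
                    gene_id=f[3] if len(f) > 3 else f"{f[0]}:{f[1]}-{f[2]}",
                    scaffold=f[0],
                    start=int(f[1]),
                    end=int(f[2]),
                    strand=f[5] if len(f) > 5 else ".",
                    homolog_group=f[6] if len(f) > 6 else None,
                )
            )
    return out


def write_genes_bed(genes: list[GeneAnnotation], path) -> None:
    with open(str(path), "w") as fh:
        for g in genes:
            fh.write(
                f"{g.scaffold}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\t{g.group}\n"
            )


def read_genes_gff(path, feature_type: str = "gene") -> list[GeneAnnotation]:
    """Gene records from a GFF3 file (via gffutils; 1-based closed -> 0-based
    half-open).  The homolog group comes from a ``homolog_group`` attribute
    when present, else the gene id."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    out = []
    for f in db.features_of_type(feature_type, order_by=("seqid", "start")):
        gene_id = f.attributes.get("ID", [f.id])[0]
        group = f.attributes.get("homolog_group", [None])[0]
        out.append(
            GeneAnnotation(
                gene_id=gene_id,
                scaffold=f.seqid,
                start=f.start - 1,
                end=f.end,
                strand=f.strand if f.strand in {"+", "-"} else ".",
                homolog_group=group,
            )
        )
    return out


def read_term_map(path) -> dict[str, set[str]]:
    """2-column TSV (gene_id, term_id) -> term -> genes."""
    out: dict[str, set[str]] = {}
    with open(str(path)) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            gene, term = line.split("\t")[:2]
            out.setdefault(term, set()).add(gene)
    return out


def write_term_map(term_map: dict[str, set[str]], path) -> None:
    with open(str(path), "w") as fh:
        for term in sorted(term_map):
            for gene in sorted(term_map[term]):
                fh.write(f"{gene}\t{term}\n")
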