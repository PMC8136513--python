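"""End-to-end scan orchestration: filter -> windows -> FST -> mPBS ->
null -> outliers -> genes -> enrichment, with per-stage logging and
reproducible outputs.

Every stage is a pure function of (inputs, config, seed); re-running on
identical inputs reproduces all output files byte for byte.  The run
report records the full effective configuration, library versions, seeds
and record counts at each filter stage, so every run is self-describing.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import __version__
from .coalsim import load_model
from .enrichment import (
    dedup_annotation,
    enrichment_table,
    fisher_enrichment,
    map_windows_to_genes,
    read_genes_bed,
    read_term_map,
)
from .selscan import mpbs_track, null_mpbs_distribution, null_quantiles, outlier_windows
from .variants import (
    FilterConfig,
    Window,
    apply_filters,
    read_population_map,
    read_scaffold_lengths,
    read_vcf,
    tile_windows,
)

log = logging.getLogger(__name__)

FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Configuration of one scan run (YAML-serializable)."""

    vcf: str
    popmap: str
    out_dir: str
    scaffolds: str | None = None
    genes: str | None = None
    go_map: str | None = None
    filters: FilterConfig = field(
        default_factory=lambda: FilterConfig(require_complete=True)
    )
    window_size: int = 50_000
    step: int = 10_000
    min_sites: int = 10
    top_fraction: float = 0.001
    flank: int = 50_000
    min_term_size: int = 1
    null_model: str | None = None
    n_null_windows: int = 0
    seed: int = 0

    def validate(self) -> None:
        for name in ("vcf", "popmap"):
            path = getattr(self, name)
            if not path or not os.path.exists(path):
                raise ValueError(f"missing input file for field {name!r}: {path}")
        for name in ("scaffolds", "genes", "go_map", "null_model"):
            path = getattr(self, name)
            if path and not os.path.exists(path):
                raise ValueError(f"missing input file for field {name!r}: {path}")

    @staticmethod
    def from_yaml(path: str) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        filt = doc.pop("filters", {})
        return RunConfig(filters=FilterConfig(**filt), **doc)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _write_tsv(frame, path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def run_scan(cfg: RunConfig) -> dict:
    """Execute the full genome scan; returns a result bundle.

    Writes, under ``cfg.out_dir``: the windowed statistic track
    (``mpbs_track.tsv``), per-population outlier BEDs, candidate-gene
    lists, enrichment tables, optional null quantiles, a run log and a
    YAML run report.
    """
    cfg.validate()
    os.makedirs(cfg.out_dir, exist_ok=True)
    handler = logging.FileHandler(os.path.join(cfg.out_dir, "run.log"), mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("tigerscan")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    report: dict = {
        "tigerscan_version": __version__,
        "numpy_version": np.__version__,
        "config": cfg.to_dict(),
        "stages": {},
    }
    try:
        popmap = read_population_map(cfg.popmap)
        scaffold_lengths = (
            read_scaffold_lengths(cfg.scaffolds) if cfg.scaffolds else None
        )
        gm = read_vcf(cfg.vcf, popmap, scaffold_lengths)
        log.info("loaded %d samples x %d sites", gm.n_samples, gm.n_sites)
        report["stages"]["load"] = {"samples": gm.n_samples, "sites": gm.n_sites}

        gm = apply_filters(gm, cfg.filters)
        report["stages"]["filter"] = {"sites": gm.n_sites}
        if gm.n_sites == 0 or not gm.scaffolds:
            raise ValueError(
                "no sites survive filtering; check min_scaffold_length and "
                "the genotype/site thresholds against the input data"
            )

        populations = gm.populations
        if len(populations) != 4:
            raise ValueError(
                f"the mPBS scan requires exactly 4 populations, got {populations}"
            )
        windows = tile_windows(gm.scaffolds, cfg.window_size, cfg.step)
        report["stages"]["windows"] = {"n_windows": len(windows)}

        track = mpbs_track(gm, populations, windows, cfg.min_sites)
        _write_tsv(track, os.path.join(cfg.out_dir, "mpbs_track.tsv"))
        n_missing = int(track[f"mpbs_{populations[0]}"].isna().sum())
        report["stages"]["track"] = {"windows": len(track), "missing": n_missing}

        outliers: dict[str, list[Window]] = {}
        for pop in populations:
            ws = outlier_windows(track, pop, cfg.top_fraction)
            outliers[pop] = ws
            with open(
                os.path.join(cfg.out_dir, f"outliers_{pop}.bed"), "w"
            ) as fh:
                for w in ws:
                    fh.write(f"{w.scaffold}\t{w.start}\t{w.end}\t{pop}\n")
        report["stages"]["outliers"] = {p: len(ws) for p, ws in outliers.items()}

        candidates: dict[str, set[str]] = {}
        enrichments: dict[str, list] = {}
        if cfg.genes:
            genes = dedup_annotation(read_genes_bed(cfg.genes))
            report["stages"]["genes"] = {"post_dedup": len(genes)}
            background = {g.gene_id for g in genes}
            term_map = read_term_map(cfg.go_map) if cfg.go_map else {}
            for pop in populations:
                cand = map_windows_to_genes(
                    outliers[pop], genes, cfg.flank, gm.scaffolds
                )
                candidates[pop] = cand
                with open(
                    os.path.join(cfg.out_dir, f"candidates_{pop}.txt"), "w"
                ) as fh:
                    fh.write("".join(f"{g}\n" for g in sorted(cand)))
                if term_map:
                    res = fisher_enrichment(
                        cand, background, term_map, cfg.min_term_size
                    )
                    enrichments[pop] = res
                    _write_tsv(
                        enrichment_table(res),
                        os.path.join(cfg.out_dir, f"enrichment_{pop}.tsv"),
                    )
            report["stages"]["candidates"] = {
                p: len(c) for p, c in candidates.items()
            }

        null = None
        if cfg.null_model and cfg.n_null_windows > 0:
            model = load_model(cfg.null_model)
            null = null_mpbs_distribution(
                model, cfg.n_null_windows, cfg.window_size, cfg.seed, cfg.min_sites
            )
            _write_tsv(
                null_quantiles(null),
                os.path.join(cfg.out_dir, "null_quantiles.tsv"),
            )
            from scipy.stats import ks_2samp

            ks = {}
            for pop in populations:
                obs = track[f"mpbs_{pop}"].dropna().to_numpy()
                if len(obs) and len(null.get(pop, [])):
                    ks[pop] = float(ks_2samp(obs, null[pop]).pvalue)
            report["stages"]["null"] = {
                "n_windows": cfg.n_null_windows,
                "ks_pvalues": ks,
            }

        with open(os.path.join(cfg.out_dir, "run_report.yaml"), "w") as fh:
            yaml.safe_dump(report, fh, sort_keys=False)
        return {
            "genotypes": gm,
            "track": track,
            "outliers": outliers,
            "candidates": candidates,
            "enrichments": enrichments,
            "null": null,
            "report": report,
        }
    except Exception:
        log.exception("scan aborted")
        raise
    finally:
        root.removeHandler(handler)
        handler.close()
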