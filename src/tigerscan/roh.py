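"""Rule-based runs-of-homozygosity detection and length-class accounting.

A transparent sliding-window rule stands in for HMM-based autozygosity
callers: every window of ``window_sites`` consecutive (non-missing) sites
with at most ``max_het_per_window`` heterozygous calls marks its sites as
run-supporting; maximal stretches of marked sites, trimmed to their
outermost homozygous sites, become segments.  Absolute ROH calls are
method-dependent; the length-class *proportions* follow the
subtraction-denominator convention:

    prop(>1 Mb)        = L(>1 Mb) / A
    prop(100 kb-1 Mb)  = L(100 kb-1 Mb) / (A - L(>1 Mb))
    prop(10-100 kb)    = L(10-100 kb) / (A - L(>100 kb))

with A the total autosome length.  Reporting classes (>2 Mb, 1-2 Mb,
100 kb-1 Mb, total >100 kb) are split out at reporting time only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .variants import MISSING, GenotypeMatrix

__all__ = ["ROHSegment", "ROHSummary", "detect_roh", "classify_roh", "roh_table"]


@dataclass
class ROHSegment:
    sample_id: str
    scaffold: str
    start: int  # 0-based half-open span of outermost homozygous sites
    end: int
    n_sites: int  # homozygous sites supporting the run

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("segment end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ROHSummary:
    sample_id: str
    autosome_length: int
    class_lengths: dict[str, int] = field(default_factory=dict)
    class_proportions: dict[str, float] = field(default_factory=dict)


def _mark_sites(het: np.ndarray, window_sites: int, max_het: int) -> np.ndarray:
    """Union of qualifying sliding windows over the site index."""
    n = len(het)
    if n == 0:
        return np.zeros(0, dtype=bool)
    w = min(window_sites, n)
    csum = np.concatenate([[0], np.cumsum(het.astype(np.int64))])
    marked = np.zeros(n, dtype=bool)
    # window starting at i covers sites [i, i+w)
    counts = csum[w:] - csum[:-w]
    good = np.flatnonzero(counts <= max_het)
    for i in good:
        marked[i : i + w] = True
    return marked


def detect_roh(
    gm: GenotypeMatrix,
    sample_id: str,
    max_het_per_window: int = 1,
    window_sites: int = 50,
    min_length: int = 10_000,
) -> list[ROHSegment]:
    """Homozygous runs for one individual, per scaffold.

    Deterministic; segments span the outermost supporting homozygous
    sites and segments shorter than ``min_length`` bp are dropped.
    """
    try:
        s = gm.sample_ids.index(sample_id)
    except ValueError:
        raise KeyError(f"no sample {sample_id!r}") from None
    out: list[ROHSegment] = []
    for scaffold in gm.scaffolds:
        sl = gm.scaffold_slice(scaffold)
        g = gm.genotypes[s, sl]
        pos = gm.positions[sl]
        ok = g != MISSING
        g = g[ok]
        pos = pos[ok]
        if len(g) < 2:
            continue
        het = g == 1
        marked = _mark_sites(het, window_sites, max_het_per_window)
        # maximal runs of marked sites
        edges = np.diff(marked.astype(np.int8))
        starts = list(np.flatnonzero(edges == 1) + 1)
        ends = list(np.flatnonzero(edges == -1) + 1)
        if marked[0]:
            starts.insert(0, 0)
        if marked[-1]:
            ends.append(len(marked))
        for i, j in zip(starts, ends):
            hom = np.flatnonzero(~het[i:j]) + i
            if len(hom) < 2:
                continue
            lo, hi = int(pos[hom[0]]), int(pos[hom[-1]]) + 1
            if hi - lo >= min_length:
                out.append(ROHSegment(sample_id, scaffold, lo, hi, len(hom)))
    return out


_METHOD_CLASSES = (
    ("gt_1mb", 1_000_000, None),
    ("100kb_1mb", 100_000, 1_000_000),
    ("10_100kb", 10_000, 100_000),
)
_REPORT_CLASSES = (
    ("gt_2mb", 2_000_000, None),
    ("1_2mb", 1_000_000, 2_000_000),
    ("100kb_1mb", 100_000, 1_000_000),
)


def classify_roh(segments: list[ROHSegment], autosome_length: int) -> ROHSummary:
    """Per-individual length-class totals and proportions.

    Segments must be non-overlapping within each scaffold (a violation
    indicates an upstream bug and raises).
    """
    if autosome_length <= 0:
        raise ValueError("autosome_length must be > 0")
    sample_ids = {s.sample_id for s in segments}
    if len(sample_ids) > 1:
        raise ValueError("segments from more than one individual")
    by_scaffold: dict[str, list[ROHSegment]] = {}
    for s in segments:
        by_scaffold.setdefault(s.scaffold, []).append(s)
    for group in by_scaffold.values():
        group.sort(key=lambda s: s.start)
        for a, b in zip(group, group[1:]):
            if b.start < a.end:
                raise ValueError("overlapping ROH segments")

    def total(lo: int, hi: int | None) -> int:
        return sum(
            s.length for s in segments if s.length >= lo and (hi is None or s.length < hi)
        )

    lengths: dict[str, int] = {}
    for name, lo, hi in _METHOD_CLASSES:
        lengths[name] = total(lo, hi)
    for name, lo, hi in _REPORT_CLASSES:
        lengths[name] = total(lo, hi)
    lengths["total_gt_100kb"] = total(100_000, None)

    a = float(autosome_length)

    def ratio(num: int, den: float) -> float:
        return num / den if den > 0 else 0.0

    props = {
        "gt_1mb": ratio(lengths["gt_1mb"], a),
        "100kb_1mb": ratio(lengths["100kb_1mb"], a - lengths["gt_1mb"]),
        "10_100kb": ratio(lengths["10_100kb"], a - lengths["total_gt_100kb"]),
    }
    return ROHSummary(
        sample_id=next(iter(sample_ids), ""),
        autosome_length=autosome_length,
        class_lengths=lengths,
        class_proportions=props,
    )


def write_segments_bed(segments: list[ROHSegment], path) -> None:
    """BED4: scaffold, start, end, supporting-site count."""
    with open(str(path), "w") as fh:
        for s in sorted(segments, key=lambda s: (s.scaffold, s.start)):
            fh.write(f"{s.scaffold}\t{s.start}\t{s.end}\t{s.n_sites}\n")


def roh_table(summaries: list[ROHSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {"sample": s.sample_id, "autosome_length": s.autosome_length}
        for k, v in s.class_lengths.items():
            row[f"len_{k}"] = v
        for k, v in s.class_proportions.items():
            row[f"prop_{k}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
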