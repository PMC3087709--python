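"""Tiling-array ChIP-chip peak calling and binding-region assembly.

The peak rule is deliberately simple and threshold-based, reproducing the
classical two-colour tiling-array analysis: a binding site is called when at
least ``min_run`` consecutive probes exceed the per-hybridisation mean by
``k_sd`` standard deviations, is reproducible across at least
``min_replicates`` experiments, and is absent from the empty-vector control
immunoprecipitation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from glnreg.genome import Gene, GenomeAnnotation, ProbeTrack

logger = logging.getLogger(__name__)


@dataclass
class PeakCallParams:
    """Parameters of the threshold peak rule.

    k_sd
        Threshold multiplier: probes must exceed mean + k_sd * sd of all
        probe values of the hybridisation (default 2.5).
    min_run
        Minimum number of consecutive qualifying probes (default 2).
    min_replicates
        Minimum number of distinct experiments a peak must appear in
        (default 2).
    max_probe_gap_bp
        Maximum genomic centre-to-centre gap between adjacent run members;
        ``None`` means twice the track's median probe spacing, so array
        coverage gaps cannot bridge unrelated probes.
    use_log_ratio
        Compute mean/sd and compare on log2 ratios instead of linear ratios.
    pooled
        Pool all supplied tracks when computing the threshold instead of the
        default per-hybridisation mean/sd.
    """

    k_sd: float = 2.5
    min_run: int = 2
    min_replicates: int = 2
    max_probe_gap_bp: int | None = None
    use_log_ratio: bool = False
    pooled: bool = False

    def __post_init__(self) -> None:
        if self.k_sd <= 0:
            raise ValueError("k_sd must be > 0")
        if self.min_run < 1:
            raise ValueError("min_run must be >= 1")
        if self.min_replicates < 1:
            raise ValueError("min_replicates must be >= 1")


@dataclass(frozen=True)
class Peak:
    """A maximal qualifying probe run in one hybridisation."""

    replicon: str
    start: int
    end: int
    max_ratio: float
    n_probes: int
    replicate_id: str
    timepoint: str

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValueError("peak must have end > start")

    def overlaps(self, other: "Peak | BindingRegion") -> bool:
        return (self.replicon == other.replicon
                and self.start < other.end and other.start < self.end)


@dataclass
class BindingRegion:
    """A replicate-merged, control-filtered binding interval."""

    replicon: str
    start: int
    end: int
    supporting_replicates: frozenset[str]
    timepoints: frozenset[str]
    present_in_control: bool = False
    intergenic: bool | None = None
    target_gene_ids: list[str] = field(default_factory=list)
    max_ratio: float = float("nan")
    region_id: str = ""

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps_interval(self, replicon: str, start: int, end: int) -> bool:
        return (self.replicon == replicon
                and self.start < end and start < self.end)


def _track_values(track: ProbeTrack, params: PeakCallParams) -> np.ndarray:
    return np.log2(track.ratio) if params.use_log_ratio else track.ratio


def track_threshold(track: ProbeTrack, params: PeakCallParams | None = None,
                    pooled_tracks: Sequence[ProbeTrack] | None = None) -> float:
    """Per-hybridisation calling threshold: mean + k_sd * sd of all probes.

    The sample (n-1) standard deviation is used.  With ``params.pooled`` and
    ``pooled_tracks`` given, mean/sd are computed over the concatenated
    values of all supplied tracks instead.
    """
    params = params or PeakCallParams()
    if len(track) < 2:
        raise ValueError("track_threshold requires >= 2 probes")
    if params.pooled and pooled_tracks:
        values = np.concatenate([_track_values(t, params)
                                 for t in pooled_tracks])
    else:
        values = _track_values(track, params)
    return float(values.mean() + params.k_sd * values.std(ddof=1))


def call_peaks_single(track: ProbeTrack,
                      params: PeakCallParams | None = None,
                      threshold: float | None = None) -> list[Peak]:
    """Call peaks on a single hybridisation.

    A peak is a maximal run of probes that are consecutive in track order,
    genomically close (gap between successive probe midpoints at most
    ``max_probe_gap_bp``), and whose value exceeds the threshold; runs
    shorter than ``min_run`` are discarded.
    """
    params = params or PeakCallParams()
    if threshold is None:
        threshold = track_threshold(track, params)
    values = _track_values(track, params)
    max_gap = params.max_probe_gap_bp
    if max_gap is None:
        max_gap = 2 * track.median_spacing() if len(track) >= 2 else np.inf

    peaks: list[Peak] = []
    run: list[int] = []

    def flush() -> None:
        if len(run) >= params.min_run:
            first, last = track.probes[run[0]], track.probes[run[-1]]
            peaks.append(Peak(
                replicon=first.replicon, start=first.start, end=last.end,
                max_ratio=float(track.ratio[run].max()),
                n_probes=len(run),
                replicate_id=track.replicate_id,
                timepoint=track.timepoint_label))
        run.clear()

    for i, above in enumerate(values > threshold):
        if not above:
            flush()
            continue
        if run:
            prev = track.probes[run[-1]]
            cur = track.probes[i]
            if (cur.replicon != prev.replicon
                    or cur.midpoint - prev.midpoint > max_gap):
                flush()
        run.append(i)
    flush()
    return peaks


def _cluster_overlap(items: Sequence[tuple[str, Peak]]
                     ) -> list[list[tuple[str, Peak]]]:
    """Single-linkage clustering of labelled peaks on >=1 bp genomic overlap."""
    clusters: list[list[tuple[str, Peak]]] = []
    for label, peak in sorted(items,
                              key=lambda lp: (lp[1].replicon, lp[1].start,
                                              lp[1].end, lp[0])):
        if clusters:
            last = clusters[-1]
            rep = last[0][1].replicon
            right = max(p.end for _, p in last)
            if peak.replicon == rep and peak.start < right:
                last.append((label, peak))
                continue
        clusters.append([(label, peak)])
    return clusters


def merge_replicates(peaksets: Mapping[str, Sequence[Peak]],
                     control_peaks: Sequence[Peak] = (),
                     params: PeakCallParams | None = None,
                     ) -> tuple[list[BindingRegion], list[BindingRegion]]:
    """Merge per-experiment peak sets into reproducible binding regions.

    ``peaksets`` maps an experiment label (e.g. replicate id, or
    ``rep:timepoint``) to its peaks.  Peaks are clustered by single-linkage
    >=1 bp overlap; clusters supported by at least ``min_replicates``
    distinct labels are kept.  Any cluster overlapping a control peak is
    marked ``present_in_control`` and moved to the diagnostics list instead
    of the reported set.

    Returns ``(reported, control_filtered)``.
    """
    params = params or PeakCallParams()
    labelled: list[tuple[str, Peak]] = [
        (label, p) for label, peaks in peaksets.items() for p in peaks]
    clusters = _cluster_overlap(labelled)

    reported: list[BindingRegion] = []
    filtered: list[BindingRegion] = []
    for cluster in clusters:
        labels = frozenset(label for label, _ in cluster)
        if len(labels) < params.min_replicates:
            continue
        peaks_in = [p for _, p in cluster]
        region = BindingRegion(
            replicon=peaks_in[0].replicon,
            start=min(p.start for p in peaks_in),
            end=max(p.end for p in peaks_in),
            supporting_replicates=labels,
            timepoints=frozenset(p.timepoint for p in peaks_in),
            max_ratio=max(p.max_ratio for p in peaks_in))
        in_control = any(
            c.replicon == region.replicon
            and c.start < region.end and region.start < c.end
            for c in control_peaks)
        region.present_in_control = in_control
        (filtered if in_control else reported).append(region)
    for i, r in enumerate(reported, start=1):
        r.region_id = f"BR{i:03d}"
    return reported, filtered


def union_binding_regions(region_sets: Iterable[Sequence[BindingRegion]]
                          ) -> list[BindingRegion]:
    """Cross-timepoint union: merge overlapping regions into one row each.

    Supporting experiments, timepoints and targets are unioned; this
    reproduces the one-row-per-region, any-timepoint reporting style.
    """
    regions = [r for rs in region_sets for r in rs]
    merged: list[BindingRegion] = []
    for r in sorted(regions, key=lambda r: (r.replicon, r.start, r.end)):
        if merged and merged[-1].replicon == r.replicon \
                and r.start < merged[-1].end:
            m = merged[-1]
            m.end = max(m.end, r.end)
            m.supporting_replicates = m.supporting_replicates | \
                r.supporting_replicates
            m.timepoints = m.timepoints | r.timepoints
            m.target_gene_ids = sorted(set(m.target_gene_ids)
                                       | set(r.target_gene_ids))
            m.max_ratio = max(m.max_ratio, r.max_ratio) \
                if np.isfinite(m.max_ratio) else r.max_ratio
        else:
            merged.append(BindingRegion(
                replicon=r.replicon, start=r.start, end=r.end,
                supporting_replicates=r.supporting_replicates,
                timepoints=r.timepoints,
                present_in_control=r.present_in_control,
                intergenic=r.intergenic,
                target_gene_ids=list(r.target_gene_ids),
                max_ratio=r.max_ratio))
    for i, r in enumerate(merged, start=1):
        r.region_id = f"UR{i:03d}"
    return merged


# ---------------------------------------------------------------------------
# target assignment
# ---------------------------------------------------------------------------

def _nearest_downstream(region: BindingRegion,
                        genes: Sequence[Gene]) -> list[Gene]:
    """Promoter-proximal downstream gene(s) of a region.

    On each side the nearest gene is found (right: smallest start at or
    beyond the region start; left: largest end at or before the region end)
    and counted as a target only if its strand points away from the region,
    i.e. the region lies promoter-proximal upstream of it.  Divergent
    intergenic regions therefore yield two targets, tandem ones one, and
    convergent ones none.
    """
    targets: list[Gene] = []
    right = [g for g in genes if g.start >= region.start]
    if right:
        nearest = min(right, key=lambda g: (g.start, g.gene_id))
        if nearest.strand == "+":
            targets.append(nearest)
    left = [g for g in genes if g.end <= region.end]
    if left:
        nearest = max(left, key=lambda g: (g.end, g.gene_id))
        if nearest.strand == "-":
            targets.append(nearest)
    return targets


def assign_targets(regions: Iterable[BindingRegion],
                   annotation: GenomeAnnotation) -> list[BindingRegion]:
    """Annotate regions in place with intergenic status and downstream targets.

    A region is intergenic iff it overlaps no gene.  Targets are the genes
    immediately downstream of the region on each side whose strand points
    away from it (the region is upstream, promoter-proximal).  Regions with
    no target are kept and logged.
    """
    regions = list(regions)
    for region in regions:
        genes = annotation.genes_on(region.replicon)
        region.intergenic = not any(
            g.start < region.end and region.start < g.end for g in genes)
        if not region.intergenic:
            logger.info("region %s:%d-%d overlaps a gene",
                        region.replicon, region.start, region.end)
        targets = _nearest_downstream(region, genes)
        region.target_gene_ids = [g.gene_id for g in targets]
        if not targets:
            logger.info("region %s:%d-%d has no downstream target",
                        region.replicon, region.start, region.end)
    return regions


def count_binding_regions(regions: Iterable[BindingRegion]
                          ) -> tuple[int, pd.Series]:
    """Total number of regions plus a per-timepoint count table.

    A region supported at several timepoints counts once per timepoint in
    the table; the total counts each region once.
    """
    regions = list(regions)
    counts: dict[str, int] = {}
    for r in regions:
        for tp in sorted(r.timepoints):
            counts[tp] = counts.get(tp, 0) + 1
    return len(regions), pd.Series(counts, dtype=int).sort_index()


def regions_to_frame(regions: Iterable[BindingRegion]) -> pd.DataFrame:
    """Tabular report of binding regions (one row per region)."""
    rows = []
    for r in regions:
        rows.append({
            "region_id": r.region_id,
            "replicon": r.replicon,
            "start": r.start,
            "end": r.end,
            "intergenic": r.intergenic,
            "target_genes": ",".join(r.target_gene_ids),
            "supporting_replicates": ",".join(sorted(r.supporting_replicates)),
            "timepoints": ",".join(sorted(r.timepoints)),
            "max_ratio": r.max_ratio,
            "present_in_control": r.present_in_control,
        })
    return pd.DataFrame(rows, columns=[
        "region_id", "replicon", "start", "end", "intergenic", "target_genes",
        "supporting_replicates", "timepoints", "max_ratio",
        "present_in_control"])


def write_regions_bed(regions: Iterable[BindingRegion], path) -> None:
    """Write regions as BED6 (score = max ratio scaled x100, capped)."""
    with open(path, "w") as fh:
        for r in regions:
            score = int(min(1000, round(100 * (r.max_ratio
                                               if np.isfinite(r.max_ratio)
                                               else 0))))
            fh.write(f"{r.replicon}\t{r.start}\t{r.end}\t"
                     f"{r.region_id or '.'}\t{score}\t.\n")
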