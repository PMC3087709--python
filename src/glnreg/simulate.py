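"""Seeded synthetic genomes, ChIP tracks and expression matrices.

The generator emulates the statistical structure of the real assays so that
every pipeline stage is testable without downloads:

* a GC-rich linear chromosome (default 1 Mb, 70% GC) carrying ~300
  non-overlapping genes in mixed orientations, with bipartite operator
  instances embedded at planted intergenic binding sites;
* two-colour tiling tracks (60-mer probes every 180 bp, mirroring a
  44,000-probe array over a full genome at the same density) in which each
  planted site produces an IP/total ratio enrichment shaped by the
  sonication-fragment footprint (300-1000 bp fragments centred on 500 bp,
  modelled as a triangular kernel of 500 bp half-width), multiplied by
  log-normal array noise; two IP replicates plus one empty-vector control
  per timepoint, with no enrichment at T0 except for designated persistent
  ("glnA-like") sites, and artefact sites enriched in IP *and* control;
* a replicated log2 expression matrix (WT and regulator-deletion strains,
  T0/T30/T45, 3 biological replicates) with planted regulator-dependent,
  regulator-independent-responsive, and null genes.

All randomness flows from the single scenario seed; identical scenarios
produce byte-identical outputs.  The module also packages transcriptions of
the published result tables (:func:`load_fixture`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from glnreg.genome import (Gene, GenomeAnnotation, Probe, ProbeTrack,
                           intergenic_regions, write_bedgraph_track,
                           write_fasta, write_gff3)
from glnreg.peaks import BindingRegion
from glnreg.expression import write_expression_tsv

FIXTURES = ("table1", "table2", "table3")

#: A strict-consensus operator instance used for embedding (two a-sites,
#: 6 bp spacer).
DEFAULT_MOTIF = "GTCACGCCCTGGTAAC"


@dataclass
class SimScenario:
    """All knobs of the synthetic study, with assay-faithful defaults."""

    seed: int = 1
    replicon: str = "chr"
    replicon_length: int = 1_000_000
    n_genes: int = 300
    gene_length_range: tuple[int, int] = (600, 1400)
    gc_content: float = 0.70
    probe_spacing: int = 180
    probe_length: int = 60
    # ChIP design
    n_planted_sites: int = 20
    enrichment_fold_range: tuple[float, float] = (4.0, 10.0)
    n_persistent_sites: int = 1
    n_artefact_sites: int = 3
    artefact_fold: float = 6.0
    fragment_min: int = 300
    fragment_mode: int = 500
    fragment_max: int = 1000
    chip_noise_sd_log2: float = 0.25
    n_chip_replicates: int = 2
    timepoints: tuple[str, ...] = ("T0", "T30", "T45")
    motif_instance: str = DEFAULT_MOTIF
    min_planted_gap: int = 1500
    # expression design
    strains: tuple[str, ...] = ("WT", "glnR")
    n_expr_replicates: int = 3
    expr_noise_sd_log2: float = 0.25
    n_dependent: int = 30
    n_independent: int = 30
    n_null: int = 200
    n_bound_dependent: int = 10
    n_bound_nonresponsive: int = 10
    induction_fold_range: tuple[float, float] = (4.0, 80.0)
    repression_fold_range: tuple[float, float] = (4.0, 16.0)
    reference_folds: tuple[float, float] = (76.4, 15.0)

    def __post_init__(self) -> None:
        mean_len = sum(self.gene_length_range) / 2
        if self.n_genes * mean_len >= self.replicon_length:
            raise ValueError("infeasible packing: genes exceed replicon")
        if self.enrichment_fold_range[0] < 1:
            raise ValueError("enrichment folds must be >= 1")


@dataclass
class PlantedSite:
    position: int
    fold: float
    persistent: bool
    artefact: bool
    target_genes: list[str]
    motif_offset: int

    def fold_at(self, timepoint: str) -> float:
        if self.persistent or self.artefact:
            return self.fold
        return 1.0 if timepoint == "T0" else self.fold


@dataclass
class SimTruth:
    """Ground truth of one simulated study."""

    sites: list[PlantedSite] = field(default_factory=list)
    artefact_sites: list[PlantedSite] = field(default_factory=list)
    dependent_genes: list[str] = field(default_factory=list)
    independent_genes: list[str] = field(default_factory=list)
    null_genes: list[str] = field(default_factory=list)
    bound_genes: list[str] = field(default_factory=list)
    category: dict[str, str] = field(default_factory=dict)
    expression_folds: dict[str, tuple[float, float]] = field(
        default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def _random_sequence(rng: np.random.Generator, length: int,
                     gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=length, p=p)


def simulate_genome(scenario: SimScenario
                    ) -> tuple[GenomeAnnotation, dict[str, str], SimTruth]:
    """Simulate an annotated GC-rich chromosome with planted binding sites.

    Genes are packed non-overlapping with random strands (so divergent,
    convergent and tandem gaps all occur); planted sites are placed at the
    centres of large intergenic gaps that have at least one promoter-
    proximal downstream gene, and a bipartite operator instance is embedded
    in the sequence at each planted position.  Artefact sites (enriched in
    the control IP too) are planted in separate gaps without a motif.
    """
    rng = np.random.default_rng(scenario.seed)
    L = scenario.replicon_length
    lo, hi = scenario.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=scenario.n_genes)
    total_gap = L - int(lengths.sum())
    if total_gap < (scenario.n_genes + 1) * 100:
        raise ValueError("infeasible packing: not enough intergenic space")
    weights = rng.random(scenario.n_genes + 1) + 0.5
    gaps = np.floor(total_gap * weights / weights.sum()).astype(int)
    strands = rng.choice(["+", "-"], size=scenario.n_genes)

    genes: list[Gene] = []
    pos = int(gaps[0])
    for i in range(scenario.n_genes):
        start, end = pos, pos + int(lengths[i])
        genes.append(Gene(gene_id=f"gene_{i + 1:04d}",
                          replicon=scenario.replicon,
                          start=start, end=end, strand=str(strands[i]),
                          product=f"synthetic protein {i + 1}"))
        pos = end + int(gaps[i + 1])
    annotation = GenomeAnnotation(replicon_lengths={scenario.replicon: L},
                                  genes=genes)

    seq = _random_sequence(rng, L, scenario.gc_content)

    # candidate gaps: wide enough and with >= 1 downstream target
    regions = intergenic_regions(annotation)
    by_id = {g.gene_id: g for g in genes}

    def gap_targets(region) -> list[str]:
        targets = []
        if region.right_gene and by_id[region.right_gene].strand == "+":
            targets.append(region.right_gene)
        if region.left_gene and by_id[region.left_gene].strand == "-":
            targets.append(region.left_gene)
        return targets

    candidates = [r for r in regions
                  if r.end - r.start >= scenario.min_planted_gap
                  and r.left_gene and r.right_gene and gap_targets(r)]
    n_needed = scenario.n_planted_sites + scenario.n_artefact_sites
    if len(candidates) < n_needed:
        raise ValueError(f"only {len(candidates)} plantable gaps for "
                         f"{n_needed} sites")
    chosen_idx = rng.choice(len(candidates), size=n_needed, replace=False)
    chosen = [candidates[i] for i in sorted(chosen_idx)]

    folds = rng.uniform(*scenario.enrichment_fold_range,
                        size=scenario.n_planted_sites)
    truth = SimTruth()
    motif = scenario.motif_instance.upper()
    for k, region in enumerate(chosen):
        mid = (region.start + region.end) // 2
        is_artefact = k >= scenario.n_planted_sites
        site = PlantedSite(
            position=mid,
            fold=scenario.artefact_fold if is_artefact else float(folds[k]),
            persistent=(not is_artefact
                        and k < scenario.n_persistent_sites),
            artefact=is_artefact,
            target_genes=gap_targets(region),
            motif_offset=mid - len(motif) // 2)
        if is_artefact:
            truth.artefact_sites.append(site)
        else:
            off = site.motif_offset
            seq[off:off + len(motif)] = np.frombuffer(
                motif.encode(), dtype="S1")
            truth.sites.append(site)
    sequences = {scenario.replicon: seq.tobytes().decode()}
    return annotation, sequences, truth


# ---------------------------------------------------------------------------
# ChIP tracks
# ---------------------------------------------------------------------------

def _expected_ratio(midpoints: np.ndarray, sites: Sequence[PlantedSite],
                    timepoint: str, half_width: float) -> np.ndarray:
    expected = np.ones_like(midpoints, dtype=float)
    for site in sites:
        fold = site.fold_at(timepoint)
        if fold <= 1.0:
            continue
        w = np.clip(1.0 - np.abs(midpoints - site.position) / half_width,
                    0.0, None)
        expected += (fold - 1.0) * w
    return expected


def simulate_chip_tracks(scenario: SimScenario,
                         annotation: GenomeAnnotation,
                         truth: SimTruth,
                         rng: np.random.Generator | None = None
                         ) -> dict[str, list[ProbeTrack]]:
    """IP replicate + control tracks per timepoint.

    The expected probe ratio is ``1 + sum_sites (fold - 1) * w(d)`` with a
    triangular kernel ``w`` of half-width equal to the modal sonication
    fragment size, multiplied by log-normal noise (sd of log2 ratio as
    configured).  Control tracks see only the artefact sites.
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed + 1)
    L = annotation.replicon_lengths[scenario.replicon]
    starts = np.arange(0, L - scenario.probe_length + 1,
                       scenario.probe_spacing)
    probes = [Probe(probe_id=f"p{i:06d}", replicon=scenario.replicon,
                    start=int(s), end=int(s) + scenario.probe_length)
              for i, s in enumerate(starts)]
    mids = starts + scenario.probe_length // 2
    half_width = float(scenario.fragment_mode)
    sd = scenario.chip_noise_sd_log2

    tracks: dict[str, list[ProbeTrack]] = {}
    for tp in scenario.timepoints:
        tracks[tp] = []
        ip_expected = _expected_ratio(
            mids, truth.sites + truth.artefact_sites, tp, half_width)
        ctrl_expected = _expected_ratio(
            mids, truth.artefact_sites, tp, half_width)
        for r in range(1, scenario.n_chip_replicates + 1):
            noise = 2.0 ** rng.normal(0.0, sd, size=len(mids)) if sd > 0 \
                else 1.0
            tracks[tp].append(ProbeTrack(
                probes=list(probes), ratio=ip_expected * noise,
                replicate_id=f"rep{r}", timepoint_label=tp))
        noise = 2.0 ** rng.normal(0.0, sd, size=len(mids)) if sd > 0 else 1.0
        tracks[tp].append(ProbeTrack(
            probes=list(probes), ratio=ctrl_expected * noise,
            replicate_id="control", timepoint_label=tp, is_control=True))
    return tracks


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def _assign_roles(scenario: SimScenario, truth: SimTruth,
                  gene_ids: Sequence[str] | None) -> SimTruth:
    """Fill dependent/independent/null/bound role lists into the truth."""
    if gene_ids is None:
        n = scenario.n_dependent + scenario.n_independent + scenario.n_null
        gene_ids = [f"gene_{i + 1:04d}" for i in range(n)]
    gene_ids = list(gene_ids)

    chip_targets: list[str] = []
    for site in truth.sites:
        for g in site.target_genes:
            if g not in chip_targets:
                chip_targets.append(g)

    if chip_targets:
        # genome-wide run: bound genes come from the planted ChIP sites
        n_dep_bound = min(scenario.n_bound_dependent, len(chip_targets))
        bound_dep = chip_targets[:n_dep_bound]
        bound_nonresp = chip_targets[n_dep_bound:]
        rest = [g for g in gene_ids if g not in chip_targets]
        n_dep_extra = max(0, scenario.n_dependent - len(bound_dep))
        dep = bound_dep + rest[:n_dep_extra]
        indep = rest[n_dep_extra:n_dep_extra + scenario.n_independent]
        null = rest[n_dep_extra + scenario.n_independent:] + bound_nonresp
        bound = chip_targets
    else:
        # expression-only run: bound evidence is designated synthetically
        dep = gene_ids[:scenario.n_dependent]
        indep = gene_ids[scenario.n_dependent:
                         scenario.n_dependent + scenario.n_independent]
        null = gene_ids[scenario.n_dependent + scenario.n_independent:]
        bound = dep[:scenario.n_bound_dependent] + \
            null[:scenario.n_bound_nonresponsive]

    truth.dependent_genes = sorted(dep)
    truth.independent_genes = sorted(indep)
    truth.null_genes = sorted(set(null))
    truth.bound_genes = sorted(set(bound))
    bound_set = set(truth.bound_genes)
    for g in truth.dependent_genes:
        truth.category[g] = "i" if g in bound_set else "ii"
    for g in truth.independent_genes:
        truth.category[g] = "iii"
    for g in truth.null_genes:
        truth.category[g] = "iv" if g in bound_set else "none"
    return truth


def simulate_expression(scenario: SimScenario,
                        truth: SimTruth | None = None,
                        gene_ids: Sequence[str] | None = None,
                        rng: np.random.Generator | None = None
                        ) -> tuple[pd.DataFrame, SimTruth]:
    """Replicated log2 expression matrix with planted response structure.

    Dependent genes rise by log2(fold_induction) at T30 and fall by
    log2(fold_repression) at T45 in the wild type only; independent genes
    respond identically in every strain; null genes are flat.  Gaussian
    log2 noise is i.i.d. per observation.  The first dependent gene gets
    the reference fold pair (default 76.4 / 15.0) so headline fold changes
    are reproduced by construction; the rest are drawn from the configured
    ranges (all >= the recovery floor of 4).
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed + 2)
    if truth is None:
        truth = SimTruth()
    if not truth.dependent_genes:
        _assign_roles(scenario, truth, gene_ids)

    genes = sorted(set(truth.dependent_genes + truth.independent_genes
                       + truth.null_genes))
    responsive = sorted(set(truth.dependent_genes
                            + truth.independent_genes))
    dep_sorted = truth.dependent_genes
    for j, g in enumerate(responsive):
        if dep_sorted and g == dep_sorted[0]:
            ind, rep = scenario.reference_folds
        else:
            ind = float(rng.uniform(*scenario.induction_fold_range))
            rep = float(rng.uniform(*scenario.repression_fold_range))
        truth.expression_folds[g] = (ind, rep)

    cols = pd.MultiIndex.from_tuples(
        [(s, tp, f"r{r}") for s in scenario.strains
         for tp in ("T0", "T30", "T45")
         for r in range(1, scenario.n_expr_replicates + 1)],
        names=("strain", "timepoint", "replicate"))
    base = rng.uniform(6.0, 10.0, size=len(genes))
    dep_set = set(truth.dependent_genes)
    indep_set = set(truth.independent_genes)

    data = np.zeros((len(genes), len(cols)))
    for gi, g in enumerate(genes):
        for ci, (strain, tp, _r) in enumerate(cols):
            mean = base[gi]
            responds = (g in indep_set) or (g in dep_set and strain == "WT")
            if responds:
                ind, rep = truth.expression_folds[g]
                if tp == "T30":
                    mean += np.log2(ind)
                elif tp == "T45":
                    mean += np.log2(ind) - np.log2(rep)
            data[gi, ci] = mean
    if scenario.expr_noise_sd_log2 > 0:
        data = data + rng.normal(0.0, scenario.expr_noise_sd_log2,
                                 size=data.shape)
    matrix = pd.DataFrame(data, index=pd.Index(genes, name="gene_id"),
                          columns=cols)
    return matrix, truth


def truth_binding_regions(truth: SimTruth,
                          replicon: str = "chr") -> list[BindingRegion]:
    """Synthetic binding evidence straight from the ground truth.

    For expression-only scenarios (no ChIP tracks) this builds one nominal
    region per bound gene so classification can be exercised against the
    planted categories.
    """
    regions = []
    for i, g in enumerate(truth.bound_genes):
        regions.append(BindingRegion(
            replicon=replicon, start=1000 * i, end=1000 * i + 200,
            supporting_replicates=frozenset({"rep1", "rep2"}),
            timepoints=frozenset({"T30"}), intergenic=True,
            target_gene_ids=[g], region_id=f"TR{i + 1:03d}"))
    return regions


# ---------------------------------------------------------------------------
# bundles and fixtures
# ---------------------------------------------------------------------------

@dataclass
class SimBundle:
    scenario: SimScenario
    annotation: GenomeAnnotation
    sequences: dict[str, str]
    tracks: dict[str, list[ProbeTrack]]
    expression: pd.DataFrame
    truth: SimTruth


def simulate_all(scenario: SimScenario | None = None) -> SimBundle:
    """Run the whole generator: genome, ChIP tracks and expression."""
    scenario = scenario or SimScenario()
    annotation, sequences, truth = simulate_genome(scenario)
    tracks = simulate_chip_tracks(scenario, annotation, truth)
    gene_ids = [g.gene_id for g in annotation.genes]
    _assign_roles(scenario, truth, gene_ids)
    expression, truth = simulate_expression(scenario, truth)
    return SimBundle(scenario=scenario, annotation=annotation,
                     sequences=sequences, tracks=tracks,
                     expression=expression, truth=truth)


def write_bundle(bundle: SimBundle, outdir: str | Path) -> dict[str, str]:
    """Write a bundle to disk: FASTA, GFF3, bedGraphs, expression TSV, truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    write_fasta(bundle.sequences, outdir / "genome.fa")
    paths["fasta"] = str(outdir / "genome.fa")
    write_gff3(bundle.annotation, outdir / "genome.gff3")
    paths["gff3"] = str(outdir / "genome.gff3")
    for tp, tracks in bundle.tracks.items():
        for t in tracks:
            name = f"{t.replicate_id}_{tp}" + \
                ("_control" if t.is_control else "")
            p = outdir / f"{name}.bedgraph"
            write_bedgraph_track(t, p)
            paths[name] = str(p)
    write_expression_tsv(bundle.expression, outdir / "expression.tsv")
    paths["expression"] = str(outdir / "expression.tsv")
    (outdir / "truth.json").write_text(bundle.truth.to_json())
    paths["truth"] = str(outdir / "truth.json")
    return paths


def load_fixture(name: str) -> pd.DataFrame:
    """Load a packaged transcription of a published result table.

    ``table1``: the 20 most strongly induced nitrogen-responsive genes with
    their fold induction (T30 vs T0) and repression (T30 vs T45).
    ``table2``: genes induced >5-fold in the wild type but non-responsive
    in the regulator mutant.  ``table3``: the 36 binding regions with
    downstream targets, mutant fold change at T30 and annotated bipartite
    sites (semicolon-separated 16-mers, or ``n/a``).
    """
    if name not in FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURES}")
    path = resources.files("glnreg").joinpath("data", f"{name}.tsv")
    with resources.as_file(path) as p:
        df = pd.read_csv(p, sep="\t", dtype=str, keep_default_na=False)
    if name == "table1":
        df["fold_induction"] = df["fold_induction"].astype(float)
        df["fold_repression"] = df["fold_repression"].astype(float)
    if name == "table3":
        df["site_list"] = [
            [] if s == "n/a" else s.split(";") for s in df["sites"]]
        df["n_sites"] = df["site_list"].map(len)
    return df
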