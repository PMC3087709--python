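"""Coordinate-aware genome model: genes, intergenic regions, tiling probes.

Coordinate conventions
----------------------
All coordinates are 0-based, half-open internally.  GFF3 is read and written
1-based inclusive; BED and bedGraph are 0-based half-open.  Circular
replicons are treated as linear.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

STRANDS = ("+", "-")


class GFF3ParseError(ValueError):
    """Raised on malformed GFF3 input; the message names the line number."""


@dataclass(frozen=True)
class Gene:
    """A protein-coding gene feature (0-based half-open coordinates)."""

    gene_id: str
    replicon: str
    start: int
    end: int
    strand: str
    product: str = ""
    homologue_id: str | None = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"gene {self.gene_id}: start must be < end "
                             f"({self.start} >= {self.end})")
        if self.strand not in STRANDS:
            raise ValueError(f"gene {self.gene_id}: invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeAnnotation:
    """Replicon lengths plus an ordered gene collection.

    Genes are kept sorted by (replicon, start); ``gene_id`` is unique.
    """

    replicon_lengths: dict[str, int]
    genes: list[Gene] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene_id {g.gene_id!r}")
            seen.add(g.gene_id)
            if g.replicon not in self.replicon_lengths:
                raise ValueError(f"gene {g.gene_id}: unknown replicon {g.replicon!r}")
            if g.end > self.replicon_lengths[g.replicon]:
                raise ValueError(
                    f"gene {g.gene_id} extends past the end of {g.replicon}")
        self.genes.sort(key=lambda g: (g.replicon, g.start, g.end, g.gene_id))

    def genes_on(self, replicon: str) -> list[Gene]:
        """Genes of one replicon, sorted by start."""
        return [g for g in self.genes if g.replicon == replicon]

    def by_id(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


@dataclass(frozen=True)
class IntergenicRegion:
    """A maximal interval overlapped by no gene.

    ``orientation_class`` describes the flanking genes: *divergent* when the
    left gene is on '-' and the right on '+' (the region can host two
    back-to-back promoters), *convergent* for the mirror arrangement,
    *tandem* when both flanks share a strand, *chromosome_end* when a flank
    is missing.
    """

    replicon: str
    start: int
    end: int
    left_gene: str | None
    right_gene: str | None
    orientation_class: str

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValueError("intergenic region must have end > start")


@dataclass(frozen=True)
class Probe:
    probe_id: str
    replicon: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"probe {self.probe_id}: start must be < end")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class ProbeTrack:
    """One hybridisation: ordered probes with one IP/total ratio each.

    Ratios are linear (Cy3 IP over Cy5 total DNA) and strictly positive;
    non-finite or non-positive values are dropped at load time with a logged
    count.
    """

    probes: list[Probe]
    ratio: np.ndarray
    replicate_id: str
    timepoint_label: str
    is_control: bool = False
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.ratio = np.asarray(self.ratio, dtype=float)
        if len(self.probes) != len(self.ratio):
            raise ValueError("probes and ratio have different lengths")
        if len(self.ratio) and (not np.all(np.isfinite(self.ratio))
                                or np.any(self.ratio <= 0)):
            raise ValueError("ratios must be finite and > 0 after loading")
        order = sorted(range(len(self.probes)),
                       key=lambda i: (self.probes[i].replicon,
                                      self.probes[i].start))
        if order != list(range(len(self.probes))):
            self.probes = [self.probes[i] for i in order]
            self.ratio = self.ratio[order]

    def __len__(self) -> int:
        return len(self.probes)

    @property
    def label(self) -> str:
        kind = "control" if self.is_control else "ip"
        return f"{self.replicate_id}:{self.timepoint_label}:{kind}"

    def median_spacing(self) -> float:
        """Median centre-to-centre spacing of adjacent probes (bp)."""
        if len(self.probes) < 2:
            raise ValueError("need >= 2 probes for spacing")
        mids = np.array([p.midpoint for p in self.probes], dtype=float)
        return float(np.median(np.diff(mids)))


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def _parse_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" not in part:
            raise ValueError(f"attribute without '=': {part!r}")
        key, value = part.split("=", 1)
        attrs[key] = value
    return attrs


def read_gff3(path: str | Path,
              replicon_lengths: Mapping[str, int] | None = None) -> GenomeAnnotation:
    """Read gene features from a GFF3 file into a :class:`GenomeAnnotation`.

    Replicon lengths are taken from ``##sequence-region`` pragmas unless
    supplied explicitly.  Only ``gene`` features are loaded; 1-based
    inclusive GFF coordinates become 0-based half-open.  A malformed line
    raises :class:`GFF3ParseError` naming the line number.
    """
    lengths: dict[str, int] = dict(replicon_lengths or {})
    genes: list[Gene] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) != 4:
                    raise GFF3ParseError(
                        f"{path}:{lineno}: malformed ##sequence-region pragma")
                lengths[parts[1]] = int(parts[3])
                continue
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GFF3ParseError(
                    f"{path}:{lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}")
            seqid, _source, ftype, start, end, _score, strand, _phase, attr = fields
            if ftype != "gene":
                continue
            try:
                start_i, end_i = int(start), int(end)
                attrs = _parse_attributes(attr)
            except ValueError as exc:
                raise GFF3ParseError(f"{path}:{lineno}: {exc}") from exc
            if strand not in STRANDS:
                raise GFF3ParseError(
                    f"{path}:{lineno}: invalid strand {strand!r}")
            if lengths and seqid not in lengths:
                raise GFF3ParseError(
                    f"{path}:{lineno}: unknown replicon {seqid!r}")
            gene_id = attrs.get("ID") or attrs.get("locus_tag")
            if gene_id is None:
                raise GFF3ParseError(
                    f"{path}:{lineno}: gene feature without ID attribute")
            genes.append(Gene(gene_id=gene_id, replicon=seqid,
                              start=start_i - 1, end=end_i,
                              strand=strand,
                              product=attrs.get("product", ""),
                              homologue_id=attrs.get("homologue") or None))
    if not lengths:
        # fall back to the rightmost feature end per replicon
        for g in genes:
            lengths[g.replicon] = max(lengths.get(g.replicon, 0), g.end)
    if not genes:
        logger.warning("no gene features found in %s", path)
    return GenomeAnnotation(replicon_lengths=lengths, genes=genes)


def write_gff3(annotation: GenomeAnnotation, path: str | Path) -> None:
    """Write gene features back out as GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rep in sorted(annotation.replicon_lengths):
            fh.write(f"##sequence-region {rep} 1 "
                     f"{annotation.replicon_lengths[rep]}\n")
        for g in annotation.genes:
            attrs = [f"ID={g.gene_id}"]
            if g.product:
                attrs.append(f"product={g.product}")
            if g.homologue_id:
                attrs.append(f"homologue={g.homologue_id}")
            fh.write("\t".join([g.replicon, "glnreg", "gene",
                                str(g.start + 1), str(g.end), ".",
                                g.strand, ".", ";".join(attrs)]) + "\n")


# ---------------------------------------------------------------------------
# intergenic complement
# ---------------------------------------------------------------------------

def _merge_intervals(ivals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in sorted(ivals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _orientation(left: Gene | None, right: Gene | None) -> str:
    if left is None or right is None:
        return "chromosome_end"
    if left.strand == "-" and right.strand == "+":
        return "divergent"
    if left.strand == "+" and right.strand == "-":
        return "convergent"
    return "tandem"


def intergenic_regions(annotation: GenomeAnnotation) -> list[IntergenicRegion]:
    """Complement of the union of gene intervals, per replicon.

    Overlapping or nested genes are unioned first, so they never produce
    spurious regions.  Each region carries its flanking gene ids and an
    orientation class; zero-length gaps are omitted.
    """
    out: list[IntergenicRegion] = []
    for rep, length in sorted(annotation.replicon_lengths.items()):
        genes = annotation.genes_on(rep)
        merged = _merge_intervals((g.start, g.end) for g in genes)

        def flanking(pos: int, side: str) -> Gene | None:
            # nearest gene ending at/before pos (left) or starting at/after (right)
            if side == "left":
                cands = [g for g in genes if g.end <= pos]
                return max(cands, key=lambda g: g.end) if cands else None
            cands = [g for g in genes if g.start >= pos]
            return min(cands, key=lambda g: g.start) if cands else None

        prev_end = 0
        bounds = merged + [(length, length)]
        for s, e in bounds:
            if s > prev_end:
                left = flanking(prev_end, "left")
                right = flanking(s, "right")
                out.append(IntergenicRegion(
                    replicon=rep, start=prev_end, end=s,
                    left_gene=left.gene_id if left else None,
                    right_gene=right.gene_id if right else None,
                    orientation_class=_orientation(left, right)))
            prev_end = max(prev_end, e)
    return out


# ---------------------------------------------------------------------------
# bedGraph probe tracks
# ---------------------------------------------------------------------------

def read_bedgraph_track(path: str | Path,
                        annotation: GenomeAnnotation | None = None,
                        replicate_id: str = "rep1",
                        timepoint: str = "T0",
                        is_control: bool = False) -> ProbeTrack:
    """Read a 4-column bedGraph of per-probe linear ratios into a ProbeTrack.

    Intervals are taken as probes (0-based half-open) with one value each;
    non-finite or non-positive values are dropped with a logged count.  An
    interval outside its replicon raises ``ValueError``.
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["replicon", "start", "end", "value"],
                     dtype={"replicon": str},
                     skiprows=_count_track_lines(path))
    if annotation is not None:
        for rep, grp in df.groupby("replicon"):
            if rep not in annotation.replicon_lengths:
                raise ValueError(f"{path}: unknown replicon {rep!r}")
            if (grp["start"] < 0).any() or \
                    (grp["end"] > annotation.replicon_lengths[rep]).any():
                raise ValueError(f"{path}: interval outside replicon {rep!r}")
    values = pd.to_numeric(df["value"], errors="coerce")
    ok = np.isfinite(values) & (values > 0)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("%s: dropped %d non-finite/non-positive probe values",
                    path, n_dropped)
    df = df[ok]
    values = values[ok]
    probes = [Probe(probe_id=f"p{i:06d}", replicon=r, start=int(s), end=int(e))
              for i, (r, s, e) in enumerate(
                  zip(df["replicon"], df["start"], df["end"]))]
    return ProbeTrack(probes=probes, ratio=values.to_numpy(dtype=float),
                      replicate_id=replicate_id, timepoint_label=timepoint,
                      is_control=is_control, n_dropped=n_dropped)


def _count_track_lines(path: str | Path) -> int:
    n = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith(("track", "browser")):
                n += 1
            else:
                break
    return n


def write_bedgraph_track(track: ProbeTrack, path: str | Path) -> None:
    """Write a ProbeTrack as bedGraph; the track line encodes its identity."""
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{track.label}"\n')
        for p, v in zip(track.probes, track.ratio):
            fh.write(f"{p.replicon}\t{p.start}\t{p.end}\t{v:.6g}\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into a dict of upper-case sequences by id."""
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str] | Sequence[SeqRecord],
                path: str | Path) -> None:
    if isinstance(sequences, Mapping):
        records = [SeqRecord(Seq(s), id=name, description="")
                   for name, s in sequences.items()]
    else:
        records = list(sequences)
    SeqIO.write(records, str(path), "fasta")
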