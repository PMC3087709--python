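"""Bipartite GlnR-box scanning, promoter-window extraction and PWM scoring.

The GlnR operator is bipartite: two 5-bp half-sites separated by a fixed-
length spacer.  The default strict consensus is ``GTNAC-n6-GTNAC`` (two
copies of the "a-site"); a relaxed preset (``KTNAC-n6-GWNAC``) covers the
naturally occurring variants where the first half-site starts with T or the
second is the *S. coelicolor*-style ``GaAAC`` "b-site".  A widely spaced
mode (spacer up to 18 bp) covers the nasA-style arrangement of two a-sites
18 bp apart.

Because ``GTNAC`` is its own reverse complement as a pattern, every hit of
the default consensus has a mirror-image hit on the opposite strand over the
same footprint; :func:`dedupe_palindromic` collapses these to one site.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from glnreg.genome import GenomeAnnotation
from glnreg.peaks import BindingRegion

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def _iupac_regex(pattern: str) -> str:
    out = []
    for ch in pattern.upper():
        if ch not in IUPAC:
            raise ValueError(f"non-IUPAC pattern character {ch!r}")
        bases = IUPAC[ch]
        out.append(bases if len(bases) == 1 else f"[{bases}]")
    return "".join(out)


@dataclass(frozen=True)
class BipartiteConsensus:
    """Two IUPAC half-sites separated by a spacer length range."""

    half_site_a: str = "GTNAC"
    half_site_b: str = "GTNAC"
    spacer_min: int = 6
    spacer_max: int = 6
    name: str = "strict"

    def __post_init__(self) -> None:
        _iupac_regex(self.half_site_a)
        _iupac_regex(self.half_site_b)
        if self.spacer_min > self.spacer_max or self.spacer_min < 0:
            raise ValueError("need 0 <= spacer_min <= spacer_max")

    def full_length(self, spacer: int) -> int:
        return len(self.half_site_a) + spacer + len(self.half_site_b)


#: The consensus derived in vivo: GTnAC-n6-GTnAC.
STRICT_CONSENSUS = BipartiteConsensus()
#: Relaxed preset covering a-site/b-site variants (e.g. TTAAC...GAAAC).
RELAXED_CONSENSUS = BipartiteConsensus(half_site_a="KTNAC",
                                       half_site_b="GWNAC", name="relaxed")
#: Widely spaced two-a-site arrangement (nasA-style, 18 bp apart).
WIDE_CONSENSUS = BipartiteConsensus(spacer_min=6, spacer_max=18, name="wide")


@dataclass(frozen=True)
class MotifHit:
    """One full-site match, in forward coordinates of the subject sequence."""

    sequence_id: str
    offset: int
    strand: str
    matched: str
    spacer: int
    pattern: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")

    @property
    def end(self) -> int:
        return self.offset + len(self.matched)

    @property
    def footprint(self) -> tuple[int, int]:
        return (self.offset, self.end)


def scan_bipartite(seq: str, consensus: BipartiteConsensus = STRICT_CONSENSUS,
                   sequence_id: str = "seq",
                   both_strands: bool = True) -> list[MotifHit]:
    """All bipartite consensus matches, on both strands, all spacers.

    Matching is case-insensitive; ambiguity codes in the *subject* never
    match.  Reverse-strand hits are reported in forward coordinates with
    strand '-'; overlapping hits are all reported.  Hits are sorted by
    (offset, strand, spacer).
    """
    seq = seq.upper()
    hits: list[MotifHit] = []
    strands = [("+", seq)]
    if both_strands:
        strands.append(("-", str(Seq(seq).reverse_complement())))
    for spacer in range(consensus.spacer_min, consensus.spacer_max + 1):
        pat = re.compile("(?=(" + _iupac_regex(consensus.half_site_a)
                         + "[ACGT]{%d}" % spacer
                         + _iupac_regex(consensus.half_site_b) + "))")
        full = consensus.full_length(spacer)
        for strand, subject in strands:
            for m in pat.finditer(subject):
                off = m.start()
                if strand == "-":
                    off = len(seq) - off - full
                hits.append(MotifHit(sequence_id=sequence_id, offset=off,
                                     strand=strand, matched=seq[off:off + full],
                                     spacer=spacer, pattern=consensus.name))
    hits.sort(key=lambda h: (h.offset, h.strand, h.spacer))
    return hits


def dedupe_palindromic(hits: Iterable[MotifHit]) -> list[MotifHit]:
    """Collapse hits sharing an identical footprint on opposite strands.

    Keeps one hit per (offset, length, spacer), preferring '+'.  Useful for
    counting distinct sites under self-reverse-complementary patterns.
    """
    best: dict[tuple[int, int, int], MotifHit] = {}
    for h in sorted(hits, key=lambda h: (h.offset, h.spacer, h.strand)):
        best.setdefault((h.offset, h.end, h.spacer), h)
    return [best[k] for k in sorted(best)]


def infer_spacer(sites: Iterable[str], half_len: int = 5) -> int:
    """Spacer length implied by equal-length full sites (two half-sites).

    All sites must share one length L; the spacer is ``L - 2 * half_len``.
    The in vivo full sites are 16-mers, i.e. 5 + 6 + 5.
    """
    lengths = {len(s) for s in sites}
    if len(lengths) != 1:
        raise ValueError(f"sites have mixed lengths {sorted(lengths)}")
    (length,) = lengths
    spacer = length - 2 * half_len
    if spacer < 0:
        raise ValueError("sites shorter than two half-sites")
    return spacer


# ---------------------------------------------------------------------------
# promoter windows
# ---------------------------------------------------------------------------

def promoter_windows(regions: Sequence[BindingRegion],
                     sequences: Mapping[str, str],
                     width: int = 250,
                     annotation: GenomeAnnotation | None = None
                     ) -> list[SeqRecord]:
    """Fixed-width windows centred on each binding-region midpoint.

    Windows are clipped at replicon ends (the clipped length is recorded in
    the record description).  Record ids carry the region id and its target
    genes so downstream motif tables stay traceable.
    """
    records: list[SeqRecord] = []
    for i, region in enumerate(regions):
        if region.replicon not in sequences:
            raise ValueError(f"no sequence for replicon {region.replicon!r}")
        seq = sequences[region.replicon]
        mid = region.midpoint
        lo = max(0, mid - width // 2)
        hi = min(len(seq), mid + (width - width // 2))
        name = region.region_id or f"region{i + 1:03d}"
        if region.target_gene_ids:
            name += "|" + ",".join(region.target_gene_ids)
        desc = f"{region.replicon}:{lo}-{hi}"
        if hi - lo < width:
            desc += f" clipped_len={hi - lo}"
        records.append(SeqRecord(Seq(seq[lo:hi]), id=name, description=desc))
    return records


# ---------------------------------------------------------------------------
# PWM
# ---------------------------------------------------------------------------

BASES = "ACGT"


@dataclass
class PWM:
    """Column-wise base frequency matrix with background and per-column IC.

    ``freqs`` has shape (4, L) over A,C,G,T; columns sum to 1.  Information
    content is Shannon IC, ``2 - H(column)`` bits, hence in [0, 2].
    Log-odds scoring is ``log2(freq / background)``, which is where a
    GC-rich genome background matters.
    """

    freqs: np.ndarray
    background: np.ndarray
    pseudocount: float = 0.5
    information_content: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.freqs.shape[0] != 4 or self.background.shape != (4,):
            raise ValueError("freqs must be 4xL and background length 4")
        if not np.allclose(self.freqs.sum(axis=0), 1.0):
            raise ValueError("PWM columns must sum to 1")
        with np.errstate(divide="ignore", invalid="ignore"):
            h = -np.where(self.freqs > 0,
                          self.freqs * np.log2(self.freqs), 0.0).sum(axis=0)
        self.information_content = 2.0 - h

    @property
    def length(self) -> int:
        return self.freqs.shape[1]

    @property
    def log_odds(self) -> np.ndarray:
        return np.log2(self.freqs / self.background[:, None])

    def score(self, seq: str) -> float:
        """Sum of per-column log-odds for a sequence of the PWM's length."""
        seq = seq.upper()
        if len(seq) != self.length:
            raise ValueError("sequence length must equal PWM length")
        lo = self.log_odds
        return float(sum(lo[BASES.index(b), j] for j, b in enumerate(seq)))


def genome_background(sequences: Mapping[str, str]) -> np.ndarray:
    """Mononucleotide background frequencies of a genome (A,C,G,T)."""
    counts = np.zeros(4)
    for seq in sequences.values():
        for i, b in enumerate(BASES):
            counts[i] += seq.upper().count(b)
    if counts.sum() == 0:
        return np.full(4, 0.25)
    return counts / counts.sum()


def build_pwm(sites: Sequence[str], pseudocount: float = 0.5,
              background: np.ndarray | Sequence[float] | None = None) -> PWM:
    """Build a PWM from aligned equal-length bound sites.

    Uses Bio.motifs for base counting, adds ``pseudocount`` per base per
    column, and normalises.  Background defaults to uniform; pass the
    subject genome's composition (see :func:`genome_background`) for
    GC-rich genomes.
    """
    from Bio import motifs as bio_motifs

    if len(sites) < 2:
        raise ValueError("need >= 2 sites to build a PWM")
    lengths = {len(s) for s in sites}
    if len(lengths) != 1:
        raise ValueError("sites must have equal length")
    motif = bio_motifs.create([Seq(s.upper()) for s in sites])
    counts = np.array([[motif.counts[b][j] for j in range(motif.length)]
                       for b in BASES], dtype=float)
    counts += pseudocount
    freqs = counts / counts.sum(axis=0, keepdims=True)
    bg = np.full(4, 0.25) if background is None \
        else np.asarray(background, dtype=float)
    return PWM(freqs=freqs, background=bg, pseudocount=pseudocount)


def pwm_scan(seq: str, pwm: PWM, score_threshold: float = 0.0,
             sequence_id: str = "seq") -> pd.DataFrame:
    """Log-odds score at every offset on both strands; hits >= threshold.

    Returns a frame with columns sequence_id, offset, strand, matched,
    score, sorted by descending score.  ``score_threshold=-inf`` returns
    every offset on both strands.
    """
    seq = seq.upper()
    rows = []
    rc = str(Seq(seq).reverse_complement())
    L = pwm.length
    for strand, subject in (("+", seq), ("-", rc)):
        for i in range(0, len(subject) - L + 1):
            window = subject[i:i + L]
            if any(b not in BASES for b in window):
                continue
            s = pwm.score(window)
            if s >= score_threshold:
                off = i if strand == "+" else len(seq) - i - L
                rows.append((sequence_id, off, strand, seq[off:off + L], s))
    df = pd.DataFrame(rows, columns=["sequence_id", "offset", "strand",
                                     "matched", "score"])
    return df.sort_values(["score", "offset", "strand"],
                          ascending=[False, True, True],
                          kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# region annotation
# ---------------------------------------------------------------------------

def annotate_regions_with_sites(regions: Sequence[BindingRegion],
                                windows: Sequence[SeqRecord],
                                consensus: BipartiteConsensus = STRICT_CONSENSUS,
                                dedupe: bool = True) -> pd.DataFrame:
    """Scan each region's promoter window; report its sites or ``"n/a"``.

    One row per region with the distinct full-site strings found (several
    regions carry multiple boxes); regions without a consensus match get the
    literal flag ``n/a``.  The returned frame has an attribute-style summary
    in ``.attrs``: ``n_with_sites`` and ``n_without_sites``.
    """
    if len(regions) != len(windows):
        raise ValueError("regions and windows must correspond one-to-one")
    rows = []
    n_with = 0
    for region, record in zip(regions, windows):
        hits = scan_bipartite(str(record.seq), consensus,
                              sequence_id=record.id)
        if dedupe:
            hits = dedupe_palindromic(hits)
        if hits:
            n_with += 1
            sites = ";".join(h.matched for h in hits)
        else:
            sites = "n/a"
        rows.append({
            "region_id": region.region_id or record.id,
            "target_genes": ",".join(region.target_gene_ids),
            "n_sites": len(hits),
            "sites": sites,
        })
    df = pd.DataFrame(rows, columns=["region_id", "target_genes",
                                     "n_sites", "sites"])
    df.attrs["n_with_sites"] = n_with
    df.attrs["n_without_sites"] = len(rows) - n_with
    return df
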