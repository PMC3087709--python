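import numpy as np
import pytest

from glnreg.genome import Gene, GenomeAnnotation, Probe, ProbeTrack


@pytest.fixture
def toy_annotation() -> GenomeAnnotation:
    """Six genes on a 10 kb replicon with a divergent and a convergent pair."""
    genes = [
        Gene("gA", "chr", 500, 1500, "+"),
        Gene("gB", "chr", 2000, 3000, "-"),   # gB(-) .. gC(+): divergent gap
        Gene("gC", "chr", 4000, 5000, "+"),
        Gene("gD", "chr", 5500, 6500, "+"),   # tandem gap gC..gD
        Gene("gE", "chr", 7000, 8000, "+"),
        Gene("gF", "chr", 8500, 9500, "-"),   # gE(+) .. gF(-): convergent gap
    ]
    return GenomeAnnotation(replicon_lengths={"chr": 10_000}, genes=genes)


def make_track(values, spacing=100, probe_len=60, replicate_id="rep1",
               timepoint="T30", is_control=False, replicon="chr"):
    probes = [Probe(f"p{i:04d}", replicon, i * spacing, i * spacing + probe_len)
              for i in range(len(values))]
    return ProbeTrack(probes=probes, ratio=np.asarray(values, dtype=float),
                      replicate_id=replicate_id, timepoint_label=timepoint,
                      is_control=is_control)


def random_annotation(rng: np.random.Generator, n_genes: int = 50,
                      length: int = 100_000) -> GenomeAnnotation:
    """Random non-overlapping gene packing with random strands."""
    lengths = rng.integers(200, 1200, size=n_genes)
    total_gap = length - int(lengths.sum())
    assert total_gap > 0
    w = rng.random(n_genes + 1) + 0.1
    gaps = np.floor(total_gap * w / w.sum()).astype(int)
    genes, pos = [], int(gaps[0])
    for i in range(n_genes):
        genes.append(Gene(f"g{i:03d}", "chr", pos, pos + int(lengths[i]),
                          str(rng.choice(["+", "-"]))))
        pos += int(lengths[i]) + int(gaps[i + 1])
    return GenomeAnnotation(replicon_lengths={"chr": length}, genes=genes)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
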