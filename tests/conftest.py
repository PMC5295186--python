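import numpy as np
import pytest

from pvburden.synthetic import GeneratorParams, write_bundle
from pvburden.transcripts import GenomeSequence, TranscriptModel


def make_genome(chrom: str, seq: str) -> GenomeSequence:
    return GenomeSequence(chrom, seq)


def random_transcript_and_genome(seed: int, min_exons: int = 1, max_exons: int = 6):
    """Random exon structure with a random genome; CDS spans the mRNA.

    No ORF validity is implied — intended for coordinate-arithmetic tests.
    """
    rng = np.random.default_rng(seed)
    n = int(rng.integers(min_exons, max_exons + 1))
    exons = []
    cursor = int(rng.integers(1, 20))
    for _ in range(n):
        length = int(rng.integers(5, 40))
        exons.append((cursor, cursor + length - 1))
        # keep introns >= 4 bp so donor/acceptor dinucleotides are disjoint
        cursor += length + int(rng.integers(5, 25))
    strand = "+" if rng.random() < 0.5 else "-"
    span_end = exons[-1][1] + int(rng.integers(1, 15))
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=span_end)])
    tx = TranscriptModel(
        transcript_id=f"RT{seed}",
        gene=f"G{seed}",
        chrom="chrR",
        strand=strand,
        exons=tuple(exons),
        cds_start=exons[0][0],
        cds_end=exons[-1][1],
    )
    return tx, GenomeSequence("chrR", seq)


@pytest.fixture(scope="session")
def small_params():
    """Reduced-size generator world for fast end-to-end tests."""
    return GeneratorParams(
        seed=7,
        n_genes=8,
        n_pathogenic=80,
        n_escapers=20,
        n_background=40,
        founder_count=5,
    )


@pytest.fixture(scope="session")
def small_bundle(small_params, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("bundle")
    return write_bundle(small_params, outdir)


@pytest.fixture
def three_exon_plus():
    """Hand-built 3-exon plus-strand transcript.

    exons (11,20), (31,45), (56,70): mRNA length 10+15+15 = 40;
    final junction at mRNA 25.
    """
    rng = np.random.default_rng(42)
    seq = list("".join(np.array(list("ACGT"))[rng.integers(0, 4, size=80)]))
    # canonical splice dinucleotides
    seq[20:22] = "GT"; seq[28:30] = "AG"
    seq[45:47] = "GT"; seq[53:55] = "AG"
    genome = GenomeSequence("chr3p", "".join(seq))
    tx = TranscriptModel(
        transcript_id="T3P", gene="G3P", chrom="chr3p", strand="+",
        exons=((11, 20), (31, 45), (56, 70)), cds_start=11, cds_end=70,
    )
    return tx, genome
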