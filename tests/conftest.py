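import numpy as np
import pytest

from recleth import (
    GenotypeMatrix,
    TranscriptModel,
    VariantRecord,
    emit_candidate_fixture,
    emit_gene_model_fixture,
)

STOPS = {"TAA", "TAG", "TGA"}
SENSE_CODONS = sorted(
    a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT" if a + b + c not in STOPS
)


@pytest.fixture(scope="session")
def candidate_fixture():
    return emit_candidate_fixture(decoys=32, seed=11)


@pytest.fixture(scope="session")
def gene_fixture():
    return emit_gene_model_fixture()


def random_matrix(rng, n_variants=50, n_samples=12, chrom="chr1"):
    """A random biallelic genotype matrix (SNVs, unique positions)."""
    positions = rng.choice(np.arange(1, 10_000_000), size=n_variants, replace=False)
    positions.sort()
    variants = []
    for pos in positions:
        ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
        qual = round(float(rng.uniform(0, 1000)), 1)
        variants.append(VariantRecord(chrom, int(pos), str(ref), str(alt), qual))
    samples = [f"S{i:03d}" for i in range(n_samples)]
    calls = rng.choice(
        np.array([-1, 0, 1, 2], dtype=np.int8),
        size=(n_variants, n_samples),
        p=[0.05, 0.55, 0.25, 0.15],
    )
    return GenotypeMatrix(variants, samples, calls)


def random_transcript_model(rng, n_exons=None, chrom="chrT"):
    """A random valid multi-exon transcript model on either strand."""
    n_exons = n_exons or int(rng.integers(1, 5))
    utr5 = int(rng.integers(0, 60))
    n_codons = int(rng.integers(2, 40))
    utr3 = int(rng.integers(0, 60))
    codons = ["ATG"] + [str(rng.choice(SENSE_CODONS)) for _ in range(n_codons - 1)]
    cds = "".join(codons) + str(rng.choice(sorted(STOPS)))
    seq_len = utr5 + len(cds) + utr3
    seq = (
        "".join(rng.choice(list("ACGT"), size=utr5))
        + cds
        + "".join(rng.choice(list("ACGT"), size=utr3))
    )
    # split seq_len into n_exons positive parts
    if n_exons > 1:
        cuts = sorted(rng.choice(np.arange(1, seq_len), size=n_exons - 1, replace=False))
    else:
        cuts = []
    bounds = [0] + [int(c) for c in cuts] + [seq_len]
    lengths = [b - a for a, b in zip(bounds, bounds[1:])]
    strand = "+" if rng.random() < 0.5 else "-"
    g = int(rng.integers(1_000, 100_000))
    genomic_exons = []  # ascending genomic order
    order = lengths if strand == "+" else lengths[::-1]
    for ln in order:
        genomic_exons.append((g, g + ln - 1))
        g += ln + int(rng.integers(50, 500))
    exons = genomic_exons if strand == "+" else genomic_exons[::-1]
    return TranscriptModel(
        transcript_id="TXR.1",
        chrom=chrom,
        strand=strand,
        exons=exons,
        cds_start_tx=utr5 + 1,
        cds_len_nt=len(cds),
        sequence=seq,
    )
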