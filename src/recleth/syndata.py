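"""Seeded synthetic populations emulating a recessive-lethal haplotype study.

Three layers:

* published study inputs that downstream analyses consume directly — the
  candidate-variant panel from the sequenced-genome screen, the
  status x genotype contingency counts of the genotyped selection cohort,
  and the headline deficiency / mating / frequency figures;
* a deterministic sequenced-panel fixture (the candidate variants plus
  decoy variants that each violate exactly one filter condition) and a
  deterministic gene-model fixture for the consequence engine;
* a seeded forward simulator for a genotyped cohort (founder allele at a
  set frequency, juvenile lethality of homozygotes before genotyping age,
  recombination-shortened haplotypes and array-genotyping error driving
  status-vs-genotype discordance) and for at-risk carrier x carrier
  matings (Mendelian litters, sex-specific birthweights, a growth deficit
  and early death of homozygous lambs).

All randomness flows from a single integer seed; a fixed seed reproduces
byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    HET,
    HOM_ALT,
    HOM_REF,
    CALL_CODES,
    GenotypeMatrix,
    MatingRecord,
    PhenotypeRecord,
    SampleStatus,
    VariantRecord,
    write_matings_table,
    write_status_table,
    write_vcf,
)
from .consequence import TranscriptModel, write_gene_model

CHROM = "NC_040254.1"

#: mapped haplotype interval on chromosome 3 (1-based inclusive)
HAPLOTYPE_REGION = f"{CHROM}:146243481-147946399"
#: the haplotype interval extended by 1 Mb on each side
EXTENDED_REGION = f"{CHROM}:145243481-148946399"

#: candidate SNVs surviving the carrier-concordance screen of 88 sequenced
#: genomes: (pos, ref, alt, qual, impact, consequence term)
CANDIDATE_VARIANTS = (
    (145_928_967, "C", "G", 347.3, "MODIFIER", "intergenic"),
    (146_173_708, "G", "A", 396.0, "MODIFIER", "intergenic"),
    (146_566_556, "C", "T", 133.1, "MODIFIER", "intronic"),
    (146_718_479, "G", "A", 272.7, "MODIFIER", "intronic"),
    (146_809_812, "T", "C", 604.4, "MODIFIER", "intronic"),
    (147_207_999, "C", "A", 506.7, "HIGH", "stop_gained"),
    (147_345_297, "G", "A", 192.3, "MODIFIER", "intergenic"),
    (148_189_184, "A", "G", 596.7, "MODIFIER", "intergenic"),
    (148_212_194, "A", "C", 181.7, "MODIFIER", "intergenic"),
    (148_417_713, "A", "G", 545.8, "MODIFIER", "intergenic"),
    (148_904_267, "G", "A", 439.1, "MODIFIER", "intronic"),
)

CAUSAL_POS = 147_207_999

#: genotyped 2021 selection cohort: haplotype status (rows: non_carrier,
#: carrier_het, carrier_hom) x variant genotype (cols: hom_ref, het, hom_alt)
COHORT_CONTINGENCY = np.array(
    [
        [2540, 9, 0],
        [3, 399, 0],
        [0, 0, 1],
    ]
)
COHORT_STATUS_LABELS = ("non_carrier", "carrier_het", "carrier_hom")
COHORT_GENOTYPE_LABELS = (HOM_REF, HET, HOM_ALT)

#: headline figures of the originating haplotype screen and validation
DEFICIENCY_OBSERVED = 3
DEFICIENCY_EXPECTED = 72.0
ATRISK_OFFSPRING_COUNTS = (5, 6, 5)  # hom_ref, het, hom_alt lambs
AI_SUCCESS = (11, 17)  # pregnancies / inseminated ewes
ALLELE_FREQUENCY_ROUND = 0.06
LAMB_MORTALITY_RATE = 0.15
SWISS_LACAUNE_COUNTS = (27, 10, 0)  # hom_ref, het, hom_alt in the diversity panel


def cohort_genotype_counts() -> tuple:
    """Genotype totals (hom_ref, het, hom_alt) of the genotyped cohort."""
    totals = COHORT_CONTINGENCY.sum(axis=0)
    return tuple(int(x) for x in totals)


def cohort_association_table() -> np.ndarray:
    """2x2 genotype x status table, the homozygous individual excluded.

    Rows: hom_ref / het genotype; columns: non-carrier /
    heterozygous-carrier status.
    """
    return COHORT_CONTINGENCY[:2, :2].T.copy()


def cohort_as_samples() -> dict:
    """Expand the contingency counts into a per-sample status/genotype map."""
    cohort = {}
    i = 0
    for r, status in enumerate(COHORT_STATUS_LABELS):
        for c, genotype in enumerate(COHORT_GENOTYPE_LABELS):
            for _ in range(int(COHORT_CONTINGENCY[r, c])):
                cohort[f"COHORT{i:05d}"] = (status, genotype)
                i += 1
    return cohort


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """Study-condition parameters of the synthetic population.

    Defaults reproduce the scale and rates of the genotyped cohort and
    the at-risk mating trial: a 2952-animal cohort, causal-allele
    frequency 0.06, 27-marker haplotype, discordance rates matching the
    observed 9/408 recombination-shortened and 3/2543 status-error
    classes, homozygote survival to genotyping age of 3/72, and 17
    carrier x carrier inseminations with 65% success.
    """

    seed: int = 0
    n_cohort: int = 2952
    q_causal: float = 0.06
    n_markers_haplotype: int = 27
    p_recomb_short_haplotype: float = 9 / 408
    genotyping_error_rate: float = 3 / 2543
    n_sequenced_carriers: int = 2
    n_sequenced_noncarriers: int = 86
    lethality_survival: float = 3 / 72  # hom_alt survival to genotyping age
    n_matings_at_risk: int = 17
    ai_success_rate: float = 0.65
    twin_prob: float = 0.45  # 16 lambs from 11 pregnancies
    adg_mean: float = 330.0  # g/day, unaffected lambs
    adg_effect: float = 120.0  # mean reduction for hom_alt lambs
    adg_sd: float = 40.0
    birthweight_male: tuple = (4.9, 1.0)  # kg mean, sd
    birthweight_female: tuple = (3.9, 0.6)
    lethality_survival_matings: float = 0.2  # hom_alt lambs escaping early death
    censor_day: int = 180

    def __post_init__(self):
        probs = {
            "q_causal": self.q_causal,
            "p_recomb_short_haplotype": self.p_recomb_short_haplotype,
            "genotyping_error_rate": self.genotyping_error_rate,
            "lethality_survival": self.lethality_survival,
            "ai_success_rate": self.ai_success_rate,
            "twin_prob": self.twin_prob,
            "lethality_survival_matings": self.lethality_survival_matings,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        if self.n_cohort < 1:
            raise ValueError("n_cohort must be >= 1")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("birthweight_male", "birthweight_female"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SyntheticTruth:
    """Ground truth aligned 1:1 with the emitted cohort (recovery tests)."""

    per_sample: pd.DataFrame  # sample_id, true_genotype, status, recomb_flag, error_flag
    n_conceived: int
    n_died_before_genotyping: int


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

_CODE_TO_GENO = {0: HOM_REF, 1: HET, 2: HOM_ALT}


@dataclass
class CohortSimulation:
    matrix: GenotypeMatrix
    statuses: list
    truth: SyntheticTruth


def simulate_cohort(cfg: SimulationConfig, out_dir=None) -> CohortSimulation:
    """Draw a genotyped cohort under the study's population model.

    Conceived individuals carry the causal allele at Hardy-Weinberg
    frequencies q_causal; homozygous-alternate individuals survive to
    genotyping age with probability ``lethality_survival`` and dead ones
    never enter the cohort.  The haplotype status of each survivor is
    derived from its true genotype and then perturbed: a heterozygote
    carries a recombination-shortened (unrecognized) haplotype with
    probability ``p_recomb_short_haplotype`` and is called non-carrier; a
    homozygous-reference animal is mis-called heterozygous-carrier with
    probability ``genotyping_error_rate``.  With ``out_dir`` set, writes
    cohort.vcf, status.tsv and truth.tsv.
    """
    rng = np.random.default_rng(cfg.seed)
    q = cfg.q_causal
    geno = rng.choice(3, size=cfg.n_cohort, p=[(1 - q) ** 2, 2 * q * (1 - q), q * q])
    died = (geno == 2) & (rng.random(cfg.n_cohort) >= cfg.lethality_survival)
    geno = geno[~died]
    n = geno.size

    recomb = (geno == 1) & (rng.random(n) < cfg.p_recomb_short_haplotype)
    error = (geno == 0) & (rng.random(n) < cfg.genotyping_error_rate)
    status = np.array(["non_carrier", "carrier_het", "carrier_hom"])[geno]
    status[recomb] = "non_carrier"
    status[error] = "carrier_het"

    ids = [f"COHSIM{i:06d}" for i in range(n)]
    variant = VariantRecord(
        CHROM, CAUSAL_POS, "C", "A", 506.7,
        (("IMPACT", "HIGH"), ("CSQ", "stop_gained")),
    )
    matrix = GenotypeMatrix([variant], ids, geno.astype(np.int8).reshape(1, -1))
    statuses = [
        SampleStatus(ids[i], "Lacaune", str(status[i]), False, 2021) for i in range(n)
    ]
    truth = SyntheticTruth(
        per_sample=pd.DataFrame(
            {
                "sample_id": ids,
                "true_genotype": [_CODE_TO_GENO[int(g)] for g in geno],
                "haplotype_status": status,
                "recomb_flag": recomb,
                "error_flag": error,
            }
        ),
        n_conceived=cfg.n_cohort,
        n_died_before_genotyping=int(died.sum()),
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_vcf(matrix, out / "cohort.vcf")
        write_status_table(statuses, out / "status.tsv")
        truth.per_sample.to_csv(out / "truth.tsv", sep="\t", index=False)
    return CohortSimulation(matrix, statuses, truth)


# ---------------------------------------------------------------------------
# at-risk matings
# ---------------------------------------------------------------------------


def simulate_matings(cfg: SimulationConfig, sires=None, dams=None, out_dir=None) -> list:
    """Simulate carrier x carrier inseminations and their litters.

    ``sires``/``dams`` are parental genotype lists (all het by default: 3
    rams rotated over ``n_matings_at_risk`` ewes).  Pregnancy is
    Bernoulli(ai_success_rate); litters are singletons or twins; lamb
    genotypes are Mendelian; birthweight is sex-specific normal; ADG is
    normal with a ``adg_effect`` reduction for homozygous-alternate
    lambs, which die between day 15 and 25 unless they escape with
    probability ``lethality_survival_matings``.
    """
    from .stats import mendelian_probs

    rng = np.random.default_rng(cfg.seed + 1)
    if dams is None:
        dams = [HET] * cfg.n_matings_at_risk
    if sires is None:
        sires = [HET] * min(3, len(dams))
    for g in list(sires) + list(dams):
        if g not in (HOM_REF, HET, HOM_ALT):
            raise ValueError(f"parental genotype {g!r} invalid")
    matings = []
    lamb_no = 0
    for i, dam_g in enumerate(dams):
        sire_g = sires[i % len(sires)]
        pregnant = bool(rng.random() < cfg.ai_success_rate)
        m = MatingRecord(f"MATING{i + 1:02d}", sire_g, dam_g, True, pregnant)
        if pregnant:
            probs = mendelian_probs(sire_g, dam_g)
            n_lambs = 1 + int(rng.random() < cfg.twin_prob)
            for _ in range(n_lambs):
                lamb_no += 1
                g = (HOM_REF, HET, HOM_ALT)[rng.choice(3, p=probs)]
                sex = "M" if rng.random() < 0.5 else "F"
                mu, sd = cfg.birthweight_male if sex == "M" else cfg.birthweight_female
                bw = max(0.5, rng.normal(mu, sd))
                adg = rng.normal(cfg.adg_mean, cfg.adg_sd)
                if g == HOM_ALT:
                    adg -= cfg.adg_effect
                w15 = bw + adg * 15.0 / 1000.0
                if g == HOM_ALT and rng.random() >= cfg.lethality_survival_matings:
                    days, censored = int(rng.integers(15, 26)), False
                else:
                    days, censored = cfg.censor_day, True
                m.offspring.append(
                    PhenotypeRecord(
                        f"LAMB{lamb_no:03d}", sex, g,
                        round(bw, 3), round(w15, 3), days, censored,
                    )
                )
        matings.append(m)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_matings_table(matings, out / "matings.tsv")
    return matings


# ---------------------------------------------------------------------------
# sequenced-panel fixture (candidate variants + decoys)
# ---------------------------------------------------------------------------

_OTHER_BREEDS = (
    "Romane", "Texel", "Suffolk", "Charollais", "Ile de France", "Romanov",
    "Merinos d'Arles", "Tarasconnaise", "Manech tete rousse", "Corse",
    "Limousine", "Charmoise", "Rava",
)

DECOY_KINDS = ("region", "quality", "carrier_not_het", "noncarrier_not_homref")


@dataclass
class CandidateFixture:
    matrix: GenotypeMatrix
    statuses: list
    annotations: dict  # (chrom, pos, alt) -> impact class
    carrier_ids: frozenset
    noncarrier_ids: frozenset
    decoy_kinds: dict = field(default_factory=dict)  # (chrom, pos, alt) -> violated condition


def emit_candidate_fixture(decoys: int = 30, seed: int = 1, out_dir=None) -> CandidateFixture:
    """Build the sequenced-panel fixture for the concordance filter.

    88 samples: 24 within-breed genomes of which the first two are the
    haplotype carriers (heterozygous at every candidate variant), plus 64
    genomes from unrelated breeds, all homozygous reference at the
    candidates.  ``decoys`` extra variants are generated, each violating
    exactly one filter condition (outside the extended region; quality
    <= 30; a carrier not heterozygous; a non-carrier not homozygous
    reference) while satisfying the others.  Only the stop-gain candidate
    carries a HIGH impact annotation.  With ``out_dir`` set, writes
    panel.vcf and status.tsv.
    """
    rng = np.random.default_rng(seed)
    lacaune = [f"LAC{i:03d}" for i in range(1, 25)]
    carriers = lacaune[:2]
    others = [f"PANEL{i:03d}" for i in range(25, 89)]
    samples = lacaune + others
    carrier_idx = [0, 1]
    noncarrier_idx = list(range(2, 88))

    het, hom_ref, hom_alt = CALL_CODES[HET], CALL_CODES[HOM_REF], CALL_CODES[HOM_ALT]
    variants, rows = [], []
    annotations = {}
    for pos, ref, alt, qual, impact, term in CANDIDATE_VARIANTS:
        v = VariantRecord(CHROM, pos, ref, alt, qual, (("IMPACT", impact), ("CSQ", term)))
        variants.append(v)
        row = np.full(88, hom_ref, dtype=np.int8)
        row[carrier_idx] = het
        rows.append(row)
        annotations[(CHROM, pos, alt)] = impact

    used = {pos for pos, *_ in CANDIDATE_VARIANTS}
    bases = np.array(list("ACGT"))
    decoy_kinds = {}
    for k in range(decoys):
        kind = DECOY_KINDS[k % len(DECOY_KINDS)]
        while True:
            if kind == "region":
                # well clear of the extended region under any flank handling
                pos = int(
                    rng.integers(139_000_000, 144_000_000)
                    if rng.random() < 0.5
                    else rng.integers(150_000_000, 155_000_000)
                )
            else:
                pos = int(rng.integers(145_300_000, 148_900_000))
            if pos not in used:
                used.add(pos)
                break
        ref, alt = rng.choice(bases, size=2, replace=False)
        qual = round(float(rng.uniform(5.0, 29.9)), 1) if kind == "quality" else round(
            float(rng.uniform(50.0, 900.0)), 1
        )
        row = np.full(88, hom_ref, dtype=np.int8)
        row[carrier_idx] = het
        if kind == "carrier_not_het":
            row[int(rng.choice(carrier_idx))] = int(rng.choice([hom_ref, hom_alt]))
        elif kind == "noncarrier_not_homref":
            row[int(rng.choice(noncarrier_idx))] = int(rng.choice([het, hom_alt]))
        v = VariantRecord(
            CHROM, pos, str(ref), str(alt), qual,
            (("IMPACT", "MODIFIER"), ("CSQ", "intergenic")),
        )
        variants.append(v)
        rows.append(row)
        annotations[(CHROM, pos, str(alt))] = "MODIFIER"
        decoy_kinds[(CHROM, pos, str(alt))] = kind

    matrix = GenotypeMatrix(
        variants, samples,
        np.vstack(rows) if rows else np.empty((0, 88), dtype=np.int8),
    )
    statuses = [
        SampleStatus(s, "Lacaune", "carrier_het" if s in carriers else "non_carrier", True)
        for s in lacaune
    ] + [
        SampleStatus(s, _OTHER_BREEDS[i % len(_OTHER_BREEDS)], "non_carrier", True)
        for i, s in enumerate(others)
    ]
    fixture = CandidateFixture(
        matrix, statuses, annotations,
        frozenset(carriers), frozenset(samples[2:]), decoy_kinds,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_vcf(matrix, out / "panel.vcf")
        write_status_table(statuses, out / "status.tsv")
    return fixture


# ---------------------------------------------------------------------------
# gene-model fixture
# ---------------------------------------------------------------------------

_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = sorted(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOPS
)

#: residue coordinates of the protein domains (1-based inclusive)
PROTEIN_DOMAINS = (
    ("NYD-SP28", 5, 108),
    ("CC1", 112, 170),
    ("CC2", 200, 260),
    ("CC3", 300, 360),
)


@dataclass
class GeneModelFixture:
    model: TranscriptModel
    variant: VariantRecord
    domains: tuple


def emit_gene_model_fixture(out_dir=None) -> GeneModelFixture:
    """Deterministic minus-strand gene model mirroring the affected gene.

    The transcript has a 190-nt 5'UTR, a 1497-nt CDS (498 residues plus
    the stop), and a 200-nt 3'UTR over four exons; codon 111 is GAA
    (glutamate) at transcript positions 521-523, and the genomic base
    under transcript position 521 is placed at the published variant
    coordinate so that the forward-strand C>A substitution reads G>T on
    the transcript and truncates the protein at residue 111.  The 190-nt
    5'UTR is a coordinate-reconciling assumption of this fixture, not an
    annotated UTR length.
    """
    rng = np.random.default_rng(20_211_224)  # fixed: fixture is deterministic
    utr5 = "".join(rng.choice(list("ACGT"), size=190))
    n_codons = 498
    codons = ["ATG"] + [str(rng.choice(_SENSE_CODONS)) for _ in range(n_codons - 1)]
    codons[110] = "GAA"  # residue 111, transcript 521-523
    cds = "".join(codons) + "TAA"
    utr3 = "".join(rng.choice(list("ACGT"), size=200))
    sequence = utr5 + cds + utr3
    assert len(sequence) == 1887

    # minus-strand exon layout (transcript order = descending genomic);
    # transcript position 521 sits 171 bases into exon 3
    exon_lengths = (150, 200, 600, 937)
    introns = (800, 900, 1000)
    g_end3 = CAUSAL_POS + (521 - 350 - 1)
    g_start3 = g_end3 - exon_lengths[2] + 1
    g_start2 = g_end3 + introns[1] + 1
    g_end2 = g_start2 + exon_lengths[1] - 1
    g_start1 = g_end2 + introns[0] + 1
    g_end1 = g_start1 + exon_lengths[0] - 1
    g_end4 = g_start3 - introns[2] - 1
    g_start4 = g_end4 - exon_lengths[3] + 1
    exons = [
        (g_start1, g_end1),
        (g_start2, g_end2),
        (g_start3, g_end3),
        (g_start4, g_end4),
    ]
    model = TranscriptModel(
        transcript_id="TX_CANDIDATE.1",
        chrom=CHROM,
        strand="-",
        exons=exons,
        cds_start_tx=191,
        cds_len_nt=1497,
        sequence=sequence,
    )
    variant = VariantRecord(
        CHROM, CAUSAL_POS, "C", "A", 506.7,
        (("IMPACT", "HIGH"), ("CSQ", "stop_gained")),
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_gene_model([model], out / "gene_model.tsv", out / "transcripts.fasta")
        pd.DataFrame(
            [{"name": n, "start_res": s, "end_res": e} for n, s, e in PROTEIN_DOMAINS]
        ).to_csv(out / "domains.tsv", sep="\t", index=False)
    return GeneModelFixture(model, variant, PROTEIN_DOMAINS)
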