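"""On-disk artifacts of the screening pipeline.

Readers/writers for the VCF v4.2 subset used by the concordance filter
(GT-only, biallelic), sample-status and mating TSVs, and the in-memory
containers the rest of the package operates on.  All user-facing genomic
coordinates are 1-based inclusive; interval arithmetic internal to a
function is 0-based half-open and converted at the boundary.
"""

from __future__ import annotations

import logging
import os
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger("recleth")

# ---------------------------------------------------------------------------
# genotype call encoding
# ---------------------------------------------------------------------------

HOM_REF = "hom_ref"
HET = "het"
HOM_ALT = "hom_alt"
MISSING = "missing"

CALLS = (HOM_REF, HET, HOM_ALT, MISSING)

#: integer codes used inside GenotypeMatrix.calls
CALL_CODES = {HOM_REF: 0, HET: 1, HOM_ALT: 2, MISSING: -1}
CODE_TO_CALL = {v: k for k, v in CALL_CODES.items()}

#: VCF GT strings for each diploid call (unphased; phase is never used)
_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}

HAPLOTYPE_STATUSES = ("carrier_het", "carrier_hom", "non_carrier", "unknown")

#: accepted haplotype-status spellings in status TSVs, including the
#: genotyping-report style "+/+" / "HAP/+" / "HAP/HAP" labels
_STATUS_ALIASES = {
    "carrier_het": "carrier_het",
    "carrier_hom": "carrier_hom",
    "non_carrier": "non_carrier",
    "noncarrier": "non_carrier",
    "unknown": "unknown",
    "+/+": "non_carrier",
    "ldhh6/+": "carrier_het",
    "ldhh6/ldhh6": "carrier_hom",
    "hap/+": "carrier_het",
    "hap/hap": "carrier_hom",
}


class VcfParseError(ValueError):
    """Raised when a VCF header or record cannot be interpreted."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic small variant (SNV or InDel) with its call quality.

    ``pos`` is the 1-based genomic coordinate of the first REF base.
    ``annotations`` carries free-form key/value strings, e.g. a predicted
    impact class under key ``"IMPACT"``.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    qual: float = 0.0
    annotations: tuple = ()  # tuple of (key, value) pairs, hashable

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")
        for allele in (self.ref, self.alt):
            if not allele or set(allele) - set("ACGT"):
                raise ValueError(f"allele {allele!r} not drawn from {{A,C,G,T}}+")
        if self.qual < 0:
            raise ValueError("qual must be non-negative")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    def annotation(self, key: str, default=None):
        return dict(self.annotations).get(key, default)


@dataclass
class GenotypeMatrix:
    """Diploid calls for an ordered variant list over an ordered sample panel.

    ``calls`` is an int8 array of shape (n_variants, n_samples) holding the
    codes in :data:`CALL_CODES` (-1 = missing).  ``rejected`` records every
    input record that was not loaded, as (identifier, reason) pairs, so that
    no record is ever silently dropped.
    """

    variants: list
    samples: list
    calls: np.ndarray
    rejected: list = field(default_factory=list, compare=False)

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.variants), len(self.samples)):
            raise ValueError(
                f"calls shape {self.calls.shape} != "
                f"({len(self.variants)}, {len(self.samples)})"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("sample ids must be unique")

    def __eq__(self, other):
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.variants == other.variants
            and self.samples == other.samples
            and np.array_equal(self.calls, other.calls)
        )

    def call(self, variant_index: int, sample_id: str) -> str:
        return CODE_TO_CALL[int(self.calls[variant_index, self.sample_index(sample_id)])]

    def sample_index(self, sample_id: str) -> int:
        index = getattr(self, "_sample_index", None)
        if index is None or len(index) != len(self.samples):
            index = {s: j for j, s in enumerate(self.samples)}
            object.__setattr__(self, "_sample_index", index)
        return index[sample_id]

    @property
    def n_variants(self) -> int:
        return len(self.variants)


@dataclass(frozen=True)
class SampleStatus:
    """Haplotype-test status of one animal in the genotyped panel."""

    sample_id: str
    breed: str
    haplotype_status: str
    sequenced: bool = False
    cohort_year: int | None = None

    def __post_init__(self):
        if self.haplotype_status not in HAPLOTYPE_STATUSES:
            raise ValueError(
                f"haplotype_status {self.haplotype_status!r} not in {HAPLOTYPE_STATUSES}"
            )


@dataclass
class PhenotypeRecord:
    """One lamb from an at-risk mating: genotype, growth and survival."""

    lamb_id: str
    sex: str
    genotype: str
    birthweight: float | None = None
    weight_d15: float | None = None
    survival_days: int | None = None
    censored: bool = True

    def __post_init__(self):
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be M or F, got {self.sex!r}")
        if self.genotype not in CALLS:
            raise ValueError(f"genotype {self.genotype!r} not a diploid call")

    @property
    def adg_0_15(self) -> float | None:
        """Average daily gain over days 0-15, g/day."""
        if self.birthweight is None or self.weight_d15 is None:
            return None
        return (self.weight_d15 - self.birthweight) / 15.0 * 1000.0


@dataclass
class MatingRecord:
    """One carrier x carrier mating and its outcome."""

    mating_id: str
    sire_genotype: str
    dam_genotype: str
    inseminated: bool = True
    pregnant: bool = False
    offspring: list = field(default_factory=list)

    def __post_init__(self):
        if self.offspring and not self.pregnant:
            raise ValueError("offspring recorded for a non-pregnant mating")


# ---------------------------------------------------------------------------
# region strings
# ---------------------------------------------------------------------------

_REGION_RE = re.compile(r"^([^:]+):([\d,]+)-([\d,]+)$")


def parse_region(region: str) -> tuple[str, int, int]:
    """Parse ``chrom:start-end`` (1-based inclusive; commas allowed)."""
    m = _REGION_RE.match(region)
    if not m:
        raise ValueError(f"malformed region {region!r}, expected chrom:start-end")
    chrom = m.group(1)
    start = int(m.group(2).replace(",", ""))
    end = int(m.group(3).replace(",", ""))
    if start < 1 or end < start:
        raise ValueError(f"malformed region {region!r}: need 1 <= start <= end")
    return chrom, start, end


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def read_vcf(path, region: str | None = None, split_multiallelic: bool = False) -> GenotypeMatrix:
    """Load a VCF into a :class:`GenotypeMatrix`.

    Only the GT FORMAT field is interpreted; the phase separator ``|`` is
    treated as ``/``.  Multi-allelic records are rejected with a logged
    reason unless ``split_multiallelic`` is set, in which case they are
    split into biallelic records sharing the site.  ``region`` restricts
    the output to records with ``start <= pos <= end`` on the given
    chromosome (no index is required; the file is streamed).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    want = parse_region(region) if region else None
    try:
        vcf = VCF(str(path), gts012=True)
        samples = list(vcf.samples)
    except Exception as exc:  # htslib reports header problems as generic errors
        raise VcfParseError(f"cannot read VCF header of {path}: {exc}") from exc

    variants: list[VariantRecord] = []
    rows: list[np.ndarray] = []
    rejected: list[tuple[str, str]] = []
    seen_chroms: set[str] = set()
    for v in vcf:
        seen_chroms.add(v.CHROM)
        ident = f"{v.CHROM}:{v.POS}"
        if want is not None:
            chrom, start, end = want
            if v.CHROM != chrom or not (start <= v.POS <= end):
                continue
        alts = v.ALT
        if len(alts) != 1 and not split_multiallelic:
            rejected.append((ident, "multiallelic"))
            logger.warning("rejected multi-allelic record at %s", ident)
            continue
        # gts012=True: 0 hom_ref, 1 het, 2 hom_alt, 3 unknown
        gt = np.asarray(v.gt_types, dtype=np.int8)
        gt[gt == 3] = CALL_CODES[MISSING]
        qual = 0.0 if v.QUAL is None else round(float(v.QUAL), 3)
        ann = tuple((k, str(val)) for k, val in dict(v.INFO).items())
        for alt in alts:
            try:
                rec = VariantRecord(v.CHROM, v.POS, v.REF, alt, qual, ann)
            except ValueError as exc:
                rejected.append((ident, f"malformed: {exc}"))
                logger.warning("rejected record at %s: %s", ident, exc)
                continue
            variants.append(rec)
            rows.append(gt.copy())
    if want is not None and want[0] not in seen_chroms:
        logger.warning("region chromosome %s absent from %s", want[0], path)
    calls = (
        np.vstack(rows) if rows else np.empty((0, len(samples)), dtype=np.int8)
    )
    return GenotypeMatrix(variants, samples, calls, rejected=rejected)


def write_vcf(matrix: GenotypeMatrix, path) -> None:
    """Write a GT-only VCF v4.2 with deterministic (chrom, pos, alt) order."""
    order = sorted(
        range(len(matrix.variants)),
        key=lambda i: (matrix.variants[i].chrom, matrix.variants[i].pos, matrix.variants[i].alt),
    )
    contigs = []
    for i in order:
        c = matrix.variants[i].chrom
        if c not in contigs:
            contigs.append(c)
    info_keys: list[str] = []
    for v in matrix.variants:
        for k, _ in v.annotations:
            if k not in info_keys:
                info_keys.append(k)
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c}>" for c in contigs]
    lines += [
        f'##INFO=<ID={k},Number=1,Type=String,Description="{k}">' for k in info_keys
    ]
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(matrix.samples)
    )
    for i in order:
        v = matrix.variants[i]
        info = (
            ";".join(f"{k}={val}" for k, val in v.annotations) if v.annotations else "."
        )
        qual = f"{v.qual:g}"
        gts = "\t".join(_GT_STRINGS[int(c)] for c in matrix.calls[i])
        lines.append(
            f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t{qual}\t.\t{info}\tGT\t{gts}"
        )
    tmp = f"{path}.tmp"
    with open(tmp, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    os.replace(tmp, path)


# ---------------------------------------------------------------------------
# sample-status and mating tables
# ---------------------------------------------------------------------------


def read_status_table(path) -> list[SampleStatus]:
    """Read a sample-status TSV (sample_id, breed, haplotype_status, sequenced[, cohort_year]).

    Unknown status labels become ``unknown`` and are counted in a single
    warning; duplicate sample ids are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "breed", "haplotype_status"}
    if not required <= set(df.columns):
        raise ValueError(f"status table missing columns {required - set(df.columns)}")
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate sample ids in status table: {sorted(set(dup))}")
    out = []
    n_unknown_labels = 0
    for row in df.itertuples(index=False):
        raw = str(row.haplotype_status).strip().lower()
        status = _STATUS_ALIASES.get(raw)
        if status is None:
            status = "unknown"
            n_unknown_labels += 1
        sequenced = str(getattr(row, "sequenced", "False")).strip().lower() in ("1", "true", "yes")
        year = getattr(row, "cohort_year", None)
        year = int(year) if year is not None and str(year) not in ("", "nan", "None") else None
        out.append(SampleStatus(row.sample_id, row.breed, status, sequenced, year))
    if n_unknown_labels:
        logger.warning("%d unrecognized haplotype-status labels mapped to 'unknown'", n_unknown_labels)
    return out


def write_status_table(statuses: list[SampleStatus], path) -> None:
    df = pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "breed": s.breed,
                "haplotype_status": s.haplotype_status,
                "sequenced": s.sequenced,
                "cohort_year": "" if s.cohort_year is None else s.cohort_year,
            }
            for s in statuses
        ]
    )
    df.to_csv(path, sep="\t", index=False)


def write_matings_table(matings: list[MatingRecord], path) -> None:
    """One row per lamb; matings without offspring keep one row with empty lamb fields."""
    rows = []
    for m in matings:
        base = {
            "mating_id": m.mating_id,
            "sire_genotype": m.sire_genotype,
            "dam_genotype": m.dam_genotype,
            "inseminated": m.inseminated,
            "pregnant": m.pregnant,
        }
        if not m.offspring:
            rows.append({**base, "lamb_id": "", "sex": "", "genotype": "",
                         "birthweight": "", "weight_d15": "", "survival_days": "", "censored": ""})
        for lamb in m.offspring:
            rows.append(
                {
                    **base,
                    "lamb_id": lamb.lamb_id,
                    "sex": lamb.sex,
                    "genotype": lamb.genotype,
                    "birthweight": "" if lamb.birthweight is None else round(lamb.birthweight, 3),
                    "weight_d15": "" if lamb.weight_d15 is None else round(lamb.weight_d15, 3),
                    "survival_days": "" if lamb.survival_days is None else lamb.survival_days,
                    "censored": lamb.censored,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_matings_table(path) -> list[MatingRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    matings: dict[str, MatingRecord] = {}
    for row in df.itertuples(index=False):
        mid = row.mating_id
        if mid not in matings:
            matings[mid] = MatingRecord(
                mating_id=mid,
                sire_genotype=row.sire_genotype,
                dam_genotype=row.dam_genotype,
                inseminated=str(row.inseminated).lower() in ("1", "true", "yes"),
                pregnant=str(row.pregnant).lower() in ("1", "true", "yes"),
            )
        if row.lamb_id:
            matings[mid].offspring.append(
                PhenotypeRecord(
                    lamb_id=row.lamb_id,
                    sex=row.sex,
                    genotype=row.genotype,
                    birthweight=float(row.birthweight) if row.birthweight else None,
                    weight_d15=float(row.weight_d15) if row.weight_d15 else None,
                    survival_days=int(float(row.survival_days)) if row.survival_days else None,
                    censored=str(row.censored).lower() in ("1", "true", "yes"),
                )
            )
    return list(matings.values())
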