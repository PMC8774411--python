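"""Candidate-variant prioritization for a homozygote-deficient haplotype.

Given small-variant calls over a sequenced panel containing known
heterozygous carriers of the haplotype, a variant is a candidate for the
linked recessive lethal iff

  (i)   its alternate allele differs from the reference (well-formedness),
  (ii)  every carrier sample is heterozygous for it, and
  (iii) every other sample is homozygous reference,

after restriction to the mapped haplotype region (extended by a flank)
and a call-quality cut.  A missing genotype at any required sample fails
the variant — the conservative choice for a screen whose false positives
are cheap to re-inspect but whose false negative would lose the causal
variant.  A final impact filter keeps only variants annotated with the
required severity class (typically HIGH, i.e. protein-truncating).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from .io_formats import CALL_CODES, GenotypeMatrix, parse_region

logger = logging.getLogger("recleth")

#: fixed first-fail reporting order
FAIL_REASONS = (
    "region",
    "quality",
    "carrier_missing",
    "carrier_not_het",
    "noncarrier_missing",
    "noncarrier_not_homref",
    "impact",
)


@dataclass
class FilterConfig:
    """Parameters of the concordance filter.

    ``region`` is ``chrom:start-end`` (1-based inclusive), extended by
    ``flank_bp`` on each side before filtering.  ``noncarrier_ids`` of
    ``None`` means *all* samples not in ``carrier_ids`` must be homozygous
    reference (carriers of the haplotype are absent from unrelated breeds,
    so every other sequenced genome is informative).
    """

    region: str
    carrier_ids: frozenset
    noncarrier_ids: frozenset | None = None
    flank_bp: int = 1_000_000
    min_qual: float = 30.0
    require_impact: str | None = "HIGH"

    def __post_init__(self):
        self.carrier_ids = frozenset(self.carrier_ids)
        if self.noncarrier_ids is not None:
            self.noncarrier_ids = frozenset(self.noncarrier_ids)
            if self.carrier_ids & self.noncarrier_ids:
                raise ValueError("carrier and non-carrier sets must be disjoint")
        if not self.carrier_ids:
            raise ValueError("carrier_ids must be non-empty")
        if self.flank_bp < 0:
            raise ValueError("flank_bp must be >= 0")
        parse_region(self.region)


@dataclass
class FilterReport:
    """Survivors plus a per-variant first-fail audit trail.

    Counts are monotone: n_input >= n_region >= n_qual >= n_concordant
    >= n_impact.  Every dropped variant appears exactly once in
    ``fail_reasons`` with the first condition (in :data:`FAIL_REASONS`
    order) that it violated.
    """

    n_input: int
    n_region: int
    n_qual: int
    n_concordant: int
    n_impact: int | None = None
    surviving: list = field(default_factory=list)
    fail_reasons: dict = field(default_factory=dict)

    def __post_init__(self):
        counts = [self.n_input, self.n_region, self.n_qual, self.n_concordant]
        if self.n_impact is not None:
            counts.append(self.n_impact)
        if any(a < b for a, b in zip(counts, counts[1:])):
            raise ValueError(f"filter counts not monotone: {counts}")

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_region": self.n_region,
            "n_qual": self.n_qual,
            "n_concordant": self.n_concordant,
            "n_impact": self.n_impact,
            "surviving": [
                {"chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt, "qual": v.qual}
                for v in self.surviving
            ],
            "fail_reasons": {f"{c}:{p}:{a}": r for (c, p, a), r in self.fail_reasons.items()},
        }


def _variant_key(v):
    return (v.chrom, v.pos, v.alt)


def concordance_filter(matrix: GenotypeMatrix, cfg: FilterConfig) -> FilterReport:
    """Apply region -> quality -> carrier-concordance filtering.

    Raises ``KeyError`` listing any configured sample id absent from the
    matrix.  The returned report's ``surviving`` list preserves matrix
    order; ``n_impact`` is left unset (run :func:`impact_filter` next).
    """
    sample_set = set(matrix.samples)
    required = set(cfg.carrier_ids) | set(cfg.noncarrier_ids or ())
    missing = sorted(required - sample_set)
    if missing:
        raise KeyError(f"sample ids not in matrix: {missing}")

    chrom, start, end = parse_region(cfg.region)
    lo, hi = max(1, start - cfg.flank_bp), end + cfg.flank_bp
    carrier_idx = [matrix.samples.index(s) for s in sorted(cfg.carrier_ids)]
    if cfg.noncarrier_ids is None:
        noncarrier_idx = [
            j for j, s in enumerate(matrix.samples) if s not in cfg.carrier_ids
        ]
    else:
        noncarrier_idx = [matrix.samples.index(s) for s in sorted(cfg.noncarrier_ids)]

    het = CALL_CODES["het"]
    hom_ref = CALL_CODES["hom_ref"]
    missing_code = CALL_CODES["missing"]

    surviving = []
    fail = {}
    n_region = n_qual = n_conc = 0
    for i, v in enumerate(matrix.variants):
        key = _variant_key(v)
        if not (v.chrom == chrom and lo <= v.pos <= hi):
            fail[key] = "region"
            continue
        n_region += 1
        if not v.qual > cfg.min_qual:  # strict: "quality score > 30"
            fail[key] = "quality"
            continue
        n_qual += 1
        row = matrix.calls[i]
        carrier_calls = row[carrier_idx]
        if (carrier_calls == missing_code).any():
            fail[key] = "carrier_missing"
            continue
        if not (carrier_calls == het).all():
            fail[key] = "carrier_not_het"
            continue
        nc_calls = row[noncarrier_idx]
        if (nc_calls == missing_code).any():
            fail[key] = "noncarrier_missing"
            continue
        if not (nc_calls == hom_ref).all():
            fail[key] = "noncarrier_not_homref"
            continue
        n_conc += 1
        surviving.append(v)

    report = FilterReport(
        n_input=matrix.n_variants,
        n_region=n_region,
        n_qual=n_qual,
        n_concordant=n_conc,
        surviving=surviving,
        fail_reasons=fail,
    )
    logger.info(
        "concordance filter: %d input -> %d in region -> %d pass quality -> %d concordant",
        report.n_input, report.n_region, report.n_qual, report.n_concordant,
    )
    return report


def impact_filter(
    report: FilterReport, annotations: dict, require_impact: str = "HIGH"
) -> FilterReport:
    """Keep survivors whose annotated impact class equals ``require_impact``.

    ``annotations`` maps (chrom, pos, alt) -> impact string; a survivor's
    own ``IMPACT`` annotation is used as fallback.  An unannotated survivor
    is an error: annotation must run before this filter.
    """
    kept, fail = [], dict(report.fail_reasons)
    for v in report.surviving:
        impact = annotations.get(_variant_key(v), v.annotation("IMPACT"))
        if impact is None:
            raise ValueError(f"variant {_variant_key(v)} has no impact annotation")
        if impact.upper() == require_impact.upper():
            kept.append(v)
        else:
            fail[_variant_key(v)] = "impact"
    out = replace(
        report, n_impact=len(kept), surviving=kept, fail_reasons=fail
    )
    logger.info("impact filter (%s): %d -> %d", require_impact, report.n_concordant, out.n_impact)
    return out
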