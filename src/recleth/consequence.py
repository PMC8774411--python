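"""Minimal transcript-aware consequence engine.

Maps a genomic SNV through a strand-aware exon model onto the spliced
transcript, substitutes the base, translates the coding sequence and
classifies the functional consequence (stop_gained / missense /
synonymous / UTR / intronic / intergenic), emitting HGVS-style g., c.
and p. names.

Coding-coordinate numbering supports two dialects:

``cds``
    strict HGVS: c.1 is the A of the initiator ATG.
``transcript``
    numbering from the first transcript base, as used by annotation
    reports that count through the 5'UTR.

A reference-consistency check compares the model's transcript base with
the (strand-adjusted) VCF REF base and raises on mismatch, which guards
against exon-coordinate bookkeeping errors.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from .io_formats import VariantRecord

logger = logging.getLogger("recleth")

IMPACTS = ("HIGH", "MODERATE", "LOW", "MODIFIER")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class ReferenceMismatchError(ValueError):
    """Transcript sequence disagrees with the VCF REF allele at the mapped base."""


@dataclass
class TranscriptModel:
    """Strand-aware gene model housing the g. <-> c. coordinate arithmetic.

    ``exons`` are genomic 1-based inclusive (start, end) intervals listed in
    *transcript* order (for a minus-strand gene that is decreasing genomic
    order).  ``sequence`` is the spliced transcript on the sense strand.
    ``cds_start_tx`` is the 1-based transcript offset of the first CDS base,
    so the 5'UTR length is ``cds_start_tx - 1``; ``cds_len_nt`` includes the
    terminal stop codon.
    """

    transcript_id: str
    chrom: str
    strand: str
    exons: list
    cds_start_tx: int
    cds_len_nt: int
    sequence: str

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        self.sequence = self.sequence.upper()
        spliced = sum(e - s + 1 for s, e in self.exons)
        if spliced != len(self.sequence):
            raise ValueError(
                f"spliced exon length {spliced} != transcript length {len(self.sequence)}"
            )
        if self.cds_len_nt % 3:
            raise ValueError("CDS length must be divisible by 3")
        if self.cds_start_tx < 1 or self.cds_start_tx + self.cds_len_nt - 1 > spliced:
            raise ValueError("CDS does not fit inside the transcript")
        # exons must be disjoint and ordered along the transcript
        self.exons = [tuple(e) for e in self.exons]
        genomic_sorted = sorted(self.exons)
        for (_, e1), (s2, _) in zip(genomic_sorted, genomic_sorted[1:]):
            if s2 <= e1:
                raise ValueError("exons overlap")
        expected = genomic_sorted if self.strand == "+" else genomic_sorted[::-1]
        if self.exons != expected:
            raise ValueError("exons not in transcript order for the declared strand")
        prot = str(Seq(self.cds).translate())
        if "*" in prot[:-1]:
            raise ValueError("reference CDS contains an internal stop codon")
        if not prot.endswith("*"):
            raise ValueError("reference CDS does not end with a stop codon")

    @property
    def utr5_len(self) -> int:
        return self.cds_start_tx - 1

    @property
    def cds(self) -> str:
        return self.sequence[self.cds_start_tx - 1 : self.cds_start_tx - 1 + self.cds_len_nt]

    @property
    def protein(self) -> str:
        """Reference protein, terminal stop excluded."""
        return str(Seq(self.cds).translate())[:-1]

    @property
    def gene_span(self) -> tuple[int, int]:
        starts, ends = zip(*self.exons)
        return min(starts), max(ends)


@dataclass
class ConsequenceCall:
    """Classified effect of one SNV on one transcript."""

    hgvs_g: str
    hgvs_c: str | None
    hgvs_p: str | None
    impact: str
    consequence_term: str
    codon_index: int | None = None
    ref_protein_len: int | None = None
    alt_protein_len: int | None = None

    def __post_init__(self):
        if self.impact not in IMPACTS:
            raise ValueError(f"impact {self.impact!r} not in {IMPACTS}")
        if (self.impact == "HIGH") != (self.consequence_term == "stop_gained"):
            raise ValueError("HIGH impact is reserved for stop_gained in this engine")


# ---------------------------------------------------------------------------
# coordinate mapping
# ---------------------------------------------------------------------------


def genomic_to_transcript(model: TranscriptModel, pos: int, allele_fwd: str):
    """Map a genomic position + forward-strand allele onto the transcript.

    Returns ``(tx_pos, allele_tx)`` with ``tx_pos`` the 1-based position in
    the spliced transcript, or ``None`` if ``pos`` falls outside every exon.
    On a minus-strand model the allele is reverse-complemented.
    """
    offset = 0
    for start, end in model.exons:
        if start <= pos <= end:
            if model.strand == "+":
                tx_pos = offset + (pos - start + 1)
            else:
                tx_pos = offset + (end - pos + 1)
            allele_tx = allele_fwd if model.strand == "+" else revcomp(allele_fwd)
            return tx_pos, allele_tx
        offset += end - start + 1
    return None


def transcript_to_genomic(model: TranscriptModel, tx_pos: int) -> int:
    """Inverse of :func:`genomic_to_transcript` for a single base."""
    if tx_pos < 1 or tx_pos > len(model.sequence):
        raise ValueError(f"tx_pos {tx_pos} outside transcript")
    offset = 0
    for start, end in model.exons:
        length = end - start + 1
        if tx_pos <= offset + length:
            within = tx_pos - offset - 1
            return start + within if model.strand == "+" else end - within
        offset += length
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# consequence calling
# ---------------------------------------------------------------------------


def _hgvs_g(variant: VariantRecord) -> str:
    return f"{variant.chrom}:g.{variant.pos}{variant.ref}>{variant.alt}"


def call_consequence(
    model: TranscriptModel, variant: VariantRecord, dialect: str = "cds"
) -> ConsequenceCall:
    """Classify one SNV against one transcript model.

    ``dialect`` selects the c. numbering origin (see module docstring).
    InDels are not classified: they pass through with consequence term
    ``unsupported`` and impact MODIFIER, with a warning.
    """
    if dialect not in ("cds", "transcript"):
        raise ValueError(f"unknown dialect {dialect!r}")
    hgvs_g = _hgvs_g(variant)
    if not variant.is_snv:
        logger.warning("InDel %s passed through unclassified (SNV-only engine)", hgvs_g)
        return ConsequenceCall(hgvs_g, None, None, "MODIFIER", "unsupported")
    if variant.chrom != model.chrom:
        return ConsequenceCall(hgvs_g, None, None, "MODIFIER", "intergenic")

    mapped = genomic_to_transcript(model, variant.pos, variant.alt)
    if mapped is None:
        lo, hi = model.gene_span
        term = "intronic" if lo <= variant.pos <= hi else "intergenic"
        return ConsequenceCall(hgvs_g, None, None, "MODIFIER", term)
    tx_pos, alt_tx = mapped
    ref_tx = variant.ref if model.strand == "+" else revcomp(variant.ref)
    model_base = model.sequence[tx_pos - 1]
    if model_base != ref_tx:
        raise ReferenceMismatchError(
            f"transcript {model.transcript_id} has {model_base} at tx position "
            f"{tx_pos}, VCF REF maps to {ref_tx}"
        )

    c_number = tx_pos if dialect == "transcript" else tx_pos - model.utr5_len
    hgvs_c = f"{model.transcript_id}:c.{c_number}{ref_tx}>{alt_tx}"

    cds_pos = tx_pos - model.utr5_len  # 1-based within CDS when positive
    if cds_pos < 1:
        return ConsequenceCall(hgvs_g, hgvs_c, None, "MODIFIER", "5_prime_utr")
    if cds_pos > model.cds_len_nt:
        return ConsequenceCall(hgvs_g, hgvs_c, None, "MODIFIER", "3_prime_utr")

    codon_index = math.ceil(cds_pos / 3)
    ref_cds = model.cds
    alt_cds = ref_cds[: cds_pos - 1] + alt_tx + ref_cds[cds_pos:]
    ref_prot_full = str(Seq(ref_cds).translate())  # ends with '*'
    alt_prot_full = str(Seq(alt_cds).translate())
    ref_len = len(ref_prot_full) - 1
    alt_stop = alt_prot_full.find("*")
    alt_len = alt_stop if alt_stop != -1 else len(alt_prot_full)

    ref_aa = ref_prot_full[codon_index - 1]
    alt_aa = alt_prot_full[codon_index - 1]

    if ref_aa == "*":  # substitution inside the terminal stop codon
        if alt_aa == "*":
            term, impact = "synonymous", "LOW"
            hgvs_p = f"{model.transcript_id}:p.Ter{codon_index}="
        else:
            # stop-loss is outside the severity scope of this engine
            term, impact = "stop_lost", "MODERATE"
            hgvs_p = f"{model.transcript_id}:p.Ter{codon_index}{seq3(alt_aa)}ext*?"
            logger.warning("stop_lost at %s classified MODERATE (engine scope)", hgvs_g)
        return ConsequenceCall(hgvs_g, hgvs_c, hgvs_p, impact, term, codon_index, ref_len, alt_len)

    if alt_aa == "*":
        term, impact = "stop_gained", "HIGH"
        hgvs_p = f"{model.transcript_id}:p.{seq3(ref_aa)}{codon_index}*"
    elif alt_aa == ref_aa:
        term, impact = "synonymous", "LOW"
        hgvs_p = f"{model.transcript_id}:p.{seq3(ref_aa)}{codon_index}="
    else:
        term, impact = "missense", "MODERATE"
        hgvs_p = f"{model.transcript_id}:p.{seq3(ref_aa)}{codon_index}{seq3(alt_aa)}"
    return ConsequenceCall(
        hgvs_g, hgvs_c, hgvs_p, impact, term, codon_index, ref_len, alt_len
    )


def truncation_summary(call: ConsequenceCall, domains: list) -> dict:
    """Partition protein domains by a premature-stop call.

    ``domains`` is a list of (name, start_res, end_res) with 1-based
    inclusive residue coordinates.  A domain wholly C-terminal of the new
    stop is ``lost``; one straddling it is ``partially_retained``; one
    ending before it is ``retained``.
    """
    if call.consequence_term != "stop_gained":
        raise ValueError("truncation summary is only defined for stop_gained calls")
    idx = call.codon_index
    out = {"retained": [], "partially_retained": [], "lost": []}
    for name, start, end in domains:
        if end < idx:
            out["retained"].append(name)
        elif start >= idx:
            out["lost"].append(name)
        else:
            out["partially_retained"].append(name)
    return out


# ---------------------------------------------------------------------------
# gene-model files
# ---------------------------------------------------------------------------


def read_gene_model(tsv_path, fasta_path) -> list[TranscriptModel]:
    """Load transcript models from a gene-model TSV plus a transcript FASTA.

    TSV columns: transcript_id, chrom, strand, exons ("start-end;start-end",
    transcript order), cds_start_tx, cds_len_nt.  The FASTA is keyed by
    transcript id and holds the spliced sense-strand sequence.
    """
    import pandas as pd
    from Bio import SeqIO

    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    df = pd.read_csv(tsv_path, sep="\t", dtype=str)
    models = []
    for row in df.itertuples(index=False):
        exons = []
        for chunk in row.exons.split(";"):
            s, e = chunk.split("-")
            exons.append((int(s.replace(",", "")), int(e.replace(",", ""))))
        if row.transcript_id not in seqs:
            raise ValueError(f"transcript {row.transcript_id} missing from FASTA")
        models.append(
            TranscriptModel(
                transcript_id=row.transcript_id,
                chrom=row.chrom,
                strand=row.strand,
                exons=exons,
                cds_start_tx=int(row.cds_start_tx),
                cds_len_nt=int(row.cds_len_nt),
                sequence=seqs[row.transcript_id],
            )
        )
    return models


def write_gene_model(models: list, tsv_path, fasta_path) -> None:
    import pandas as pd

    rows = [
        {
            "transcript_id": m.transcript_id,
            "chrom": m.chrom,
            "strand": m.strand,
            "exons": ";".join(f"{s}-{e}" for s, e in m.exons),
            "cds_start_tx": m.cds_start_tx,
            "cds_len_nt": m.cds_len_nt,
        }
        for m in models
    ]
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)
    with open(fasta_path, "w") as fh:
        for m in models:
            fh.write(f">{m.transcript_id}\n")
            for i in range(0, len(m.sequence), 60):
                fh.write(m.sequence[i : i + 60] + "\n")
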