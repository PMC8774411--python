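"""End-to-end orchestration: ingest/simulate -> prioritize -> consequence -> stats.

A single configuration dict (flat YAML on disk) drives every stage and
the result is one :class:`PipelineReport` mirroring the study's result
set: the filter funnel, the consequence call for each high-impact
candidate, and the validation statistics (homozygote deficiency, exact
association, Hardy-Weinberg, segregation, concordance audit, allele
frequency, AI success, attributable mortality).  Any stage failure
aborts with a stage-tagged error; the JSON/TSV report is written
atomically.  When an input file is not named, the packaged deterministic
fixtures / published counts stand in, so the full chain runs with no
external data.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

from . import consequence as cq
from . import io_formats as iof
from . import prioritize as pri
from . import stats as st
from . import syndata as syn

logger = logging.getLogger("recleth")

REPORT_SCHEMA_VERSION = 1


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


DEFAULT_CONFIG = {
    "seed": 1,
    "prioritize": {
        "vcf": None,
        "status": None,
        "region": syn.HAPLOTYPE_REGION,
        "flank_bp": 1_000_000,
        "min_qual": 30.0,
        "require_impact": "HIGH",
        "decoys": 30,
    },
    "consequence": {
        "gene_model": None,  # "TSV,FASTA" paths; packaged fixture when null
        "dialect": "transcript",
    },
    "stats": {
        "deficiency": {
            "observed": syn.DEFICIENCY_OBSERVED,
            "expected": syn.DEFICIENCY_EXPECTED,
        },
        "cohort_counts": None,  # published contingency when null
        "matings": None,  # matings TSV; published offspring counts when null
        "ai": {"successes": syn.AI_SUCCESS[0], "trials": syn.AI_SUCCESS[1]},
        "mortality": {"q": syn.ALLELE_FREQUENCY_ROUND, "m": syn.LAMB_MORTALITY_RATE},
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            out[k] = _merge(base[k], v)
        else:
            out[k] = v
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Default config, optionally overlaid with a YAML file and a dict."""
    cfg = DEFAULT_CONFIG
    if path is not None:
        import yaml

        with open(path) as fh:
            cfg = _merge(cfg, yaml.safe_load(fh) or {})
    return _merge(cfg, overrides or {})


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


@dataclass
class PipelineReport:
    """All stage results plus provenance; serializable as JSON and flat TSV."""

    config: dict
    provenance: dict
    filter: dict = field(default_factory=dict)
    consequence: list = field(default_factory=list)
    stats: dict = field(default_factory=dict)
    skipped: dict = field(default_factory=dict)  # section -> reason

    def to_dict(self) -> dict:
        return {
            "schema_version": REPORT_SCHEMA_VERSION,
            "provenance": self.provenance,
            "filter": self.filter,
            "consequence": self.consequence,
            "stats": self.stats,
            "skipped": self.skipped,
        }

    def flat_items(self):
        def walk(prefix, obj):
            if isinstance(obj, dict):
                for k, v in obj.items():
                    yield from walk(f"{prefix}.{k}" if prefix else str(k), v)
            elif isinstance(obj, (list, tuple)):
                for i, v in enumerate(obj):
                    yield from walk(f"{prefix}[{i}]", v)
            else:
                yield prefix, obj

        yield from walk("", self.to_dict())

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        payload = json.dumps(self.to_dict(), indent=2, default=_jsonable)
        tmp = out / "report.json.tmp"
        tmp.write_text(payload + "\n")
        os.replace(tmp, out / "report.json")
        lines = ["key\tvalue"] + [f"{k}\t{v}" for k, v in self.flat_items()]
        tmp = out / "report.tsv.tmp"
        tmp.write_text("\n".join(lines) + "\n")
        os.replace(tmp, out / "report.tsv")


def _jsonable(x):
    import numpy as np

    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    return str(x)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _stage_prioritize(config):
    c = config["prioritize"]
    if c["vcf"] is not None:
        matrix = iof.read_vcf(c["vcf"], region=None)
        statuses = iof.read_status_table(c["status"])
        carriers = frozenset(
            s.sample_id for s in statuses if s.haplotype_status == "carrier_het" and s.sequenced
        )
        annotations = {}
    else:
        fixture = syn.emit_candidate_fixture(decoys=int(c["decoys"]), seed=int(config["seed"]))
        matrix, carriers, annotations = fixture.matrix, fixture.carrier_ids, fixture.annotations
    if not carriers:
        raise StageError("prioritize: no sequenced heterozygous carriers in the status table")
    fcfg = pri.FilterConfig(
        region=c["region"],
        carrier_ids=carriers,
        flank_bp=int(c["flank_bp"]),
        min_qual=float(c["min_qual"]),
        require_impact=c["require_impact"],
    )
    report = pri.concordance_filter(matrix, fcfg)
    report = pri.impact_filter(report, annotations, require_impact=c["require_impact"])
    return report


def _stage_consequence(config, survivors):
    c = config["consequence"]
    if c["gene_model"] is not None:
        tsv, fasta = (p.strip() for p in str(c["gene_model"]).split(","))
        models = cq.read_gene_model(tsv, fasta)
        domains = ()
    else:
        fixture = syn.emit_gene_model_fixture()
        models, domains = [fixture.model], fixture.domains
    calls = []
    for v in survivors:
        for model in models:
            call = cq.call_consequence(model, v, dialect=c["dialect"])
            entry = {
                "hgvs_g": call.hgvs_g,
                "hgvs_c": call.hgvs_c,
                "hgvs_p": call.hgvs_p,
                "impact": call.impact,
                "consequence_term": call.consequence_term,
                "codon_index": call.codon_index,
                "ref_protein_len": call.ref_protein_len,
                "alt_protein_len": call.alt_protein_len,
            }
            if call.consequence_term == "stop_gained" and domains:
                entry["domains"] = cq.truncation_summary(call, list(domains))
            calls.append(entry)
    return calls


def _stage_stats(config):
    c = config["stats"]
    out = {}
    skipped = {}

    d = c["deficiency"]
    res = st.deficiency_test(int(d["observed"]), float(d["expected"]))
    out["deficiency"] = {
        "observed": res.observed, "expected": res.expected,
        "deficit": res.deficit, "deficit_percent": st.percent_half_up(res.deficit),
        "p_value": res.p_value, "model": res.model,
    }

    if c["cohort_counts"] is None:
        counts = syn.cohort_genotype_counts()
        table2x2 = syn.cohort_association_table()
        cohort = syn.cohort_as_samples()
    else:
        counts = tuple(int(x) for x in c["cohort_counts"])
        table2x2 = None
        cohort = None
    hwe = st.hwe_chisq(counts)
    freq = st.allele_frequency(counts)
    out["cohort_hwe"] = {
        "observed": hwe.observed, "expected": hwe.expected,
        "chi2": hwe.chi2, "df": hwe.df, "p_value": hwe.p_value,
    }
    out["allele_frequency"] = {
        "n": freq.n, "q_hat": freq.q_hat, "q_percent": freq.q_percent,
        "carrier_frequency": freq.carrier_frequency,
        "carrier_percent": freq.carrier_percent,
    }
    if table2x2 is not None:
        out["association"] = {
            "table": [list(map(int, r)) for r in table2x2],
            "fisher_p": st.fisher_exact_2x2(table2x2),
        }
    else:
        skipped["association"] = "no status x genotype contingency provided"
    if cohort is not None:
        audit = st.concordance_audit(cohort)
        out["audit"] = {
            "n": audit.n, "n_discordant": audit.n_discordant,
            "status_noncarrier_genotype_het": audit.status_noncarrier_genotype_het,
            "status_carrier_genotype_homref": audit.status_carrier_genotype_homref,
            "other_discordant": audit.other_discordant, "n_missing": audit.n_missing,
        }
    else:
        skipped["audit"] = "no per-sample status/genotype cohort provided"

    if c["matings"] is not None:
        matings = iof.read_matings_table(c["matings"])
        seg = st.segregation_test(matings, df_mode="classes")
        offspring_counts = seg.observed
        out["segregation"] = {
            "observed": seg.observed, "expected": seg.expected,
            "chi2": seg.chi2, "df": seg.df, "p_value": seg.p_value,
            "n_mendelian_errors": seg.n_mendelian_errors,
        }
    else:
        offspring_counts = syn.ATRISK_OFFSPRING_COUNTS
        skipped["segregation"] = "no matings table; pooled offspring counts used for HWE test"
    seg_hwe = st.hwe_chisq(offspring_counts)
    out["offspring_hwe"] = {
        "observed": seg_hwe.observed, "expected": seg_hwe.expected,
        "chi2": seg_hwe.chi2, "df": seg_hwe.df, "p_value": seg_hwe.p_value,
    }

    ai = st.rate(int(c["ai"]["successes"]), int(c["ai"]["trials"]))
    out["ai_success"] = {
        "successes": ai.successes, "trials": ai.trials,
        "proportion": ai.proportion, "percent": ai.percent,
    }

    m = c["mortality"]
    mort = st.attributable_mortality(float(m["q"]), float(m["m"]))
    out["attributable_mortality"] = {
        "q": mort.q, "m": mort.m,
        "fraction_of_deaths": mort.fraction_of_deaths,
        "as_percent": mort.as_percent, "as_one_in_n": mort.as_one_in_n,
    }
    return out, skipped


def run_pipeline(config: dict | None = None, out_dir=None) -> PipelineReport:
    """Execute every stage in order and return (and optionally write) the report."""
    config = _merge(DEFAULT_CONFIG, config or {})
    try:
        pkg_version = version("recleth")
    except PackageNotFoundError:  # running from a source tree
        pkg_version = "unknown"
    report = PipelineReport(
        config=config,
        provenance={
            "seed": config["seed"],
            "config_hash": _config_hash(config),
            "package_version": pkg_version,
            "schema_version": REPORT_SCHEMA_VERSION,
        },
    )

    try:
        filter_report = _stage_prioritize(config)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"prioritize: {exc}") from exc
    report.filter = filter_report.to_dict()

    if filter_report.n_impact:
        try:
            report.consequence = _stage_consequence(config, filter_report.surviving)
        except Exception as exc:
            raise StageError(f"consequence: {exc}") from exc
    else:
        report.skipped["consequence"] = "no high-impact candidate survived the filter"

    try:
        report.stats, skipped = _stage_stats(config)
    except Exception as exc:
        raise StageError(f"stats: {exc}") from exc
    report.skipped.update(skipped)

    if out_dir is not None:
        report.write(out_dir)
    return report
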