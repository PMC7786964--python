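"""Stage orchestration: run the whole analysis from a single validated
config and write every stage's outputs plus a summary report.

Stages run in dependency order: classify -> identify -> specificity /
features / sexbias -> synteny -> neighbors -> goenrich.  A stage failure
aborts with a stage-tagged error; outputs already written are preserved.
The config (and its hash) are recorded in the report so identical configs
provably produce identical results.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import (
    context_classifier,
    conservation_synteny,
    diffexp_summary,
    expression_specificity,
    genomic_features,
    lncrna_identification,
    neighbor_regulation,
)
from .io_formats import (
    read_de_table,
    read_evidence_table,
    read_expression_table,
    read_fasta,
    read_go_annotations,
    read_gtf,
    read_ortholog_table,
    read_te_bed,
    write_gtf,
)
from .lncrna_identification import FilterCriteria, round_half_up

logger = logging.getLogger("lncscape")

__all__ = ["PipelineError", "load_config", "run_pipeline", "report_ratio"]

KNOWN_INPUT_KEYS = {
    "genome", "reference_gtf", "candidates_gtf", "te_bed",
    "counts", "groups", "lengths", "library_sizes",
    "evidence", "de_table", "orthologs", "go", "go_terms",
    "lnc_b_loci", "pcg_b_gtf",
}
REQUIRED_INPUT_KEYS = {
    "genome", "reference_gtf", "candidates_gtf", "te_bed",
    "counts", "groups", "lengths", "evidence", "de_table",
}
KNOWN_PARAM_KEYS = {
    "min_length_nt", "min_exons", "max_orf_nt", "min_rpkm_max",
    "js_threshold", "max_dist", "cis_threshold", "q_cutoff",
    "te_mode", "synteny_k", "synteny_min_shared", "allow_inversion",
}
KNOWN_TOP_KEYS = {"inputs", "params", "outdir", "seed"}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def report_ratio(numerator: float, denominator: float) -> str:
    """Percentage string, two decimals, round half-up ('63.75%');
    'NA' for a zero denominator."""
    if denominator == 0:
        return "NA"
    return f"{round_half_up(100.0 * numerator / denominator, 2):.2f}%"


def load_config(path: str | Path) -> dict:
    """Load and schema-validate a YAML pipeline config; unknown keys are
    rejected and required inputs must exist on disk."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    unknown = set(cfg) - KNOWN_TOP_KEYS
    if unknown:
        raise PipelineError("config", f"unknown keys: {sorted(unknown)}")
    inputs = cfg.get("inputs", {})
    unknown = set(inputs) - KNOWN_INPUT_KEYS
    if unknown:
        raise PipelineError("config", f"unknown input keys: {sorted(unknown)}")
    missing = REQUIRED_INPUT_KEYS - set(inputs)
    if missing:
        raise PipelineError("config", f"missing inputs: {sorted(missing)}")
    params = cfg.get("params", {})
    unknown = set(params) - KNOWN_PARAM_KEYS
    if unknown:
        raise PipelineError("config", f"unknown param keys: {sorted(unknown)}")
    base = Path(path).parent
    for key, p in inputs.items():
        full = (base / p) if not Path(p).is_absolute() else Path(p)
        if not full.exists():
            raise PipelineError("config", f"input {key!r} not found: {full}")
        inputs[key] = str(full)
    cfg["inputs"] = inputs
    cfg["params"] = params
    return cfg


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()
    ).hexdigest()[:16]


def run_pipeline(cfg: dict, outdir: str | Path | None = None) -> dict:
    """Run every stage; returns a results dict and writes per-stage TSVs
    plus ``report.json`` under the output directory."""
    out = Path(outdir or cfg.get("outdir", "lncscape_out"))
    out.mkdir(parents=True, exist_ok=True)
    inputs = cfg["inputs"]
    params = cfg.get("params", {})
    results: dict = {"config_hash": _config_hash(cfg)}

    def stage(name):
        logger.info("stage %s", name)

    # ---- load inputs --------------------------------------------------
    try:
        genome = read_fasta(inputs["genome"])
        reference = read_gtf(inputs["reference_gtf"])
        reference.chrom_sizes.update({c: len(s) for c, s in genome.items()})
        candidates = read_gtf(inputs["candidates_gtf"])
        te_track = read_te_bed(inputs["te_bed"])
        expression = read_expression_table(
            inputs["counts"], inputs["groups"], inputs["lengths"],
            inputs.get("library_sizes"),
        )
        evidence = read_evidence_table(inputs["evidence"])
        de_table = read_de_table(inputs["de_table"])
    except Exception as exc:  # noqa: BLE001 - stage-tagged rethrow
        raise PipelineError("load", str(exc)) from exc

    # ---- classify -----------------------------------------------------
    stage("classify")
    try:
        codes = context_classifier.classify_transcripts(candidates, reference)
        codes_out = codes.copy()
        codes_out["code"] = [c.letter for c in codes_out["code"]]
        codes_out.to_csv(out / "codes.tsv", sep="\t")
        results["codes"] = codes
    except Exception as exc:
        raise PipelineError("classify", str(exc)) from exc

    # ---- identify -----------------------------------------------------
    stage("identify")
    try:
        criteria = FilterCriteria(
            min_length_nt=params.get("min_length_nt", 200),
            min_exons=params.get("min_exons", 2),
            max_orf_nt=params.get("max_orf_nt", 300),
            min_rpkm_max=params.get("min_rpkm_max", 1.0),
        )
        code_map = codes["code"].to_dict()
        pool = [candidates[tid] for tid, code in code_map.items()
                if code in context_classifier.CANDIDATE_CODES]
        records, report = lncrna_identification.apply_filter_cascade(
            pool, code_map, genome, evidence, expression, criteria
        )
        from .io_formats import Annotation
        lnc_annotation = Annotation(
            [r.transcript for r in records],
            chrom_sizes=reference.chrom_sizes,
        )
        write_gtf(lnc_annotation, out / "lncRNA.gtf")
        report.to_frame().to_csv(out / "filter_report.tsv", sep="\t",
                                 index=False)
        composition = lncrna_identification.summarize_composition(records)
        composition.to_csv(out / "composition.tsv", sep="\t")
        results["records"] = records
        results["composition"] = composition
        results["filter_report"] = report
    except Exception as exc:
        raise PipelineError("identify", str(exc)) from exc

    lnc_ids = {r.transcript.transcript_id for r in records}
    pcg_gene_ids = reference.gene_ids()

    # ---- specificity --------------------------------------------------
    stage("specificity")
    try:
        profile = expression_specificity.average_replicates(expression)
        scores = expression_specificity.score_profiles(profile)
        scores.to_csv(out / "specificity_scores.tsv", sep="\t")
        lnc_scores = scores.loc[scores.index.isin(lnc_ids)]
        pcg_scores = scores.loc[scores.index.isin(pcg_gene_ids)]
        ks = expression_specificity.compare_specificity(
            lnc_scores["js_score"], pcg_scores["js_score"]
        )
        results["specificity"] = {
            "scores": scores,
            "ks_lnc_vs_pcg": ks,
            "js_median_lnc": float(lnc_scores["js_score"].median()),
            "js_median_pcg": float(pcg_scores["js_score"].median()),
        }
        results["profile"] = profile
    except Exception as exc:
        raise PipelineError("specificity", str(exc)) from exc

    # ---- features -----------------------------------------------------
    stage("features")
    try:
        lnc_transcripts = [r.transcript for r in records]
        pcg_transcripts = list(reference)
        lnc_stats = genomic_features.size_stats(lnc_transcripts)
        pcg_stats = genomic_features.size_stats(pcg_transcripts)
        te_mode = params.get("te_mode", "exon")
        flags_lnc, flags_pcg, table, fisher = genomic_features.te_overlap(
            lnc_transcripts, te_track, pcg_transcripts, mode=te_mode
        )
        chrom_table, chrom_corr = genomic_features.chromosome_distribution(
            lnc_transcripts, reference
        )
        chrom_table.to_csv(out / "chromosome_distribution.tsv", sep="\t")
        results["features"] = {
            "lnc_medians": lnc_stats.medians(),
            "pcg_medians": pcg_stats.medians(),
            "te_table": table,
            "te_fisher": fisher,
            "te_share_lnc": report_ratio(int(flags_lnc.sum()), len(flags_lnc)),
            "chrom_correlations": chrom_corr,
        }
    except Exception as exc:
        raise PipelineError("features", str(exc)) from exc

    # ---- sexbias ------------------------------------------------------
    stage("sexbias")
    try:
        up, down = diffexp_summary.call_biased(de_table)
        lnc_up, lnc_down = len(up & lnc_ids), len(down & lnc_ids)
        pcg_up = len(up & pcg_gene_ids)
        pcg_down = len(down & pcg_gene_ids)
        odds, fisher = diffexp_summary.sex_bias_fisher(
            pcg_up, pcg_down, lnc_up, lnc_down
        )
        pd.DataFrame([
            {"class": "PCG", "male_biased": pcg_up, "female_biased": pcg_down},
            {"class": "lncRNA", "male_biased": lnc_up,
             "female_biased": lnc_down},
        ]).to_csv(out / "sex_bias.tsv", sep="\t", index=False)
        results["sexbias"] = {
            "pcg": (pcg_up, pcg_down), "lnc": (lnc_up, lnc_down),
            "odds_ratio": odds, "fisher": fisher,
        }
    except Exception as exc:
        raise PipelineError("sexbias", str(exc)) from exc

    # ---- synteny (optional inputs) ------------------------------------
    if {"orthologs", "lnc_b_loci", "pcg_b_gtf"} <= set(inputs):
        stage("synteny")
        try:
            orthologs = read_ortholog_table(inputs["orthologs"])
            pcg_b = read_gtf(inputs["pcg_b_gtf"])
            lnc_b_df = pd.read_csv(inputs["lnc_b_loci"], sep="\t")
            loci_b = {
                str(r.locus_id): (str(r.chrom), int(r.start), int(r.end))
                for r in lnc_b_df.itertuples()
            }
            loci_a: dict[str, tuple[str, int, int]] = {}
            for r in records:
                t = r.transcript
                if t.gene_id in loci_a:
                    c, s, e = loci_a[t.gene_id]
                    loci_a[t.gene_id] = (c, min(s, t.start), max(e, t.end))
                else:
                    loci_a[t.gene_id] = (t.chrom, t.start, t.end)
            families, pairs = conservation_synteny.find_synteny_families(
                loci_a, loci_b, reference, pcg_b, orthologs,
                k=params.get("synteny_k", 3),
                min_shared=params.get("synteny_min_shared", 3),
                allow_inversion=params.get("allow_inversion", False),
            )
            pairs.to_csv(out / "synteny_pairs.tsv", sep="\t", index=False)
            fam_rows = [
                {"family_id": f.family_id,
                 "members": ";".join(
                     f"{sp}:{l}" for sp in sorted(f.members)
                     for l in sorted(f.members[sp]))}
                for f in families
            ]
            pd.DataFrame(fam_rows).to_csv(out / "families.tsv", sep="\t",
                                          index=False)
            results["synteny"] = {"families": families, "pairs": pairs}
        except Exception as exc:
            raise PipelineError("synteny", str(exc)) from exc

    # ---- neighbors ----------------------------------------------------
    stage("neighbors")
    try:
        max_dist = params.get("max_dist", 10_000)
        pcg_spans = reference.gene_spans()
        lnc_spans = pd.DataFrame(
            {
                "chrom": [r.transcript.chrom for r in records],
                "start": [r.transcript.start for r in records],
                "end": [r.transcript.end for r in records],
                "strand": [r.transcript.strand for r in records],
            },
            index=[r.transcript.transcript_id for r in records],
        )
        lnc_pairs = neighbor_regulation.find_neighbors(
            lnc_spans, pcg_spans, max_dist=max_dist
        )
        pcg_pairs = neighbor_regulation.find_neighbors(
            pcg_spans, pcg_spans, max_dist=max_dist
        )
        neighbor_regulation.correlate_pairs(lnc_pairs, profile)
        neighbor_regulation.correlate_pairs(pcg_pairs, profile)
        threshold = params.get("cis_threshold", 0.5)
        cis, n_pos, n_neg = neighbor_regulation.call_cis_candidates(
            lnc_pairs, threshold
        )
        strata = neighbor_regulation.compare_strata(lnc_pairs, pcg_pairs)
        pd.DataFrame([vars(p) for p in lnc_pairs]).to_csv(
            out / "neighbor_pairs.tsv", sep="\t", index=False)
        results["neighbors"] = {
            "lnc_pairs": lnc_pairs, "pcg_pairs": pcg_pairs,
            "cis": cis, "n_pos": n_pos, "n_neg": n_neg, "strata": strata,
        }
    except Exception as exc:
        raise PipelineError("neighbors", str(exc)) from exc

    # ---- goenrich (optional input) ------------------------------------
    if "go" in inputs:
        stage("goenrich")
        try:
            go = read_go_annotations(inputs["go"], inputs.get("go_terms"))
            query = sorted({p.partner_id for p in cis
                            if p.partner_id in pcg_gene_ids})
            background = sorted(pcg_gene_ids)
            enrich = neighbor_regulation.go_enrichment(
                query, background, go, q_cutoff=params.get("q_cutoff", 0.05)
            )
            enrich.to_csv(out / "go_enrichment.tsv", sep="\t", index=False)
            results["goenrich"] = enrich
        except Exception as exc:
            raise PipelineError("goenrich", str(exc)) from exc

    # ---- report -------------------------------------------------------
    total = len(records)
    comp = results["composition"]
    report_obj = {
        "config_hash": results["config_hash"],
        "n_candidates": len(candidates),
        "n_lncRNA": total,
        "n_loci": len({r.transcript.gene_id for r in records}),
        "composition": {
            cls: {
                "count": int(comp.loc[cls, "count"]),
                "pct": report_ratio(int(comp.loc[cls, "count"]), total),
            }
            for cls in comp.index
        },
        "te_overlap_share_lnc": results["features"]["te_share_lnc"],
        "js_median_lnc": results["specificity"]["js_median_lnc"],
        "js_median_pcg": results["specificity"]["js_median_pcg"],
        "sex_bias": {
            "pcg_male_vs_female": list(results["sexbias"]["pcg"]),
            "lnc_male_vs_female": list(results["sexbias"]["lnc"]),
            "fisher_p": results["sexbias"]["fisher"].p_value,
        },
        "n_cis_candidates": len(results["neighbors"]["cis"]),
        "cis_positive": results["neighbors"]["n_pos"],
        "cis_negative": results["neighbors"]["n_neg"],
    }
    if "synteny" in results:
        report_obj["n_synteny_families"] = len(results["synteny"]["families"])
    with open(out / "report.json", "w") as fh:
        json.dump(report_obj, fh, indent=2, sort_keys=True)
    results["report"] = report_obj
    return results


def run_pipeline_from_file(config_path: str | Path) -> dict:
    cfg = load_config(config_path)
    return run_pipeline(cfg)


def write_default_config(path: str | Path, fixture_dir: str | Path,
                         outdir: str | Path) -> None:
    """Emit a config pointing at a written fixture directory."""
    fixture = Path(fixture_dir).resolve()
    cfg = {
        "inputs": {
            "genome": str(fixture / "genome_a.fa"),
            "reference_gtf": str(fixture / "ref_a.gtf"),
            "candidates_gtf": str(fixture / "candidates.gtf"),
            "te_bed": str(fixture / "te.bed"),
            "counts": str(fixture / "counts.tsv"),
            "groups": str(fixture / "groups.tsv"),
            "lengths": str(fixture / "lengths.tsv"),
            "library_sizes": str(fixture / "library_sizes.tsv"),
            "evidence": str(fixture / "evidence.tsv"),
            "de_table": str(fixture / "de_testis_vs_ovary.tsv"),
            "orthologs": str(fixture / "orthologs.tsv"),
            "go": str(fixture / "go.tsv"),
            "go_terms": str(fixture / "go_terms.tsv"),
            "lnc_b_loci": str(fixture / "lnc_b_loci.tsv"),
            "pcg_b_gtf": str(fixture / "ref_b.gtf"),
        },
        "params": {},
        "outdir": str(outdir),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
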