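"""End-to-end pipeline runs: filter -> collapse -> rates -> DMG -> network
-> cross-verification -> DEG -> intersection, driven by one YAML config.

Every stage writes a TSV into the run directory and a manifest records the
configuration and content hashes of all inputs and outputs, so a rerun on
identical inputs reproduces identical files.  Timestamps go only to the
log, never into stage outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .burden_matrix import collapse, group_rates, shared_true_genes
from .crossval import (
    external_gene_overlap,
    overlap_variants,
    read_rna_variants,
    verify_gene_panel,
)
from .dmg_network import (
    call_dmgs,
    cluster_samples,
    dmg_frame,
    edge_frame,
    label_dmgs,
    pearson_network,
)
from .expression_overlap import (
    basic_two_group_stats,
    deg_frame,
    select_degs,
)
from .io_core import (
    CohortDesign,
    read_design,
    read_expression_stats,
    read_gene_set,
    read_variant_table,
    write_variant_table,
)
from .variant_filter import FilterConfig, filter_cohort

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def _sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _filter_config(d: Mapping[str, Any] | None) -> FilterConfig:
    if not d:
        return FilterConfig()
    allowed = {
        "sift_max", "af_max", "missing_af_policy", "missing_sift_policy_indel",
        "clinvar_requires_class", "clinvar_rescue_independent",
    }
    unknown = set(d) - allowed
    if unknown:
        raise PipelineError(f"filter config: unknown keys {sorted(unknown)}")
    return FilterConfig(**d)


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise PipelineError("run config must be a YAML mapping")
    return cfg


def run_pipeline(cfg: Mapping[str, Any], outdir: str | Path) -> Path:
    """Execute all configured stages and write a manifest.

    Required config keys: ``design`` (sample->group TSV) and ``variants``
    (mapping sample_id -> variant table path, or a list of
    ``{sample_id, path, dialect}``).  Optional: ``filter`` (threshold and
    policy overrides), ``comparisons`` (list of [case, control] pairs;
    default all non-control groups vs the control), ``control_group``
    (default first design group), ``diff_min``, ``r_min``, ``p_max``,
    ``crossval`` (``rna``: sample -> 4-column TSV), ``expression``
    (``stats`` table or ``counts`` + ``case_group``/``control_group``),
    ``external_sets`` (name -> gene-list path).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs: dict[str, str] = {}
    outputs: dict[str, str] = {}

    def record_in(path: str | Path) -> Path:
        p = Path(path)
        inputs[str(p)] = _sha256_file(p)
        return p

    def write_done(name: str) -> Path:
        p = outdir / name
        outputs[name] = _sha256_file(p)
        return p

    stage = "design"
    try:
        design = read_design(record_in(cfg["design"]))

        stage = "filter"
        spec = cfg["variants"]
        variants = []
        if isinstance(spec, Mapping):
            entries = [
                {"sample_id": s, "path": p, "dialect": "annovar_tsv"}
                for s, p in spec.items()
            ]
        else:
            entries = list(spec)
        for e in entries:
            variants.extend(
                read_variant_table(
                    record_in(e["path"]), e["sample_id"], e.get("dialect", "annovar_tsv")
                )
            )
        fcfg = _filter_config(cfg.get("filter"))
        candidates, summary = filter_cohort(variants, fcfg)
        write_variant_table(candidates, outdir / "candidates.tsv")
        write_done("candidates.tsv")
        summary.per_sample.to_csv(outdir / "filter_summary.tsv", sep="\t")
        write_done("filter_summary.tsv")

        stage = "collapse"
        matrix = collapse(candidates, design)
        matrix.write_tsv(outdir / "matrix.tsv")
        write_done("matrix.tsv")
        matrix.write_provenance_tsv(outdir / "provenance.tsv")
        write_done("provenance.tsv")

        stage = "rates"
        rates = group_rates(matrix, design)
        rates.write_tsv(outdir / "rates.tsv")
        write_done("rates.tsv")
        shared = sorted(shared_true_genes(rates)) if len(design.groups) >= 2 else []
        (outdir / "shared_true_genes.txt").write_text(
            "".join(g + "\n" for g in shared)
        )
        write_done("shared_true_genes.txt")

        stage = "dmg"
        control = cfg.get("control_group", design.labels[0])
        comparisons = [
            (a, b) for a, b in cfg.get(
                "comparisons",
                [[g, control] for g in design.labels if g != control],
            )
        ]
        records = call_dmgs(rates, comparisons, diff_min=cfg.get("diff_min", 0.6))
        case_groups = {a for a, _ in comparisons}
        records = label_dmgs(records, case_groups, control)
        dmg_frame(records).to_csv(outdir / "dmgs.tsv", sep="\t", index=False)
        write_done("dmgs.tsv")
        dmg_genes = sorted({r.gene for r in records})

        stage = "network"
        edges = []
        if dmg_genes and len(matrix.samples) >= 3:
            sub = matrix.restrict_genes(dmg_genes)
            edges = pearson_network(
                sub, r_min=cfg.get("r_min", 0.8), p_max=cfg.get("p_max", 0.05)
            )
        edge_frame(edges).to_csv(outdir / "edges.tsv", sep="\t", index=False)
        write_done("edges.tsv")

        stage = "clustering"
        if matrix.genes:
            clust = cluster_samples(matrix)
            (outdir / "sample_order.txt").write_text(
                "".join(s + "\n" for s in clust.sample_order)
            )
        else:
            (outdir / "sample_order.txt").write_text("")
        write_done("sample_order.txt")

        stage = "crossval"
        if cfg.get("crossval"):
            rna_sets = [
                read_rna_variants(record_in(p), s)
                for s, p in sorted(cfg["crossval"]["rna"].items())
            ]
            match = bool(cfg["crossval"].get("match_samples", True))
            report = overlap_variants(candidates, rna_sets, match_samples=match)
            report.per_sample.sort_index().to_csv(outdir / "verification.tsv", sep="\t")
            write_done("verification.tsv")
            verified = (
                sorted(verify_gene_panel(set(dmg_genes), candidates, rna_sets,
                                         match_samples=match))
                if dmg_genes else []
            )
            (outdir / "verified_genes.txt").write_text(
                "".join(g + "\n" for g in verified)
            )
            write_done("verified_genes.txt")

        stage = "external"
        if cfg.get("external_sets") and dmg_genes:
            ext = {
                name: read_gene_set(record_in(p))
                for name, p in sorted(cfg["external_sets"].items())
            }
            table, membership = external_gene_overlap(set(dmg_genes), ext)
            table.to_csv(outdir / "external_overlap.tsv", sep="\t", index=False)
            write_done("external_overlap.tsv")
            membership.to_csv(outdir / "external_membership.tsv", sep="\t")
            write_done("external_membership.tsv")

        stage = "deg"
        if cfg.get("expression"):
            ecfg = cfg["expression"]
            if "stats" in ecfg:
                stats_list = read_expression_stats(record_in(ecfg["stats"]))
            else:
                counts = pd.read_csv(record_in(ecfg["counts"]), sep="\t", index_col=0)
                stats_list = basic_two_group_stats(
                    counts, design, ecfg["case_group"], ecfg["control_group"]
                )
            degs = select_degs(
                stats_list,
                p_max=ecfg.get("p_max", 0.05),
                fc_up=ecfg.get("fc_up", 2.0),
                fc_down=ecfg.get("fc_down", 0.5),
            )
            deg_frame(degs).to_csv(outdir / "degs.tsv", sep="\t", index=False)
            write_done("degs.tsv")
    except PipelineError:
        raise
    except Exception as exc:
        manifest = {"status": "error", "failed_stage": stage, "error": str(exc)}
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    manifest = {
        "status": "ok",
        "version": __version__,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "inputs": dict(sorted(inputs.items())),
        "outputs": dict(sorted(outputs.items())),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return outdir


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

_REQUIRED_ARTIFACTS = [
    "manifest.json", "candidates.tsv", "filter_summary.tsv", "matrix.tsv",
    "rates.tsv", "dmgs.tsv", "edges.tsv",
]


def summarize_run(run_dir: str | Path) -> dict[str, Any]:
    """Re-derive the headline numbers of a completed run from its outputs."""
    run_dir = Path(run_dir)
    missing = [a for a in _REQUIRED_ARTIFACTS if not (run_dir / a).exists()]
    if missing:
        raise FileNotFoundError(f"incomplete run directory, missing: {missing}")
    candidates = pd.read_csv(run_dir / "candidates.tsv", sep="\t")
    is_snp = (
        (candidates["Ref"].str.len() == 1)
        & (candidates["Alt"].str.len() == 1)
        & (candidates["Ref"] != "-")
        & (candidates["Alt"] != "-")
    ) if len(candidates) else pd.Series(dtype=bool)
    matrix = pd.read_csv(run_dir / "matrix.tsv", sep="\t", index_col=0)
    dmgs = pd.read_csv(run_dir / "dmgs.tsv", sep="\t")
    edges = pd.read_csv(run_dir / "edges.tsv", sep="\t")
    out: dict[str, Any] = {
        "n_candidates": int(len(candidates)),
        "n_candidate_snps": int(is_snp.sum()),
        "n_candidate_indels": int(len(candidates) - is_snp.sum()),
        "n_genes_mutated": int(matrix.shape[0]),
        "n_samples": int(matrix.shape[1]),
        "n_dmg_records": int(len(dmgs)),
        "n_dmg_genes": int(dmgs["gene"].nunique()) if len(dmgs) else 0,
        "n_susceptible_genes": int(
            dmgs.loc[dmgs["label"] == "susceptible", "gene"].nunique()
        ) if len(dmgs) else 0,
        "n_protective_genes": int(
            dmgs.loc[dmgs["label"] == "protective", "gene"].nunique()
        ) if len(dmgs) else 0,
        "n_network_edges": int(len(edges)),
    }
    shared = run_dir / "shared_true_genes.txt"
    if shared.exists():
        out["n_shared_true_genes"] = len(shared.read_text().split())
    verif = run_dir / "verification.tsv"
    if verif.exists():
        v = pd.read_csv(verif, sep="\t")
        total = int(v["wes_total"].sum())
        verified = int(v["snp_overlap"].sum() + v["indel_overlap"].sum())
        out["n_variants_verified"] = verified
        out["verification_rate"] = verified / total if total else 0.0
        out["n_dmg_genes_verified"] = len(
            (run_dir / "verified_genes.txt").read_text().split()
        )
    degs = run_dir / "degs.tsv"
    if degs.exists():
        d = pd.read_csv(degs, sep="\t")
        out["n_degs_up"] = int((d["direction"] == "up").sum()) if len(d) else 0
        out["n_degs_down"] = int((d["direction"] == "down").sum()) if len(d) else 0
    return out


def render_report(run_dir: str | Path) -> tuple[Path, Path]:
    """Write report.md and report.json summarising a run directory."""
    run_dir = Path(run_dir)
    summary = summarize_run(run_dir)
    json_path = run_dir / "report.json"
    json_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    lines = ["# Pipeline run summary", ""]
    for key, value in sorted(summary.items()):
        lines.append(f"- **{key}**: {value}")
    lines.append("")
    md_path = run_dir / "report.md"
    md_path.write_text("\n".join(lines))
    return md_path, json_path
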