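"""End-to-end orchestration of the analysis stages.

Stage order: index -> (curves | classify | linkage | pathways) -> report.
Every stage is independently togglable, every output table carries a header
block with version, config hash and seed, and the consolidated report only
collates numbers already present in stage outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import re
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

import hgtscan
from hgtscan import index as hidx
from hgtscan import io as hio
from hgtscan import linkage as hlink
from hgtscan import pathways as hpath
from hgtscan import phylo as hphylo
from hgtscan import simulate as hsim
from hgtscan.curves import survival_curve

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid run configuration (exit code 2 at the CLI)."""


class DataError(ValueError):
    """Missing or inconsistent stage input (exit code 3 at the CLI)."""


@dataclass
class RunConfig:
    """Thresholds, stage toggles and input paths of one run."""

    # thresholds (defaults follow the analysis design: matched-set cut
    # 1e-5, genome-alignment cut 1e-3, foreignness threshold 30 bits)
    epsilon1: float = 1e-5
    epsilon2: float = 1e-3
    theta: float = 30.0
    s_min: float = 0.75
    l_min: int = 40
    d_end: int = 1000
    top_k: int = 5
    min_nonfocal: int = 3
    ai_constant: float = 1e-200
    coverage_cut: float = 0.5
    # stage toggles
    run_index: bool = True
    run_curves: bool = False
    run_classify: bool = True
    run_linkage: bool = True
    run_pathways: bool = True
    # inputs: either a synthetic study ...
    synthetic: bool = True
    n_transcripts: int = 500
    foreign_fraction: float = 0.10
    # ... or file paths
    hits: str | None = None
    transcript_fasta: str | None = None
    trees: str | None = None
    focal_pattern: str = r"^(?!.*\|)"  # focal leaves carry no taxon separator
    genome_alignments: str | None = None
    contig_lengths: str | None = None
    ec_calls: str | None = None
    pathway_map: str | None = None
    seed: int = 0
    out_dir: str = "hgtscan_out"

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


_FIELDS = {f.name: f for f in dataclasses.fields(RunConfig)}


def validate_config(raw: Mapping[str, Any] | RunConfig) -> RunConfig:
    """Normalise a raw mapping into a RunConfig; reject unknown keys and
    out-of-range thresholds with the offending key named."""
    if isinstance(raw, RunConfig):
        cfg = raw
    else:
        unknown = set(raw) - set(_FIELDS)
        if unknown:
            import difflib

            msgs = []
            for key in sorted(unknown):
                close = difflib.get_close_matches(key, _FIELDS, n=1)
                hint = f" (did you mean {close[0]!r}?)" if close else ""
                msgs.append(f"{key!r}{hint}")
            raise ConfigError(f"unknown config keys: {', '.join(msgs)}")
        coerced = {}
        for key, value in raw.items():
            ftype = _FIELDS[key].type
            try:
                if ftype in ("float",):
                    value = float(value)
                elif ftype in ("int",):
                    value = int(value)
                elif ftype in ("bool",):
                    if isinstance(value, str):
                        value = value.lower() in ("1", "true", "yes")
                    value = bool(value)
            except (TypeError, ValueError):
                raise ConfigError(f"config key {key!r}: cannot coerce {value!r}")
            coerced[key] = value
        cfg = RunConfig(**coerced)
    for key in ("epsilon1", "epsilon2"):
        v = getattr(cfg, key)
        if not 0 < v <= 1:
            raise ConfigError(f"config key {key!r} must lie in (0, 1], got {v}")
    if cfg.theta <= 0:
        raise ConfigError(f"config key 'theta' must be positive, got {cfg.theta}")
    for key in ("l_min", "d_end", "top_k", "min_nonfocal", "n_transcripts"):
        if getattr(cfg, key) <= 0:
            raise ConfigError(f"config key {key!r} must be positive")
    if not 0 <= cfg.s_min <= 1:
        raise ConfigError(f"config key 's_min' must lie in [0, 1], got {cfg.s_min}")
    return cfg


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    return validate_config(raw)


def _write_table(df: pd.DataFrame, path: Path, cfg: RunConfig) -> None:
    if path.exists():
        raise DataError(f"refusing to overwrite existing output {path}")
    with open(path, "w") as fh:
        fh.write(f"# hgtscan {hgtscan.__version__}\n")
        fh.write(f"# config_hash: {cfg.config_hash()}\n")
        fh.write(f"# seed: {cfg.seed}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: RunConfig | Mapping[str, Any]) -> dict:
    """Run the enabled stages in dependency order; return the report dict.

    With ``synthetic=True`` all inputs are generated in memory from the
    shared seed and the report additionally echoes generator truth.  Stage
    outputs are written under ``out_dir``; partial outputs are never
    silently overwritten.
    """
    cfg = validate_config(config)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    report: dict[str, Any] = {
        "version": hgtscan.__version__,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "stages": {},
    }

    truth = None
    if cfg.synthetic:
        params = hsim.SimParams(
            n_transcripts=cfg.n_transcripts,
            foreign_fraction=cfg.foreign_fraction,
            seed=cfg.seed,
        )
        hits, truth = hsim.generate_hit_table(params)
        lengths = truth.lengths
    else:
        if not cfg.hits:
            raise DataError("index stage: no hit table configured")
        hits = hio.read_hits_frame(cfg.hits)
        lengths = (
            hio.read_fasta_lengths(cfg.transcript_fasta)
            if cfg.transcript_fasta else {}
        )

    # ---- index ----------------------------------------------------------
    if not cfg.run_index:
        raise DataError("the index stage is required by all later stages")
    profiles, n_excluded = hidx.build_profiles(
        hits, top_k=cfg.top_k, epsilon=cfg.epsilon1, lengths=lengths
    )
    records = hidx.evaluate_profiles(
        profiles, theta=cfg.theta, epsilon=cfg.epsilon1, ai_constant=cfg.ai_constant
    )
    summary = hidx.summarize(records, profiles, theta=cfg.theta, epsilon=cfg.epsilon1)
    rec_df = hidx.records_frame(records)
    _write_table(rec_df, out / "hgt_records.tsv", cfg)
    categories = {r.transcript_id: r.category for r in records}
    source_taxa = {r.transcript_id: r.best_nonmetazoan_taxon for r in records}
    report["stages"]["index"] = {
        "matched": summary.matched,
        "excluded": n_excluded,
        "foreign": summary.foreign,
        "foreign_fraction": summary.foreign_fraction,
        "foreign_without_metazoan_fraction": summary.foreign_without_metazoan_fraction,
        "source_composition": summary.source_composition,
    }
    if truth is not None:
        true_foreign = set(truth.foreign_ids)
        called = {r.transcript_id for r in records if r.category == "foreign"}
        denom = len(records)
        report["stages"]["index"]["truth"] = {
            "true_foreign_fraction": len(true_foreign) / len(truth.origins),
            "call_accuracy": (
                sum(
                    (r.transcript_id in true_foreign) == (r.category == "foreign")
                    for r in records
                ) / denom if denom else 0.0
            ),
        }

    # ---- curves ---------------------------------------------------------
    if cfg.run_curves:
        curve = survival_curve([r.h for r in records], species="dataset")
        _write_table(
            pd.DataFrame({"h": curve.grid, "pct": curve.pct}),
            out / "survival_curve.tsv", cfg,
        )
        report["stages"]["curves"] = {"pct_at_theta": curve.at(cfg.theta)}

    # ---- classify -------------------------------------------------------
    if cfg.run_classify:
        assessments = []
        if cfg.synthetic:
            trees, _support = hsim.generate_trees(truth, params)
            newicks = trees.values()
            taxon_of = hsim.taxon_of_leaf
            is_focal = lambda label: "|" not in label  # noqa: E731
        else:
            if not cfg.trees:
                raise DataError("classify stage: no tree file configured")
            with open(cfg.trees) as fh:
                newicks = [line.strip() for line in fh if line.strip()]
            pat = re.compile(cfg.focal_pattern)
            taxon_of = hsim.taxon_of_leaf
            is_focal = lambda label: bool(pat.match(label))  # noqa: E731
        for newick in newicks:
            tree = hio.read_newick_supports(newick)
            leaf_labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
            focal = next((l for l in leaf_labels if is_focal(l)), None)
            if focal is None:
                raise DataError(f"no focal leaf found in tree: {newick[:60]}...")
            a = hphylo.extract_monophyly_supports(tree, focal, taxon_of)
            hphylo.assign_group(a, s_min=cfg.s_min, min_nonfocal=cfg.min_nonfocal)
            assessments.append(a)
        n_no_met = sum(
            1 for r in records
            if r.category == "foreign" and not r.has_significant_metazoan
        )
        groups = hphylo.summarize_groups(assessments, n_without_metazoan=n_no_met)
        _write_table(
            pd.DataFrame(
                {
                    "transcript_id": [a.transcript_id for a in assessments],
                    "group": [a.group for a in assessments],
                    "n_nonfocal_leaves": [a.n_nonfocal_leaves for a in assessments],
                }
            ),
            out / "phylo_groups.tsv", cfg,
        )
        report["stages"]["classify"] = {
            "counts": groups["counts"],
            "verified_rate": groups["verified_rate"],
            "combined_verified_rate": groups["combined_verified_rate"],
        }
        if truth is not None and assessments:
            correct = sum(
                1 for a in assessments
                if a.group == 5
                or (a.group == 4)
            )
            report["stages"]["classify"]["truth"] = {
                "foreign_recovered_rate": correct / len(assessments)
            }

    # ---- linkage --------------------------------------------------------
    if cfg.run_linkage:
        if cfg.synthetic:
            contig_lengths, aln, _link_truth = hsim.generate_genome(truth, params)
            tlengths = truth.lengths
        else:
            if not (cfg.genome_alignments and cfg.contig_lengths):
                raise DataError(
                    "linkage stage: genome_alignments and contig_lengths required"
                )
            aln = hio.read_hits_frame(cfg.genome_alignments, taxon="Metazoa")
            aln = aln.drop(columns=["taxon"])
            contig_lengths = hio.read_contig_lengths(cfg.contig_lengths)
            tlengths = lengths
            if not tlengths:
                raise DataError("linkage stage: transcript lengths required")
        results = hlink.chain_all(
            aln, tlengths, contig_lengths,
            eps=cfg.epsilon2, l_min=cfg.l_min, d_end=cfg.d_end,
        )
        hist = hlink.coverage_histogram(results, categories, cut=cfg.coverage_cut)
        coloc = hlink.colocalization_report(results, categories, source_taxa)
        _write_table(
            pd.DataFrame(
                {
                    "transcript_id": list(results),
                    "coverage_fraction": [r.coverage_fraction for r in results.values()],
                    "contigs": [",".join(sorted(r.contigs_on)) for r in results.values()],
                }
            ),
            out / "genome_coverage.tsv", cfg,
        )
        link_report = {
            "fraction_above_cut": hist["all"]["fraction_above_cut"],
            "colocalization_fraction": coloc["colocalization_fraction"],
        }
        if "by_category" in hist and "foreign" in hist["by_category"]:
            link_report["foreign_fraction_above_cut"] = (
                hist["by_category"]["foreign"]["fraction_above_cut"]
            )
        report["stages"]["linkage"] = link_report

    # ---- pathways -------------------------------------------------------
    if cfg.run_pathways:
        if cfg.synthetic:
            pmap = hsim.generate_pathway_map(int(params.rng("ec").integers(2**31)))
            spike = set(list(sorted(pmap))[:2])
            ec_table = hsim.generate_ec_annotations(truth, pmap, spike, params)
        else:
            if not (cfg.ec_calls and cfg.pathway_map):
                raise DataError("pathways stage: ec_calls and pathway_map required")
            ec_table = pd.read_csv(cfg.ec_calls, sep="\t")
            pmap = hio.read_pathway_map(cfg.pathway_map)
        calls = [
            hpath.ECCall(str(r.transcript_id), r.ec, r.category)
            for r in ec_table.itertuples(index=False)
        ]
        colors = hpath.color_ec(calls)
        enriched = hpath.enrich_pathways(colors, pmap)
        enz = hpath.summarize_enzymes(calls, categories or {}, colors)
        _write_table(hpath.pathway_frame(enriched), out / "pathway_enrichment.tsv", cfg)
        sig = [r.pathway_id for r in enriched if r.q < 0.05]
        report["stages"]["pathways"] = {
            "n_ec": enz["n_ec"],
            "foreign_contribution_fraction": enz["foreign_contribution_fraction"],
            "n_enriched_q05": len(sig),
            "enriched": sorted(sig),
        }
        if truth is not None:
            report["stages"]["pathways"]["truth"] = {
                "spiked": sorted(truth.spiked_pathways),
                "spiked_recovered": sorted(
                    set(sig) & truth.spiked_pathways
                ),
            }

    report_path = out / "report.json"
    if report_path.exists():
        raise DataError(f"refusing to overwrite existing output {report_path}")
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True))
    logger.info("pipeline finished in %.1fs; report at %s", time.time() - t0,
                report_path)
    return report
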