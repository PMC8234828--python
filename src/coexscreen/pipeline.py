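"""Config-driven orchestration of the full analysis.

Stages run in a fixed order — simulate/load, normalize, contrast,
screen, similarity clustering, enrichment + term clustering, complex
detection, dose trend — with explicit file hand-offs.  Optional stages
that lack their inputs (no network file, no dose column) are skipped
with a warning; required stages abort the run.  All randomness derives
from the single top-level ``rng_seed`` via fixed per-stage offsets, so
identical config + seed gives byte-identical tabular outputs.
"""

from __future__ import annotations

import dataclasses
import difflib
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as xio
from . import synthetic
from .contrasts import DoseTrendConfig, dose_trend, welch_contrast
from .corrstruct import hierarchical_clusters, similarity_matrix
from .enrichment import cluster_terms, enrich_gene_sets
from .mcode import MCODEParams, predict_complexes
from .screen import SIGN_NEGATIVE, SIGN_POSITIVE, ScreenConfig, run_seed_screen

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised when a pipeline config is invalid; message lists all problems."""


# allowed keys per config section (None marks required sections/keys elsewhere)
_SCHEMA: dict[str, set[str]] = {
    "": {
        "rng_seed",
        "output_dir",
        "simulate",
        "inputs",
        "normalize",
        "contrast",
        "screen",
        "simmatrix",
        "enrichment",
        "mcode",
        "dosetrend",
    },
    "simulate": {
        "n_null",
        "n_pos",
        "n_neg",
        "n_donors",
        "n_subsets",
        "planted_r",
        "noise_sd",
        "group_effect",
        "n_terms",
        "planted_term_overlap",
        "clique_sizes",
        "n_background_nodes",
        "background_edge_prob",
        "bridge_edges",
    },
    "inputs": {"matrix", "metadata", "gmt", "edges"},
    "normalize": {"quantile"},
    "contrast": {"enabled", "groups"},
    "screen": {"seed_gene", "permutations", "fdr", "center", "two_sided"},
    "simmatrix": {"enabled", "genes", "top_n", "k"},
    "enrichment": {"enabled", "kappa_threshold"},
    "mcode": {"enabled", "vwp", "haircut", "fluff", "min_size"},
    "dosetrend": {"enabled", "permutations", "alpha"},
}


@dataclass
class PipelineConfig:
    output_dir: Path
    rng_seed: int = 0
    simulate: dict[str, Any] | None = None
    inputs: dict[str, str] = field(default_factory=dict)
    quantile: bool = False
    contrast_enabled: bool = True
    contrast_groups: tuple[str, str] | None = None
    seed_gene: str | None = None
    permutations: int = 1000
    fdr: float = 0.1
    center: bool = True
    two_sided: bool = True
    simmatrix_enabled: bool = True
    simmatrix_genes: list[str] | None = None
    simmatrix_top_n: int = 20
    simmatrix_k: int = 2
    enrichment_enabled: bool = True
    kappa_threshold: float = 0.3
    mcode_enabled: bool = True
    mcode_params: MCODEParams = field(default_factory=MCODEParams)
    dosetrend_enabled: bool = False
    dosetrend_permutations: int = 1000
    dosetrend_alpha: float = 0.05
    raw: dict[str, Any] = field(default_factory=dict)

    def config_hash(self) -> str:
        canonical = json.dumps(self.raw, sort_keys=True, default=str)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]


def _check_keys(section: str, block: dict, errors: list[str]) -> None:
    allowed = _SCHEMA[section]
    for key in block:
        if key not in allowed:
            hint = difflib.get_close_matches(key, allowed, n=1)
            where = section or "top level"
            msg = f"unknown key {key!r} in {where}"
            if hint:
                msg += f" (did you mean {hint[0]!r}?)"
            errors.append(msg)


def validate_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML/JSON pipeline config, applying defaults.

    All violations are collected and reported together.
    """
    path = Path(path)
    data = yaml.safe_load(path.read_text(encoding="utf-8"))
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    errors: list[str] = []
    _check_keys("", data, errors)
    for section in _SCHEMA:
        if section and section in data:
            block = data[section]
            if not isinstance(block, dict):
                errors.append(f"section {section!r} must be a mapping")
            else:
                _check_keys(section, block, errors)

    sim = data.get("simulate")
    inputs = data.get("inputs") or {}
    if sim is None and "matrix" not in inputs:
        errors.append("either a 'simulate' block or inputs.matrix is required")
    screen_block = data.get("screen") or {}
    seed_gene = screen_block.get("seed_gene")
    if seed_gene is None and sim is not None:
        seed_gene = synthetic.SEED_GENE
    if seed_gene is None:
        errors.append("screen.seed_gene is required when not simulating")
    if "output_dir" not in data:
        errors.append("output_dir is required")
    for key, p in (inputs or {}).items():
        if isinstance(p, str) and not Path(p).exists():
            errors.append(f"inputs.{key}: file not found: {p}")
    if errors:
        raise ConfigError(f"{path}: invalid config:\n  - " + "\n  - ".join(errors))

    contrast_block = data.get("contrast") or {}
    simmatrix_block = data.get("simmatrix") or {}
    enrich_block = data.get("enrichment") or {}
    mcode_block = data.get("mcode") or {}
    dose_block = data.get("dosetrend") or {}
    groups = contrast_block.get("groups")
    return PipelineConfig(
        output_dir=Path(data["output_dir"]),
        rng_seed=int(data.get("rng_seed", 0)),
        simulate=sim,
        inputs=dict(inputs),
        quantile=bool((data.get("normalize") or {}).get("quantile", False)),
        contrast_enabled=bool(contrast_block.get("enabled", True)),
        contrast_groups=tuple(groups) if groups else None,
        seed_gene=seed_gene,
        permutations=int(screen_block.get("permutations", 1000)),
        fdr=float(screen_block.get("fdr", 0.1)),
        center=bool(screen_block.get("center", True)),
        two_sided=bool(screen_block.get("two_sided", True)),
        simmatrix_enabled=bool(simmatrix_block.get("enabled", True)),
        simmatrix_genes=simmatrix_block.get("genes"),
        simmatrix_top_n=int(simmatrix_block.get("top_n", 20)),
        simmatrix_k=int(simmatrix_block.get("k", 2)),
        enrichment_enabled=bool(enrich_block.get("enabled", True)),
        kappa_threshold=float(enrich_block.get("kappa_threshold", 0.3)),
        mcode_enabled=bool(mcode_block.get("enabled", True)),
        mcode_params=MCODEParams(
            vwp=float(mcode_block.get("vwp", 0.2)),
            haircut=bool(mcode_block.get("haircut", True)),
            fluff=bool(mcode_block.get("fluff", False)),
            min_complex_size=int(mcode_block.get("min_size", 3)),
        ),
        dosetrend_enabled=bool(dose_block.get("enabled", False)),
        dosetrend_permutations=int(dose_block.get("permutations", 1000)),
        dosetrend_alpha=float(dose_block.get("alpha", 0.05)),
        raw=data,
    )


def _write_table(df: pd.DataFrame, path: Path, header: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# {header}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute all enabled stages; returns (and writes) the JSON report."""
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    stamp = f"coexscreen v{__version__} config_hash={config.config_hash()} rng_seed={config.rng_seed}"
    report: dict[str, Any] = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "rng_seed": config.rng_seed,
        "config": config.raw,
        "stages": {},
    }
    timings: dict[str, float] = {}

    def stage(name: str):
        class _Timer:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                logger.info("stage %s: start", name)
                return self_inner

            def __exit__(self_inner, *exc):
                timings[name] = time.perf_counter() - self_inner.t0
                return False

        return _Timer()

    truth = None
    catalog = None
    graph = None
    meta = None

    # --- simulate or load -------------------------------------------------
    with stage("inputs"):
        if config.simulate is not None:
            sim_kwargs = dict(config.simulate)
            if "clique_sizes" in sim_kwargs:
                sim_kwargs["clique_sizes"] = tuple(sim_kwargs["clique_sizes"])
            matrix, meta, truth, catalog, graph = synthetic.generate_study_dataset(
                rng_seed=config.rng_seed, **sim_kwargs
            )
            in_dir = out / "inputs"
            in_dir.mkdir(exist_ok=True)
            xio.write_expression_tsv(matrix, in_dir / "matrix.tsv", header_comment=stamp)
            xio.write_metadata_tsv(meta, in_dir / "metadata.tsv")
            xio.write_gmt(catalog, in_dir / "sets.gmt")
            xio.write_edge_list(graph, in_dir / "network.tsv")
            truth.to_json(in_dir / "truth.json")
            report["stages"]["inputs"] = {
                "simulated": True,
                "n_genes": matrix.n_genes,
                "n_samples": matrix.n_samples,
            }
        else:
            matrix = xio.read_expression_tsv(config.inputs["matrix"])
            if "metadata" in config.inputs:
                meta = xio.read_metadata_tsv(config.inputs["metadata"])
                xio.check_metadata(meta, matrix)
            if "gmt" in config.inputs:
                catalog = xio.read_gmt(config.inputs["gmt"])
            if "edges" in config.inputs:
                graph = xio.read_edge_list(config.inputs["edges"])
            report["stages"]["inputs"] = {
                "simulated": False,
                "n_genes": matrix.n_genes,
                "n_samples": matrix.n_samples,
            }

    # --- normalize --------------------------------------------------------
    if config.quantile:
        with stage("normalize"):
            matrix = xio.quantile_normalize(matrix)
            xio.write_expression_tsv(matrix, out / "normalized_matrix.tsv", header_comment=stamp)
            report["stages"]["normalize"] = {"method": "quantile"}

    # --- group contrast ---------------------------------------------------
    if config.contrast_enabled:
        if meta is None or meta["group"].nunique() < 2:
            logger.warning("contrast stage skipped: no two-group metadata")
            report["stages"]["contrast"] = {"skipped": "no two-group metadata"}
        else:
            with stage("contrast"):
                groups = config.contrast_groups or tuple(
                    pd.unique(meta["group"])[:2]
                )
                ctab = welch_contrast(matrix, meta, groups)
                _write_table(ctab, out / "contrast.tsv", stamp)
                report["stages"]["contrast"] = {
                    "groups": list(groups),
                    "n_significant_q05": int((ctab["q_value"] < 0.05).sum()),
                }

    # --- seed screen ------------------------------------------------------
    with stage("screen"):
        screen_cfg = ScreenConfig(
            seed_gene_id=config.seed_gene,
            n_permutations=config.permutations,
            fdr_threshold=config.fdr,
            center_genes=config.center,
            rng_seed=config.rng_seed + 1,
            two_sided=config.two_sided,
        )
        result = run_seed_screen(matrix, screen_cfg)
        _write_table(result.table, out / "screen.tsv", stamp)
        report["stages"]["screen"] = {
            "seed_gene": config.seed_gene,
            "n_positive": result.n_positive,
            "n_negative": result.n_negative,
            "fdr_threshold": config.fdr,
            "permutations": config.permutations,
        }
    pos_genes = result.genes_with_sign(SIGN_POSITIVE)
    neg_genes = result.genes_with_sign(SIGN_NEGATIVE)

    # --- similarity matrix + clustering -----------------------------------
    if config.simmatrix_enabled:
        with stage("simmatrix"):
            genes = config.simmatrix_genes
            if genes is None:
                top = result.table.head(config.simmatrix_top_n)["gene_id"].tolist()
                genes = [config.seed_gene, *top]
            sim = similarity_matrix(matrix, genes)
            tree = hierarchical_clusters(sim, min(config.simmatrix_k, len(genes)))
            with open(out / "similarity.tsv", "w", encoding="utf-8") as fh:
                fh.write(f"# {stamp}\n")
                sim.to_frame().to_csv(fh, sep="\t")
            _write_table(
                pd.DataFrame(
                    {"gene_id": tree.gene_ids, "cluster": [tree.labels[g] for g in tree.gene_ids]}
                ),
                out / "clusters.tsv",
                stamp,
            )
            report["stages"]["simmatrix"] = {"n_genes": len(genes), "k": tree.k}

    # --- enrichment -------------------------------------------------------
    if config.enrichment_enabled:
        if catalog is None:
            logger.warning("enrichment stage skipped: no gene-set catalog")
            report["stages"]["enrichment"] = {"skipped": "no gene-set catalog"}
        else:
            with stage("enrichment"):
                background = sorted(
                    set(matrix.gene_ids)
                    | {g for s in catalog for g in s.genes}
                )
                enr_section = {}
                for label, query in (("negative", neg_genes), ("positive", pos_genes)):
                    if not query:
                        enr_section[label] = {"skipped": "empty query"}
                        continue
                    table = enrich_gene_sets(query, catalog, background)
                    _write_table(table, out / f"enrichment_{label}.tsv", stamp)
                    if len(table):
                        clusters = cluster_terms(
                            table, catalog, background, config.kappa_threshold
                        )
                        cl_json = [
                            {
                                "representative": c.representative,
                                "members": c.members,
                            }
                            for c in clusters
                        ]
                        (out / f"term_clusters_{label}.json").write_text(
                            json.dumps(cl_json, indent=2) + "\n", encoding="utf-8"
                        )
                        enr_section[label] = {
                            "n_terms_tested": int(len(table)),
                            "n_clusters": len(clusters),
                            "top_term": table.iloc[0]["term_id"],
                            "top_log10_p": float(table.iloc[0]["log10_p"]),
                        }
                    else:
                        enr_section[label] = {"n_terms_tested": 0}
                report["stages"]["enrichment"] = enr_section

    # --- complex detection -------------------------------------------------
    if config.mcode_enabled:
        if graph is None:
            logger.warning("mcode stage skipped: no network supplied")
            report["stages"]["mcode"] = {"skipped": "no network supplied"}
        else:
            with stage("mcode"):
                significant = set(pos_genes) | set(neg_genes)
                sub = graph.subgraph([n for n in graph if n in significant]).copy()
                complexes = predict_complexes(sub, config.mcode_params)
                rows = [
                    {
                        "rank": c.rank,
                        "seed": c.seed,
                        "score": c.score,
                        "size": len(c.nodes),
                        "nodes": ";".join(c.nodes),
                    }
                    for c in complexes
                ]
                _write_table(
                    pd.DataFrame(rows, columns=["rank", "seed", "score", "size", "nodes"]),
                    out / "mcode.tsv",
                    stamp,
                )
                report["stages"]["mcode"] = {
                    "n_network_nodes": sub.number_of_nodes(),
                    "n_complexes": len(complexes),
                    "top_score": complexes[0].score if complexes else None,
                }

    # --- dose trend --------------------------------------------------------
    if config.dosetrend_enabled:
        if meta is None or meta["dose"].isna().all():
            logger.warning("dosetrend stage skipped: no dose metadata")
            report["stages"]["dosetrend"] = {"skipped": "no dose metadata"}
        else:
            with stage("dosetrend"):
                dcfg = DoseTrendConfig(
                    n_permutations=config.dosetrend_permutations,
                    rng_seed=config.rng_seed + 2,
                    alpha=config.dosetrend_alpha,
                )
                dtab = dose_trend(matrix, meta, dcfg)
                _write_table(dtab, out / "dosetrend.tsv", stamp)
                report["stages"]["dosetrend"] = {
                    "n_down": int((dtab["direction"] == "down").sum()),
                    "n_up": int((dtab["direction"] == "up").sum()),
                }

    report["wall_clock_s"] = {k: round(v, 4) for k, v in timings.items()}
    (out / "report.json").write_text(
        json.dumps(report, indent=2, default=str) + "\n", encoding="utf-8"
    )
    return report
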