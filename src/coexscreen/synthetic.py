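"""Synthetic datasets with known planted structure.

Generators here emulate the study designs the pipeline targets — a
two-group, multi-subset donor comparison, a five-point log-spaced dose
titration, seed-centered correlated gene modules, gene-set catalogs
with a planted enriched term, and networks with planted cliques — so
that every downstream stage can be validated against recorded truth
without any external data.

Planted correlation uses a latent-factor construction: with latent
profile ``z`` and target correlation ``r``, a module gene is
``r*z + sqrt(1-r^2)*eps`` (``-z`` for the negative module), which has
population correlation exactly ``±r`` with the seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import networkx as nx

from .io import ExpressionMatrix, GeneSet, GeneSetCatalog

DEFAULT_BASELINE = 8.0
DEFAULT_DOSES = (0.1, 1.0, 10.0, 100.0, 1000.0)
SEED_GENE = "GENE_SEED"
PLANTED_TERM = "PLANTED_SIG"


@dataclass
class SyntheticTruth:
    """Record of everything planted into a synthetic dataset."""

    seed_gene_id: str = SEED_GENE
    pos_module: list[str] = field(default_factory=list)
    neg_module: list[str] = field(default_factory=list)
    planted_r: float = 0.0
    group_effect: float = 0.0
    dose_slope: float = 0.0
    affected_genes: list[str] = field(default_factory=list)
    responsive_genes: list[str] = field(default_factory=list)
    enriched_term_ids: list[str] = field(default_factory=list)
    planted_complex_nodes: list[list[str]] = field(default_factory=list)
    all_gene_ids: list[str] = field(default_factory=list)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        overlap = set(self.pos_module) & set(self.neg_module)
        if overlap:
            raise ValueError(f"pos/neg modules overlap: {sorted(overlap)}")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n",
            encoding="utf-8",
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        return cls(**json.loads(Path(path).read_text(encoding="utf-8")))


def _gene_names(prefix: str, n: int) -> list[str]:
    return [f"{prefix}_{i:04d}" for i in range(n)]


def generate_seed_screen_dataset(
    n_null: int,
    n_pos: int,
    n_neg: int,
    n_samples: int,
    planted_r: float = 0.8,
    noise_sd: float = 1.0,
    rng_seed: int = 0,
    baseline: float = DEFAULT_BASELINE,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Seed gene plus positively/negatively correlated modules among null genes.

    The seed profile is a standard-normal latent factor ``z``; module
    genes mix ``±z`` with independent noise so their population
    correlation with the seed is exactly ``±planted_r``.  All profiles
    are scaled by ``noise_sd`` and shifted to ``baseline`` log2 units.
    """
    if min(n_null, n_pos, n_neg) < 0:
        raise ValueError("gene counts must be >= 0")
    if n_samples < 4:
        raise ValueError("n_samples must be >= 4")
    if not 0.0 < planted_r <= 1.0:
        raise ValueError("planted_r must be in (0, 1]")
    rng = np.random.default_rng(rng_seed)
    z = rng.standard_normal(n_samples)
    # standardize the latent factor so the realized (not just population)
    # correlation of module genes with the seed concentrates at planted_r
    z = (z - z.mean()) / z.std()
    mix = np.sqrt(1.0 - planted_r**2)

    pos_ids = _gene_names("GENE_POS", n_pos)
    neg_ids = _gene_names("GENE_NEG", n_neg)
    null_ids = _gene_names("GENE_NULL", n_null)

    rows = [z]
    for _ in pos_ids:
        rows.append(planted_r * z + mix * rng.standard_normal(n_samples))
    for _ in neg_ids:
        rows.append(planted_r * (-z) + mix * rng.standard_normal(n_samples))
    for _ in null_ids:
        rows.append(rng.standard_normal(n_samples))
    values = baseline + noise_sd * np.vstack(rows)
    gene_ids = [SEED_GENE, *pos_ids, *neg_ids, *null_ids]
    matrix = ExpressionMatrix(gene_ids, _gene_names("S", n_samples), values)
    truth = SyntheticTruth(
        seed_gene_id=SEED_GENE,
        pos_module=pos_ids,
        neg_module=neg_ids,
        planted_r=planted_r,
        all_gene_ids=gene_ids,
        rng_seed=rng_seed,
    )
    return matrix, truth


def generate_contrast_dataset(
    n_genes: int,
    n_per_group: int,
    affected_genes: list[int],
    effect_log2: float,
    rng_seed: int = 0,
    n_subsets: int = 3,
    noise_sd: float = 1.0,
    baseline: float = DEFAULT_BASELINE,
    groups: tuple[str, str] = ("healthy", "disease"),
) -> tuple[ExpressionMatrix, pd.DataFrame, SyntheticTruth]:
    """Two-group design (n_per_group donors each, cycled over cell subsets).

    ``affected_genes`` (row indices) are shifted by ``effect_log2`` in
    the second group.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if any(i < 0 or i >= n_genes for i in affected_genes):
        raise ValueError("affected gene index out of range")
    rng = np.random.default_rng(rng_seed)
    subsets = ["naive", "memory", "plasmablast"][:n_subsets]
    sample_ids, group_labels, subset_labels, replicate = [], [], [], []
    for g_idx, group in enumerate(groups):
        for donor in range(n_per_group):
            for subset in subsets:
                sample_ids.append(f"{group}_{subset}_d{donor}")
                group_labels.append(group)
                subset_labels.append(subset)
                replicate.append(donor)
    n_samples = len(sample_ids)
    values = baseline + noise_sd * rng.standard_normal((n_genes, n_samples))
    in_group2 = np.array([g == groups[1] for g in group_labels])
    for i in affected_genes:
        values[i, in_group2] += effect_log2
    gene_ids = _gene_names("GENE", n_genes)
    matrix = ExpressionMatrix(gene_ids, sample_ids, values)
    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "group": group_labels,
            "subset": subset_labels,
            "dose": np.nan,
            "replicate": replicate,
        }
    )
    truth = SyntheticTruth(
        group_effect=effect_log2,
        affected_genes=[gene_ids[i] for i in affected_genes],
        all_gene_ids=gene_ids,
        rng_seed=rng_seed,
    )
    return matrix, meta, truth


def generate_dose_response_dataset(
    doses: tuple[float, ...] = DEFAULT_DOSES,
    n_reps: int = 3,
    n_null: int = 50,
    n_responsive: int = 1,
    dose_slope: float = -0.5,
    noise_sd: float = 0.3,
    rng_seed: int = 0,
    baseline: float = DEFAULT_BASELINE,
) -> tuple[ExpressionMatrix, pd.DataFrame, SyntheticTruth]:
    """Titration design: responsive gene mean = baseline + slope*log10(dose)."""
    doses = tuple(float(d) for d in doses)
    if any(d <= 0 for d in doses):
        raise ValueError("doses must be positive")
    if list(doses) != sorted(set(doses)):
        raise ValueError("doses must be strictly increasing")
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    rng = np.random.default_rng(rng_seed)
    sample_ids, sample_dose, replicate = [], [], []
    for d_idx, dose in enumerate(doses):
        for rep in range(n_reps):
            sample_ids.append(f"dose{d_idx}_r{rep}")
            sample_dose.append(dose)
            replicate.append(rep)
    log_dose = np.log10(np.array(sample_dose))
    resp_ids = _gene_names("GENE_RESP", n_responsive)
    null_ids = _gene_names("GENE_NULL", n_null)
    n_samples = len(sample_ids)
    rows = []
    for _ in resp_ids:
        rows.append(
            baseline + dose_slope * log_dose + noise_sd * rng.standard_normal(n_samples)
        )
    for _ in null_ids:
        rows.append(baseline + noise_sd * rng.standard_normal(n_samples))
    gene_ids = [*resp_ids, *null_ids]
    matrix = ExpressionMatrix(gene_ids, sample_ids, np.vstack(rows))
    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "group": "titration",
            "subset": "B",
            "dose": sample_dose,
            "replicate": replicate,
        }
    )
    truth = SyntheticTruth(
        dose_slope=dose_slope,
        responsive_genes=resp_ids,
        all_gene_ids=gene_ids,
        rng_seed=rng_seed,
    )
    return matrix, meta, truth


def generate_catalog_with_planted_enrichment(
    screen_truth: SyntheticTruth,
    n_terms: int = 20,
    planted_term_overlap: int = 20,
    background_size: int | None = None,
    rng_seed: int = 0,
    planted_term_size: int | None = None,
    random_term_size: int = 25,
) -> GeneSetCatalog:
    """Catalog with one term enriched in the negative module plus a duplicate.

    The planted term draws ``planted_term_overlap`` members from the
    truth's negative module and pads to ``planted_term_size`` with
    random background genes; an exact duplicate term is added so that
    redundancy clustering has a kappa=1 pair; remaining terms are random
    draws from the background.
    """
    neg = list(screen_truth.neg_module)
    if planted_term_overlap > len(neg):
        raise ValueError("planted_term_overlap exceeds negative-module size")
    background = list(screen_truth.all_gene_ids)
    if background_size is not None:
        if background_size < len(background):
            raise ValueError("background_size smaller than generated gene universe")
        background = background + _gene_names("GENE_BG", background_size - len(background))
    if planted_term_size is None:
        planted_term_size = planted_term_overlap
    if planted_term_size < planted_term_overlap:
        raise ValueError("planted_term_size must be >= planted_term_overlap")
    rng = np.random.default_rng(rng_seed)
    non_module = [g for g in background if g not in set(neg)]
    members = list(rng.choice(neg, size=planted_term_overlap, replace=False)) if planted_term_overlap else []
    pad = planted_term_size - planted_term_overlap
    if pad:
        members += list(rng.choice(non_module, size=pad, replace=False))
    catalog = GeneSetCatalog(background_size=len(background))
    if members:
        catalog.add(GeneSet(PLANTED_TERM, "planted enriched term", tuple(members)))
        catalog.add(
            GeneSet(PLANTED_TERM + "_DUP", "duplicate of planted term", tuple(members))
        )
    for t in range(n_terms):
        draw = rng.choice(background, size=min(random_term_size, len(background)), replace=False)
        catalog.add(GeneSet(f"RANDOM_{t:03d}", f"random term {t}", tuple(draw)))
    return catalog


def generate_study_dataset(
    n_null: int = 800,
    n_pos: int = 50,
    n_neg: int = 50,
    n_donors: int = 4,
    n_subsets: int = 3,
    planted_r: float = 0.8,
    noise_sd: float = 1.0,
    group_effect: float = -1.0,
    n_terms: int = 20,
    planted_term_overlap: int = 20,
    clique_sizes: tuple[int, ...] = (8, 5),
    n_background_nodes: int = 40,
    background_edge_prob: float = 0.05,
    bridge_edges: int = 4,
    rng_seed: int = 0,
    groups: tuple[str, str] = ("healthy", "disease"),
) -> tuple[ExpressionMatrix, pd.DataFrame, SyntheticTruth, GeneSetCatalog, nx.Graph]:
    """Full two-group study with planted modules, catalog and network.

    Samples are ``2 * n_donors * n_subsets`` (two groups, donors cycled
    over cell subsets); the seed gene carries ``group_effect`` log2
    units in the second group; the catalog plants an enriched term in
    the negative module; the first planted clique is wired onto
    negative-module genes so complex detection has known structure.
    """
    n_samples = 2 * n_donors * n_subsets
    matrix, truth = generate_seed_screen_dataset(
        n_null, n_pos, n_neg, n_samples, planted_r, noise_sd, rng_seed
    )
    subsets = ["naive", "memory", "plasmablast"][:n_subsets]
    sample_ids, group_labels, subset_labels, replicate = [], [], [], []
    for group in groups:
        for donor in range(n_donors):
            for subset in subsets:
                sample_ids.append(f"{group}_{subset}_d{donor}")
                group_labels.append(group)
                subset_labels.append(subset)
                replicate.append(donor)
    matrix = ExpressionMatrix(
        matrix.gene_ids, sample_ids, matrix.values, matrix.log_scale
    )
    in_group2 = np.array([g == groups[1] for g in group_labels])
    matrix.values[matrix.gene_index(truth.seed_gene_id), in_group2] += group_effect
    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "group": group_labels,
            "subset": subset_labels,
            "dose": np.nan,
            "replicate": replicate,
        }
    )
    truth.group_effect = group_effect
    truth.affected_genes = [truth.seed_gene_id]
    catalog = generate_catalog_with_planted_enrichment(
        truth,
        n_terms=n_terms,
        planted_term_overlap=min(planted_term_overlap, n_neg),
        rng_seed=rng_seed + 1,
    )
    truth.enriched_term_ids = [PLANTED_TERM, PLANTED_TERM + "_DUP"]
    clique_names: list[list[str]] = []
    pool = [*truth.neg_module, *truth.pos_module]
    start = 0
    for size in clique_sizes:
        if start + size > len(pool):
            raise ValueError("clique sizes exceed available planted-module genes")
        clique_names.append(pool[start : start + size])
        start += size
    graph, net_truth = generate_planted_network(
        clique_sizes,
        n_background_nodes=n_background_nodes,
        background_edge_prob=background_edge_prob,
        bridge_edges=bridge_edges,
        rng_seed=rng_seed + 2,
        clique_node_names=clique_names,
    )
    truth.planted_complex_nodes = net_truth.planted_complex_nodes
    return matrix, meta, truth, catalog, graph


def generate_planted_network(
    clique_sizes: tuple[int, ...],
    n_background_nodes: int = 0,
    background_edge_prob: float = 0.05,
    bridge_edges: int = 0,
    rng_seed: int = 0,
    clique_node_names: list[list[str]] | None = None,
) -> tuple[nx.Graph, SyntheticTruth]:
    """Disjoint planted cliques over a sparse random background.

    ``bridge_edges`` random edges are added between distinct components
    (clique-to-background when background nodes exist, clique-to-clique
    otherwise).  ``clique_node_names`` optionally assigns real gene ids
    to clique nodes so the network lines up with an expression dataset.
    """
    if any(s < 3 for s in clique_sizes):
        raise ValueError("clique sizes must be >= 3")
    rng = np.random.default_rng(rng_seed)
    graph: nx.Graph = nx.Graph()
    cliques: list[list[str]] = []
    for c_idx, size in enumerate(clique_sizes):
        if clique_node_names is not None:
            nodes = list(clique_node_names[c_idx])
            if len(nodes) != size:
                raise ValueError("clique_node_names lengths must match clique_sizes")
        else:
            nodes = [f"CLQ{c_idx}_N{i}" for i in range(size)]
        cliques.append(nodes)
        graph.add_nodes_from(nodes)
        graph.add_edges_from(
            (nodes[i], nodes[j]) for i in range(size) for j in range(i + 1, size)
        )
    bg_nodes = [f"BG_N{i}" for i in range(n_background_nodes)]
    graph.add_nodes_from(bg_nodes)
    for i in range(n_background_nodes):
        for j in range(i + 1, n_background_nodes):
            if rng.random() < background_edge_prob:
                graph.add_edge(bg_nodes[i], bg_nodes[j])
    component_of = {}
    for c_idx, nodes in enumerate(cliques):
        for n in nodes:
            component_of[n] = c_idx
    for n in bg_nodes:
        component_of[n] = len(cliques)
    all_nodes = [n for nodes in cliques for n in nodes] + bg_nodes
    added = 0
    attempts = 0
    while added < bridge_edges:
        attempts += 1
        if attempts > 1000 * max(1, bridge_edges):
            raise ValueError("cannot place requested bridge edges")
        u, v = rng.choice(all_nodes, size=2, replace=False)
        if component_of[u] == component_of[v] or graph.has_edge(u, v):
            continue
        graph.add_edge(u, v)
        added += 1
    truth = SyntheticTruth(
        planted_complex_nodes=[list(c) for c in cliques],
        all_gene_ids=all_nodes,
        rng_seed=rng_seed,
    )
    return graph, truth
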