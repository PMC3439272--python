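"""Synthetic networks, annotations and expression tables with planted signal.

The generators emulate a small transcriptomic study over an interactome: a
connected random network, a designated connected module of genes whose
expression is elevated several-fold in "hot" conditions, replicated noisy
measurements on the intensity scale, and a term annotation covering the
module among size-matched decoy terms under a shallow toy ontology.  All
output is reproducible from the seed and written in the same text formats
the readers consume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import DataSet
from .network import AnnotationMap, Edge, InteractionNetwork, compute_levels

__all__ = [
    "PlantedScenario",
    "generate_network",
    "generate_expression",
    "generate_annotations",
    "generate_scenario",
    "write_bundle",
]


@dataclass
class PlantedScenario:
    """Study conditions for the planted-module benchmark.

    Defaults: a 200-node / 600-edge connected network with a 10-node
    module whose genes are 10-fold elevated in the hot condition, measured
    in triplicate with 0.25 log2-units of replicate noise (typical
    microarray replicate scatter).  Condition 0 is the unperturbed
    baseline; later conditions are hot.
    """

    n_nodes: int = 200
    n_edges: int = 600
    module_size: int = 10
    background_weight: float = 1.0
    module_weight: float = 10.0
    n_conditions: int = 2
    n_replicates: int = 3
    replicate_noise_sd: float = 0.25
    hot_conditions: tuple[int, ...] = (1,)
    n_decoy_terms: int = 20
    seed: int = 0
    topology: str = "er"  # "er" (uniform random) or "pa" (preferential)

    def __post_init__(self):
        if self.module_weight <= self.background_weight or self.background_weight <= 0:
            raise ValueError("need module_weight > background_weight > 0")
        if any(c == 0 for c in self.hot_conditions):
            raise ValueError("condition 0 is the unperturbed baseline")

    def condition_names(self) -> list[str]:
        return [f"c{i}" for i in range(self.n_conditions)]


def _node_names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(n)]


def generate_network(n_nodes: int, n_edges: int, module_size: int,
                     seed: int, topology: str = "er"
                     ) -> tuple[InteractionNetwork, list[str]]:
    """Connected random graph with a designated connected module.

    A random spanning tree guarantees connectivity (the module is wired as
    its own subtree first, so it induces at least module_size - 1 internal
    edges); extra undirected edges are added uniformly at random, or with
    probability proportional to degree when ``topology='pa'`` to mimic the
    hub bias of literature-curated interactomes.
    """
    if n_edges < n_nodes - 1:
        raise ValueError(f"need n_edges >= n_nodes - 1 for connectivity "
                         f"({n_edges} < {n_nodes - 1})")
    if not (3 <= module_size <= n_nodes):
        raise ValueError(f"module_size must be in [3, n_nodes], got {module_size}")
    max_edges = n_nodes * (n_nodes - 1) // 2
    if n_edges > max_edges:
        raise ValueError(f"n_edges={n_edges} exceeds the simple-graph "
                         f"maximum {max_edges}")
    rng = np.random.default_rng(seed)
    names = _node_names(n_nodes)
    module = names[:module_size]
    pairs: set[tuple[int, int]] = set()

    def add(i: int, j: int) -> bool:
        if i == j:
            return False
        key = (i, j) if i < j else (j, i)
        if key in pairs:
            return False
        pairs.add(key)
        return True

    degree = np.zeros(n_nodes, dtype=float)
    # spanning tree: module subtree first, then the rest attaches anywhere
    for i in range(1, n_nodes):
        # nodes 0..module_size-1 are the module, so attaching to any earlier
        # node keeps the module's own subtree internal and connected
        j = int(rng.integers(0, i))
        add(i, j)
        degree[i] += 1
        degree[j] += 1
    while len(pairs) < n_edges:
        if topology == "pa":
            p = (degree + 1.0) / (degree + 1.0).sum()
            i, j = rng.choice(n_nodes, size=2, replace=False, p=p)
        else:
            i, j = rng.choice(n_nodes, size=2, replace=False)
        if add(int(i), int(j)):
            degree[int(i)] += 1
            degree[int(j)] += 1
    edges = [Edge(names[i], names[j], directed=False, etype="pp")
             for i, j in sorted(pairs)]
    return InteractionNetwork(edges), module


def generate_expression(scenario: PlantedScenario,
                        network: InteractionNetwork,
                        module_nodes: list[str]) -> DataSet:
    """Replicated intensity table on the linear scale.

    Per gene, condition and replicate the intensity is
    2**Normal(log2(weight), noise_sd), with the module weight applying only
    to module genes in hot conditions.  Columns are named c{i}_r{j}.
    """
    rng = np.random.default_rng(scenario.seed + 1)
    genes = sorted(network.nodes)
    module = set(module_nodes)
    data: dict[str, object] = {"gene": genes}
    for ci in range(scenario.n_conditions):
        hot = ci in scenario.hot_conditions
        mu = np.array([
            math.log2(scenario.module_weight) if (hot and g in module)
            else math.log2(scenario.background_weight)
            for g in genes])
        for ri in range(scenario.n_replicates):
            log2_vals = rng.normal(mu, scenario.replicate_noise_sd)
            data[f"c{ci}_r{ri}"] = 2.0 ** log2_vals
    return DataSet(pd.DataFrame(data), "gene")


def generate_annotations(network: InteractionNetwork,
                         module_nodes: list[str],
                         n_decoy_terms: int,
                         seed: int) -> AnnotationMap:
    """Module-covering term plus size-matched random decoys and a 3-level
    toy ontology (root -> branch -> term) supplying term levels."""
    rng = np.random.default_rng(seed + 2)
    genes = sorted(network.nodes)
    size = len(module_nodes)
    term_to_genes = {"T_MODULE": frozenset(module_nodes)}
    term_names = {"T_MODULE": "planted module"}
    for d in range(n_decoy_terms):
        term = f"T_DECOY{d:03d}"
        members = rng.choice(len(genes), size=size, replace=False)
        term_to_genes[term] = frozenset(genes[i] for i in members)
        term_names[term] = f"decoy set {d}"
    parents: dict[str, set[str]] = {}
    branches = ["B_PROCESS", "B_COMPONENT"]
    for b in branches:
        parents[b] = {"ROOT"}
    for i, term in enumerate(sorted(term_to_genes)):
        parents[term] = {branches[i % len(branches)]}
    levels = compute_levels(parents)
    return AnnotationMap(term_to_genes=term_to_genes, term_names=term_names,
                         ontology_parents=parents, levels=levels)


@dataclass
class ScenarioBundle:
    network: InteractionNetwork
    module_nodes: list[str]
    expression: DataSet
    annotation: AnnotationMap
    scenario: PlantedScenario


def generate_scenario(scenario: PlantedScenario | None = None,
                      **overrides) -> ScenarioBundle:
    """Generate the full fixture set for one scenario."""
    if scenario is None:
        scenario = PlantedScenario(**overrides)
    network, module = generate_network(scenario.n_nodes, scenario.n_edges,
                                       scenario.module_size, scenario.seed,
                                       scenario.topology)
    expression = generate_expression(scenario, network, module)
    annotation = generate_annotations(network, module,
                                      scenario.n_decoy_terms, scenario.seed)
    return ScenarioBundle(network=network, module_nodes=module,
                          expression=expression, annotation=annotation,
                          scenario=scenario)


def write_bundle(bundle: ScenarioBundle, out_dir) -> dict[str, Path]:
    """Write network/expression/annotation/ontology files (the formats the
    readers consume) plus the module gene list."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "network": out / "network.tsv",
        "expression": out / "expression.tsv",
        "annotations": out / "annotations.gmt",
        "ontology": out / "ontology.tsv",
        "module": out / "module_genes.txt",
    }
    with open(paths["network"], "w") as fh:
        fh.write("# source\ttarget\tdirectedness\ttype\n")
        for e in bundle.network.edges:
            flag = "directed" if e.directed else "undirected"
            fh.write(f"{e.source}\t{e.target}\t{flag}\t{e.etype}\n")
    bundle.expression.to_tsv(paths["expression"])
    with open(paths["annotations"], "w") as fh:
        for term in sorted(bundle.annotation.term_to_genes):
            genes = "\t".join(sorted(bundle.annotation.term_to_genes[term]))
            name = bundle.annotation.term_names.get(term, "")
            fh.write(f"{term}\t{name}\t{genes}\n")
    with open(paths["ontology"], "w") as fh:
        for child in sorted(bundle.annotation.ontology_parents or {}):
            for parent in sorted(bundle.annotation.ontology_parents[child]):
                fh.write(f"{child}\t{parent}\n")
    with open(paths["module"], "w") as fh:
        for g in bundle.module_nodes:
            fh.write(g + "\n")
    return paths
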