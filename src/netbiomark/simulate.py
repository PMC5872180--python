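"""Synthetic interactomes and multi-dataset expression with known ground truth.

Two generators mirror the pipeline's inputs:

* :func:`simulate_interactome` draws a scale-free (preferential-attachment)
  background interactome, marks two overlapping pathway seed sets whose
  induced subgraph has one large component, and appends small isolated seed
  clusters that are reachable only through a designated non-seed *planted
  connector* — the unique bridge the augmentation algorithm must recover.
  Channel confidence scores are drawn so planted edges pass the 0.400
  medium-confidence filter while decoy edges fall below it.

* :func:`simulate_expression` draws per-gene variances from the scaled
  inverse-chi-square prior σ²_g ~ s0²·d0/χ²(d0) (shared across datasets, so
  the moderated-t model is exactly satisfied), baselines μ_g ~ N(8, 1), and
  adds planted group effects β_g of known sign — identical across datasets
  for concordant genes, alternating for designated discordant ones.

Preferential attachment is used for the background because hub/bottleneck
classification by mean + 1 SD is only meaningful on a heavy-tailed degree
distribution; on a degree-regular graph no node crosses the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .diffexpr import ExpressionDataset
from .interactome import Interaction, SeedSet

import pandas as pd

__all__ = [
    "SyntheticNetworkTruth",
    "SyntheticExpressionTruth",
    "simulate_interactome",
    "make_expression_truth",
    "simulate_expression",
    "SyntheticStudy",
    "simulate_study",
]

CHANNELS = ("experimental", "database")


@dataclass
class SyntheticNetworkTruth:
    """Global interaction table plus the planted structure to recover."""

    interactions: list[Interaction]
    seed_sets: tuple[SeedSet, SeedSet]
    planted_connectors: list[str]
    expected_connected: bool
    seed: int


@dataclass
class SyntheticExpressionTruth:
    """Planted effects and variance-prior parameters for recovery tests."""

    genes: list[str]
    beta: dict[str, float]           # per-gene effect; 0 for nulls
    discordant: frozenset[str]       # genes whose effect sign flips per dataset
    d0: float
    s0_sq: float
    n_control: int
    n_case: int
    n_datasets: int
    seed: int

    def __post_init__(self) -> None:
        if not (self.d0 > 0):
            raise ValueError(f"d0 must be > 0, got {self.d0}")
        if not (self.s0_sq > 0):
            raise ValueError(f"s0_sq must be > 0, got {self.s0_sq}")


def _node_name(i: int) -> str:
    return f"G{i:04d}"


def simulate_interactome(
    n_background: int = 300,
    seed_sizes: tuple[int, int] = (140, 180),
    overlap: int = 25,
    n_isolated_clusters: int = 5,
    cluster_size: int = 3,
    seed: int = 0,
    pathway_ids: tuple[str, str] = ("ST", "Ca"),
    n_decoys: int = 40,
) -> SyntheticNetworkTruth:
    """Generate a confidence-scored interaction universe with planted bridges.

    The two seed sets total ``seed_sizes[0] + seed_sizes[1] - overlap`` genes;
    ``n_isolated_clusters`` cliques of ``cluster_size`` seed genes sit outside
    the background graph and touch it only through their planted connector (a
    non-seed background node also wired to the main seed component). Decoy
    interactions carry sub-threshold scores just under 0.400, so filtering at
    medium confidence must discard them.
    """
    if overlap > min(seed_sizes):
        raise ValueError("overlap cannot exceed the smaller seed set")
    n_seeds_total = seed_sizes[0] + seed_sizes[1] - overlap
    n_cluster_genes = n_isolated_clusters * cluster_size
    n_main_seeds = n_seeds_total - n_cluster_genes
    if n_main_seeds < 2:
        raise ValueError("seed sets too small for the requested clusters")
    if n_main_seeds + n_isolated_clusters > n_background:
        raise ValueError(
            "background too small: needs at least "
            f"{n_main_seeds + n_isolated_clusters} nodes for seeds + connectors"
        )
    rng = np.random.default_rng(seed)

    background = nx.barabasi_albert_graph(n_background, 3, seed=int(rng.integers(2**31)))
    background = nx.relabel_nodes(background, {i: _node_name(i) for i in background.nodes})

    # main seeds: BFS from the highest-degree node, so the induced subgraph
    # contains the BFS tree and is connected
    start = max(background.degree, key=lambda kv: (kv[1], kv[0]))[0]
    order = [start] + [v for _, v in nx.bfs_edges(background, start)]
    main_seeds = order[:n_main_seeds]
    non_seed_pool = [n for n in background.nodes if n not in set(main_seeds)]
    rng.shuffle(non_seed_pool)
    connectors = non_seed_pool[:n_isolated_clusters]

    def passing_scores() -> dict[str, float]:
        return {
            "experimental": float(rng.uniform(0.45, 0.95)),
            "database": float(rng.uniform(0.0, 0.6)),
        }

    def decoy_scores() -> dict[str, float]:
        return {
            "experimental": float(rng.uniform(0.05, 0.39)),
            "database": 0.0,
        }

    interactions: dict[tuple[str, str], dict[str, float]] = {}

    def add(a: str, b: str, scores: dict[str, float]) -> None:
        pair = (a, b) if a <= b else (b, a)
        interactions.setdefault(pair, scores)

    for a, b in background.edges:
        add(a, b, passing_scores())

    cluster_genes: list[str] = []
    main_seed_set = set(main_seeds)
    for c, connector in enumerate(connectors):
        members = [f"X{c}_{j}" for j in range(cluster_size)]
        cluster_genes.extend(members)
        for i in range(cluster_size):
            for j in range(i + 1, cluster_size):
                add(members[i], members[j], passing_scores())
            add(members[i], connector, passing_scores())
        # guarantee the connector reaches the main component at high confidence
        anchor = main_seeds[int(rng.integers(len(main_seeds)))]
        add(connector, anchor, passing_scores())

    # decoy edges from cluster genes into the background: sub-threshold, so
    # they must not create alternative bridges after filtering
    background_nodes = list(background.nodes)
    for _ in range(n_decoys):
        g = cluster_genes[int(rng.integers(len(cluster_genes)))] if cluster_genes else None
        if g is None:
            break
        target = background_nodes[int(rng.integers(len(background_nodes)))]
        add(g, target, decoy_scores())

    all_seeds = main_seeds + cluster_genes
    shuffled = list(all_seeds)
    rng.shuffle(shuffled)
    shared = shuffled[:overlap]
    only_a = shuffled[overlap : seed_sizes[0]]
    only_b = shuffled[seed_sizes[0] :]
    seed_a = SeedSet(pathway_ids[0], frozenset(shared + only_a))
    seed_b = SeedSet(pathway_ids[1], frozenset(shared + only_b))

    interaction_list = [
        Interaction(protein_a=a, protein_b=b, channel_scores=scores)
        for (a, b), scores in sorted(interactions.items())
    ]
    return SyntheticNetworkTruth(
        interactions=interaction_list,
        seed_sets=(seed_a, seed_b),
        planted_connectors=connectors,
        expected_connected=True,
        seed=seed,
    )


def make_expression_truth(
    genes: list[str],
    de_genes: dict[str, float] | None = None,
    discordant: set[str] | None = None,
    d0: float = 4.0,
    s0_sq: float = 0.05,
    n_control: int = 10,
    n_case: int = 10,
    n_datasets: int = 3,
    seed: int = 0,
) -> SyntheticExpressionTruth:
    """Assemble a SyntheticExpressionTruth; ``de_genes`` maps planted genes to
    their effect β (others are null)."""
    beta = {g: 0.0 for g in genes}
    for g, b in (de_genes or {}).items():
        if g not in beta:
            raise KeyError(f"planted gene {g!r} not in the gene universe")
        beta[g] = b
    return SyntheticExpressionTruth(
        genes=list(genes),
        beta=beta,
        discordant=frozenset(discordant or ()),
        d0=d0,
        s0_sq=s0_sq,
        n_control=n_control,
        n_case=n_case,
        n_datasets=n_datasets,
        seed=seed,
    )


def simulate_expression(truth: SyntheticExpressionTruth) -> list[ExpressionDataset]:
    """Draw the multi-dataset expression matrices described by *truth*.

    Per-gene variances are drawn once (shared across datasets); baselines and
    noise are dataset-specific. Reproducible: the same truth yields identical
    matrices.
    """
    rng = np.random.default_rng(truth.seed)
    genes = truth.genes
    m = len(genes)
    if np.isinf(truth.d0):
        sigma_sq = np.full(m, truth.s0_sq)
    else:
        sigma_sq = truth.s0_sq * truth.d0 / rng.chisquare(truth.d0, size=m)
    sigma = np.sqrt(sigma_sq)
    beta = np.array([truth.beta[g] for g in genes])
    flip = np.array([g in truth.discordant for g in genes])

    n = truth.n_control + truth.n_case
    datasets = []
    for d in range(truth.n_datasets):
        mu = rng.normal(8.0, 1.0, size=m)
        effect = np.where(flip & (d % 2 == 1), -beta, beta)
        noise = rng.normal(0.0, 1.0, size=(m, n)) * sigma[:, None]
        values = mu[:, None] + noise
        values[:, truth.n_control :] += effect[:, None]
        samples = [f"ctrl_{i}" for i in range(truth.n_control)] + [
            f"case_{i}" for i in range(truth.n_case)
        ]
        matrix = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=samples)
        groups = pd.Series(
            ["control"] * truth.n_control + ["case"] * truth.n_case, index=samples
        )
        datasets.append(
            ExpressionDataset(dataset_id=f"SIM{d + 1}", matrix=matrix, groups=groups)
        )
    return datasets


@dataclass
class SyntheticStudy:
    """A full synthetic study: network inputs, expression datasets, and the
    planted truth needed to score recovery."""

    network: SyntheticNetworkTruth
    expression_truth: SyntheticExpressionTruth
    datasets: list[ExpressionDataset]
    planted_central: list[str] = field(default_factory=list)
    planted_noncentral: list[str] = field(default_factory=list)


def simulate_study(
    seed: int = 0,
    n_genes: int = 500,
    n_planted_de: int = 50,
    n_planted_central: int = 20,
    delta: float = 1.5,
    d0: float = 4.0,
    s0_sq: float = 0.05,
    n_control: int = 10,
    n_case: int = 10,
    n_datasets: int = 3,
) -> SyntheticStudy:
    """Simulate an end-to-end study: a plantable interactome plus multi-dataset
    expression with concordant effects planted on central network nodes.

    The interactome is built and classified internally so that
    ``n_planted_central`` of the planted DE genes are genuinely central
    (HB/NH-B); the remaining planted genes are non-central nodes or filler
    genes outside the network. The gene universe is the network's nodes padded
    with filler genes to at least ``n_genes``.
    """
    from .interactome import augment_with_connectors, filter_interactions, induced_subgraph
    from .topology import centrality_table

    rng = np.random.default_rng(seed)
    network = simulate_interactome(
        n_background=500,
        seed_sizes=(230, 270),
        overlap=40,
        n_isolated_clusters=3,
        cluster_size=2,
        seed=int(rng.integers(2**31)),
    )
    filtered = filter_interactions(network.interactions, CHANNELS, 0.400)
    seed_graph = induced_subgraph(filtered, network.seed_sets)
    result = augment_with_connectors(filtered, seed_graph)
    records, _ = centrality_table(result.graph)
    central = sorted(r.node for r in records if r.is_central)
    noncentral = sorted(r.node for r in records if not r.is_central)
    # the mean + 1 SD rule selects a scale-free-graph-dependent number of
    # central nodes; plant on as many as the draw provides, up to the request
    n_central_planted = min(n_planted_central, len(central))
    planted_central = [str(g) for g in rng.choice(central, size=n_central_planted, replace=False)]
    n_other = n_planted_de - n_central_planted
    planted_noncentral = [str(g) for g in rng.choice(noncentral, size=n_other, replace=False)]

    nodes = sorted(result.graph.nodes)
    fillers = [f"F{i:04d}" for i in range(max(0, n_genes - len(nodes)))]
    genes = nodes + fillers

    signs = rng.choice([-1.0, 1.0], size=n_planted_de)
    de_genes = {
        g: float(s * delta)
        for g, s in zip(planted_central + planted_noncentral, signs)
    }
    truth = make_expression_truth(
        genes,
        de_genes=de_genes,
        d0=d0,
        s0_sq=s0_sq,
        n_control=n_control,
        n_case=n_case,
        n_datasets=n_datasets,
        seed=int(rng.integers(2**31)),
    )
    datasets = simulate_expression(truth)
    return SyntheticStudy(
        network=network,
        expression_truth=truth,
        datasets=datasets,
        planted_central=planted_central,
        planted_noncentral=planted_noncentral,
    )
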