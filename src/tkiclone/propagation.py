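"""Heat diffusion of mutated genes over a PPI graph, gene-set scoring, clustering.

Mutated genes act as heat sources. With A the adjacency matrix, D the degree
matrix and W' = D^(-1/2) A D^(-1/2) the symmetrically normalised adjacency,
the walk-with-restart iteration

    F <- alpha * W' F + (1 - alpha) * F0

is run to steady state (L1 change < tol). Because the spectral radius of
alpha*W' is at most alpha < 1, the iteration contracts and equals the direct
solve of (I - alpha W') F = (1 - alpha) F0. ``propagate`` returns that raw
fixed point; the assembled gene x subline score matrix renormalises each
subline column to sum 1 (symmetric normalisation does not conserve mass on
irregular graphs, so conservation is imposed once, globally, per subline).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr
from sklearn.metrics import silhouette_score

from .errors import ConfigurationError, ConvergenceError, EmptySeedError, InputError
from .filtering import FilterConfig, VariantTrajectory, subline_pass_keys

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PropagationConfig:
    """Diffusion parameters.

    restart: retention fraction alpha in (0, 1]; the fraction of heat that
        keeps flowing through the network each round (1 - alpha returns to
        the sources). Default 0.5 — results should always be reported with it.
    tol: L1 convergence tolerance. max_iter: iteration cap.
    seed_weighting: 'binary' (1 per mutated gene) or 'vaf' (sum of VAFs).
    """

    restart: float = 0.5
    tol: float = 1e-8
    max_iter: int = 10_000
    seed_weighting: str = "binary"

    def __post_init__(self) -> None:
        if not 0 < self.restart <= 1:
            raise ConfigurationError("restart must be in (0, 1]")
        if self.tol <= 0:
            raise ConfigurationError("tol must be positive")
        if self.seed_weighting not in ("binary", "vaf"):
            raise ConfigurationError(f"unknown seed_weighting {self.seed_weighting!r}")


@dataclass
class PropagationResult:
    """Steady-state heat per gene and subline plus derived clusterings."""

    scores: pd.DataFrame  # genes x sublines, columns sum to 1
    iterations: dict[str, int]
    subline_clusters: pd.Series | None = None
    geneset_scores: pd.DataFrame | None = None
    geneset_clusters: pd.Series | None = None
    config: PropagationConfig = field(default_factory=PropagationConfig)


def seed_vector(
    trajectories: list[VariantTrajectory],
    level: str,
    graph: nx.Graph,
    cfg: PropagationConfig | None = None,
    filter_cfg: FilterConfig | None = None,
) -> pd.Series:
    """Initial heat vector F0 over graph genes for one resistant subline.

    Binary mode puts weight 1 on every graph gene with at least one PASS
    variant acquired in this subline; vaf mode sums the subline's VAFs over
    each gene's PASS variants. The vector is normalised to sum 1. Mutated
    genes missing from the graph are dropped with a logged count.
    """
    cfg = cfg or PropagationConfig()
    keys = subline_pass_keys(trajectories, level, filter_cfg)
    nodes = sorted(graph.nodes)
    weights: dict[str, float] = {}
    dropped = 0
    for t in trajectories:
        if t.key not in keys:
            continue
        gene = t.gene.upper()
        if gene not in graph:
            dropped += 1
            continue
        if cfg.seed_weighting == "binary":
            weights[gene] = 1.0
        else:
            vaf = {"low": t.vaf_low, "high": t.vaf_high}[level] or 0.0
            weights[gene] = weights.get(gene, 0.0) + vaf
    if dropped:
        logger.warning("%d mutated variants in genes absent from the graph", dropped)
    if not weights:
        raise EmptySeedError(f"no mutated gene of stage {level!r} is present in the graph")
    f0 = pd.Series(0.0, index=nodes)
    for gene, w in weights.items():
        f0[gene] = w
    return f0 / f0.sum()


def normalized_adjacency(graph: nx.Graph, nodes: list[str]) -> np.ndarray:
    """Symmetric degree-normalised adjacency D^(-1/2) A D^(-1/2) (dense)."""
    A = nx.to_numpy_array(graph, nodelist=nodes, weight=None)
    deg = A.sum(axis=1)
    with np.errstate(divide="ignore"):
        dinv = np.where(deg > 0, 1.0 / np.sqrt(deg), 0.0)
    return dinv[:, None] * A * dinv[None, :]


def propagate(
    f0: pd.Series, graph: nx.Graph, cfg: PropagationConfig | None = None
) -> tuple[pd.Series, int]:
    """Iterate the restart walk to its fixed point.

    Returns the raw steady state (not renormalised), which satisfies
    ||F - [alpha W' F + (1-alpha) F0]||_1 < tol, and the iteration count.
    Heat seeded in one connected component never reaches another.
    """
    cfg = cfg or PropagationConfig()
    nodes = list(f0.index)
    if set(nodes) != set(graph.nodes):
        raise InputError("seed vector index must match the graph's node set")
    W = normalized_adjacency(graph, nodes)
    alpha = cfg.restart
    f = f0.to_numpy(dtype=float).copy()
    base = (1 - alpha) * f0.to_numpy(dtype=float)
    for iteration in range(1, cfg.max_iter + 1):
        f_new = alpha * (W @ f) + base
        change = np.abs(f_new - f).sum()
        f = f_new
        if change < cfg.tol:
            return pd.Series(f, index=nodes), iteration
    raise ConvergenceError(
        f"propagation did not converge in {cfg.max_iter} iterations", residual=float(change)
    )


def propagate_sublines(
    trajectories_by_trio: dict[str, list[VariantTrajectory]],
    graph: nx.Graph,
    cfg: PropagationConfig | None = None,
    filter_cfg: FilterConfig | None = None,
) -> PropagationResult:
    """Run the diffusion for every resistant subline and assemble the score matrix.

    Each subline column of the result is renormalised to sum 1 so heats are
    comparable across sublines. Sublines with an empty seed are skipped with
    a warning.
    """
    cfg = cfg or PropagationConfig()
    nodes = sorted(graph.nodes)
    columns: dict[str, np.ndarray] = {}
    iterations: dict[str, int] = {}
    for trio_id, trajectories in trajectories_by_trio.items():
        for level in ("low", "high"):
            label = f"{level}{trio_id}"
            try:
                f0 = seed_vector(trajectories, level, graph, cfg, filter_cfg)
            except EmptySeedError:
                logger.warning("subline %s has no seed genes in the graph; skipped", label)
                continue
            f, n_iter = propagate(f0, graph, cfg)
            total = f.sum()
            columns[label] = (f / total).to_numpy()
            iterations[label] = n_iter
    scores = pd.DataFrame(columns, index=nodes)
    return PropagationResult(scores=scores, iterations=iterations, config=cfg)


def score_genesets(
    scores: pd.DataFrame, genesets: dict[str, set[str]], scale: bool = True
) -> pd.DataFrame:
    """Gene-set x subline matrix: mean propagated score over each set's graph genes.

    With ``scale=True`` every row is z-scaled across sublines; rows with no
    graph genes or zero variance are dropped with a warning.
    """
    rows = {}
    for name, genes in genesets.items():
        members = [g for g in (s.upper() for s in genes) if g in scores.index]
        if not members:
            logger.warning("gene set %s has no genes in the graph; excluded", name)
            continue
        rows[name] = scores.loc[members].mean(axis=0)
    matrix = pd.DataFrame(rows).T
    matrix.columns = scores.columns
    if not scale:
        return matrix
    std = matrix.std(axis=1, ddof=0)
    constant = std[std == 0].index
    if len(constant):
        logger.warning("dropping %d constant gene-set rows before scaling", len(constant))
        matrix = matrix.drop(index=constant)
        std = std.drop(index=constant)
    return matrix.sub(matrix.mean(axis=1), axis=0).div(std, axis=0)


def cluster(matrix: pd.DataFrame, k: int | None = None) -> pd.Series:
    """Agglomerative clustering of the matrix rows.

    Distance is 1 - Pearson correlation between rows, average linkage. With
    ``k=None`` the cut is chosen by the largest silhouette over
    k in [2, min(10, n-1)]. Constant rows (undefined correlation) are dropped
    with a warning; a single row yields the identity partition.
    """
    values = matrix.to_numpy(dtype=float)
    keep = values.std(axis=1) > 0
    if (~keep).any():
        logger.warning("dropping %d constant rows before clustering", int((~keep).sum()))
    matrix = matrix.loc[keep]
    n = len(matrix)
    if n == 0:
        return pd.Series(dtype=int)
    if n == 1:
        return pd.Series([1], index=matrix.index, name="cluster")
    corr = np.corrcoef(matrix.to_numpy(dtype=float))
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    if k is not None:
        labels = fcluster(Z, t=k, criterion="maxclust")
    else:
        best_labels, best_score = None, -np.inf
        for candidate in range(2, min(10, n - 1) + 1):
            labels = fcluster(Z, t=candidate, criterion="maxclust")
            if len(np.unique(labels)) < 2:
                continue
            score = silhouette_score(dist, labels, metric="precomputed")
            if score > best_score:
                best_labels, best_score = labels, score
        labels = best_labels if best_labels is not None else np.ones(n, dtype=int)
    return pd.Series(labels, index=matrix.index, name="cluster")


def compare_matrices(
    propagation_scores: pd.DataFrame, enrichment: pd.DataFrame
) -> tuple[pd.Series, float]:
    """Spearman correlation per shared gene-set row plus the median across rows.

    Rows and columns are intersected; fewer than 3 shared columns is an error.
    No significance is attached.
    """
    shared_rows = propagation_scores.index.intersection(enrichment.index)
    shared_cols = propagation_scores.columns.intersection(enrichment.columns)
    if len(shared_cols) < 3:
        raise InputError(f"need at least 3 shared subline columns, got {len(shared_cols)}")
    if len(shared_rows) == 0:
        raise InputError("matrices share no gene-set rows")
    correlations = {}
    for name in shared_rows:
        rho = spearmanr(
            propagation_scores.loc[name, shared_cols], enrichment.loc[name, shared_cols]
        ).statistic
        correlations[name] = float(rho)
    per_row = pd.Series(correlations, name="spearman_rho")
    return per_row, float(per_row.median())
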