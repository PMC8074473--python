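"""Network-level orchestration, edge scores and precision-recall evaluation.

Because regulatory interactions act with a lag of one time point, no
acyclicity constraint is needed and the N parent sets can be learned by N
independent per-node regressions.  The learned covariate sets are merged
into a directed graph: the edge Z_i -> Z_j is present exactly when X_i is
in the parent set of Z_j.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .models import CouplingHyper, Variant
from .regression import ExpressionMatrix, build_regression_task
from .sampler import ChainConfig, ChainResult, PosteriorSample, run_chain


@dataclass(frozen=True)
class Network:
    """A directed graph over named nodes; self-loops are disallowed."""

    nodes: tuple[str, ...]
    edges: frozenset[tuple[str, str]]

    def __post_init__(self):
        nodes = tuple(self.nodes)
        edges = frozenset((str(a), str(b)) for a, b in self.edges)
        known = set(nodes)
        for a, b in edges:
            if a == b:
                raise ValueError(f"self-loop {a}->{b} not allowed")
            if a not in known or b not in known:
                raise ValueError(f"edge {a}->{b} references unknown node")
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "edges", edges)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g


@dataclass
class EdgeScoreMatrix:
    """Posterior edge probabilities; scores[i, j] is for edge node_i -> node_j."""

    scores: np.ndarray
    node_names: tuple[str, ...]

    def as_dict(self) -> dict[tuple[str, str], float]:
        out = {}
        N = len(self.node_names)
        for i in range(N):
            for j in range(N):
                if i != j:
                    out[(self.node_names[i], self.node_names[j])] = float(
                        self.scores[i, j]
                    )
        return out


@dataclass
class InferenceResult:
    chains: dict[str, ChainResult]
    scores: EdgeScoreMatrix
    seed: int
    node_seeds: dict[str, int]


def node_seed(master_seed: int, node_name: str) -> int:
    """Deterministic per-node chain seed keyed by node *name*.

    Keyed by name (CRC-32) rather than row position, so permuting the
    input rows or re-running a node subset reproduces the same chains.
    """
    return int(
        np.random.SeedSequence(
            [int(master_seed), zlib.crc32(node_name.encode())]
        ).generate_state(1)[0]
        % (2**31)
    )


def infer_network(
    data: ExpressionMatrix,
    variant: Variant,
    hyper: CouplingHyper | None = None,
    config: ChainConfig | None = None,
    seed: int = 0,
    n_jobs: int = 1,
) -> InferenceResult:
    """Run one RJMCMC chain per target node and collect edge scores."""
    hyper = hyper or CouplingHyper()
    config = config or ChainConfig()
    seeds = {name: node_seed(seed, name) for name in data.node_names}

    # canonical (name-sorted) internal node order, so that permuting the
    # input rows permutes the returned scores and nothing else
    order = sorted(range(data.n_nodes), key=lambda i: data.node_names[i])
    canonical = ExpressionMatrix(
        values=data.values[order],
        node_names=tuple(data.node_names[i] for i in order),
        series_boundaries=data.series_boundaries,
    )

    def one(target: int) -> tuple[str, ChainResult]:
        name = canonical.node_names[target]
        task = build_regression_task(canonical, target)
        try:
            return name, run_chain(task, variant, hyper, config, seed=seeds[name])
        except Exception as err:  # annotate with node identity
            raise RuntimeError(f"chain for node '{name}' failed: {err}") from err

    targets = range(data.n_nodes)
    if n_jobs != 1:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=n_jobs)(delayed(one)(t) for t in targets)
    else:
        results = [one(t) for t in targets]
    chains = dict(results)
    canon_scores = edge_scores(
        {name: chains[name].samples for name in canonical.node_names},
        canonical.node_names,
    )
    # map back to the caller's node order
    pos = {name: i for i, name in enumerate(canonical.node_names)}
    idx = [pos[name] for name in data.node_names]
    scores = EdgeScoreMatrix(
        scores=canon_scores.scores[np.ix_(idx, idx)],
        node_names=tuple(data.node_names),
    )
    return InferenceResult(
        chains=chains, scores=scores, seed=seed, node_seeds=seeds
    )


def edge_scores(
    samples: dict[str, list[PosteriorSample]],
    node_names: tuple[str, ...],
) -> EdgeScoreMatrix:
    """Fraction of posterior samples containing each edge.

    e_hat[i, j] = (1/W) * #{w : X_i in pi_j^(w)}.
    """
    N = len(node_names)
    scores = np.zeros((N, N))
    for j, name in enumerate(node_names):
        node_samples = samples[name]
        if not node_samples:
            raise ValueError(f"no posterior samples for node '{name}'")
        candidates = [i for i in range(N) if i != j]
        counts = np.zeros(len(candidates))
        for s in node_samples:
            for p in s.parents:
                counts[p] += 1
        for c, i in enumerate(candidates):
            scores[i, j] = counts[c] / len(node_samples)
    return EdgeScoreMatrix(scores=scores, node_names=tuple(node_names))


def precision_recall_auc(
    scores: EdgeScoreMatrix,
    truth: Network,
    interpolation: str = "trapezoid",
) -> float:
    """Area under the precision-recall curve of thresholded edge scores.

    For each threshold xi the n_xi edges with score strictly exceeding xi
    are extracted and the true positives T_xi among them counted;
    precision P = T/n is plotted against recall R = T/M (M = number of
    true edges).  xi runs over the distinct score values plus a value
    below the minimum, so both the empty and the full prediction are on
    the curve.  The area is the trapezoidal rule over the (R, P) points
    with a (0, P_first) left endpoint; ``interpolation="step"`` uses the
    right-continuous step rule instead.
    """
    if truth.n_edges == 0:
        raise ValueError("truth network needs at least one edge")
    M = truth.n_edges
    pairs = scores.as_dict()
    vals = np.array(list(pairs.values()))
    labels = np.array([(a, b) in truth.edges for (a, b) in pairs], dtype=bool)
    thresholds = np.unique(vals)
    points = []  # (recall, precision), increasing recall
    for xi in thresholds[::-1]:
        sel = vals > xi
        n_xi = int(sel.sum())
        if n_xi == 0:
            continue
        T_xi = int(labels[sel].sum())
        points.append((T_xi / M, T_xi / n_xi))
    sel = vals >= thresholds[0]  # full prediction
    points.append((int(labels.sum()) / M, int(labels.sum()) / len(vals)))
    # deduplicate identical recall values, keeping the first (highest-threshold)
    seen: dict[float, float] = {}
    ordered = []
    for r, p in points:
        if r not in seen:
            seen[r] = p
            ordered.append((r, p))
    if len(ordered) == 1:
        r, p = ordered[0]
        return float(p * r)
    rs = np.array([r for r, _ in ordered])
    ps = np.array([p for _, p in ordered])
    if rs[0] > 0.0:  # left endpoint at zero recall
        rs = np.concatenate(([0.0], rs))
        ps = np.concatenate(([ps[0]], ps))
    if interpolation == "trapezoid":
        return float(np.trapezoid(ps, rs))
    if interpolation == "step":
        return float(np.sum(np.diff(rs) * ps[1:]))
    raise ValueError(f"unknown interpolation '{interpolation}'")


def top_k_prediction(scores: EdgeScoreMatrix, k: int) -> Network:
    """The k highest-scoring edges as a network prediction.

    Ties at the cut are broken deterministically: lexicographically
    smaller (parent, child) name pairs win.
    """
    pairs = scores.as_dict()
    if k > len(pairs):
        raise ValueError(f"k={k} exceeds the {len(pairs)} candidate edges")
    ranked = sorted(pairs.items(), key=lambda kv: (-kv[1], kv[0]))
    return Network(
        nodes=scores.node_names,
        edges=frozenset(edge for edge, _ in ranked[:k]),
    )
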