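"""Synthetic benchmark data with known network truth.

Two generators emulate the standard simulation protocols for
non-homogeneous network inference:

* :func:`generate_study1` — the 11-node / 20-edge RAF signalling pathway
  (Sachs et al. consensus topology) with H = 4 segments of m data points.
  Per node, the first-segment coefficient vector is standard Gaussian
  normalised to unit Euclidean norm, and each later segment either keeps
  (coupled, delta_h = 1) or sign-flips (uncoupled, delta_h = 0) the
  previous vector according to the chosen coupling scenario.
* :func:`generate_study2` — the 5-node / 8-edge synthetic yeast (IRMA)
  network with H = 4 segments: w_1 = w_2 = w_diamond (unit norm) and
  w_3 = w_4 = (w_diamond + w_star)/||w_diamond + w_star|| with
  ||w_star|| = 0.5, i.e. an identical pair, a moderate transition, and a
  second identical pair.

Values are generated recursively: each time point is the noisy linear
response to the *observed* (noisy) parent values of the previous time
point, mirroring how measured expression data feed forward.  A
non-recursive mode propagates a noise-free latent trajectory instead and
adds observation noise on top.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .network import Network
from .regression import ExpressionMatrix, Segmentation

FIXTURE_NAMES = ("raf", "yeast")


@dataclass(frozen=True)
class CouplingScenario:
    """True coupling indicators (delta_2, delta_3, delta_4); delta_1 == 0."""

    delta_true: tuple[int, int, int]

    def __post_init__(self):
        if len(self.delta_true) != 3 or any(
            d not in (0, 1) for d in self.delta_true
        ):
            raise ValueError("scenario must be three binary indicators")

    @classmethod
    def from_string(cls, s: str) -> "CouplingScenario":
        """Parse '0101'-style labels; a leading 0 for delta_1 may be included."""
        if len(s) == 4 and s[0] == "0":
            s = s[1:]
        return cls(tuple(int(c) for c in s))

    def __str__(self) -> str:
        return "0" + "".join(str(d) for d in self.delta_true)


ALL_SCENARIOS = tuple(
    CouplingScenario((a, b, c)) for a in (0, 1) for b in (0, 1) for c in (0, 1)
)


@dataclass
class SyntheticDataset:
    """A generated expression matrix plus full generating truth."""

    data: ExpressionMatrix
    truth: Network
    segmentation: Segmentation
    coefficients: dict[str, np.ndarray]  # node -> (H, k+1) per-segment vectors
    parent_names: dict[str, tuple[str, ...]]
    noise_sd: float
    seed: int
    scenario: CouplingScenario | None = None
    aux: dict = field(default_factory=dict)


def fixture_network(name: str) -> Network:
    """One of the bundled benchmark topologies ('raf' or 'yeast')."""
    if name not in FIXTURE_NAMES:
        raise ValueError(f"unknown fixture '{name}'; choose from {FIXTURE_NAMES}")
    text = resources.files("nhdbn.data").joinpath(f"{name}.tsv").read_text()
    edges = []
    nodes: list[str] = []
    for line in text.strip().splitlines():
        a, b = line.split("\t")
        edges.append((a, b))
        for v in (a, b):
            if v not in nodes:
                nodes.append(v)
    return Network(nodes=tuple(nodes), edges=frozenset(edges))


def _simulate(
    net: Network,
    coeffs: dict[str, np.ndarray],
    parents: dict[str, tuple[str, ...]],
    H: int,
    m: int,
    noise_sd: float,
    rng: np.random.Generator,
    recursive: bool,
) -> np.ndarray:
    """Roll the network dynamics forward over H*m + 1 time points."""
    names = net.nodes
    N = len(names)
    T = H * m
    observed = np.empty((N, T + 1))
    latent = np.empty((N, T + 1))
    init = rng.standard_normal(N)
    latent[:, 0] = init
    observed[:, 0] = init
    idx = {n: i for i, n in enumerate(names)}
    source = observed if recursive else latent
    for t in range(1, T + 1):
        h = (t - 1) // m  # 0-based segment of observation t
        prev = source[:, t - 1]
        for i, name in enumerate(names):
            w = coeffs[name][h]
            z = w[0]
            for j, p in enumerate(parents[name]):
                z += w[j + 1] * prev[idx[p]]
            latent[i, t] = z
            observed[i, t] = z + noise_sd * rng.standard_normal()
    return observed


def _parent_map(net: Network) -> dict[str, tuple[str, ...]]:
    order = {n: i for i, n in enumerate(net.nodes)}
    out = {}
    for child in net.nodes:
        ps = sorted(
            (a for a, b in net.edges if b == child), key=lambda n: order[n]
        )
        out[child] = tuple(ps)
    return out


def generate_study1(
    scenario: CouplingScenario | str,
    seed: int,
    noise_sd: float = 0.05,
    m: int = 10,
    recursive: bool = True,
) -> SyntheticDataset:
    """RAF-pathway data with sign-flip (un)coupling between segments.

    H = 4 segments of ``m`` observations each; per node w_1 ~ N(0, I)
    normalised to unit norm and w_h = +/- w_{h-1} depending on the
    scenario's delta_h.  Gaussian observation noise with standard
    deviation ``noise_sd`` is added element-wise.
    """
    if isinstance(scenario, str):
        scenario = CouplingScenario.from_string(scenario)
    if m < 2:
        raise ValueError("need at least m=2 observations per segment")
    H = 4
    net = fixture_network("raf")
    parents = _parent_map(net)
    rng = np.random.default_rng(seed)
    coeffs = {}
    for name in net.nodes:
        k1 = len(parents[name]) + 1
        w1 = rng.standard_normal(k1)
        w1 /= np.linalg.norm(w1)
        W = np.empty((H, k1))
        W[0] = w1
        for h in range(1, H):
            W[h] = W[h - 1] if scenario.delta_true[h - 1] == 1 else -W[h - 1]
        coeffs[name] = W
    values = _simulate(net, coeffs, parents, H, m, noise_sd, rng, recursive)
    data = ExpressionMatrix(values=values, node_names=net.nodes)
    return SyntheticDataset(
        data=data,
        truth=net,
        segmentation=Segmentation((m, 2 * m, 3 * m)),
        coefficients=coeffs,
        parent_names=parents,
        noise_sd=noise_sd,
        seed=seed,
        scenario=scenario,
    )


def generate_study2(
    m: int,
    seed: int,
    noise_sd: float = 0.05,
    recursive: bool = True,
) -> SyntheticDataset:
    """Yeast-network data with an identical / moderate / identical pattern.

    H = 4 segments of ``m`` observations; per node two standard Gaussian
    vectors are drawn and renormalised to norms 1 (w_diamond) and 0.5
    (w_star); then w_1 = w_2 = w_diamond and
    w_3 = w_4 = (w_diamond + w_star) / ||w_diamond + w_star||.
    """
    if m < 2:
        raise ValueError("need at least m=2 observations per segment")
    H = 4
    net = fixture_network("yeast")
    parents = _parent_map(net)
    rng = np.random.default_rng(seed)
    coeffs = {}
    aux = {"w_diamond": {}, "w_star": {}}
    for name in net.nodes:
        k1 = len(parents[name]) + 1
        w_d = rng.standard_normal(k1)
        w_d /= np.linalg.norm(w_d)
        w_s = rng.standard_normal(k1)
        w_s *= 0.5 / np.linalg.norm(w_s)
        w_late = w_d + w_s
        w_late /= np.linalg.norm(w_late)
        coeffs[name] = np.stack([w_d, w_d, w_late, w_late])
        aux["w_diamond"][name] = w_d
        aux["w_star"][name] = w_s
    values = _simulate(net, coeffs, parents, H, m, noise_sd, rng, recursive)
    data = ExpressionMatrix(values=values, node_names=net.nodes)
    return SyntheticDataset(
        data=data,
        truth=net,
        segmentation=Segmentation((m, 2 * m, 3 * m)),
        coefficients=coeffs,
        parent_names=parents,
        noise_sd=noise_sd,
        seed=seed,
        scenario=None,
        aux=aux,
    )
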