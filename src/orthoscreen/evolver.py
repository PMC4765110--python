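"""Generative construction of ground-truth training clusters.

True-homology (H) training clusters are, at desk scale, simulated
protein families: tips of a shallow random tree evolved from a random
root under the WAG amino-acid substitution model.  Non-homology (NH)
decoys come in two flavours mirroring how false positives arise in
practice:

* ``NH_RANDOM`` — clusters of sequences drawn at random from the whole
  protein pool, with cluster size sampled from Poisson(λ = 44.3056),
  the average size of the reference homology clusters;
* ``NH_EVOLVED_{0,25,50}`` — for each member of an H cluster, grow a
  random binary tree whose tip count is a discretized Normal(50, 15)
  draw, evolve the member along it under WAG+I (invariable-site
  proportion 0 %, 25 % or 50 %), and keep a single randomly chosen tip.
  The picks are deeply diverged, so the resulting cluster retains the
  size and residue composition of a real cluster while lacking common
  ancestry.

Evolution is substitution-only (no indels): a continuous-time Markov
process per site, with transition matrices exp(Q·t) obtained from one
eigendecomposition of the reversible WAG rate matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from ._wag import WAG_ORDER, wag_exchangeabilities, wag_frequencies
from .cluster_io import (
    Cluster,
    ClusterLabel,
    Provenance,
    SequenceRecord,
)
from .msa_align import AlignParams, progressive_align

_WAG_INDEX = {c: i for i, c in enumerate(WAG_ORDER)}


@dataclass(frozen=True)
class TreeParams:
    """Random binary tree shape: Normal tip count, exponential branches."""

    tip_mean: float = 50.0
    tip_sd: float = 15.0
    branch_length_mean: float = 0.5  # substitutions/site per edge
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tip_mean <= 2:
            raise ValueError("tip_mean must exceed 2")
        if self.tip_sd <= 0 or self.branch_length_mean <= 0:
            raise ValueError("tip_sd and branch_length_mean must be positive")


@dataclass(frozen=True)
class NHGenParams:
    """Cluster-size model for random-draw NH decoys."""

    poisson_lambda: float = 44.3056
    min_cluster_size: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.poisson_lambda <= 0:
            raise ValueError("poisson_lambda must be positive")


@dataclass(frozen=True)
class RandomTree:
    """Rooted binary tree with per-edge lengths in substitutions/site."""

    tree: dendropy.Tree
    n_tips: int

    def newick(self) -> str:
        return self.tree.as_string(schema="newick").strip()


class EvolutionModel:
    """WAG exchangeabilities + equilibrium frequencies + invariable sites.

    The rate matrix q_ij = s_ij π_j (i≠j) is scaled to one expected
    substitution per site per unit branch length at equilibrium.
    """

    def __init__(
        self,
        exchangeabilities: np.ndarray | None = None,
        equilibrium_freqs: np.ndarray | None = None,
        p_inv: float = 0.0,
    ):
        self.exchangeabilities = (
            wag_exchangeabilities() if exchangeabilities is None else exchangeabilities
        )
        self.equilibrium_freqs = (
            wag_frequencies() if equilibrium_freqs is None else equilibrium_freqs
        )
        if not np.isclose(self.equilibrium_freqs.sum(), 1.0):
            raise ValueError("equilibrium frequencies must sum to 1")
        if not (0.0 <= p_inv < 1.0) and p_inv != 1.0:
            raise ValueError("p_inv must lie in [0, 1]")
        self.p_inv = float(p_inv)
        self._decomposition: tuple | None = None

    @property
    def rate_matrix(self) -> np.ndarray:
        pi = self.equilibrium_freqs
        q = self.exchangeabilities * pi[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        scale = -np.sum(pi * np.diag(q))
        return q / scale

    def _eigen(self):
        if self._decomposition is None:
            pi = self.equilibrium_freqs
            q = self.rate_matrix
            sqrt_pi = np.sqrt(pi)
            sym = (sqrt_pi[:, None] * q) / sqrt_pi[None, :]
            eigvals, eigvecs = np.linalg.eigh((sym + sym.T) / 2.0)
            left = eigvecs.T * sqrt_pi[None, :]
            right = eigvecs / sqrt_pi[:, None]
            self._decomposition = (eigvals, right, left)
        return self._decomposition

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Q t); exact via the reversible eigendecomposition."""
        if t < 0:
            raise ValueError("branch length must be nonnegative")
        eigvals, right, left = self._eigen()
        p = (right * np.exp(eigvals * t)[None, :]) @ left
        np.clip(p, 0.0, None, out=p)
        p /= p.sum(axis=1, keepdims=True)
        return p

    def provenance(self) -> Provenance:
        tag = int(round(self.p_inv * 100))
        try:
            return Provenance[f"NH_EVOLVED_{tag}"]
        except KeyError as exc:
            raise ValueError(
                f"no provenance tag for p_inv={self.p_inv}; "
                "use 0, 0.25 or 0.5 or label the cluster yourself"
            ) from exc


def _random_topology(
    n_tips: int, branch_length_mean: float, rng: np.random.Generator
) -> RandomTree:
    """Random sequential coalescence of n_tips lineages, Exp branch lengths."""
    taxa = dendropy.TaxonNamespace([f"t{i}" for i in range(n_tips)])
    nodes = []
    for i in range(n_tips):
        leaf = dendropy.Node(taxon=taxa[i])
        leaf.edge.length = float(rng.exponential(branch_length_mean))
        nodes.append(leaf)
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        parent = dendropy.Node()
        parent.edge.length = float(rng.exponential(branch_length_mean))
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[j] = parent
        nodes.pop(i)
    root = nodes[0]
    root.edge.length = None  # the root has no incoming edge
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root
    return RandomTree(tree=tree, n_tips=n_tips)


def sample_tree(
    params: TreeParams, rng: np.random.Generator | None = None
) -> RandomTree:
    """Random binary tree; tip count = round(Normal(tip_mean, tip_sd)), ≥ 2."""
    rng = np.random.default_rng(params.seed) if rng is None else rng
    while True:
        n_tips = int(round(rng.normal(params.tip_mean, params.tip_sd)))
        if n_tips >= 2:
            break
    return _random_topology(n_tips, params.branch_length_mean, rng)


def _encode_wag(residues: str) -> np.ndarray:
    try:
        return np.fromiter(
            (_WAG_INDEX[c] for c in residues), dtype=np.int64, count=len(residues)
        )
    except KeyError as exc:
        raise ValueError(
            f"cannot evolve residue {exc.args[0]!r}: only the 20 standard "
            "amino acids are allowed (no 'X', no gaps)"
        ) from exc


def _sample_children(
    states: np.ndarray, p: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    cum = np.cumsum(p, axis=1)
    u = rng.random(len(states))
    return (u[:, None] > cum[states]).sum(axis=1)


def evolve_on_tree(
    root: SequenceRecord,
    tree: RandomTree,
    model: EvolutionModel,
    seed: int,
) -> list[SequenceRecord]:
    """Evolve a root sequence down every edge; returns one record per tip.

    A Bernoulli(p_inv) mask per site, drawn once per root, marks sites
    that never mutate anywhere in the tree.
    """
    rng = np.random.default_rng(seed)
    root_states = _encode_wag(root.ungapped())
    length = len(root_states)
    invariable = rng.random(length) < model.p_inv
    variable_idx = np.flatnonzero(~invariable)
    states: dict[int, np.ndarray] = {id(tree.tree.seed_node): root_states}
    tips: list[SequenceRecord] = []
    for node in tree.tree.preorder_node_iter():
        if node is tree.tree.seed_node:
            node_states = root_states
        else:
            parent_states = states[id(node.parent_node)]
            node_states = parent_states.copy()
            if len(variable_idx) and node.edge.length > 0:
                p = model.transition_matrix(node.edge.length)
                node_states[variable_idx] = _sample_children(
                    parent_states[variable_idx], p, rng
                )
            states[id(node)] = node_states
        states[id(node)] = node_states
        if node.is_leaf():
            residues = "".join(WAG_ORDER[s] for s in node_states)
            tips.append(
                SequenceRecord(
                    id=f"{root.id}|{node.taxon.label}", residues=residues
                )
            )
    return tips


def make_nh_evolved(
    h_cluster: Cluster,
    model: EvolutionModel,
    tparams: TreeParams,
    seed: int,
    align: bool = True,
    align_params: AlignParams | None = None,
) -> Cluster:
    """Deep-divergence NH decoy: one random evolved tip per H member."""
    rng = np.random.default_rng(seed)
    picks: list[SequenceRecord] = []
    for member in h_cluster.members:
        tree = sample_tree(tparams, rng)
        tips = evolve_on_tree(
            member, tree, model, seed=int(rng.integers(0, 2**31 - 1))
        )
        pick = tips[int(rng.integers(0, len(tips)))]
        picks.append(pick)
    cluster = Cluster(
        cluster_id=f"{h_cluster.cluster_id}_evolved_{int(round(model.p_inv*100))}",
        members=picks,
        label=ClusterLabel.NH,
        provenance=model.provenance(),
    )
    if align:
        cluster = progressive_align(cluster, align_params)
    return cluster


def sample_cluster_size(
    params: NHGenParams,
    rng: np.random.Generator,
    truncate: bool = True,
    max_size: int | None = None,
) -> int:
    """Poisson(λ) cluster-size draw, redrawn to honour the size bounds."""
    while True:
        s = int(rng.poisson(params.poisson_lambda))
        if not truncate:
            return s
        if s >= params.min_cluster_size and (max_size is None or s <= max_size):
            return s


def make_nh_random(
    pool: list[SequenceRecord],
    params: NHGenParams,
    rng: np.random.Generator | None = None,
    cluster_id: str = "nh_random",
    align: bool = True,
    align_params: AlignParams | None = None,
) -> Cluster:
    """Random-draw NH decoy from the totality of the protein pool."""
    if len(pool) < params.min_cluster_size:
        raise ValueError(
            f"pool of {len(pool)} sequences is smaller than the minimum "
            f"cluster size {params.min_cluster_size}"
        )
    rng = np.random.default_rng(params.seed) if rng is None else rng
    size = sample_cluster_size(params, rng, truncate=True, max_size=len(pool))
    chosen = rng.choice(len(pool), size=size, replace=False)
    members = [pool[int(i)] for i in sorted(chosen)]
    cluster = Cluster(
        cluster_id=cluster_id,
        members=members,
        label=ClusterLabel.NH,
        provenance=Provenance.NH_RANDOM,
    )
    if align:
        cluster = progressive_align(cluster, align_params)
    return cluster


def make_h_synthetic(
    n_clusters: int,
    size_lambda: float = 44.3056,
    root_length_range: tuple[int, int] = (100, 400),
    divergence: float = 0.05,
    seed: int = 0,
    align: bool = True,
    align_params: AlignParams | None = None,
) -> list[Cluster]:
    """Simulated protein families standing in for curated H clusters.

    Each cluster is the full tip set of one shallow random tree (branch
    lengths Exp(mean = divergence)) grown from an i.i.d. WAG-equilibrium
    root, so members are conserved and of equal length.
    """
    rng = np.random.default_rng(seed)
    model = EvolutionModel(p_inv=0.0)
    freqs = model.equilibrium_freqs
    lo, hi = root_length_range
    if not (1 <= lo <= hi):
        raise ValueError("root_length_range must satisfy 1 <= lo <= hi")
    size_params = NHGenParams(poisson_lambda=size_lambda)
    clusters: list[Cluster] = []
    for k in range(n_clusters):
        n_tips = sample_cluster_size(size_params, rng, truncate=True)
        length = int(rng.integers(lo, hi + 1))
        root_states = rng.choice(20, size=length, p=freqs)
        root = SequenceRecord(
            id=f"h{k:05d}", residues="".join(WAG_ORDER[s] for s in root_states)
        )
        tree = _random_topology(n_tips, divergence, rng)
        tips = evolve_on_tree(
            root, tree, model, seed=int(rng.integers(0, 2**31 - 1))
        )
        cluster = Cluster(
            cluster_id=f"h{k:05d}",
            members=tips,
            label=ClusterLabel.H,
            provenance=Provenance.H_SYNTH,
        )
        if align:
            cluster = progressive_align(cluster, align_params)
        clusters.append(cluster)
    return clusters


def generate_pools(
    n_h: int,
    n_nh_random: int,
    n_nh_evolved_each: int,
    seed: int = 0,
    divergence: float = 0.05,
    root_length_range: tuple[int, int] = (100, 400),
    size_lambda: float = 44.3056,
    tparams: TreeParams | None = None,
    p_inv_levels: tuple[float, ...] = (0.0, 0.25, 0.5),
    align: bool = True,
    align_params: AlignParams | None = None,
) -> dict[Provenance, list[Cluster]]:
    """Full ground-truth generation: H families plus the four NH flavours.

    Evolved decoys are derived from the H clusters themselves; the
    random-draw pool is the union of all H members (the 'proteome').
    """
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(4)
    h_clusters = make_h_synthetic(
        n_h,
        size_lambda=size_lambda,
        root_length_range=root_length_range,
        divergence=divergence,
        seed=int(seeds[0]),
        align=align,
        align_params=align_params,
    )
    pools: dict[Provenance, list[Cluster]] = {Provenance.H_SYNTH: h_clusters}
    pool_seqs = [m for c in h_clusters for m in c.members]
    rng = np.random.default_rng(int(seeds[1]))
    nh_random = [
        make_nh_random(
            pool_seqs,
            NHGenParams(poisson_lambda=size_lambda),
            rng=rng,
            cluster_id=f"nhr{k:05d}",
            align=align,
            align_params=align_params,
        )
        for k in range(n_nh_random)
    ]
    pools[Provenance.NH_RANDOM] = nh_random
    tparams = tparams or TreeParams()
    for level_idx, p_inv in enumerate(p_inv_levels):
        model = EvolutionModel(p_inv=p_inv)
        evo_rng = np.random.default_rng(int(seeds[2]) + level_idx)
        clusters = [
            make_nh_evolved(
                h_clusters[k % len(h_clusters)],
                model,
                tparams,
                seed=int(evo_rng.integers(0, 2**31 - 1)),
                align=align,
                align_params=align_params,
            )
            for k in range(n_nh_evolved_each)
        ]
        pools[model.provenance()] = clusters
    return pools
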