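"""Collapsed Gibbs sampler for a Dirichlet-process mixture of categoricals.

The model: a Chinese Restaurant Process prior with concentration ``alpha``
over partitions of ``N`` respondents, and, per cluster and per item dimension
``d``, a categorical likelihood whose probability vector carries a symmetric
Dirichlet(``beta``) prior.  The Dirichlet parameters are integrated out
analytically, so a cluster is summarized by its response-count sufficient
statistics and a new observation is scored by the Dirichlet-categorical
posterior predictive

    F_k(o) = prod_d (n_{k,d,o_d} + beta) / (n_k + V_d * beta)

with the prior predictive ``prod_d 1/V_d`` for an empty cluster.  A Gibbs
sweep removes each respondent in turn and reseats it with probability
proportional to ``n_k * F_k(o)`` for each occupied table and ``alpha * F_new(o)``
for a new one.  Chains are initialized by seating respondents sequentially
with the same likelihood-weighted rule, then burned in, thinned, and pooled
across independent replicate chains.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .data import CategoricalDataset, validate_observation
from .partition import Partition


@dataclass
class SamplerConfig:
    """Sampling protocol; defaults mirror the full-scale study protocol.

    alpha : CRP concentration (> 0); weight of founding a new cluster.
    beta : symmetric Dirichlet concentration per response option (> 0).
    burn_in : sweeps discarded before retention.
    thinning : keep every ``thinning``-th sweep after burn-in.
    n_samples : retained draws per chain (S).
    n_chains : independent replicate chains, pooled afterwards.
    seed : master seed; per-chain child seeds are spawned deterministically.
    prior_only : replace the likelihood by a constant (samples the bare CRP).
    init_with_likelihood : sequential initialization weighted by the predictive
        likelihood (the default) or by the CRP prior alone.
    random_scan : reseat items in a fresh seeded permutation each sweep
        instead of ascending index order.
    """

    alpha: float = 1.0
    beta: float = 1.0
    burn_in: int = 500
    thinning: int = 160
    n_samples: int = 2048
    n_chains: int = 2
    seed: int = 0
    prior_only: bool = False
    init_with_likelihood: bool = True
    random_scan: bool = False

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        if self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")
        if self.thinning < 1:
            raise ValueError("thinning must be a positive integer")
        if self.n_samples < 1:
            raise ValueError("n_samples must be a positive integer")
        if self.n_chains < 1:
            raise ValueError("n_chains must be a positive integer")


def prior_seating_probs(sizes: Sequence[int], alpha: float) -> np.ndarray:
    """CRP prior probabilities for the next arrival, one per occupied table
    plus a final entry for founding a new table.

    Entry ``k`` is ``n_k / (N + alpha)``; the last entry is
    ``alpha / (N + alpha)`` where ``N = sum(sizes)``.
    """
    sizes = np.asarray(sizes, dtype=float)
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    if sizes.size and sizes.min() <= 0:
        raise ValueError("occupied tables must have size >= 1")
    total = sizes.sum() + alpha
    return np.append(sizes, alpha) / total


def predictive_likelihood(
    obs: Sequence[int],
    category_counts: Sequence[int],
    beta: float = 1.0,
    counts: np.ndarray | None = None,
    size: int = 0,
) -> float:
    """Dirichlet-categorical posterior predictive of one response vector.

    ``counts`` is the cluster's ``D x V_max`` tally of previous responses
    (``None`` or all-zero for an empty cluster, which reduces to the prior
    predictive ``prod_d 1/V_d``).
    """
    category_counts = np.asarray(category_counts, dtype=np.int64)
    obs = validate_observation(obs, category_counts)
    if beta <= 0:
        raise ValueError("beta must be > 0")
    d = category_counts.size
    if counts is None:
        counts = np.zeros((d, int(category_counts.max())))
        size = 0
    counts = np.asarray(counts, dtype=float)
    num = counts[np.arange(d), obs] + beta
    den = size + category_counts * beta
    return float(np.prod(num / den))


class ClusterState:
    """Sufficient statistics of the current seating arrangement.

    Holds per-cluster sizes ``n_k``, per-cluster response tallies
    ``n_{k,d,v}`` and the current table of every item.  Clusters emptied by a
    removal are deleted immediately and ids compacted, so ids always run
    ``0 .. K-1``.
    """

    def __init__(self, data: CategoricalDataset):
        self.data = data
        self.vmax = int(data.category_counts.max())
        self.sizes: np.ndarray = np.zeros(0, dtype=np.int64)
        # counts kept flat as (K, D * V_max) so one fancy index scores a row
        self.counts: np.ndarray = np.zeros((0, data.d * self.vmax))
        self.assignments: np.ndarray = np.full(data.n, -1, dtype=np.int64)
        # (N, D) codes -> flat offsets into a (D * V_max) count row
        self._obs_flat = (np.arange(data.d) * self.vmax)[None, :] + data.responses
        # log prior-predictive of any single observation under the base measure
        self._log_new = -float(np.log(data.category_counts).sum())
        self._uniq_v, self._v_mult = np.unique(data.category_counts, return_counts=True)

    @property
    def n_clusters(self) -> int:
        return int(self.sizes.size)

    @property
    def n_seated(self) -> int:
        return int(self.sizes.sum())

    def partition(self) -> Partition:
        if np.any(self.assignments < 0):
            raise ValueError("not all items are seated")
        return Partition(self.assignments)

    def check_invariants(self) -> None:
        assert np.all(self.sizes >= 1)
        per_dim = self.counts.reshape(self.n_clusters, self.data.d, self.vmax).sum(axis=2)
        assert np.all(per_dim == self.sizes[:, None])

    # -- mutation -------------------------------------------------------------

    def remove_item(self, i: int) -> None:
        k = self.assignments[i]
        if k < 0:
            raise ValueError(f"item {i} is not seated")
        self.assignments[i] = -1
        self.sizes[k] -= 1
        self.counts[k, self._obs_flat[i]] -= 1
        if self.sizes[k] == 0:
            self.sizes = np.delete(self.sizes, k)
            self.counts = np.delete(self.counts, k, axis=0)
            self.assignments[self.assignments > k] -= 1

    def place_item(self, i: int, k: int) -> None:
        """Seat item ``i`` at table ``k`` (``k == n_clusters`` founds a table)."""
        if k == self.n_clusters:
            self.sizes = np.append(self.sizes, 0)
            self.counts = np.vstack([self.counts, np.zeros(self.counts.shape[1])])
        self.assignments[i] = k
        self.sizes[k] += 1
        self.counts[k, self._obs_flat[i]] += 1

    # -- seating law ----------------------------------------------------------

    def seating_log_weights(self, i: int, cfg: SamplerConfig) -> np.ndarray:
        """Unnormalized log seating weights for item ``i`` over the K occupied
        tables plus one new table: ``log n_k + log F_k(o_i)`` and
        ``log alpha + log F_new(o_i)``."""
        log_prior = np.append(np.log(self.sizes.astype(float)), np.log(cfg.alpha))
        if cfg.prior_only:
            return log_prior
        beta = cfg.beta
        num = self.counts[:, self._obs_flat[i]] + beta  # (K, D)
        # denominator sum_d log(n_k + V_d beta), grouped by distinct V_d
        den = np.log(self.sizes[:, None] + self._uniq_v[None, :] * beta) @ self._v_mult
        log_lik = np.log(num).sum(axis=1) - den
        return log_prior + np.append(log_lik, self._log_new)


def seat_item(i: int, state: ClusterState, cfg: SamplerConfig, rng: np.random.Generator) -> int:
    """Draw a table for the (currently unseated) item ``i`` from the collapsed
    conditional and seat it there.  Returns the chosen table id."""
    logw = state.seating_log_weights(i, cfg)
    logw -= logw.max()
    w = np.exp(logw)
    k = int(rng.choice(w.size, p=w / w.sum()))
    state.place_item(i, k)
    return k


def gibbs_sweep(state: ClusterState, cfg: SamplerConfig, rng: np.random.Generator) -> ClusterState:
    """One full sweep: remove and reseat every item once."""
    n = state.data.n
    order = rng.permutation(n) if cfg.random_scan else range(n)
    for i in order:
        state.remove_item(i)
        seat_item(i, state, cfg, rng)
    return state


def initialize_state(data: CategoricalDataset, cfg: SamplerConfig, rng: np.random.Generator) -> ClusterState:
    """Sequentially seat items 0..N-1 into an initially empty restaurant."""
    state = ClusterState(data)
    init_cfg = cfg if cfg.init_with_likelihood else replace(cfg, prior_only=True)
    for i in range(data.n):
        seat_item(i, state, init_cfg, rng)
    return state


@dataclass
class SampleChain:
    """Pooled retained draws from one or more replicate chains."""

    partitions: list[Partition]
    config: SamplerConfig
    chain_ids: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    k_trace: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))

    def by_chain(self, chain: int) -> list[Partition]:
        return [p for p, c in zip(self.partitions, self.chain_ids) if c == chain]

    def cluster_counts(self) -> np.ndarray:
        return self.k_trace

    def save(self, partitions_path, metadata_path=None) -> None:
        """Write one JSON-array partition per line plus a metadata JSON
        (config, chain ids, cluster-count trace)."""
        import json
        from dataclasses import asdict
        from pathlib import Path

        partitions_path = Path(partitions_path)
        with open(partitions_path, "w") as fh:
            fh.writelines(p.to_json() + "\n" for p in self.partitions)
        if metadata_path is None:
            metadata_path = partitions_path.with_suffix(".meta.json")
        meta = {
            "config": asdict(self.config),
            "chain_ids": self.chain_ids.tolist(),
            "k_trace": self.k_trace.tolist(),
        }
        Path(metadata_path).write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, partitions_path, metadata_path=None) -> "SampleChain":
        import json
        from pathlib import Path

        partitions_path = Path(partitions_path)
        if metadata_path is None:
            metadata_path = partitions_path.with_suffix(".meta.json")
        meta = json.loads(Path(metadata_path).read_text())
        partitions = [
            Partition(json.loads(line))
            for line in partitions_path.read_text().splitlines()
            if line.strip()
        ]
        return cls(
            partitions=partitions,
            config=SamplerConfig(**meta["config"]),
            chain_ids=np.asarray(meta["chain_ids"], dtype=np.int64),
            k_trace=np.asarray(meta["k_trace"], dtype=np.int64),
        )


def run_chain(data: CategoricalDataset, cfg: SamplerConfig) -> SampleChain:
    """Run ``cfg.n_chains`` independent chains and pool their retained draws.

    Each chain: sequential initialization, ``burn_in`` discarded sweeps, then
    ``thinning * n_samples`` sweeps keeping every ``thinning``-th partition.
    Fully reproducible given ``cfg.seed``.
    """
    partitions: list[Partition] = []
    chain_ids: list[int] = []
    k_trace: list[int] = []
    children = np.random.SeedSequence(cfg.seed).spawn(cfg.n_chains)
    for c, child in enumerate(children):
        rng = np.random.default_rng(child)
        state = initialize_state(data, cfg, rng)
        for _ in range(cfg.burn_in):
            gibbs_sweep(state, cfg, rng)
        for _ in range(cfg.n_samples):
            for _ in range(cfg.thinning):
                gibbs_sweep(state, cfg, rng)
            partitions.append(state.partition())
            chain_ids.append(c)
            k_trace.append(state.n_clusters)
    return SampleChain(
        partitions=partitions,
        config=cfg,
        chain_ids=np.asarray(chain_ids, dtype=np.int64),
        k_trace=np.asarray(k_trace, dtype=np.int64),
    )
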