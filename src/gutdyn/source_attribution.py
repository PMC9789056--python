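"""Bayesian source attribution of a later sample to an earlier one.

For each ordered same-individual pair (earlier "source" sample ->
later "sink" sample) we estimate the fraction of the sink community
attributable to the source versus an Unknown component, with the
collapsed Gibbs sampler of the SourceTracker class of models:

Each sink read i carries a taxon ``t_i`` and a latent environment
assignment ``z_i`` in {source_1..source_V, Unknown}.  The conditional
for one read given all others is

    P(z_i = v)  proportional to  P(t_i | v) * (n_v^{-i} + beta)

where ``n_v^{-i}`` counts sink reads currently assigned to v (a
Dirichlet(beta) prior on the mixing proportions); for a known source,
P(t | v) = (m_vt + alpha1) / (depth_v + alpha1 * T) from the fixed
source counts; for the Unknown environment the taxon distribution is
learned from the reads currently assigned to it,
P(t | Unknown) = (u_t + alpha2 * n) / (n_Unknown + alpha2 * n * T),
with the prior scaled by the sink depth n so that the Unknown stays
smooth until the data force structure on it.  The reported mixing
proportions are posterior means over draws from several independently
initialized restarts.

Aggregating the known-source proportion over pairs binned by sampling
interval (M1/Y1/Y2/Y3) yields the community fraction retained over
1 month, 2-12 months, 13-24 months, and >24 months.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core_io import (
    DEFAULT_GROUP_BOUNDS,
    AbundanceTable,
    SampleMetadata,
    metadata_by_sample,
)
from .dissimilarity import assign_group

_SEED_MOD = 2**31 - 1


@dataclass
class GibbsSettings:
    """Hyperparameters and chain settings for the collapsed Gibbs sampler.

    alpha1/alpha2/beta defaults follow the published defaults of the
    SourceTracker method; ``rarefaction_depth=None`` rarefies sink and
    sources to their common minimum depth capped at 1000 (runtime
    control without depth artifacts).
    """

    alpha1: float = 0.001
    alpha2: float = 0.1
    beta: float = 10.0
    burn_in: int = 100
    restarts: int = 10
    draws_per_restart: int = 1
    delay: int = 1
    rarefaction_depth: int | None = None

    def __post_init__(self) -> None:
        for name in ("alpha1", "alpha2", "beta", "burn_in", "restarts",
                     "draws_per_restart", "delay"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SourceEstimate:
    """Posterior mixing proportions of one sink over sources + Unknown."""

    sink_id: str
    source_ids: list[str]  # known sources then "Unknown"
    proportions: np.ndarray
    proportions_sd: np.ndarray
    settings: GibbsSettings
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        s = float(np.sum(self.proportions))
        if abs(s - 1.0) > 1e-9 or np.any(self.proportions < 0):
            raise ValueError("proportions must be a simplex vector")

    def proportion_of(self, source_id: str) -> float:
        return float(self.proportions[self.source_ids.index(source_id)])


# ---------------------------------------------------------------------------
# Gibbs kernel (numba-compiled when available)
# ---------------------------------------------------------------------------


def _gibbs_chain_py(read_tax, src_prob, alpha2, beta, burn_in, n_draws,
                    delay, seed, out):
    # One restart: random init, burn-in sweeps, thinned proportion draws.
    np.random.seed(seed)
    n = read_tax.shape[0]
    V = src_prob.shape[0]
    T = src_prob.shape[1]
    nv = np.zeros(V + 1, np.int64)
    u = np.zeros(T, np.int64)
    z = np.empty(n, np.int64)
    for i in range(n):
        v = np.random.randint(0, V + 1)
        z[i] = v
        nv[v] += 1
        if v == V:
            u[read_tax[i]] += 1
    order = np.arange(n)
    pr = np.empty(V + 1)
    a2n = alpha2 * n  # unknown prior scales with sink depth
    total_iters = burn_in + (n_draws - 1) * delay + 1
    draw_i = 0
    for it in range(total_iters):
        for i in range(n - 1, 0, -1):  # Fisher-Yates resweep order
            j = np.random.randint(0, i + 1)
            tmp = order[i]
            order[i] = order[j]
            order[j] = tmp
        for oi in range(n):
            i = order[oi]
            t = read_tax[i]
            v = z[i]
            nv[v] -= 1
            if v == V:
                u[t] -= 1
            tot = 0.0
            for v2 in range(V):
                pr[v2] = src_prob[v2, t] * (nv[v2] + beta)
                tot += pr[v2]
            pr[V] = ((u[t] + a2n) / (nv[V] + a2n * T)) * (nv[V] + beta)
            tot += pr[V]
            r = np.random.random() * tot
            vnew = 0
            acc = pr[0]
            while acc < r and vnew < V:
                vnew += 1
                acc += pr[vnew]
            z[i] = vnew
            nv[vnew] += 1
            if vnew == V:
                u[t] += 1
        if it >= burn_in and (it - burn_in) % delay == 0 and draw_i < n_draws:
            for v2 in range(V + 1):
                out[draw_i, v2] = nv[v2] / n
            draw_i += 1


try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _gibbs_chain = njit(cache=False)(_gibbs_chain_py)
except ImportError:  # pragma: no cover
    _gibbs_chain = _gibbs_chain_py


def rarefy(counts: np.ndarray, depth: int, rng: np.random.Generator) -> np.ndarray:
    """Subsample a counts vector without replacement to ``depth`` reads."""
    counts = np.asarray(counts)
    total = int(counts.sum())
    if depth > total:
        raise ValueError(
            f"rarefaction depth {depth} exceeds available counts {total}"
        )
    if depth == total:
        return counts.astype(np.int64)
    return rng.multivariate_hypergeometric(counts.astype(np.int64), depth)


def gibbs_source_proportions(
    sink: np.ndarray,
    sources: np.ndarray,
    settings: GibbsSettings | None = None,
    rng_seed: int | None = None,
    sink_id: str = "sink",
    source_ids: Sequence[str] | None = None,
) -> SourceEstimate:
    """Estimate a sink's mixing proportions over known sources + Unknown.

    ``sink`` is a taxon counts vector; ``sources`` a (V, T) matrix of
    source counts (one row per known source).  Identical seeds give
    identical estimates.
    """
    settings = settings or GibbsSettings()
    sink = np.asarray(sink)
    sources = np.atleast_2d(np.asarray(sources))
    if sink.sum() <= 0:
        raise ValueError("sink has zero depth")
    if sources.shape[0] < 1 or sources.shape[1] != sink.shape[0]:
        raise ValueError("sources must be a (n_sources, n_taxa) counts matrix")
    V, T = sources.shape
    if source_ids is None:
        source_ids = [f"source{v+1}" for v in range(V)]
    source_ids = list(source_ids) + ["Unknown"]

    ss = np.random.SeedSequence(rng_seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    depth = settings.rarefaction_depth
    if depth is None:
        depth = int(min(sink.sum(), sources.sum(axis=1).min(), 1000))
    sink_r = rarefy(sink, depth, rng)
    sources_r = np.stack([rarefy(sources[v], depth, rng) for v in range(V)])

    # fixed source taxon probabilities, alpha1-smoothed
    src_prob = (sources_r + settings.alpha1) / (
        sources_r.sum(axis=1, keepdims=True) + settings.alpha1 * T
    )
    read_tax = np.repeat(np.arange(T, dtype=np.int64), sink_r)

    chain_seeds = np.random.SeedSequence(rng_seed).generate_state(
        settings.restarts + 1
    )[1:] % _SEED_MOD
    draws = np.empty((settings.restarts, settings.draws_per_restart, V + 1))
    for r in range(settings.restarts):
        out = np.empty((settings.draws_per_restart, V + 1))
        _gibbs_chain(
            read_tax,
            np.ascontiguousarray(src_prob, dtype=np.float64),
            float(settings.alpha2),
            float(settings.beta),
            int(settings.burn_in),
            int(settings.draws_per_restart),
            int(settings.delay),
            int(chain_seeds[r]),
            out,
        )
        draws[r] = out
    flat = draws.reshape(-1, V + 1)
    props = flat.mean(axis=0)
    props = props / props.sum()
    return SourceEstimate(
        sink_id=sink_id,
        source_ids=source_ids,
        proportions=props,
        proportions_sd=flat.std(axis=0),
        settings=settings,
        rng_seed=rng_seed,
    )


# ---------------------------------------------------------------------------
# Cohort-level aggregation
# ---------------------------------------------------------------------------


def retained_fraction_by_interval(
    table: AbundanceTable,
    metadata: Iterable[SampleMetadata],
    settings: GibbsSettings | None = None,
    group_bounds: dict[str, tuple[int, int]] = DEFAULT_GROUP_BOUNDS,
    rng_seed: int | None = None,
) -> tuple[dict[str, float], pd.DataFrame]:
    """Mean retained (known-source) proportion per interval group.

    For every ordered same-individual pair the earlier sample is the
    sole known source and the later sample the sink; the pair's shared
    proportion is the source's posterior mixing weight.  Returns the
    per-group means and the per-pair long table.
    """
    if not table.counts:
        raise ValueError("source attribution requires a counts table")
    settings = settings or GibbsSettings()
    meta = metadata_by_sample(metadata)
    missing = [s for s in table.samples if s not in meta]
    if missing:
        raise ValueError(f"samples with no metadata: {missing}")

    by_ind: dict[str, list[str]] = {}
    for s in table.samples:
        by_ind.setdefault(meta[s].individual_id, []).append(s)

    pairs: list[tuple[str, str, str, int, str]] = []
    for ind, samp in by_ind.items():
        samp = sorted(samp, key=lambda s: meta[s].month_index)
        for i in range(len(samp)):
            for j in range(i + 1, len(samp)):
                interval = meta[samp[j]].month_index - meta[samp[i]].month_index
                group = assign_group(interval, group_bounds)
                if group is None:
                    continue
                pairs.append((ind, samp[i], samp[j], interval, group))

    col = {s: k for k, s in enumerate(table.samples)}
    seeds = np.random.SeedSequence(rng_seed).generate_state(
        len(pairs) + 1
    )[1:] % _SEED_MOD
    rows = []
    for k, (ind, src, snk, interval, group) in enumerate(pairs):
        est = gibbs_source_proportions(
            table.values[:, col[snk]].astype(np.int64),
            table.values[:, col[src]].astype(np.int64)[None, :],
            settings=settings,
            rng_seed=int(seeds[k]),
            sink_id=snk,
            source_ids=[src],
        )
        rows.append(
            dict(
                individual_id=ind,
                source=src,
                sink=snk,
                interval_months=interval,
                group=group,
                shared_proportion=est.proportion_of(src),
                unknown_proportion=est.proportion_of("Unknown"),
                sd=float(est.proportions_sd[0]),
            )
        )
    df = pd.DataFrame(rows)
    means = (
        df.groupby("group")["shared_proportion"].mean().to_dict()
        if len(df)
        else {}
    )
    return means, df
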