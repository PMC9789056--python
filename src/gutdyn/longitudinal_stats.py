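"""Inference on dependent pairwise dissimilarities.

Pairwise Bray-Curtis values within an individual share samples, so they
are not independent observations and the tabulated null of the Wilcoxon
rank-sum test does not apply.  The remedy implemented here permutes the
*time labels* of an individual's samples: under the null hypothesis that
community composition does not depend on sampling time, the month
indices are exchangeable across that individual's samples, so shuffling
them — while holding the dissimilarity matrix fixed — and re-binning the
pairs by the permuted intervals yields a valid null distribution for
the rank-sum statistic of any interval-group contrast.

The Mantel test (matrix correlation under row/column permutation) used
for the nine-covariate association screen lives here too.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import rankdata

from .core_io import DEFAULT_GROUP_BOUNDS, SampleMetadata, metadata_by_sample
from .dissimilarity import DistanceMatrix, assign_group


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> float:
    """Rank-sum W of group ``x`` in the pooled sample, with midranks for ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    ranks = rankdata(np.concatenate([x, y]))
    return float(ranks[: x.size].sum())


@dataclass
class PermTestResult:
    """Permuted-time-point Wilcoxon test for one interval-group contrast.

    ``observed_W`` is the rank-sum of the *later* interval group, so
    large values mean the longer-interval pairs are more dissimilar and
    the one-sided p is the upper tail of the permutation null.
    """

    individual_id: str  # or "pooled"
    group_pair: tuple[str, str]
    observed_W: float
    null_W: np.ndarray
    critical_values: dict[int, float]  # percentile -> W
    p_value: float
    reps: int
    rng_seed: int | None = None
    alternative: str = "greater"


class _IndividualPairs:
    """Per-individual pair indexing reused across permutation replicates."""

    def __init__(self, sample_idx: list[int], months: np.ndarray):
        self.idx = np.asarray(sample_idx)
        self.months = np.asarray(months)
        n = len(sample_idx)
        iu, ju = np.triu_indices(n, k=1)
        self.iu, self.ju = iu, ju

    def intervals(self, months: np.ndarray) -> np.ndarray:
        return np.abs(months[self.iu] - months[self.ju])


def _group_masks(
    intervals: np.ndarray,
    group_pair: tuple[str, str],
    bounds: dict[str, tuple[int, int]],
) -> tuple[np.ndarray, np.ndarray]:
    lo_a, hi_a = bounds[group_pair[0]]
    lo_b, hi_b = bounds[group_pair[1]]
    return (
        (intervals >= lo_a) & (intervals <= hi_a),
        (intervals >= lo_b) & (intervals <= hi_b),
    )


def permute_timepoint_test(
    dm: DistanceMatrix,
    metadata: Iterable[SampleMetadata],
    individual_id: str | None,
    group_pair: tuple[str, str] = ("M1", "Y3"),
    reps: int = 1000,
    rng_seed: int | None = None,
    group_bounds: dict[str, tuple[int, int]] = DEFAULT_GROUP_BOUNDS,
    alternative: str = "greater",
) -> PermTestResult:
    """Permutation-Wilcoxon test that later-interval pairs are more dissimilar.

    ``individual_id=None`` runs the pooled test: month labels are
    permuted independently within every individual and the contrast
    pools pairs across individuals.  Replicates in which either group
    comes up empty are discarded and redrawn, up to ``10 * reps``
    attempts.  p uses the add-one estimator, so p > 0 always.
    """
    if alternative not in ("greater", "less", "two-sided"):
        raise ValueError(f"unknown alternative: {alternative!r}")
    meta = metadata_by_sample(metadata)
    missing = [s for s in dm.sample_ids if s not in meta]
    if missing:
        raise ValueError(f"samples with no metadata: {missing}")

    groups: dict[str, list[int]] = {}
    for j, s in enumerate(dm.sample_ids):
        m = meta[s]
        if individual_id is None or m.individual_id == individual_id:
            groups.setdefault(m.individual_id, []).append(j)
    if not groups:
        raise ValueError(f"no samples for individual {individual_id!r}")

    blocks = [
        _IndividualPairs(cols, np.array([meta[dm.sample_ids[j]].month_index
                                         for j in cols]))
        for cols in groups.values()
    ]
    # pair dissimilarities, fixed across permutations
    dvals = [dm.values[b.idx[b.iu], b.idx[b.ju]] for b in blocks]

    def statistic(months_per_block: list[np.ndarray]) -> float | None:
        early: list[np.ndarray] = []
        late: list[np.ndarray] = []
        for b, d, months in zip(blocks, dvals, months_per_block):
            iv = b.intervals(months)
            m_early, m_late = _group_masks(iv, group_pair, group_bounds)
            early.append(d[m_early])
            late.append(d[m_late])
        x = np.concatenate(late)
        y = np.concatenate(early)
        if x.size == 0 or y.size == 0:
            return None
        return wilcoxon_rank_sum(x, y)

    observed = statistic([b.months for b in blocks])
    if observed is None:
        raise ValueError(
            f"individual {individual_id!r} has no pairs in one of "
            f"{group_pair} under the observed schedule"
        )

    rng = np.random.default_rng(rng_seed)
    null: list[float] = []
    attempts = 0
    while len(null) < reps and attempts < 10 * reps:
        attempts += 1
        w = statistic([rng.permutation(b.months) for b in blocks])
        if w is not None:
            null.append(w)
    if len(null) < 2:
        raise ValueError(
            f"only {len(null)} of {attempts} permutations produced both "
            f"groups for {group_pair}; schedule too sparse for this contrast"
        )
    null_arr = np.asarray(null)
    n_valid = len(null_arr)
    p_hi = (1 + int(np.sum(null_arr >= observed))) / (1 + n_valid)
    p_lo = (1 + int(np.sum(null_arr <= observed))) / (1 + n_valid)
    if alternative == "greater":
        p = p_hi
    elif alternative == "less":
        p = p_lo
    else:
        p = min(1.0, 2 * min(p_hi, p_lo))
    return PermTestResult(
        individual_id=individual_id if individual_id is not None else "pooled",
        group_pair=tuple(group_pair),
        observed_W=observed,
        null_W=null_arr,
        critical_values={
            q: float(np.percentile(null_arr, q)) for q in (90, 95, 99)
        },
        p_value=float(p),
        reps=n_valid,
        rng_seed=rng_seed,
        alternative=alternative,
    )


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------


@dataclass
class MantelResult:
    factor_name: str
    r: float
    p_value: float
    reps: int
    undefined: bool = False
    rng_seed: int | None = None


def factor_distance_matrix(
    values: Sequence, kind: str
) -> np.ndarray:
    """Square factor-distance matrix: |difference| for numeric factors,
    0/1 mismatch for categorical ones."""
    if kind == "numeric":
        v = np.asarray([float(x) for x in values])
        return np.abs(v[:, None] - v[None, :])
    if kind == "categorical":
        v = np.asarray([str(x) for x in values], dtype=object)
        return (v[:, None] != v[None, :]).astype(float)
    raise ValueError(f"factor_kind must be numeric or categorical, got {kind!r}")


def mantel_test(
    dm_microbiome: DistanceMatrix,
    factor_values: Sequence,
    factor_kind: str = "numeric",
    reps: int = 999,
    rng_seed: int | None = None,
    factor_name: str = "factor",
    method: str = "pearson",
    exact: bool = False,
) -> MantelResult:
    """Mantel association between community distances and one covariate.

    r is the Pearson (or Spearman) correlation of the vectorized upper
    triangles; p is the upper-tail proportion over ``reps`` random row/
    column relabelings of the factor matrix (or all n! relabelings when
    ``exact=True``, feasible for tiny n).  A constant factor yields an
    undefined result rather than a division error.
    """
    n = len(dm_microbiome.sample_ids)
    if len(factor_values) != n:
        raise ValueError("factor must be defined for every sample")
    fmat = factor_distance_matrix(factor_values, factor_kind)
    iu, ju = np.triu_indices(n, k=1)
    d = dm_microbiome.values[iu, ju]
    f = fmat[iu, ju]
    if method == "spearman":
        d = rankdata(d)

    def corr(fv: np.ndarray) -> float:
        if method == "spearman":
            fv = rankdata(fv)
        sd_d, sd_f = d.std(), fv.std()
        if sd_d == 0 or sd_f == 0:
            return math.nan
        return float(np.corrcoef(d, fv)[0, 1])

    r_obs = corr(f)
    if math.isnan(r_obs):
        return MantelResult(factor_name, math.nan, math.nan, 0,
                            undefined=True, rng_seed=rng_seed)

    if exact:
        perms = [np.asarray(p) for p in itertools.permutations(range(n))]
    else:
        rng = np.random.default_rng(rng_seed)
        perms = [rng.permutation(n) for _ in range(reps)]
    null = np.array([corr(fmat[p[iu], p[ju]]) for p in perms])
    if exact:
        # identity is among the n! relabelings: exact p, no add-one
        p_val = float(np.mean(null >= r_obs - 1e-12))
    else:
        p_val = (1 + int(np.sum(null >= r_obs))) / (1 + len(null))
    return MantelResult(
        factor_name=factor_name,
        r=r_obs,
        p_value=float(p_val),
        reps=len(null),
        rng_seed=rng_seed,
    )
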