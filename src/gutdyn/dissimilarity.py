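"""Bray-Curtis dissimilarity and interval-group pair bookkeeping.

Every unordered pair of samples is compared once.  Same-individual
pairs are binned by sampling interval in calendar months — M1 (one
month apart), Y1 (2-12), Y2 (13-24), Y3 (>24) — and pairs of samples
from different individuals form group D.  Same-individual pairs taken
in the same calendar month (interval 0) are excluded: the short-interval
group is defined as *consecutive* months.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .core_io import (
    DEFAULT_GROUP_BOUNDS,
    AbundanceTable,
    SampleMetadata,
    metadata_by_sample,
)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarities with sample labels."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{n} sample ids"
            )
        if np.any(np.abs(self.values - self.values.T) > 1e-12):
            raise ValueError("distance matrix is not symmetric within 1e-12")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix diagonal must be exactly 0")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        i = self.sample_ids.index(a)
        j = self.sample_ids.index(b)
        return float(self.values[i, j])

    def condensed(self) -> np.ndarray:
        """Upper triangle in scipy condensed order."""
        return squareform(self.values, checks=False)

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, index=self.sample_ids,
                          columns=self.sample_ids)
        df.index.name = "sample"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls([str(s) for s in df.columns], df.to_numpy(dtype=float))


def bray_curtis(table: AbundanceTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity between samples.

    BC(u, v) = sum_i |u_i - v_i| / sum_i (u_i + v_i), computed on a
    relative-abundance table (reject counts: convert first so that
    sequencing depth never masquerades as community difference).
    """
    if table.counts:
        raise ValueError(
            "bray_curtis requires relative abundance; call to_relative() first"
        )
    if len(table.samples) < 2:
        raise ValueError("need at least 2 samples")
    condensed = pdist(table.values.T, metric="braycurtis")
    dm = squareform(condensed)
    np.fill_diagonal(dm, 0.0)
    return DistanceMatrix(list(table.samples), dm)


@dataclass(frozen=True)
class PairComparison:
    """One unordered sample pair with its interval group and dissimilarity."""

    sample_a: str
    sample_b: str
    individual_a: str
    individual_b: str
    interval_months: int
    group: str  # M1 | Y1 | Y2 | Y3 | D
    dissimilarity: float


def assign_group(
    interval_months: int,
    group_bounds: dict[str, tuple[int, int]] = DEFAULT_GROUP_BOUNDS,
) -> str | None:
    """Interval-group label for a same-individual pair, or None (excluded)."""
    for g, (lo, hi) in group_bounds.items():
        if lo <= interval_months <= hi:
            return g
    return None


def enumerate_pairs(
    dm: DistanceMatrix,
    metadata: Iterable[SampleMetadata],
    group_bounds: dict[str, tuple[int, int]] = DEFAULT_GROUP_BOUNDS,
) -> list[PairComparison]:
    """All unordered sample pairs, labelled M1/Y1/Y2/Y3 (same individual,
    by calendar-month interval) or D (different individuals).

    Same-individual interval-0 pairs are dropped.
    """
    meta = metadata_by_sample(metadata)
    missing = [s for s in dm.sample_ids if s not in meta]
    if missing:
        raise ValueError(f"samples with no metadata: {missing}")
    out: list[PairComparison] = []
    ids = dm.sample_ids
    for i in range(len(ids)):
        mi = meta[ids[i]]
        for j in range(i + 1, len(ids)):
            mj = meta[ids[j]]
            interval = abs(mi.month_index - mj.month_index)
            if mi.individual_id == mj.individual_id:
                group = assign_group(interval, group_bounds)
                if group is None:
                    continue
            else:
                group = "D"
            out.append(
                PairComparison(
                    sample_a=ids[i],
                    sample_b=ids[j],
                    individual_a=mi.individual_id,
                    individual_b=mj.individual_id,
                    interval_months=interval,
                    group=group,
                    dissimilarity=float(dm.values[i, j]),
                )
            )
    return out


def group_values(pairs: Iterable[PairComparison]) -> dict[str, np.ndarray]:
    """Dissimilarities per interval group."""
    acc: dict[str, list[float]] = {}
    for p in pairs:
        acc.setdefault(p.group, []).append(p.dissimilarity)
    return {g: np.asarray(v) for g, v in acc.items()}


def pairs_to_frame(pairs: Sequence[PairComparison]) -> pd.DataFrame:
    return pd.DataFrame([p.__dict__ for p in pairs])
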