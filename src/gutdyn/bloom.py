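"""Short-term bloom detection.

A sample is a short-term bloom for a taxon when that taxon's relative
abundance in the sample exceeds ``fold_threshold`` (default 5) times the
taxon's mean relative abundance over *all* of the same individual's
samples.  The mean includes the candidate sample itself and counts
zeros; the comparison is strictly greater, so a taxon sitting exactly at
the threshold, or one that is absent from every sample of an individual
(mean 0), never yields a call.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core_io import AbundanceTable, SampleMetadata, metadata_by_sample


@dataclass(frozen=True)
class BloomCall:
    """One (sample, taxon) exceeding the fold rule for its individual."""

    individual_id: str
    sample_id: str
    taxon: str
    abundance: float
    individual_mean: float
    fold: float


@dataclass
class BloomSummary:
    """Cohort-level bloom bookkeeping at one taxonomic level."""

    level: str
    n_samples_total: int
    n_samples_with_bloom: int
    fraction_samples_with_bloom: float
    n_taxa_blooming: int
    per_taxon_by_individual: pd.DataFrame  # taxa x individuals call counts


def detect_blooms(
    table: AbundanceTable,
    metadata: Iterable[SampleMetadata],
    fold_threshold: float = 5.0,
    exclude_self: bool = False,
) -> list[BloomCall]:
    """Find every (sample, taxon) whose abundance is > fold_threshold x
    the taxon's mean across the individual's samples.

    ``exclude_self=True`` switches to a leave-one-out mean (the candidate
    sample's own value removed); the default inclusive mean is the
    deterministic single-pass reading of the rule.
    """
    if table.counts:
        raise ValueError("detect_blooms requires a relative-abundance table")
    meta = metadata_by_sample(metadata)
    missing = [s for s in table.samples if s not in meta]
    if missing:
        raise ValueError(f"samples with no metadata: {missing}")

    by_ind: dict[str, list[int]] = {}
    for j, s in enumerate(table.samples):
        by_ind.setdefault(meta[s].individual_id, []).append(j)

    calls: list[BloomCall] = []
    for ind, cols in by_ind.items():
        sub = table.values[:, cols]  # taxa x this individual's samples
        n = sub.shape[1]
        mean = sub.mean(axis=1)
        for k, j in enumerate(cols):
            if exclude_self:
                if n < 2:
                    continue
                ref = (mean * n - sub[:, k]) / (n - 1)
            else:
                ref = mean
            hot = np.where((ref > 0) & (sub[:, k] > fold_threshold * ref))[0]
            for t in hot:
                calls.append(
                    BloomCall(
                        individual_id=ind,
                        sample_id=table.samples[j],
                        taxon=table.taxa[t],
                        abundance=float(sub[t, k]),
                        individual_mean=float(ref[t]),
                        fold=float(sub[t, k] / ref[t]),
                    )
                )
    calls.sort(key=lambda c: (c.individual_id, c.sample_id, c.taxon))
    return calls


def summarize_blooms(
    calls: Sequence[BloomCall],
    metadata: Iterable[SampleMetadata],
    level: str,
) -> BloomSummary:
    """Count bloom samples and blooming taxa.

    A sample counts once toward ``n_samples_with_bloom`` however many of
    its taxa bloom; the per-taxon-by-individual matrix counts every call.
    """
    metadata = list(metadata)
    n_total = len(metadata)
    bloom_samples = {c.sample_id for c in calls}
    taxa = sorted({c.taxon for c in calls})
    individuals = sorted({m.individual_id for m in metadata})
    counts = pd.DataFrame(0, index=taxa, columns=individuals, dtype=int)
    for c in calls:
        counts.loc[c.taxon, c.individual_id] += 1
    return BloomSummary(
        level=level,
        n_samples_total=n_total,
        n_samples_with_bloom=len(bloom_samples),
        fraction_samples_with_bloom=(
            len(bloom_samples) / n_total if n_total else 0.0
        ),
        n_taxa_blooming=len(taxa),
        per_taxon_by_individual=counts,
    )


def calls_to_frame(calls: Sequence[BloomCall]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in calls])


def itol_annotation(summary: BloomSummary) -> pd.DataFrame:
    """Per-genus, per-individual bloom-count matrix plus totals, in a
    layout suitable for external taxonomy-tree annotation tools."""
    df = summary.per_taxon_by_individual.copy()
    df.insert(0, "total_blooms", df.sum(axis=1))
    df.index.name = "taxon"
    return df
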