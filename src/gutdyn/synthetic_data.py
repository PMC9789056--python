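"""Synthetic longitudinal gut-community cohorts with known ground truth.

The generator emulates the statistical structure the downstream
analysis assumes, so that every stage is testable without any external
download:

* individual-specific baseline compositions (log-abundance offsets of
  spread ``baseline_sd`` around cohort-level taxon means),
* slow compositional drift — a Gaussian random walk on latent
  log-abundance with per-month step ``drift_sd``, so dissimilarity
  between two samples of the same individual grows with their interval,
* sporadic transient taxon blooms (one uniformly chosen taxon
  multiplied ``bloom_fold``-fold in a sample, pre-closure, with
  probability ``bloom_prob``; blooms do not feed back into the latent
  state),
* gradual community turnover: each month a ``retention_decay`` fraction
  of the composition (per month elapsed) is replaced by a fresh sparse
  random pool, so the fraction attributable to an earlier sample decays
  as ``(1 - retention_decay)^interval``,
* multinomial sequencing noise at ``seq_depth`` reads per sample.

The default cohort mirrors a 7-individual, 44-calendar-month monthly
sampling design with 37 candidate time points and 15-31 samples per
individual.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import (
    COVARIATE_NAMES,
    AbundanceTable,
    SampleMetadata,
    month_index,
    validate_metadata,
)

#: Oct 2016 .. May 2020 inclusive: the 44-calendar-month study window.
STUDY_WINDOW = (month_index(2016, 10), month_index(2020, 5))


@dataclass
class SimConfig:
    """Knobs of the cohort generator (see module docstring for the model)."""

    n_individuals: int = 7
    n_taxa: int = 60
    months: list[list[int]] | None = None  # per-individual schedules
    n_timepoints: int = 37       # candidate months drawn from the window
    samples_per_individual: tuple[int, int] = (15, 31)
    baseline_sd: float = 1.0
    taxon_sd: float = 2.0        # cross-taxon spread of cohort log-means
    drift_sd: float = 0.15       # random-walk step per month, log scale
    bloom_prob: float = 0.1
    bloom_fold: float = 50.0
    retention_decay: float = 0.02  # fraction replaced per month
    seq_depth: int = 30000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.bloom_prob <= 1:
            raise ValueError("bloom_prob must be in [0,1]")
        if not 0 <= self.retention_decay <= 1:
            raise ValueError("retention_decay must be in [0,1]")
        if self.seq_depth < 1:
            raise ValueError("seq_depth must be >= 1")
        if self.drift_sd < 0 or self.baseline_sd < 0:
            raise ValueError("standard deviations must be non-negative")


@dataclass
class BloomEvent:
    sample_id: str
    taxon: str
    fold: float


@dataclass
class SimTruth:
    """Ground truth for parameter-recovery tests."""

    blooms: list[BloomEvent]
    retention_decay: float
    latent: dict[str, np.ndarray]  # sample_id -> pre-noise composition

    def expected_retained(self, interval_months: int) -> float:
        return (1.0 - self.retention_decay) ** interval_months

    def validate(self, table: AbundanceTable) -> None:
        taxa = set(table.taxa)
        samples = set(table.samples)
        for b in self.blooms:
            if b.sample_id not in samples or b.taxon not in taxa:
                raise ValueError(f"bloom references unknown sample/taxon: {b}")


def _default_schedules(cfg: SimConfig, rng: np.random.Generator) -> list[list[int]]:
    lo, hi = STUDY_WINDOW
    window = np.arange(lo, hi + 1)
    n_tp = min(cfg.n_timepoints, window.size)
    candidates = np.sort(rng.choice(window, size=n_tp, replace=False))
    schedules = []
    lo_n, hi_n = cfg.samples_per_individual
    for _ in range(cfg.n_individuals):
        n_i = int(rng.integers(lo_n, min(hi_n, n_tp) + 1))
        months = np.sort(rng.choice(candidates, size=n_i, replace=False))
        schedules.append([int(m) for m in months])
    return schedules


def simulate_cohort(
    config: SimConfig | None = None,
) -> tuple[AbundanceTable, list[SampleMetadata], SimTruth]:
    """Simulate a longitudinal cohort; identical seeds give identical output.

    Returns a genus-level counts table (columns sum to ``seq_depth``
    exactly), per-sample metadata, and the injected ground truth.
    """
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.rng_seed)
    schedules = cfg.months if cfg.months is not None else _default_schedules(cfg, rng)
    if len(schedules) == 0 or any(len(s) == 0 for s in schedules):
        raise ValueError("every individual needs a non-empty month list")

    n_ind = len(schedules)
    T = cfg.n_taxa
    taxa = [f"g{t+1:03d}" for t in range(T)]
    taxon_mean = rng.normal(0.0, cfg.taxon_sd, size=T)

    # map months to time-point labels across the union of all schedules
    all_months = sorted({m for s in schedules for m in s})
    tp_label = {m: f"T{k+1}" for k, m in enumerate(all_months)}

    samples: list[str] = []
    metadata: list[SampleMetadata] = []
    columns: list[np.ndarray] = []
    blooms: list[BloomEvent] = []
    latent: dict[str, np.ndarray] = {}

    for i in range(n_ind):
        ind = f"P{i+1}"
        months = sorted(schedules[i])
        if len(set(months)) != len(months):
            raise ValueError(f"duplicate months in schedule of {ind}")
        baseline = taxon_mean + rng.normal(0.0, cfg.baseline_sd, size=T)
        comp = np.exp(baseline)
        comp /= comp.sum()
        prev_month = None
        for m in months:
            if prev_month is not None:
                delta = m - prev_month
                if cfg.drift_sd > 0:
                    step = rng.normal(0.0, cfg.drift_sd * np.sqrt(delta), size=T)
                    comp = comp * np.exp(step)
                    comp /= comp.sum()
                retained = (1.0 - cfg.retention_decay) ** delta
                if retained < 1.0:
                    fresh = rng.dirichlet(np.full(T, 0.2))
                    comp = retained * comp + (1.0 - retained) * fresh
            prev_month = m
            sid = f"{ind}_{tp_label[m]}"
            obs = comp.copy()
            if rng.random() < cfg.bloom_prob:
                t = int(rng.integers(T))
                obs[t] *= cfg.bloom_fold
                obs /= obs.sum()
                blooms.append(BloomEvent(sid, taxa[t], cfg.bloom_fold))
            counts = rng.multinomial(cfg.seq_depth, obs)
            samples.append(sid)
            columns.append(counts)
            latent[sid] = obs
            metadata.append(
                SampleMetadata(
                    sample_id=sid,
                    individual_id=ind,
                    month_index=m,
                    timepoint_label=tp_label[m],
                    covariates={},
                )
            )

    table = AbundanceTable(
        "genus", taxa, samples, np.column_stack(columns), counts=True
    )
    truth = SimTruth(blooms=blooms, retention_decay=cfg.retention_decay,
                     latent=latent)
    truth.validate(table)
    return table, validate_metadata(metadata), truth


def simulate_covariates(
    metadata: Sequence[SampleMetadata],
    linked_factor_effect: float = 0.8,
    rng_seed: int | None = None,
    linked_factor: str = "workspace_office",
    n_categories: int = 3,
) -> list[SampleMetadata]:
    """Fill the nine survey covariates.

    One designated factor (default workspace/office) is generated with a
    controllable association to individual identity: with probability
    ``linked_factor_effect`` a sample takes its individual's canonical
    category, otherwise a uniform random one.  All other covariates are
    independent of the community.
    """
    rng = np.random.default_rng(rng_seed)
    individuals = sorted({m.individual_id for m in metadata})
    canon = {ind: f"office{(k % n_categories) + 1}"
             for k, ind in enumerate(individuals)}
    out = []
    for m in metadata:
        cov = dict(m.covariates)
        cov["participant_id"] = m.individual_id
        cov["date"] = m.month_index
        if rng.random() < linked_factor_effect:
            linked_val = canon[m.individual_id]
        else:
            linked_val = f"office{int(rng.integers(n_categories)) + 1}"
        cov[linked_factor] = linked_val
        for name, kind in (
            ("drug_use", "binary"),
            ("yogurt", "binary"),
            ("fruit", "binary"),
            ("travel_abroad", "binary"),
        ):
            if name != linked_factor:
                cov[name] = ["no", "yes"][int(rng.integers(2))]
        if "blood_pressure" != linked_factor:
            cov["blood_pressure"] = float(np.round(rng.normal(120, 10), 1))
        if "blood_sugar" != linked_factor:
            cov["blood_sugar"] = float(np.round(rng.normal(6.0, 1.0), 2))
        out.append(replace(m, covariates=cov))
    return out


def truth_to_frame(truth: SimTruth) -> pd.DataFrame:
    return pd.DataFrame([b.__dict__ for b in truth.blooms])


def write_truth(truth: SimTruth, path: str | Path) -> None:
    truth_to_frame(truth).to_csv(path, sep="\t", index=False)
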