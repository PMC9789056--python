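"""Data model and I/O for longitudinal microbiome profiles.

The package's substrate is a taxon-by-sample abundance table at one
taxonomic level (phylum/genus/species/OTU/ASV), together with per-sample
metadata that records which individual a sample came from and in which
calendar month it was collected.  Time is handled as an absolute month
index (``year*12 + month``) so that sampling intervals are calendar
months even when the time-point schedule has gaps.

Also provided here: the read-level quality filter (trailing <Q20 trim,
length floor) applied to FASTQ input before upstream taxonomic
profiling, and the analysis configuration with every pipeline constant.
"""

from __future__ import annotations

import dataclasses
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

LEVELS = ("phylum", "genus", "species", "otu", "asv")

#: The nine per-sample covariates collected by the monthly survey.
COVARIATE_NAMES = (
    "participant_id",
    "date",
    "workspace_office",
    "drug_use",
    "yogurt",
    "fruit",
    "travel_abroad",
    "blood_pressure",
    "blood_sugar",
)

#: Interval groups for same-individual pairs, in months (lo, hi) inclusive.
DEFAULT_GROUP_BOUNDS: dict[str, tuple[int, int]] = {
    "M1": (1, 1),
    "Y1": (2, 12),
    "Y2": (13, 24),
    "Y3": (25, 10**9),
}


def month_index(year: int, month: int) -> int:
    """Absolute calendar month: ``year*12 + month`` (e.g. 2016-10 -> 24202)."""
    if not 1 <= month <= 12:
        raise ValueError(f"month out of range: {month}")
    return year * 12 + month


_DATE_RE = re.compile(r"^(\d{4})-(\d{1,2})(?:-\d{1,2})?$")


def parse_month(date: str) -> int:
    """Parse an ISO ``YYYY-MM`` (or ``YYYY-MM-DD``) date into a month index."""
    m = _DATE_RE.match(str(date).strip())
    if not m:
        raise ValueError(f"unparseable collection date: {date!r}")
    return month_index(int(m.group(1)), int(m.group(2)))


# ---------------------------------------------------------------------------
# Abundance table
# ---------------------------------------------------------------------------


@dataclass
class AbundanceTable:
    """Taxon x sample abundance matrix at one taxonomic level.

    ``values[i, j]`` is the abundance of ``taxa[i]`` in ``samples[j]``.
    In relative mode every column sums to 1; in counts mode entries are
    non-negative integers (read counts).
    """

    level: str
    taxa: list[str]
    samples: list[str]
    values: np.ndarray
    counts: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.taxa = [str(t) for t in self.taxa]
        self.samples = [str(s) for s in self.samples]
        self.validate()

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"unknown taxonomic level: {self.level!r}")
        if self.values.shape != (len(self.taxa), len(self.samples)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.taxa)} taxa x {len(self.samples)} samples"
            )
        for kind, labels in (("taxon", self.taxa), ("sample", self.samples)):
            seen: set[str] = set()
            for lab in labels:
                if lab in seen:
                    raise ValueError(f"duplicate {kind} label: {lab!r}")
                seen.add(lab)
        if np.any(self.values < 0):
            i, j = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative abundance for taxon {self.taxa[i]!r} "
                f"in sample {self.samples[j]!r}"
            )
        if self.counts:
            if not np.allclose(self.values, np.round(self.values)):
                raise ValueError("counts mode requires integer entries")
        else:
            colsum = self.values.sum(axis=0)
            bad = np.where(np.abs(colsum - 1.0) > 1e-9)[0]
            if bad.size:
                j = bad[0]
                raise ValueError(
                    f"sample {self.samples[j]!r} column sums to "
                    f"{colsum[j]!r}, not 1 (relative mode)"
                )

    # -- conversions ---------------------------------------------------
    def to_relative(self) -> "AbundanceTable":
        """Column-normalize counts to relative abundance (closure)."""
        if not self.counts:
            return self
        colsum = self.values.sum(axis=0)
        zero = np.where(colsum == 0)[0]
        if zero.size:
            raise ValueError(
                f"sample {self.samples[zero[0]]!r} has zero total count"
            )
        return AbundanceTable(
            self.level, list(self.taxa), list(self.samples),
            self.values / colsum, counts=False,
        )

    def subset_samples(self, keep: Sequence[str]) -> "AbundanceTable":
        keep = list(keep)
        idx = {s: j for j, s in enumerate(self.samples)}
        missing = [s for s in keep if s not in idx]
        if missing:
            raise KeyError(f"samples not in table: {missing}")
        cols = [idx[s] for s in keep]
        return AbundanceTable(
            self.level, list(self.taxa), keep, self.values[:, cols],
            counts=self.counts,
        )

    def sample_depths(self) -> np.ndarray:
        return self.values.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.taxa, columns=self.samples)

    # -- I/O -----------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "taxon"
        df.to_csv(path, sep="\t")

    def to_biom_json(self, path: str | Path) -> None:
        """Write as a BIOM 1.0 (JSON, sparse) table."""
        rows, cols = np.nonzero(self.values)
        data = [
            [int(r), int(c), float(self.values[r, c])]
            for r, c in zip(rows, cols)
        ]
        doc = {
            "id": None,
            "format": "Biological Observation Matrix 1.0.0",
            "format_url": "http://biom-format.org",
            "type": "OTU table",
            "generated_by": "gutdyn",
            "date": "",
            "matrix_type": "sparse",
            "matrix_element_type": "int" if self.counts else "float",
            "shape": [len(self.taxa), len(self.samples)],
            "rows": [{"id": t, "metadata": None} for t in self.taxa],
            "columns": [{"id": s, "metadata": None} for s in self.samples],
            "data": data,
            "gutdyn:level": self.level,
            "gutdyn:counts": self.counts,
        }
        Path(path).write_text(json.dumps(doc))


def read_abundance_table(
    path: str | Path,
    level: str,
    mode: str = "relative",
) -> AbundanceTable:
    """Read a taxon x sample table from TSV or BIOM-1.0 JSON.

    ``mode='relative'`` column-normalizes count input; ``mode='counts'``
    keeps raw counts (required by the Gibbs source-attribution stage).
    """
    if mode not in ("relative", "counts"):
        raise ValueError(f"mode must be 'relative' or 'counts', got {mode!r}")
    path = Path(path)
    text = path.read_text()
    if text.lstrip().startswith("{"):
        doc = json.loads(text)
        taxa = [r["id"] for r in doc["rows"]]
        samples = [c["id"] for c in doc["columns"]]
        values = np.zeros((len(taxa), len(samples)))
        if doc.get("matrix_type") == "dense":
            values[:] = np.asarray(doc["data"], dtype=float)
        else:
            for r, c, v in doc["data"]:
                values[r, c] = v
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
        taxa = [str(t) for t in df.index]
        samples = [str(s) for s in df.columns]
        values = df.to_numpy(dtype=float)
    is_integral = bool(np.allclose(values, np.round(values)))
    if mode == "counts":
        if not is_integral:
            raise ValueError(
                "mode='counts' but the table has fractional entries"
            )
        return AbundanceTable(level, taxa, samples, values, counts=True)
    if is_integral and values.max(initial=0) > 1.5:
        return AbundanceTable(level, taxa, samples, values, counts=True).to_relative()
    # already fractional: enforce relative invariants directly
    return AbundanceTable(level, taxa, samples, values, counts=False)


def write_abundance_table(table: AbundanceTable, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".biom" or path.suffix == ".json":
        table.to_biom_json(path)
    else:
        table.to_tsv(path)


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleMetadata:
    """One sample's provenance: who, when, and the nine survey covariates."""

    sample_id: str
    individual_id: str
    month_index: int
    timepoint_label: str | None = None
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.month_index <= 0:
            raise ValueError(
                f"month_index must be positive, got {self.month_index}"
            )


def validate_metadata(metadata: Iterable[SampleMetadata]) -> list[SampleMetadata]:
    """Check uniqueness invariants over a sample set."""
    metadata = list(metadata)
    seen_ids: set[str] = set()
    seen_pairs: set[tuple[str, int]] = set()
    for m in metadata:
        if m.sample_id in seen_ids:
            raise ValueError(f"duplicate sample_id: {m.sample_id!r}")
        seen_ids.add(m.sample_id)
        key = (m.individual_id, m.month_index)
        if key in seen_pairs:
            raise ValueError(
                f"individual {m.individual_id!r} has two samples in "
                f"month {m.month_index} (sample {m.sample_id!r})"
            )
        seen_pairs.add(key)
    return metadata


def read_metadata(path: str | Path) -> list[SampleMetadata]:
    """Read per-sample metadata from TSV.

    Required columns: ``sample_id``, ``individual_id``, ``date``
    (ISO year-month).  An optional ``timepoint`` column and any further
    columns are retained verbatim as covariates (missing values stay
    missing).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "individual_id", "date"):
        if col not in df.columns:
            raise ValueError(f"metadata is missing required column {col!r}")
    out = []
    extra = [c for c in df.columns
             if c not in ("sample_id", "individual_id", "date", "timepoint")]
    for _, row in df.iterrows():
        if pd.isna(row["individual_id"]) or str(row["individual_id"]) == "":
            raise ValueError(
                f"sample {row['sample_id']!r} has no individual_id"
            )
        cov = {c: (None if pd.isna(row[c]) else row[c]) for c in extra}
        cov.setdefault("participant_id", str(row["individual_id"]))
        cov.setdefault("date", str(row["date"]))
        out.append(
            SampleMetadata(
                sample_id=str(row["sample_id"]),
                individual_id=str(row["individual_id"]),
                month_index=parse_month(row["date"]),
                timepoint_label=(
                    None if "timepoint" not in df.columns or pd.isna(row["timepoint"])
                    else str(row["timepoint"])
                ),
                covariates=cov,
            )
        )
    return validate_metadata(out)


def write_metadata(metadata: Sequence[SampleMetadata], path: str | Path) -> None:
    rows = []
    for m in metadata:
        year, month = divmod(m.month_index - 1, 12)
        month += 1
        row = {
            "sample_id": m.sample_id,
            "individual_id": m.individual_id,
            "date": f"{year:04d}-{month:02d}",
            "timepoint": m.timepoint_label,
        }
        row.update({k: v for k, v in m.covariates.items()
                    if k not in ("participant_id", "date")})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def metadata_by_sample(metadata: Iterable[SampleMetadata]) -> dict[str, SampleMetadata]:
    return {m.sample_id: m for m in metadata}


# ---------------------------------------------------------------------------
# Read-level QC
# ---------------------------------------------------------------------------


@dataclass
class QCReport:
    """Summary of the trailing-quality trim + length filter."""

    n_input: int
    n_kept: int
    n_dropped: int
    q30_fraction: float  # of kept bases; dataset property, not a filter
    mean_kept_length: float


def qc_filter_reads(
    reads: Iterable[SeqRecord],
    qual_floor: int = 20,
    min_len: int = 200,
) -> tuple[list[SeqRecord], QCReport]:
    """Trim trailing low-quality bases and drop short reads.

    Each read is truncated at the start of its maximal trailing run of
    bases with Phred quality < ``qual_floor`` (a suffix scan; interior
    low-quality bases are untouched).  Reads shorter than ``min_len``
    after trimming are discarded.
    """
    kept: list[SeqRecord] = []
    n_input = 0
    n_bases = 0
    n_q30 = 0
    for rec in reads:
        n_input += 1
        quals = rec.letter_annotations.get("phred_quality")
        if quals is None:
            raise ValueError(f"record {n_input - 1} has no quality scores")
        end = len(quals)
        while end > 0 and quals[end - 1] < qual_floor:
            end -= 1
        if end < min_len:
            continue
        trimmed = rec[:end]
        kept.append(trimmed)
        q = trimmed.letter_annotations["phred_quality"]
        n_bases += len(q)
        n_q30 += sum(1 for x in q if x >= 30)
    report = QCReport(
        n_input=n_input,
        n_kept=len(kept),
        n_dropped=n_input - len(kept),
        q30_fraction=(n_q30 / n_bases) if n_bases else float("nan"),
        mean_kept_length=(n_bases / len(kept)) if kept else float("nan"),
    )
    return kept, report


def read_fastq(path: str | Path) -> list[SeqRecord]:
    """Parse a Sanger/Phred+33 FASTQ file, naming the offending record on error."""
    records = []
    try:
        for i, rec in enumerate(SeqIO.parse(str(path), "fastq")):
            records.append(rec)
    except ValueError as exc:
        raise ValueError(
            f"malformed FASTQ record at index {len(records)}: {exc}"
        ) from exc
    return records


def write_fastq(records: Iterable[SeqRecord], path: str | Path) -> None:
    SeqIO.write(list(records), str(path), "fastq")


def make_read(name: str, seq: str, quals: Sequence[int]) -> SeqRecord:
    """Convenience constructor for a FASTQ record (used by tests and docs)."""
    rec = SeqRecord(Seq(seq), id=name, description="")
    rec.letter_annotations["phred_quality"] = list(quals)
    return rec


# ---------------------------------------------------------------------------
# Analysis configuration
# ---------------------------------------------------------------------------


@dataclass
class AnalysisConfig:
    """Every pipeline constant in one place.

    Defaults are the published analysis choices: the >5x bloom rule,
    1000 permutation replicates, alpha = 0.05, the 0.1% display floor,
    the Q20/200 bp read filter, and the M1/Y1/Y2/Y3 interval bounds.
    """

    bloom_fold_threshold: float = 5.0
    perm_reps: int = 1000
    alpha: float = 0.05
    display_abundance_floor: float = 0.001
    qc_min_len: int = 200
    qc_qual_floor: int = 20
    group_bounds: dict = field(
        default_factory=lambda: dict(DEFAULT_GROUP_BOUNDS)
    )
    # Gibbs source-attribution hyperparameters (cited method's defaults)
    gibbs_alpha1: float = 0.001
    gibbs_alpha2: float = 0.1
    gibbs_beta: float = 10.0
    gibbs_burn_in: int = 100
    gibbs_restarts: int = 10
    gibbs_draws_per_restart: int = 1
    gibbs_delay: int = 1
    gibbs_rarefaction_depth: int | None = None  # None = min depth capped at 1000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "bloom_fold_threshold", "perm_reps", "alpha",
            "display_abundance_floor", "qc_min_len", "qc_qual_floor",
            "gibbs_alpha1", "gibbs_alpha2", "gibbs_beta",
            "gibbs_burn_in", "gibbs_restarts", "gibbs_draws_per_restart",
            "gibbs_delay",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        self.group_bounds = {
            g: (int(lo), int(hi)) for g, (lo, hi) in self.group_bounds.items()
        }
        prev_hi = 0
        for g, (lo, hi) in self.group_bounds.items():
            if lo > hi or lo <= prev_hi:
                raise ValueError(
                    f"group bounds must be ordered and non-overlapping; "
                    f"{g}=({lo},{hi}) follows hi={prev_hi}"
                )
            prev_hi = hi

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "group_bounds" in raw:
            raw["group_bounds"] = {
                g: tuple(v) for g, v in raw["group_bounds"].items()
            }
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["group_bounds"] = {g: list(v) for g, v in self.group_bounds.items()}
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))
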