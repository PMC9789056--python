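"""End-to-end orchestration: QC -> blooms -> distances -> tests -> report.

`run_pipeline` chains every analysis stage on one abundance table +
metadata pair, writes each stage's tables as TSV under the output
directory, and records a manifest (config snapshot, input digests, RNG
seed, stage timings, output inventory with digests) so two runs with
the same seed are verifiably identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import bloom as bloom_mod
from . import dissimilarity as dis_mod
from . import longitudinal_stats as stats_mod
from . import ordination as ord_mod
from . import source_attribution as src_mod
from .core_io import (
    COVARIATE_NAMES,
    AbundanceTable,
    AnalysisConfig,
    SampleMetadata,
    metadata_by_sample,
    qc_filter_reads,
    read_abundance_table,
    read_fastq,
    read_metadata,
    write_fastq,
)

log = logging.getLogger("gutdyn")

#: Covariates treated as numeric in the Mantel screen; the rest are categorical.
NUMERIC_COVARIATES = {"date", "blood_pressure", "blood_sugar"}

POOLED_CONTRASTS = (("M1", "Y1"), ("M1", "Y2"), ("M1", "Y3"),
                    ("Y1", "Y2"), ("Y2", "Y3"))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclasses.dataclass
class RunManifest:
    config: dict
    inputs: dict[str, str]        # path -> digest
    rng_seed: int | None
    stage_seconds: dict[str, float]
    outputs: dict[str, str]       # relative path -> digest

    def to_json(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2))


def subset_before_timepoint(
    table: AbundanceTable,
    metadata: Sequence[SampleMetadata],
    cutoff: str | int,
) -> tuple[AbundanceTable, list[SampleMetadata]]:
    """Keep only samples at or before a cutoff (sensitivity analysis).

    ``cutoff`` is either a time-point label like ``"T28"`` (compared by
    its ordinal number) or an integer month index.
    """
    if isinstance(cutoff, str) and cutoff.upper().startswith("T"):
        limit = int(cutoff[1:])

        def keep(m: SampleMetadata) -> bool:
            if m.timepoint_label is None:
                raise ValueError(
                    f"sample {m.sample_id!r} has no timepoint label"
                )
            return int(str(m.timepoint_label).lstrip("Tt")) <= limit
    else:
        limit = int(cutoff)

        def keep(m: SampleMetadata) -> bool:
            return m.month_index <= limit

    kept = [m for m in metadata if keep(m)]
    if not kept:
        raise ValueError(f"cutoff {cutoff!r} removes every sample")
    kept_ids = [m.sample_id for m in kept]
    return table.subset_samples(kept_ids), kept


def run_pipeline(
    config: AnalysisConfig,
    table_path: str | Path,
    metadata_path: str | Path,
    out_dir: str | Path,
    level: str = "genus",
    fastq_paths: Sequence[str | Path] | None = None,
    seed: int | None = None,
    cutoff_timepoint: str | int | None = None,
    skip_source: bool = False,
) -> RunManifest:
    """Run every stage on one table/metadata pair; see module docstring."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.rng_seed if seed is None else seed
    timings: dict[str, float] = {}
    inputs = {str(p): _sha256(Path(p)) for p in [table_path, metadata_path]}

    def stage(name: str):
        class _T:
            def __enter__(self_inner):
                log.info("stage %s: start (seed=%s)", name, seed)
                self_inner.t0 = time.perf_counter()

            def __exit__(self_inner, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self_inner.t0, 3)
                if exc is not None:
                    log.error("stage %s: FAILED: %s", name, exc)
                    raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
                log.info("stage %s: done in %.2fs", name, timings[name])

        return _T()

    # -- optional read-level QC ---------------------------------------
    if fastq_paths:
        with stage("qc"):
            rows = []
            for fq in fastq_paths:
                kept, rep = qc_filter_reads(
                    read_fastq(fq), config.qc_qual_floor, config.qc_min_len
                )
                write_fastq(kept, out / (Path(fq).stem + ".qc.fastq"))
                rows.append(dict(file=str(fq), **dataclasses.asdict(rep)))
            pd.DataFrame(rows).to_csv(out / "qc_report.tsv", sep="\t",
                                      index=False)

    # -- load ----------------------------------------------------------
    with stage("load"):
        counts_table: AbundanceTable | None
        try:
            counts_table = read_abundance_table(table_path, level, "counts")
        except ValueError:
            counts_table = None  # relative-only input: no source stage
        rel = (
            counts_table.to_relative()
            if counts_table is not None
            else read_abundance_table(table_path, level, "relative")
        )
        metadata = read_metadata(metadata_path)
        if cutoff_timepoint is not None:
            rel, metadata = subset_before_timepoint(rel, metadata,
                                                    cutoff_timepoint)
            if counts_table is not None:
                counts_table = counts_table.subset_samples(
                    [m.sample_id for m in metadata]
                )

    # -- blooms ---------------------------------------------------------
    with stage("bloom"):
        calls = bloom_mod.detect_blooms(rel, metadata,
                                        config.bloom_fold_threshold)
        summary = bloom_mod.summarize_blooms(calls, metadata, level)
        bloom_mod.calls_to_frame(calls).to_csv(out / "bloom_calls.tsv",
                                               sep="\t", index=False)
        bloom_mod.itol_annotation(summary).to_csv(
            out / "bloom_counts_by_individual.tsv", sep="\t"
        )

    # -- distances & pairs ----------------------------------------------
    with stage("distance"):
        dm = dis_mod.bray_curtis(rel)
        dm.to_tsv(out / f"distance_{level}.tsv")
        pairs = dis_mod.enumerate_pairs(dm, metadata, config.group_bounds)
        dis_mod.pairs_to_frame(pairs).to_csv(out / "pairs.tsv", sep="\t",
                                             index=False)

    # -- permutation tests ------------------------------------------------
    with stage("permtest"):
        results = []
        individuals = sorted({m.individual_id for m in metadata})
        jobs = [(None, gp) for gp in POOLED_CONTRASTS]
        jobs += [(ind, ("M1", "Y3")) for ind in individuals]
        for k, (ind, gp) in enumerate(jobs):
            try:
                res = stats_mod.permute_timepoint_test(
                    dm, metadata, ind, gp, reps=config.perm_reps,
                    rng_seed=None if seed is None else seed + 101 + k,
                    group_bounds=config.group_bounds,
                )
            except ValueError as exc:
                log.warning("permtest %s %s skipped: %s", ind, gp, exc)
                continue
            results.append(
                dict(
                    individual=res.individual_id,
                    group_a=gp[0], group_b=gp[1],
                    observed_W=res.observed_W, p_value=res.p_value,
                    reps=res.reps, rng_seed=res.rng_seed,
                    crit90=res.critical_values[90],
                    crit95=res.critical_values[95],
                    crit99=res.critical_values[99],
                )
            )
        perm_df = pd.DataFrame(results)
        perm_df.to_csv(out / "permtest.tsv", sep="\t", index=False)

    # -- source attribution ----------------------------------------------
    if counts_table is not None and not skip_source:
        with stage("source"):
            settings = src_mod.GibbsSettings(
                alpha1=config.gibbs_alpha1, alpha2=config.gibbs_alpha2,
                beta=config.gibbs_beta, burn_in=config.gibbs_burn_in,
                restarts=config.gibbs_restarts,
                draws_per_restart=config.gibbs_draws_per_restart,
                delay=config.gibbs_delay,
                rarefaction_depth=config.gibbs_rarefaction_depth,
            )
            means, per_pair = src_mod.retained_fraction_by_interval(
                counts_table, metadata, settings, config.group_bounds,
                rng_seed=None if seed is None else seed + 7,
            )
            per_pair.to_csv(out / "source_pairs.tsv", sep="\t", index=False)
            pd.DataFrame(
                [{"group": g, "mean_shared_proportion": v}
                 for g, v in sorted(means.items())]
            ).to_csv(out / "source_groups.tsv", sep="\t", index=False)

    # -- ordination -------------------------------------------------------
    with stage("pcoa"):
        res = ord_mod.pcoa(dm)
        coords, eigs = res.to_frames()
        coords.to_csv(out / "pcoa_coords.tsv", sep="\t")
        eigs.to_csv(out / "pcoa_eigs.tsv", sep="\t", index=False)

    # -- Mantel screen ----------------------------------------------------
    with stage("mantel"):
        meta_map = metadata_by_sample(metadata)
        rows = []
        for k, factor in enumerate(COVARIATE_NAMES):
            vals = []
            ok = True
            for s in dm.sample_ids:
                v = meta_map[s].covariates.get(factor)
                if factor == "participant_id":
                    v = meta_map[s].individual_id
                elif factor == "date":
                    v = meta_map[s].month_index
                if v is None:
                    ok = False
                    break
                vals.append(v)
            if not ok:
                log.warning("mantel: factor %s missing values, skipped", factor)
                continue
            kind = "numeric" if factor in NUMERIC_COVARIATES else "categorical"
            mres = stats_mod.mantel_test(
                dm, vals, kind, reps=config.perm_reps,
                rng_seed=None if seed is None else seed + 211 + k,
                factor_name=factor,
            )
            rows.append(dataclasses.asdict(mres))
        mantel_df = pd.DataFrame(rows)
        mantel_df.to_csv(out / "mantel.tsv", sep="\t", index=False)

    # -- report -----------------------------------------------------------
    with stage("report"):
        render_report(out, rel, metadata, config)

    outputs = {
        str(p.relative_to(out)): _sha256(p)
        for p in sorted(out.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = RunManifest(
        config=config.to_dict(),
        inputs=inputs,
        rng_seed=seed,
        stage_seconds=timings,
        outputs=outputs,
    )
    manifest.to_json(out / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------


def _composition_panel(rel: AbundanceTable, metadata, floor: float, path: Path):
    meta = metadata_by_sample(metadata)
    keep = rel.values.max(axis=1) >= floor
    df = pd.DataFrame(rel.values[keep], index=np.array(rel.taxa)[keep],
                      columns=rel.samples)
    other = 1.0 - df.sum(axis=0)
    df.loc["Other"] = np.clip(other, 0, 1)
    order = sorted(rel.samples,
                   key=lambda s: (meta[s].individual_id, meta[s].month_index))
    fig, ax = plt.subplots(figsize=(max(8, len(order) * 0.12), 4))
    bottom = np.zeros(len(order))
    for taxon in df.index:
        vals = df.loc[taxon, order].to_numpy()
        ax.bar(range(len(order)), vals, bottom=bottom, width=1.0, label=None)
        bottom += vals
    ax.set_xlim(-0.5, len(order) - 0.5)
    ax.set_ylabel("relative abundance")
    ax.set_title(f"Composition (taxa with abundance >= {floor:g} shown; "
                 "rest pooled as Other)")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def _box_panel(path: Path, groups: dict[str, np.ndarray], ylabel: str,
               title: str):
    labels = [g for g in ("M1", "Y1", "Y2", "Y3", "D") if g in groups]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.boxplot([groups[g] for g in labels], tick_labels=labels)
    ax.set_ylabel(ylabel)
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def render_report(
    out: Path,
    rel: AbundanceTable | None = None,
    metadata: Sequence[SampleMetadata] | None = None,
    config: AnalysisConfig | None = None,
) -> Path:
    """Assemble a self-contained markdown report from whatever stage
    outputs exist under ``out``; missing stages get a note, not a crash."""
    out = Path(out)
    config = config or AnalysisConfig()
    fig_dir = out / "figures"
    fig_dir.mkdir(exist_ok=True)
    lines = ["# gutdyn analysis report", ""]

    def section(title: str):
        lines.extend([f"## {title}", ""])

    section("Community composition")
    if rel is not None and metadata is not None:
        p = fig_dir / "composition.png"
        _composition_panel(rel, metadata, config.display_abundance_floor, p)
        lines.append(f"![composition]({p.relative_to(out)})")
    else:
        lines.append("*composition panel unavailable (no table loaded)*")
    lines.append("")

    section("Short-term blooms")
    f = out / "bloom_counts_by_individual.tsv"
    if f.exists():
        df = pd.read_csv(f, sep="\t", index_col=0)
        n_calls = int(df["total_blooms"].sum()) if len(df) else 0
        lines.append(f"{len(df)} taxa with blooms; {n_calls} calls total. "
                     f"See `bloom_calls.tsv`.")
    else:
        lines.append("*bloom stage output missing*")
    lines.append("")

    section("Dissimilarity by interval group")
    f = out / "pairs.tsv"
    if f.exists():
        pairs = pd.read_csv(f, sep="\t")
        groups = {g: sub["dissimilarity"].to_numpy()
                  for g, sub in pairs.groupby("group")}
        p = fig_dir / "dissimilarity_groups.png"
        _box_panel(p, groups, "Bray-Curtis dissimilarity",
                   "Pairwise dissimilarity by interval group")
        lines.append(f"![dissimilarity]({p.relative_to(out)})")
        means = {g: float(v.mean()) for g, v in groups.items()}
        lines.append("")
        lines.append("Group means: " + ", ".join(
            f"{g}={means[g]:.3f}" for g in sorted(means)))
    else:
        lines.append("*distance stage output missing*")
    lines.append("")

    section("Permutation-Wilcoxon tests")
    f = out / "permtest.tsv"
    if f.exists():
        df = pd.read_csv(f, sep="\t")
        lines.append("```\n" + df.to_string(index=False) + "\n```")
    else:
        lines.append("*permutation stage output missing*")
    lines.append("")

    section("Retained source proportion")
    f = out / "source_pairs.tsv"
    if f.exists():
        sp = pd.read_csv(f, sep="\t")
        groups = {g: sub["shared_proportion"].to_numpy()
                  for g, sub in sp.groupby("group")}
        p = fig_dir / "retained_groups.png"
        _box_panel(p, groups, "shared proportion",
                   "Source proportion retained, by interval group")
        lines.append(f"![retained]({p.relative_to(out)})")
    else:
        lines.append("*source-attribution stage output missing*")
    lines.append("")

    section("PCoA")
    f = out / "pcoa_coords.tsv"
    if f.exists() and metadata is not None:
        coords = pd.read_csv(f, sep="\t", index_col=0)
        meta = metadata_by_sample(metadata)
        fig, ax = plt.subplots(figsize=(5, 4))
        if coords.shape[1] >= 2:
            for ind in sorted({m.individual_id for m in metadata}):
                sel = [s for s in coords.index if meta[s].individual_id == ind]
                ax.scatter(coords.loc[sel, "PCo1"], coords.loc[sel, "PCo2"],
                           s=12, label=ind)
            ax.legend(fontsize=7)
            ax.set_xlabel("PCo1")
            ax.set_ylabel("PCo2")
        p = fig_dir / "pcoa.png"
        fig.tight_layout()
        fig.savefig(p, dpi=100)
        plt.close(fig)
        lines.append(f"![pcoa]({p.relative_to(out)})")
    else:
        lines.append("*ordination stage output missing*")
    lines.append("")

    section("Mantel factor associations")
    f = out / "mantel.tsv"
    if f.exists():
        df = pd.read_csv(f, sep="\t")
        lines.append("```\n" + df.to_string(index=False) + "\n```")
    else:
        lines.append("*mantel stage output missing*")
    lines.append("")

    report = out / "report.md"
    report.write_text("\n".join(lines))
    return report
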