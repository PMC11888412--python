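"""End-to-end orchestration: file formats, configuration, logging, reports.

All tabular artifacts are UTF-8 TSV with a header row ('.' decimal, no
thousands separators).  The pipeline stages are

    simulate -> score -> (select) -> scan x5 phenotypes -> q-values
             -> differential peaks -> haplotype means -> report

and a manifest records package/library versions, the seed, a hash of the
configuration and of every numerical output, so a rerun with the same seed
is verifiably identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, scoring
from .qvalue import qvalues
from .scan import (SCAN_PHENOTYPES, attach_qvalues, differential_peaks,
                   genome_scan, haplotype_means, phenotype_table)
from .selection import call_peak_haplotypes, cumulative_scores, select_rils
from .synthetic import (FounderPanel, QTLEffectSpec, RILHaplotypeMap,
                        SimStudyConfig, effects_to_frame,
                        simulate_acuity_and_preference, simulate_fly_outcomes,
                        simulate_ril_haplotypes)

logger = logging.getLogger("ymazeqtl")

EXIT_OK = 0
EXIT_SCHEMA = 2
EXIT_CONVERGENCE = 3


class SchemaError(ValueError):
    """An input table violates its documented schema."""


class ConvergenceBudgetError(RuntimeError):
    """Too many scan positions failed to converge."""


@dataclass
class PipelineConfig:
    """Flat configuration for the pipeline (round-trips through YAML).

    Every threshold of the analysis surfaces here with its standard value
    as default: the strict 0.5 bounds of the override rule, the 0.45-0.55
    neutral preference band (inclusive), the 4-RIL haplotype drop rule, the
    strict >2 odor-differential threshold, and the q <= 0.05 significance
    rule.
    """

    seed: int = 0
    outdir: str = "ymazeqtl_out"
    # input tables (empty string = produce synthetically)
    counts_tsv: str = ""
    flies_tsv: str = ""
    haplotypes_tsv: str = ""
    # scoring options
    pooled: bool = True
    neutral_band_low: float = 0.45
    neutral_band_high: float = 0.55
    # scan options
    min_ril_count: int = 4
    harbor_threshold: float = 0.5
    diff_threshold: float = 2.0
    diff_k: int = 3
    diff_separation: int = 10
    q_significance: float = 0.05
    max_nonconverged_frac: float = 0.05
    scan_climbing: bool = True
    make_plots: bool = True
    # simulation block
    sim_chromosomes: str = "X:100,2:200,3:200"
    sim_n_rils: int = 50
    sim_flies_min: int = 60
    sim_flies_max: int = 80
    sim_n_replicates: int = 3
    sim_sd_ril: float = 0.3
    sim_sd_replicate: float = 0.2
    sim_baseline_correct_logit: float = 0.0
    sim_baseline_climb_logit: float = 0.0
    sim_recomb_prob: float = 0.02
    sim_soft_prob_noise: float = 50.0
    sim_effects: str = ""  # "chrom:pos:founder:effect:odor_scope:phenotype_scope;..."

    def __post_init__(self) -> None:
        if not 0.0 <= self.harbor_threshold <= 1.0:
            raise ValueError("harbor_threshold must be in [0, 1]")
        if self.min_ril_count < 1:
            raise ValueError("min_ril_count must be >= 1")
        if self.diff_threshold < 0 or self.diff_k < 1 or self.diff_separation < 1:
            raise ValueError("bad differential-peak options")
        if not 0 <= self.neutral_band_low <= self.neutral_band_high <= 1:
            raise ValueError("bad neutral band")

    # -- serialization ----------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()

    # -- derived objects --------------------------------------------------
    def panel(self) -> FounderPanel:
        chroms = []
        for item in self.sim_chromosomes.split(","):
            name, n = item.split(":")
            chroms.append((name.strip(), int(n)))
        return FounderPanel(chromosomes=tuple(chroms))

    def sim_config(self) -> SimStudyConfig:
        return SimStudyConfig(
            n_rils=self.sim_n_rils,
            flies_per_vial=(self.sim_flies_min, self.sim_flies_max),
            n_replicates=self.sim_n_replicates,
            sd_ril=self.sim_sd_ril,
            sd_replicate=self.sim_sd_replicate,
            baseline_correct_logit=self.sim_baseline_correct_logit,
            baseline_climb_logit=self.sim_baseline_climb_logit,
            recomb_prob=self.sim_recomb_prob,
            soft_prob_noise=self.sim_soft_prob_noise or None,
            seed=self.seed,
        )

    def effects(self) -> list[QTLEffectSpec]:
        out = []
        if not self.sim_effects.strip():
            return out
        from .synthetic import DEFAULT_FOUNDERS
        for item in self.sim_effects.split(";"):
            chrom, pos, founder, eff, odor, pheno = (s.strip() for s in item.split(":"))
            effects = {f: 0.0 for f in DEFAULT_FOUNDERS}
            effects[founder] = float(eff)
            out.append(QTLEffectSpec(chrom, int(pos), effects, odor, pheno))
        return out


# ---------------------------------------------------------------------------
# TSV IO with schema checks


def read_tsv(path: str | Path, required: list[str], name: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{name} table not found: {path}")
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{name} table {path} missing columns: {missing}")
    return df


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def load_counts_with_mapping(path: str | Path,
                             mapping: dict[str, str] | str | Path,
                             sep: str = "\t") -> pd.DataFrame:
    """Read an externally deposited count table via a column-name mapping.

    Deposited raw tables name their columns differently from this package's
    schema; ``mapping`` (a dict or a YAML file of ``ours: theirs`` pairs)
    renames them.  Unmapped schema columns that are absent get neutral
    defaults (``n_censored`` 0, ``trained_odor`` 'none'); anything else
    missing raises :class:`SchemaError`.
    """
    if not isinstance(mapping, dict):
        mapping = yaml.safe_load(Path(mapping).read_text()) or {}
    df = pd.read_csv(path, sep=sep)
    rename = {theirs: ours for ours, theirs in mapping.items()}
    unknown = [c for c in rename if c not in df.columns]
    if unknown:
        raise SchemaError(f"mapped columns not in {path}: {unknown}")
    df = df.rename(columns=rename)
    if "n_censored" not in df.columns:
        df["n_censored"] = 0
    if "trained_odor" not in df.columns:
        df["trained_odor"] = "none"
    missing = [c for c in scoring.COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"deposit table lacks columns after mapping: {missing}")
    return df[scoring.COUNT_COLUMNS + [c for c in df.columns
                                       if c not in scoring.COUNT_COLUMNS]]


def validate_counts(df: pd.DataFrame) -> None:
    count_cols = ["n_plus", "n_minus", "n_nc", "n_censored"]
    bad_rows = []
    for i, row in enumerate(df[count_cols].itertuples(index=False)):
        vals = list(row)
        if any(pd.isna(v) for v in vals) or any(v < 0 for v in vals) \
                or any(float(v) != int(v) for v in vals):
            bad_rows.append(i + 2)  # 1-based, after header
    if bad_rows:
        raise SchemaError(
            f"counts table has invalid count values at rows {bad_rows[:10]}")
    bad_assay = [i + 2 for i, a in enumerate(df.assay) if a not in scoring.ASSAYS]
    if bad_assay:
        raise SchemaError(f"counts table has unknown assay at rows {bad_assay[:10]}")


# ---------------------------------------------------------------------------
# Stages


def run_simulate(config: PipelineConfig, outdir: Path) -> dict[str, Path]:
    """Generate the synthetic study and write every input table."""
    panel = config.panel()
    sim = config.sim_config()
    effects = config.effects()
    logger.info("simulating %d RILs x %d positions", sim.n_rils, panel.n_positions)
    haps = simulate_ril_haplotypes(panel, sim)
    flies, truth = simulate_fly_outcomes(haps, effects, sim)
    acuity_counts, latents = simulate_acuity_and_preference(haps, sim)

    paths = {
        "haplotypes": outdir / "haplotypes.tsv",
        "flies": outdir / "flies.tsv",
        "counts": outdir / "counts.tsv",
        "truth_effects": outdir / "truth_effects.tsv",
        "truth_latents": outdir / "truth_latents.tsv",
    }
    write_tsv(haps.to_frame(), paths["haplotypes"])
    write_tsv(flies, paths["flies"])

    # chamber counts for learning/memory from the fly table + acuity tables
    agg_rows = []
    for (ril, rep, odor, assay), grp in flies.groupby(
            ["ril", "replicate", "trained_odor", "assay"], sort=True):
        n_nc = int((grp.climbed == 0).sum())
        n_plus = int((grp.correct == 1).sum())
        n_minus = int((grp.correct == 0).sum())
        agg_rows.append((ril, rep, odor, assay, n_plus, n_minus, n_nc, 0))
    counts = pd.DataFrame(agg_rows, columns=scoring.COUNT_COLUMNS)
    counts = pd.concat([counts, acuity_counts], ignore_index=True)
    write_tsv(counts, paths["counts"])
    write_tsv(effects_to_frame(effects), paths["truth_effects"])
    write_tsv(latents, paths["truth_latents"])
    return paths


def run_score(config: PipelineConfig, counts_path: str | Path,
              outdir: Path) -> dict:
    """Score a counts table and build the per-RIL summary report."""
    counts = read_tsv(counts_path, scoring.COUNT_COLUMNS, "counts")
    validate_counts(counts)
    scores = scoring.score_table(counts, pooled=config.pooled)
    write_tsv(scores, outdir / "scores.tsv")

    summary = scoring.summarize_rils(scores)

    # neutral-band tally on baseline preference (inclusive bounds)
    base = scores[scores.assay == "baseline"].choice_score.dropna().astype(float)
    summary["baseline_preference"] = {
        "n_rils": int(base.size),
        "n_neutral": int(((base >= config.neutral_band_low)
                          & (base <= config.neutral_band_high)).sum()),
        "range": [float(base.min()), float(base.max())] if base.size else None,
    }

    # override table mirroring the published layout
    over = scores[(scores.assay.isin(["learning", "memory"])) & scores.override]
    write_tsv(over[["ril", "assay", "trained_odor", "choice_score",
                    "preference_score", "ppd"]], outdir / "override.tsv")

    # acuity vs performance correlations
    acuity = scores[scores.assay.isin(["odor_acuity", "sugar_acuity"])]
    perf = scores[scores.assay.isin(["learning", "memory"])]
    cors = []
    for (a_assay, a_odor), agrp in acuity.groupby(["assay", "trained_odor"]):
        a = agrp.set_index("ril").choice_score.astype(float)
        for (p_assay, p_odor), pgrp in perf.groupby(["assay", "trained_odor"]):
            b = pgrp.set_index("ril").choice_score.astype(float)
            joined = pd.concat([a, b], axis=1, join="inner").dropna()
            if len(joined) < 3:
                continue
            r = float(np.corrcoef(joined.iloc[:, 0], joined.iloc[:, 1])[0, 1])
            cors.append({
                "acuity": f"{a_assay}_{a_odor}" if a_odor != "none" else a_assay,
                "phenotype": f"{p_odor}_{p_assay}",
                "pearson_r": r, "n": len(joined),
            })
    cor_df = pd.DataFrame(cors, columns=["acuity", "phenotype", "pearson_r", "n"])
    write_tsv(cor_df, outdir / "acuity_correlations.tsv")
    summary["acuity_correlations"] = cors

    (outdir / "score_report.json").write_text(json.dumps(summary, indent=2))
    return summary


def run_select(config: PipelineConfig, phenotypes: pd.DataFrame,
               haps: RILHaplotypeMap, peaks: pd.DataFrame, k: int,
               outdir: Path, call_threshold: float = 0.5):
    """Percentile, call and select extreme RILs; write the audit table."""
    scores = cumulative_scores(phenotypes)
    calls = call_peak_haplotypes(haps, peaks, call_threshold)
    high, low, audit = select_rils(scores, calls, peaks, k)
    audit = audit.merge(scores[["ril", "pct_learning", "pct_memory"]], on="ril")
    write_tsv(audit, outdir / "selection.tsv")
    return high, low, audit


def run_scan(config: PipelineConfig, haps: RILHaplotypeMap,
             flies: pd.DataFrame, outdir: Path) -> dict:
    """Scan all odor/assay phenotypes, attach q-values, find differential
    peaks and their haplotype means."""
    phenotypes = list(SCAN_PHENOTYPES)
    if not config.scan_climbing:
        phenotypes.remove("climbing")
    scans = {}
    for label in phenotypes:
        pheno = phenotype_table(flies, label)
        scans[label] = genome_scan(
            haps, pheno, label, min_ril_count=config.min_ril_count,
            harbor_threshold=config.harbor_threshold,
            log_every=100, logger=logger)
        frac_bad = 1.0 - scans[label].converged.mean()
        logger.info("%s scan: %d positions, %.1f%% non-converged",
                    label, len(scans[label]), 100 * frac_bad)
        if frac_bad > config.max_nonconverged_frac:
            raise ConvergenceBudgetError(
                f"{label}: {frac_bad:.1%} positions failed to converge")

    full = pd.concat(scans.values(), ignore_index=True)
    full, pi0 = attach_qvalues(full)
    write_tsv(full, outdir / "scan.tsv")

    peaks_frames = []
    means_frames = []
    for assay in ("learning", "memory"):
        pk = differential_peaks(
            scans[f"OCT_{assay}"], scans[f"MCH_{assay}"],
            threshold=config.diff_threshold, k=config.diff_k,
            min_separation=config.diff_separation, phenotype=assay)
        peaks_frames.append(pk)
        pheno_by_odor = {
            "OCT": phenotype_table(flies, f"OCT_{assay}"),
            "MCH": phenotype_table(flies, f"MCH_{assay}"),
        }
        for row in pk.itertuples():
            means_frames.append(haplotype_means(
                haps, pheno_by_odor, row.chrom, int(row.pos),
                call_threshold=config.harbor_threshold))
    peaks = pd.concat(peaks_frames, ignore_index=True)
    means = (pd.concat(means_frames, ignore_index=True) if means_frames
             else pd.DataFrame(columns=["chrom", "pos", "trained_odor",
                                        "founder", "mean", "se", "n_rils"]))
    write_tsv(peaks, outdir / "differential_peaks.tsv")
    write_tsv(means, outdir / "haplotype_means.tsv")

    min_q = float(full.q.min()) if full.q.notna().any() else float("nan")
    verdict = ("significant QTLs detected" if min_q <= config.q_significance
               else "no significant QTLs")
    report = {
        "phenotypes": phenotypes,
        "n_positions": int(haps.n_positions),
        "pi0": pi0,
        "min_q": min_q,
        "verdict": verdict,
        "n_differential_peaks": int(len(peaks)),
        "differential_peaks": peaks.to_dict("records"),
    }
    (outdir / "scan_report.json").write_text(json.dumps(report, indent=2))
    if config.make_plots:
        _plot_scans(full, outdir / "scan_manhattan.png")
        if len(means):
            _plot_haplotype_means(means, outdir / "haplotype_means.png")
    return report


def run_full(config: PipelineConfig) -> dict:
    """Run every stage; returns the merged report and writes a manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")

    stage = "simulate"
    try:
        if config.counts_tsv and config.flies_tsv and config.haplotypes_tsv:
            paths = {"counts": Path(config.counts_tsv),
                     "flies": Path(config.flies_tsv),
                     "haplotypes": Path(config.haplotypes_tsv)}
        else:
            paths = run_simulate(config, outdir)

        stage = "score"
        score_report = run_score(config, paths["counts"], outdir)

        stage = "scan"
        haps = RILHaplotypeMap.from_frame(
            read_tsv(paths["haplotypes"], ["ril", "chrom", "pos"], "haplotypes"))
        flies = read_tsv(paths["flies"],
                         ["ril", "replicate", "trained_odor", "assay",
                          "climbed", "correct"], "flies")
        scan_report = run_scan(config, haps, flies, outdir)
    except Exception as exc:
        logger.error("pipeline failed in stage %r: %s", stage, exc)
        raise

    report = {"score": score_report, "scan": scan_report}
    manifest = {
        "ymazeqtl_version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "config_sha256": config.config_hash(),
        "outputs": {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(outdir.glob("*.tsv"))
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (outdir / "report.json").write_text(json.dumps(report, indent=2))
    return report


# ---------------------------------------------------------------------------
# Plot artifacts (never load-bearing; every tested surface is a table)


def _plot_scans(scan: pd.DataFrame, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    phenos = list(scan.phenotype.unique())
    fig, axes = plt.subplots(len(phenos), 1, figsize=(10, 2.2 * len(phenos)),
                             sharex=True, squeeze=False)
    chroms = list(scan.chrom.unique())
    offsets = {}
    off = 0
    for c in chroms:
        offsets[c] = off
        off += scan.pos[scan.chrom == c].max() + 10
    for ax, ph in zip(axes.ravel(), phenos):
        sub = scan[scan.phenotype == ph]
        x = sub.pos + sub.chrom.map(offsets)
        ax.scatter(x, sub.neg_log10_p, s=4,
                   c=[chroms.index(c) % 2 for c in sub.chrom], cmap="tab10")
        ax.set_ylabel(r"$-\log_{10} p$")
        ax.set_title(ph, fontsize=9)
    axes.ravel()[-1].set_xlabel("genome position (scan index)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_haplotype_means(means: pd.DataFrame, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    keys = means[["chrom", "pos"]].drop_duplicates().itertuples(index=False)
    keys = list(keys)
    fig, axes = plt.subplots(1, len(keys), figsize=(3.2 * len(keys), 3),
                             sharey=True, squeeze=False)
    for ax, (chrom, pos) in zip(axes.ravel(), keys):
        sub = means[(means.chrom == chrom) & (means.pos == pos)]
        for odor, og in sub.groupby("trained_odor"):
            ax.errorbar(og.founder, og["mean"], yerr=og.se, fmt="o",
                        capsize=3, label=odor)
        ax.set_title(f"{chrom}:{pos}", fontsize=9)
        ax.set_xlabel("founder")
    axes.ravel()[0].set_ylabel("mean proportion correct")
    axes.ravel()[0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
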