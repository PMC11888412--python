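"""Haplotype-probability genome scan for group-tested binomial phenotypes.

At every genomic position the scan asks whether founder ancestry predicts
the outcome: a base binomial mixed model (RIL and vial random intercepts
only) is compared by likelihood-ratio test against an alternative whose
fixed part adds the position's founder probabilities g_ij.  The base model
does not depend on the position, so it is fit once per phenotype and its
log-likelihood reused across the scan.

Founders carried by too few lines are dropped from a position's design
("carried" meaning g_ij above a harboring threshold): with few RILs not all
8 founder haplotypes are represented everywhere, and estimating a
coefficient from under four lines overfits.  When the retained founder
probabilities sum to ~1 for every RIL they are collinear with the
intercept, so the most frequent retained founder serves as reference for
estimation.  The chi-square reference for the LRT uses df = n_hap, the
number of retained founder haplotypes: at panel sizes of ~50 lines this
reference is well calibrated under the null, whereas chi-square on the
count of estimated coefficients (n_hap - 1 in the collinear case) is
anti-conservative because the large-sample limit is in the number of
lines, not flies (see the package methods note).  n_hap, df and the
estimated-coefficient count are all reported per position.

Phenotypes are scanned separately per training odor (OCT learning,
MCH learning, OCT memory, MCH memory) plus climbing; odor-differential
suggestive peaks are positions where the two odors' -log10 p differ by
more than a threshold (strictly), greedily thinned to distinct regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .glmm import GLMMFit, fit_binomial_glmm
from .qvalue import qvalues
from .synthetic import RILHaplotypeMap

SCAN_PHENOTYPES = ("OCT_learning", "MCH_learning", "OCT_memory", "MCH_memory", "climbing")

#: |sum of retained founder probabilities - 1| below this for every RIL
#: means the retained columns are collinear with the intercept.
_SUM_TO_ONE_TOL = 0.01


@dataclass
class PositionDesign:
    """Founder-probability design at one scan position."""

    chromosome: str
    position: int
    ril_ids: list[str]
    g: np.ndarray  # (n_ril, n_included) probabilities for included founders
    included_founders: list[str]
    reference_founder: str | None  # dropped column when probs sum to ~1
    n_coef: int  # haplotype coefficients actually estimated
    df: int  # chi-square reference df (= n_hap)

    @property
    def n_hap(self) -> int:
        return len(self.included_founders)


def build_design(haps: RILHaplotypeMap, chromosome: str, position: int,
                 min_ril_count: int = 4, harbor_threshold: float = 0.5) -> PositionDesign:
    """Build the alternative-model design at one position.

    A founder is included iff at least ``min_ril_count`` RILs harbor it,
    i.e. have g_ij > ``harbor_threshold`` there.
    """
    g_full = haps.g_at(chromosome, position)
    carriers = (g_full > harbor_threshold).sum(axis=0)
    included = [j for j in range(len(haps.founders)) if carriers[j] >= min_ril_count]
    names = [haps.founders[j] for j in included]
    g = g_full[:, included]

    reference = None
    if included:
        sums = g.sum(axis=1)
        if np.max(np.abs(sums - 1.0)) < _SUM_TO_ONE_TOL:
            ref_local = int(np.argmax(carriers[included]))
            reference = names[ref_local]
            keep = [i for i in range(len(included)) if i != ref_local]
            g = g[:, keep]
    n_coef = g.shape[1] if included else 0
    df = len(included)
    return PositionDesign(
        chromosome=chromosome, position=position, ril_ids=list(haps.ril_ids),
        g=g, included_founders=names, reference_founder=reference,
        n_coef=n_coef, df=df)


def phenotype_table(flies: pd.DataFrame, phenotype: str,
                    climbing_assay: str = "learning",
                    pool_assays: bool = False) -> pd.DataFrame:
    """Per-vial binomial (successes, trials) rows for one scan phenotype.

    Correctness phenotypes (``OCT_learning`` ... ``MCH_memory``) count CS+
    choices among climbers of the given odor/assay cell.  ``climbing``
    counts climbers among all flies of ``climbing_assay`` (or pooled over
    assays with ``pool_assays``), across both training odors.
    """
    if phenotype == "climbing":
        sub = flies if pool_assays else flies[flies.assay == climbing_assay]
        grp = sub.groupby(["ril", "replicate"], sort=True)
        out = grp.agg(successes=("climbed", "sum"), trials=("climbed", "size"))
        return out.reset_index()
    try:
        odor, assay = phenotype.split("_")
    except ValueError:
        raise ValueError(f"unknown phenotype {phenotype!r}") from None
    if odor not in ("OCT", "MCH") or assay not in ("learning", "memory"):
        raise ValueError(f"unknown phenotype {phenotype!r}")
    sub = flies[(flies.trained_odor == odor) & (flies.assay == assay)
                & (flies.climbed == 1)]
    grp = sub.groupby(["ril", "replicate"], sort=True)
    out = grp.agg(successes=("correct", "sum"), trials=("correct", "size"))
    out["successes"] = out.successes.astype(int)
    return out.reset_index()


def _model_arrays(pheno: pd.DataFrame, design: PositionDesign | None):
    rils = pheno.ril.astype(str).to_numpy()
    if design is not None:
        idx = {r: i for i, r in enumerate(design.ril_ids)}
        known = np.array([r in idx for r in rils])
        if not known.all():
            missing = sorted(set(rils[~known]))
            raise ValueError(f"phenotype RILs absent from haplotype map: {missing[:5]}")
    y = pheno.successes.to_numpy(float)
    n = pheno.trials.to_numpy(float)
    ones = np.ones((len(pheno), 1))
    if design is None or design.g.shape[1] == 0:
        X = ones
    else:
        rows = np.array([design.ril_ids.index(r) for r in rils])
        X = np.hstack([ones, design.g[rows]])
    return y, n, X, rils, pheno.replicate.astype(str).to_numpy()


def fit_base(pheno: pd.DataFrame) -> GLMMFit:
    """Intercept-only binomial mixed model for one phenotype table."""
    y, n, X, rils, vials = _model_arrays(pheno, None)
    return fit_binomial_glmm(y, n, X, rils, vials)


def fit_position(design: PositionDesign, pheno: pd.DataFrame,
                 base: GLMMFit | None = None) -> tuple[GLMMFit, GLMMFit, dict]:
    """Base and alternative fits plus the scan-result row at one position."""
    if pheno.ril.nunique() < 2:
        raise ValueError("need >= 2 RILs to fit the mixed model")
    if base is None:
        base = fit_base(pheno)
    if design.n_coef == 0:
        # alternative collapses to the base model
        result = _scan_row(design, base, base)
        return base, base, result
    y, n, X, rils, vials = _model_arrays(pheno, design)
    alt = fit_binomial_glmm(y, n, X, rils, vials, start=base)
    return base, alt, _scan_row(design, base, alt)


def _scan_row(design: PositionDesign, base: GLMMFit, alt: GLMMFit) -> dict:
    converged = base.converged and alt.converged
    if design.n_coef == 0 or design.df == 0:
        lrt, nlp = 0.0, 0.0
    elif not converged:
        lrt, nlp = np.nan, np.nan
    else:
        lrt = max(0.0, 2.0 * (alt.loglik - base.loglik))
        nlp = float(-np.log10(max(stats.chi2.sf(lrt, design.df), 1e-300)))
    return {
        "chrom": design.chromosome, "pos": design.position,
        "n_hap": design.n_hap, "df": design.df, "n_coef": design.n_coef,
        "lrt": lrt, "neg_log10_p": nlp, "converged": converged,
    }


def genome_scan(haps: RILHaplotypeMap, pheno: pd.DataFrame, phenotype: str,
                min_ril_count: int = 4, harbor_threshold: float = 0.5,
                log_every: int | None = None, logger=None) -> pd.DataFrame:
    """Scan every position of the haplotype map for one phenotype.

    Deterministic given its inputs; the base model is fit once and shared.
    Non-converged positions are emitted with missing statistics rather than
    dropped, so multiplicity corrections can count them conservatively.
    """
    common = set(pheno.ril.astype(str)) & set(haps.ril_ids)
    if not common:
        raise ValueError("no RILs shared between haplotype map and phenotype table")
    pheno = pheno[pheno.ril.astype(str).isin(common)]
    base = fit_base(pheno)
    rows = []
    n_converged = 0
    for i, (chrom, pos) in enumerate(zip(haps.positions.chrom, haps.positions.pos)):
        design = build_design(haps, chrom, int(pos), min_ril_count, harbor_threshold)
        _, _, row = fit_position(design, pheno, base=base)
        row["phenotype"] = phenotype
        n_converged += bool(row["converged"])
        rows.append(row)
        if log_every and logger and (i + 1) % log_every == 0:
            logger.info("%s: %d/%d positions scanned, %d converged",
                        phenotype, i + 1, haps.n_positions, n_converged)
    out = pd.DataFrame(rows)
    return out[["chrom", "pos", "phenotype", "n_hap", "df", "n_coef",
                "lrt", "neg_log10_p", "converged"]]


def attach_qvalues(scan: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Add Storey q-values to a scan table.

    Non-converged positions enter the correction as p = 1 (conservative)
    and get missing q in the output.
    """
    p = np.power(10.0, -scan.neg_log10_p.to_numpy(float))
    missing = ~np.isfinite(p)
    p = np.where(missing, 1.0, np.clip(p, 0.0, 1.0))
    q, pi0 = qvalues(p)
    scan = scan.copy()
    scan["q"] = np.where(missing, np.nan, q)
    return scan, pi0


def differential_peaks(scan_a: pd.DataFrame, scan_b: pd.DataFrame,
                       threshold: float = 2.0, k: int = 3,
                       min_separation: int = 10,
                       phenotype: str = "learning") -> pd.DataFrame:
    """Top odor-differential suggestive peaks between two scans.

    d(pos) = |neg_log10_p(A) - neg_log10_p(B)| is computed over the shared
    position grid; positions with d strictly greater than ``threshold`` are
    candidates, and peaks are picked greedily by descending d, suppressing
    candidates within ``min_separation`` index units of an already chosen
    peak on the same chromosome, until ``k`` peaks are found.
    """
    a = scan_a.sort_values(["chrom", "pos"]).reset_index(drop=True)
    b = scan_b.sort_values(["chrom", "pos"]).reset_index(drop=True)
    if len(a) != len(b) or not (
            (a.chrom.to_numpy() == b.chrom.to_numpy()).all()
            and (a.pos.to_numpy() == b.pos.to_numpy()).all()):
        raise ValueError("scans cover different position sets")
    d = np.abs(a.neg_log10_p.to_numpy(float) - b.neg_log10_p.to_numpy(float))
    ok = np.isfinite(d) & (d > threshold)
    cand = a.loc[ok, ["chrom", "pos"]].copy()
    cand["d"] = d[ok]
    cand = cand.sort_values(["d", "chrom", "pos"],
                            ascending=[False, True, True], kind="stable")
    chosen: list[tuple[str, int, float]] = []
    for row in cand.itertuples():
        if any(c == row.chrom and abs(p - row.pos) < min_separation
               for c, p, _ in chosen):
            continue
        chosen.append((row.chrom, int(row.pos), float(row.d)))
        if len(chosen) == k:
            break
    return pd.DataFrame(
        [{"phenotype": phenotype, "rank": i + 1, "chrom": c, "pos": p, "d": dv}
         for i, (c, p, dv) in enumerate(chosen)],
        columns=["phenotype", "rank", "chrom", "pos", "d"])


def haplotype_means(haps: RILHaplotypeMap, pheno_by_odor: dict[str, pd.DataFrame],
                    chromosome: str, position: int,
                    call_threshold: float = 0.5) -> pd.DataFrame:
    """Per-founder mean phenotype proportion at one position, per odor.

    Each RIL is assigned its most probable founder at the position (dropped
    as ambiguous when the maximum probability is below ``call_threshold``);
    per founder and training odor the mean of RIL-level pooled proportions
    is reported with its standard error (sd / sqrt(n_rils)).  Founders with
    no assigned RILs are omitted.
    """
    g = haps.g_at(chromosome, position)
    arg = g.argmax(axis=1)
    ok = g.max(axis=1) >= call_threshold
    call = {r: haps.founders[a] for r, a, keep in zip(haps.ril_ids, arg, ok) if keep}

    rows = []
    for odor, pheno in pheno_by_odor.items():
        per_ril = pheno.groupby("ril", sort=True).agg(
            successes=("successes", "sum"), trials=("trials", "sum"))
        per_ril = per_ril[per_ril.trials > 0]
        per_ril["prop"] = per_ril.successes / per_ril.trials
        per_ril["founder"] = [call.get(str(r)) for r in per_ril.index]
        per_ril = per_ril.dropna(subset=["founder"])
        for founder, grp in per_ril.groupby("founder", sort=True):
            vals = grp.prop.to_numpy(float)
            se = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
            rows.append({
                "chrom": chromosome, "pos": position, "trained_odor": odor,
                "founder": founder, "mean": float(vals.mean()),
                "se": se, "n_rils": len(vals),
            })
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "trained_odor", "founder", "mean", "se", "n_rils"])
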