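"""Extreme-line selection conditional on founder ancestry at prior QTL peaks.

Reproduces the five-step panel-selection procedure used to pick the lines
for the olfactory study from a larger previously phenotyped panel:

1. take peak positions of prior QTLs of interest,
2. call each RIL's founder haplotype at every peak (argmax probability,
   "ambiguous" below a call threshold),
3. convert each RIL's learning and memory scores to empirical-CDF
   percentiles and average them into a cumulative score,
4. split RILs into candidate high / low groups by whether their founder
   calls fall in each peak's high-performing or low-performing founder set,
5. drop RILs with mixed calls (high-set founder at one peak, low-set at
   another) and keep the top / bottom k by cumulative score.

Which founders count as high or low performers at each peak is an input
(derived from the prior study's effect estimates), not recomputed here.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synthetic import RILHaplotypeMap

AMBIGUOUS = "ambiguous"


def ecdf_percentile(values, x: float) -> float:
    """Right-continuous empirical-CDF percentile: fraction of values <= x."""
    values = np.asarray(values, float)
    if values.size == 0:
        raise ValueError("empty value vector")
    return float(np.count_nonzero(values <= x) / values.size)


def cumulative_scores(phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Percentile both phenotypes and average them per RIL.

    ``phenotypes`` has columns ril, learning, memory; output adds
    pct_learning, pct_memory and their mean, the cumulative score.
    """
    for col in ("ril", "learning", "memory"):
        if col not in phenotypes.columns:
            raise ValueError(f"phenotype table missing column {col!r}")
    out = phenotypes.copy()
    learn = out.learning.to_numpy(float)
    mem = out.memory.to_numpy(float)
    out["pct_learning"] = [ecdf_percentile(learn, x) for x in learn]
    out["pct_memory"] = [ecdf_percentile(mem, x) for x in mem]
    out["cumulative"] = (out.pct_learning + out.pct_memory) / 2.0
    return out


def call_peak_haplotypes(haps: RILHaplotypeMap, peaks: pd.DataFrame,
                         call_threshold: float = 0.5) -> pd.DataFrame:
    """Founder haplotype call for every RIL at every peak position.

    The call is the argmax founder of the RIL's probability row; when the
    maximum probability is below ``call_threshold`` the RIL is 'ambiguous'
    at that peak (and will be excluded from selection).
    """
    rows = []
    for peak in peaks.itertuples():
        g = haps.g_at(str(peak.chrom), int(peak.pos))
        arg = g.argmax(axis=1)
        pmax = g.max(axis=1)
        for ril, a, p in zip(haps.ril_ids, arg, pmax):
            rows.append({
                "ril": ril, "peak_id": peak.peak_id,
                "founder": haps.founders[a] if p >= call_threshold else AMBIGUOUS,
                "max_prob": float(p),
            })
    return pd.DataFrame(rows, columns=["ril", "peak_id", "founder", "max_prob"])


def select_rils(scores: pd.DataFrame, calls: pd.DataFrame,
                peaks: pd.DataFrame, k: int) -> tuple[list[str], list[str], pd.DataFrame]:
    """Pick the top/bottom-k extreme RILs with consistent peak haplotypes.

    ``peaks`` defines, per peak_id, comma-separated ``high_founders`` and
    ``low_founders`` sets.  A RIL is a consistent high (low) candidate iff
    its call at *every* peak lies in that peak's high (low) set; ambiguous
    calls, founders in neither set, and mixed high/low RILs are excluded.
    Within each candidate group RILs are ranked by cumulative score, ties
    broken by RIL identifier order.  Returns (high, low, audit) where audit
    carries every RIL's classification.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    sets = {}
    for peak in peaks.itertuples():
        sets[peak.peak_id] = (
            {f.strip() for f in str(peak.high_founders).split(",") if f.strip()},
            {f.strip() for f in str(peak.low_founders).split(",") if f.strip()},
        )
    wide = calls.pivot(index="ril", columns="peak_id", values="founder")
    missing_peaks = set(sets) - set(wide.columns)
    if missing_peaks:
        raise ValueError(f"calls table lacks peaks: {sorted(missing_peaks)}")
    score_by_ril = scores.set_index(scores.ril.astype(str)).cumulative
    missing_scores = set(wide.index.astype(str)) - set(score_by_ril.index)
    if missing_scores:
        raise ValueError(f"no cumulative score for RILs: {sorted(missing_scores)[:5]}")

    audit_rows = []
    for ril, row in wide.iterrows():
        votes = []
        for peak_id, (high, low) in sets.items():
            f = row[peak_id]
            if f in high:
                votes.append("high")
            elif f in low:
                votes.append("low")
            else:
                votes.append("other")
        if all(v == "high" for v in votes):
            group = "high"
        elif all(v == "low" for v in votes):
            group = "low"
        elif "other" in votes:
            group = "excluded"
        else:
            group = "mixed"
        audit_rows.append({
            "ril": str(ril), "group": group,
            "cumulative": float(score_by_ril[str(ril)]),
            **{f"call_{pid}": row[pid] for pid in sets},
        })
    audit = pd.DataFrame(audit_rows)

    def _rank(group: str, top: bool) -> list[str]:
        sub = audit[audit.group == group].sort_values(
            ["cumulative", "ril"], ascending=[not top, True], kind="stable")
        if len(sub) < k:
            raise ValueError(
                f"only {len(sub)} consistent {group}-group RILs, need k={k}")
        return list(sub.ril.head(k))

    high = _rank("high", top=True)
    low = _rank("low", top=False)
    audit["selected"] = audit.ril.isin(high + low)
    return high, low, audit
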