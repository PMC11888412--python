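"""Scores for group-tested y-maze assays.

Flies are assayed in groups: a vial of flies is released into the start
chamber of a y-maze and, after the choice period, every fly is counted in
one of three places — the CS+ arm, the CS- arm, or still in the start
chamber ("no choice").  Two decisions are scored separately:

* climbing — did the fly leave the start chamber at all (locomotion /
  motivation), and
* correctness — given that it climbed, did it pick the sucrose-paired arm.

Keeping the two decision points separate avoids the small-sample inflation
of a single performance index and lets no-choice flies carry information
about activity without contaminating the choice proportion.

The same count layout serves the untrained baseline-preference assay
(arms = OCT / MCH), the odor-acuity assay (arms = odor / odor-free) and the
sucrose-acuity plate (sides = sucrose / plain agar, plus a censored count
for flies touching neither side).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

ASSAYS = ("learning", "memory", "baseline", "odor_acuity", "sugar_acuity")
ODORS = ("OCT", "MCH", "none")


class UndefinedScoreError(ValueError):
    """Raised when a score's denominator is empty (e.g. no climbers)."""


@dataclass(frozen=True)
class ChamberCounts:
    """Terminal chamber counts of one y-maze run (or one acuity plate).

    ``n_plus`` counts flies in the CS+ arm (or focal-odor arm, or sucrose
    side), ``n_minus`` the CS-/alternate/odor-free/plain side, ``n_nc``
    flies that never left the start chamber, and ``n_censored`` flies
    excluded from scoring (sugar-acuity plates only: on the lid, on the
    agar boundary, or not recovered from anesthesia).
    """

    n_plus: int
    n_minus: int
    n_nc: int = 0
    n_censored: int = 0
    ril_id: str = ""
    replicate_id: str = ""
    trained_odor: str = "none"
    assay: str = "learning"

    def __post_init__(self) -> None:
        for name in ("n_plus", "n_minus", "n_nc", "n_censored"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative, got {getattr(self, name)}")
        if self.trained_odor not in ODORS:
            raise ValueError(f"trained_odor must be one of {ODORS}")
        if self.assay not in ASSAYS:
            raise ValueError(f"assay must be one of {ASSAYS}")

    @property
    def total(self) -> int:
        return self.n_plus + self.n_minus + self.n_nc + self.n_censored


@dataclass(frozen=True)
class FlyRecord:
    """One fly's two binomial decision scores.

    ``correct`` is None exactly when the fly did not climb: correctness is
    only defined for flies that entered an odor arm.
    """

    ril_id: str
    replicate_id: str
    trained_odor: str
    assay: str
    climbed: int
    correct: int | None

    def __post_init__(self) -> None:
        if self.climbed not in (0, 1):
            raise ValueError("climbed must be 0 or 1")
        if (self.correct is None) != (self.climbed == 0):
            raise ValueError("correct must be None iff climbed == 0")
        if self.correct is not None and self.correct not in (0, 1):
            raise ValueError("correct must be 0, 1 or None")


@dataclass(frozen=True)
class PlaceTrial:
    """Times (seconds) from one heat-box place learning/memory phase."""

    t_cool: float
    t_hot: float
    t_total: float

    def __post_init__(self) -> None:
        if min(self.t_cool, self.t_hot, self.t_total) < 0:
            raise ValueError("times must be nonnegative")
        if self.t_cool + self.t_hot > self.t_total + 1e-9:
            raise ValueError("t_cool + t_hot may not exceed t_total")


def climbing_score(c: ChamberCounts) -> float:
    """Proportion of flies that left the start chamber for either arm.

    Censored flies (sugar-acuity plates) are outside the assay and excluded
    from both numerator and denominator.
    """
    denom = c.n_plus + c.n_minus + c.n_nc
    if denom == 0:
        raise UndefinedScoreError("no uncensored flies in assay")
    return (c.n_plus + c.n_minus) / denom


def choice_score(c: ChamberCounts) -> float:
    """Proportion of climbers choosing the focal arm.

    This one proportion is the performance score (learning/memory: CS+ of
    climbers), the preference score (baseline: focal odor of climbers) and
    the odor-acuity chamber-selection score (odor arm of climbers).
    No-choice flies never enter the denominator; with zero climbers the
    score is undefined, not 0 and not 0.5.
    """
    denom = c.n_plus + c.n_minus
    if denom == 0:
        raise UndefinedScoreError("no flies entered either arm")
    return c.n_plus / denom


def ppd(performance: float, preference: float) -> float:
    """Preference-performance differential: performance minus preference.

    Both proportions must refer to the same odor the group was trained to.
    Near zero means the trained flies chose about as their untrained
    siblings would — little evidence of conditioning; the farther from
    zero (either sign), the clearer the departure from baseline.
    """
    for name, v in (("performance", performance), ("preference", preference)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    return performance - preference


def classify_override(performance: float, preference: float) -> bool:
    """True iff the group beat chance against its own baseline.

    Strict on both sides: performance > 0.5 and preference < 0.5, i.e. the
    flies picked the sucrose-paired odor even though untrained flies of the
    same genotype prefer the other one.
    """
    return performance > 0.5 and preference < 0.5


def sucrose_acuity(c: ChamberCounts) -> float:
    """Proportion of uncensored flies on the sucrose half of a split plate."""
    denom = c.n_plus + c.n_minus
    if denom == 0:
        raise UndefinedScoreError("all flies censored on sugar-acuity plate")
    return c.n_plus / denom


def place_pi(trial: PlaceTrial) -> float:
    """Heat-box performance index: (t_cool - t_hot) / t_total in [-1, 1].

    +1 is total avoidance of the hot-associated side, -1 total preference
    for it.
    """
    if trial.t_total <= 0:
        raise UndefinedScoreError("t_total must be positive")
    return (trial.t_cool - trial.t_hot) / trial.t_total


def to_fly_records(c: ChamberCounts) -> list[FlyRecord]:
    """Expand chamber counts into individual two-decision fly records."""
    common = dict(
        ril_id=c.ril_id,
        replicate_id=c.replicate_id,
        trained_odor=c.trained_odor,
        assay=c.assay,
    )
    records = [FlyRecord(climbed=0, correct=None, **common) for _ in range(c.n_nc)]
    records += [FlyRecord(climbed=1, correct=0, **common) for _ in range(c.n_minus)]
    records += [FlyRecord(climbed=1, correct=1, **common) for _ in range(c.n_plus)]
    return records


def from_fly_records(records: Iterable[FlyRecord]) -> ChamberCounts:
    """Re-aggregate fly records from one run back into chamber counts.

    Exact inverse of :func:`to_fly_records` (censored flies are never
    expanded, so the round trip holds for n_censored = 0).
    """
    records = list(records)
    if not records:
        raise ValueError("no records to aggregate")
    labels = {(r.ril_id, r.replicate_id, r.trained_odor, r.assay) for r in records}
    if len(labels) > 1:
        raise ValueError("records from more than one run")
    ril, rep, odor, assay = next(iter(labels))
    n_nc = sum(1 for r in records if r.climbed == 0)
    n_minus = sum(1 for r in records if r.correct == 0)
    n_plus = sum(1 for r in records if r.correct == 1)
    return ChamberCounts(
        n_plus=n_plus, n_minus=n_minus, n_nc=n_nc, n_censored=0,
        ril_id=ril, replicate_id=rep, trained_odor=odor, assay=assay,
    )


def pool_counts(counts: Iterable[ChamberCounts]) -> ChamberCounts:
    """Sum counts across replicates of one (RIL, odor, assay) cell.

    Pooled (fly-weighted) proportions are the default summary level: the
    pooled choice score equals the climber-weighted mean of replicate
    scores, so small vials cannot inflate a line's score the way a mean of
    per-replicate proportions would.
    """
    counts = list(counts)
    if not counts:
        raise ValueError("nothing to pool")
    keys = {(c.ril_id, c.trained_odor, c.assay) for c in counts}
    if len(keys) > 1:
        raise ValueError(f"cannot pool across cells: {sorted(keys)}")
    first = counts[0]
    return replace(
        first,
        n_plus=sum(c.n_plus for c in counts),
        n_minus=sum(c.n_minus for c in counts),
        n_nc=sum(c.n_nc for c in counts),
        n_censored=sum(c.n_censored for c in counts),
        replicate_id="pooled",
    )


# ---------------------------------------------------------------------------
# Tabular interface: counts DataFrame -> per-RIL score table


COUNT_COLUMNS = [
    "ril", "replicate", "trained_odor", "assay",
    "n_plus", "n_minus", "n_nc", "n_censored",
]


def counts_to_frame(counts: Iterable[ChamberCounts]) -> pd.DataFrame:
    rows = [
        {
            "ril": c.ril_id, "replicate": c.replicate_id,
            "trained_odor": c.trained_odor, "assay": c.assay,
            "n_plus": c.n_plus, "n_minus": c.n_minus,
            "n_nc": c.n_nc, "n_censored": c.n_censored,
        }
        for c in counts
    ]
    return pd.DataFrame(rows, columns=COUNT_COLUMNS)


def frame_to_counts(frame: pd.DataFrame) -> list[ChamberCounts]:
    missing = [c for c in COUNT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"counts table missing columns: {missing}")
    return [
        ChamberCounts(
            n_plus=int(r.n_plus), n_minus=int(r.n_minus),
            n_nc=int(r.n_nc), n_censored=int(r.n_censored),
            ril_id=str(r.ril), replicate_id=str(r.replicate),
            trained_odor=str(r.trained_odor), assay=str(r.assay),
        )
        for r in frame.itertuples()
    ]


def score_table(counts: pd.DataFrame, pooled: bool = True) -> pd.DataFrame:
    """Per-(ril, assay, trained_odor) score set from a counts table.

    With ``pooled`` (default) replicate counts are summed before scoring;
    otherwise replicate proportions are averaged.  Learning/memory rows get
    a PPD and override flag against the same RIL's baseline preference for
    the trained odor; baseline counts are stored with OCT in ``n_plus``, so
    the MCH-trained preference is the complement.
    """
    cells = []
    group_cols = ["ril", "assay", "trained_odor"]
    for (ril, assay, odor), grp in counts.groupby(group_cols, sort=True):
        reps = frame_to_counts(grp)
        if pooled:
            pooledc = pool_counts(reps)
            climb = _safe(climbing_score, pooledc)
            choice = _safe(choice_score, pooledc)
        else:
            climbs = [_safe(climbing_score, c) for c in reps]
            choices = [_safe(choice_score, c) for c in reps]
            climb = float(np.mean([v for v in climbs if v is not None])) if any(
                v is not None for v in climbs) else None
            choice = float(np.mean([v for v in choices if v is not None])) if any(
                v is not None for v in choices) else None
        cells.append({
            "ril": ril, "assay": assay, "trained_odor": odor,
            "n_total": int(grp[["n_plus", "n_minus", "n_nc", "n_censored"]].sum().sum()),
            "n_climbers": int(grp.n_plus.sum() + grp.n_minus.sum()),
            "climbing_score": climb,
            "choice_score": choice,
        })
    out = pd.DataFrame(cells)

    # baseline preference for the trained odor: OCT focal stored, MCH = 1 - OCT
    base = out[out.assay == "baseline"].set_index("ril").choice_score
    def _pref(row):
        if row.assay not in ("learning", "memory") or row.ril not in base.index:
            return np.nan
        p = base.loc[row.ril]
        if p is None or np.isnan(p):
            return np.nan
        return p if row.trained_odor == "OCT" else 1.0 - p

    out["preference_score"] = out.apply(_pref, axis=1)
    perf = out.choice_score.astype(float)
    out["ppd"] = np.where(
        out.preference_score.notna() & perf.notna(),
        perf - out.preference_score, np.nan)
    out["override"] = (perf > 0.5) & (out.preference_score < 0.5)
    return out


def _safe(fn, c):
    try:
        return fn(c)
    except UndefinedScoreError:
        return None


def summarize_rils(scores: pd.DataFrame) -> dict:
    """Study-level summary: per-phenotype mean/min/max and override tallies.

    Override tallies split RILs into learning-only / memory-only / both,
    per trained odor (the both-count holds RILs overriding in the learning
    AND the memory assay for that odor).
    """
    summary: dict = {"phenotypes": {}, "override": {}}
    for (assay, odor), grp in scores.groupby(["assay", "trained_odor"]):
        vals = grp.choice_score.dropna().astype(float)
        if vals.empty:
            continue
        summary["phenotypes"][f"{odor}_{assay}" if odor != "none" else assay] = {
            "mean": float(vals.mean()),
            "min": float(vals.min()),
            "max": float(vals.max()),
            "n_rils": int(vals.size),
        }
    for odor in ("OCT", "MCH"):
        learn = set(scores.ril[(scores.assay == "learning")
                               & (scores.trained_odor == odor) & scores.override])
        mem = set(scores.ril[(scores.assay == "memory")
                             & (scores.trained_odor == odor) & scores.override])
        summary["override"][odor] = {
            "learning_only": len(learn - mem),
            "memory_only": len(mem - learn),
            "both": len(learn & mem),
        }
    return summary
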