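"""Synthetic DSPR-like study generator with known ground truth.

Emulates the data a group-tested olfactory conditioning study of an
8-founder multiparent RIL panel produces, so the whole scoring / selection /
genome-scan pipeline can be exercised end to end without the deposited raw
data:

* founder-mosaic haplotype probabilities per RIL and genomic position
  (first-order Markov mosaic, optionally softened away from hard calls the
  way HMM-inferred ancestry probabilities are near- but not exactly certain);
* fly-level Bernoulli outcomes for the two y-maze decision points (climbing,
  then correctness), with RIL and vial random intercepts on the logit scale
  and planted founder-haplotype effects that may apply to only one training
  odor or phenotype;
* untrained baseline-preference, odor-acuity and sucrose-acuity count tables.

All randomness flows from a single integer seed through independent,
documented streams (haplotypes, outcomes, acuity), so repeated calls with
the same config are byte-identical and the three generators can be used in
any combination.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

N_FOUNDERS = 8
DEFAULT_FOUNDERS = tuple(f"A{i}" for i in range(1, 9))

_STREAM_HAPLOTYPES = 1
_STREAM_OUTCOMES = 2
_STREAM_ACUITY = 3


@dataclass(frozen=True)
class FounderPanel:
    """The founder set and marker grid of a multiparent RIL panel."""

    founder_ids: tuple[str, ...] = DEFAULT_FOUNDERS
    chromosomes: tuple[tuple[str, int], ...] = (("X", 100), ("2", 200), ("3", 200))
    position_spacing: float = 1.0  # map-distance units between adjacent positions

    def __post_init__(self) -> None:
        if len(self.founder_ids) != N_FOUNDERS:
            raise ValueError(f"exactly {N_FOUNDERS} founders required")
        if len(set(self.founder_ids)) != N_FOUNDERS:
            raise ValueError("founder ids must be unique")
        for name, n in self.chromosomes:
            if n < 1:
                raise ValueError(f"chromosome {name} needs >= 1 position")

    @property
    def n_positions(self) -> int:
        return sum(n for _, n in self.chromosomes)


@dataclass(frozen=True)
class QTLEffectSpec:
    """A planted additive founder effect at one scan position.

    ``effects`` maps every founder label to a logit-scale effect (zeros
    allowed); a fly's linear predictor gains ``sum_j g_ij * effect_j`` where
    g_ij is its RIL's founder probability at the position.  ``odor_scope``
    restricts the effect to flies trained to one odor; ``phenotype_scope``
    selects which decision it acts on.
    """

    chromosome: str
    position_index: int
    effects: dict[str, float]
    odor_scope: str = "both"  # both | OCT_only | MCH_only
    phenotype_scope: str = "learning"  # learning | memory | climbing

    def __post_init__(self) -> None:
        if self.odor_scope not in ("both", "OCT_only", "MCH_only"):
            raise ValueError(f"bad odor_scope {self.odor_scope!r}")
        if self.phenotype_scope not in ("learning", "memory", "climbing"):
            raise ValueError(f"bad phenotype_scope {self.phenotype_scope!r}")

    def applies_to_odor(self, odor: str) -> bool:
        return self.odor_scope == "both" or self.odor_scope == f"{odor}_only"


@dataclass(frozen=True)
class SimStudyConfig:
    """Study-design knobs for the synthetic generators.

    Defaults mirror the group-tested olfactory study design: 50 RILs, vials
    of 60-80 flies, three replicate vials per RIL per training odor, modest
    line and vial heterogeneity on the logit scale, chance-level baseline
    correctness and climbing, near-certain softened founder calls, and a
    mosaic with a handful of ancestry switches per chromosome.
    """

    n_rils: int = 50
    flies_per_vial: tuple[int, int] = (60, 80)
    n_replicates: int = 3  # vials per RIL per trained odor
    sd_ril: float = 0.3
    sd_replicate: float = 0.2
    baseline_correct_logit: float = 0.0
    baseline_climb_logit: float = 0.0
    recomb_prob: float = 0.02  # per-interval prob of redrawing founder ancestry
    soft_prob_noise: float | None = 50.0  # Dirichlet concentration; None = hard calls
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rils < 1:
            raise ValueError("n_rils must be >= 1")
        if self.flies_per_vial[0] < 1 or self.flies_per_vial[1] < self.flies_per_vial[0]:
            raise ValueError("flies_per_vial must be a (min, max) range with min >= 1")
        if self.sd_ril < 0 or self.sd_replicate < 0:
            raise ValueError("random-effect SDs must be >= 0")
        if not 0.0 <= self.recomb_prob <= 1.0:
            raise ValueError("recomb_prob must be in [0, 1]")
        if self.soft_prob_noise is not None and self.soft_prob_noise < 0:
            raise ValueError("soft_prob_noise concentration must be >= 0")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([stream, self.seed])


class RILHaplotypeMap:
    """Per-position 8-founder ancestry probabilities for a RIL panel.

    Stores a dense (n_rils, n_positions, 8) probability array plus RIL ids
    and a position table (chromosome, index within chromosome).  Rows are
    probability vectors over founders and sum to 1.
    """

    def __init__(self, probs: np.ndarray, ril_ids: list[str],
                 positions: pd.DataFrame, founders: tuple[str, ...] = DEFAULT_FOUNDERS):
        probs = np.asarray(probs, dtype=float)
        if probs.ndim != 3 or probs.shape[2] != N_FOUNDERS:
            raise ValueError("probs must have shape (n_rils, n_positions, 8)")
        if probs.shape[0] != len(ril_ids) or probs.shape[1] != len(positions):
            raise ValueError("probs shape inconsistent with ids/positions")
        if (probs < -1e-12).any():
            raise ValueError("negative founder probabilities")
        sums = probs.sum(axis=2)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("founder probabilities must sum to 1 at every position")
        self.probs = probs
        self.ril_ids = list(ril_ids)
        self.positions = positions.reset_index(drop=True)
        self.founders = tuple(founders)

    @property
    def n_rils(self) -> int:
        return self.probs.shape[0]

    @property
    def n_positions(self) -> int:
        return self.probs.shape[1]

    def position_index(self, chromosome: str, index: int) -> int:
        hit = self.positions.index[
            (self.positions.chrom == chromosome) & (self.positions.pos == index)]
        if len(hit) == 0:
            raise KeyError(f"position ({chromosome}, {index}) not in map")
        return int(hit[0])

    def g_at(self, chromosome: str, index: int) -> np.ndarray:
        """(n_rils, 8) founder probabilities at one position."""
        return self.probs[:, self.position_index(chromosome, index), :]

    def to_frame(self) -> pd.DataFrame:
        """Long table: one row per (ril, position) with p_<founder> columns."""
        n_r, n_p = self.n_rils, self.n_positions
        out = pd.DataFrame({
            "ril": np.repeat(self.ril_ids, n_p),
            "chrom": np.tile(self.positions.chrom.to_numpy(), n_r),
            "pos": np.tile(self.positions.pos.to_numpy(), n_r),
        })
        flat = self.probs.reshape(n_r * n_p, N_FOUNDERS)
        for j, f in enumerate(self.founders):
            out[f"p_{f}"] = flat[:, j]
        return out

    @classmethod
    def from_frame(cls, frame: pd.DataFrame,
                   founders: tuple[str, ...] = DEFAULT_FOUNDERS) -> "RILHaplotypeMap":
        cols = [f"p_{f}" for f in founders]
        missing = [c for c in ["ril", "chrom", "pos", *cols] if c not in frame.columns]
        if missing:
            raise ValueError(f"haplotype table missing columns: {missing}")
        frame = frame.copy()
        frame["chrom"] = frame.chrom.astype(str)
        ril_ids = list(pd.unique(frame.ril.astype(str)))
        positions = frame[["chrom", "pos"]].drop_duplicates().reset_index(drop=True)
        n_r, n_p = len(ril_ids), len(positions)
        if len(frame) != n_r * n_p:
            raise ValueError("haplotype table is not a complete ril x position grid")
        frame = frame.sort_values(
            ["ril", "chrom", "pos"],
            key=lambda s: s.map({v: i for i, v in enumerate(pd.unique(s))})
            if s.name in ("ril",) else s)
        order = positions.sort_values(["chrom", "pos"]).index
        # rebuild in the stored position order
        pos_key = {(c, p): i for i, (c, p) in enumerate(zip(positions.chrom, positions.pos))}
        probs = np.empty((n_r, n_p, N_FOUNDERS))
        ril_key = {r: i for i, r in enumerate(ril_ids)}
        ri = frame.ril.astype(str).map(ril_key).to_numpy()
        pi = [pos_key[(c, p)] for c, p in zip(frame.chrom, frame.pos)]
        probs[ri, pi, :] = frame[cols].to_numpy()
        return cls(probs, ril_ids, positions, founders)


def simulate_ril_haplotypes(panel: FounderPanel, config: SimStudyConfig) -> RILHaplotypeMap:
    """Simulate founder-mosaic ancestry probabilities for a RIL panel.

    Each RIL's genome is a first-order Markov mosaic: ancestry at the first
    position of each chromosome is uniform over the 8 founders, and at each
    interval the founder is redrawn uniformly (from all 8) with probability
    ``recomb_prob`` — a symmetric chain whose stationary distribution is
    uniform, so per-position founder frequencies are 1/8 in expectation at
    any recombination rate.  ``recomb_prob=1`` makes positions independent;
    an actual ancestry *switch* occurs with probability ``7/8 * recomb_prob``.

    Hard one-hot calls are then optionally softened by mixing each row with
    a flat Dirichlet draw at weight ``1 / (soft_prob_noise + 1)``, emulating
    near-certain HMM ancestry probabilities.
    """
    rng = config.rng(_STREAM_HAPLOTYPES)
    n_r = config.n_rils
    founders = np.empty((n_r, panel.n_positions), dtype=np.int64)
    col = 0
    for _, n_pos in panel.chromosomes:
        state = rng.integers(0, N_FOUNDERS, size=n_r)
        founders[:, col] = state
        for j in range(1, n_pos):
            redraw = rng.random(n_r) < config.recomb_prob
            proposal = rng.integers(0, N_FOUNDERS, size=n_r)
            state = np.where(redraw, proposal, state)
            founders[:, col + j] = state
        col += n_pos

    probs = np.zeros((n_r, panel.n_positions, N_FOUNDERS))
    np.put_along_axis(probs, founders[:, :, None], 1.0, axis=2)

    if config.soft_prob_noise is not None and config.soft_prob_noise > 0:
        c = config.soft_prob_noise
        noise = rng.dirichlet(np.ones(N_FOUNDERS), size=(n_r, panel.n_positions))
        probs = (c * probs + noise) / (c + 1.0)

    positions = pd.DataFrame({
        "chrom": np.concatenate([[name] * n for name, n in panel.chromosomes]),
        "pos": np.concatenate([np.arange(n) for _, n in panel.chromosomes]),
    })
    ril_ids = [f"RIL{i + 1:03d}" for i in range(n_r)]
    return RILHaplotypeMap(probs, ril_ids, positions, panel.founder_ids)


def _effect_offsets(haps: RILHaplotypeMap, effects: list[QTLEffectSpec],
                    phenotype: str, odor: str) -> np.ndarray:
    """Per-RIL logit offsets from planted effects active for (phenotype, odor)."""
    out = np.zeros(haps.n_rils)
    for eff in effects:
        if eff.phenotype_scope != phenotype or not eff.applies_to_odor(odor):
            continue
        unknown = set(eff.effects) - set(haps.founders)
        if unknown:
            raise ValueError(f"unknown founder labels in effect: {sorted(unknown)}")
        g = haps.g_at(eff.chromosome, eff.position_index)
        evec = np.array([eff.effects.get(f, 0.0) for f in haps.founders])
        out += g @ evec
    return out


def _invlogit(x: np.ndarray) -> np.ndarray:
    from scipy.special import expit
    return expit(x)


def simulate_fly_outcomes(haps: RILHaplotypeMap, effects: list[QTLEffectSpec],
                          config: SimStudyConfig) -> tuple[pd.DataFrame, dict]:
    """Simulate fly-level two-decision outcomes for the conditioning study.

    Every RIL is tested in ``n_replicates`` vials per training odor with
    uniformly drawn vial sizes.  Per fly:

    * ``climbed ~ Bernoulli(invlogit(b0_climb + a_ril + b_vial + climbing effects))``
    * climbers get ``correct ~ Bernoulli(invlogit(b0_corr + a'_ril + b'_vial
      + learning effects))`` in the learning assay;
    * flies that chose CS+ at learning are re-tested for memory 4 h later:
      they climb again under the same climbing predictor and, if they climb,
      score ``correct`` under the memory-scope effects.

    RIL intercepts (separate for climbing and correctness) are drawn once
    per RIL with SD ``sd_ril``; vial intercepts once per vial with SD
    ``sd_replicate``.  Returns the per-fly table and a ground-truth dict
    holding the drawn intercepts and the planted effects.
    """
    for eff in effects:
        haps.position_index(eff.chromosome, eff.position_index)  # validates
        unknown = set(eff.effects) - set(haps.founders)
        if unknown:
            raise ValueError(f"unknown founder labels in effect: {sorted(unknown)}")

    rng = config.rng(_STREAM_OUTCOMES)
    n_r = haps.n_rils
    a_climb = rng.normal(0.0, config.sd_ril, size=n_r)
    a_corr = rng.normal(0.0, config.sd_ril, size=n_r)

    rows = []
    truth_vials = []
    lo, hi = config.flies_per_vial
    for i, ril in enumerate(haps.ril_ids):
        for odor in ("OCT", "MCH"):
            off_climb = _effect_offsets(haps, effects, "climbing", odor)[i]
            off_learn = _effect_offsets(haps, effects, "learning", odor)[i]
            off_mem = _effect_offsets(haps, effects, "memory", odor)[i]
            for rep in range(1, config.n_replicates + 1):
                vial = f"{ril}_{odor}_r{rep}"
                b_climb = rng.normal(0.0, config.sd_replicate)
                b_corr = rng.normal(0.0, config.sd_replicate)
                n_flies = int(rng.integers(lo, hi + 1))
                truth_vials.append({
                    "ril": ril, "replicate": vial, "trained_odor": odor,
                    "b_climb": b_climb, "b_correct": b_corr, "n_flies": n_flies,
                })
                p_climb = _invlogit(config.baseline_climb_logit
                                    + a_climb[i] + b_climb + off_climb)
                p_learn = _invlogit(config.baseline_correct_logit
                                    + a_corr[i] + b_corr + off_learn)
                p_mem = _invlogit(config.baseline_correct_logit
                                  + a_corr[i] + b_corr + off_mem)
                climbed = rng.random(n_flies) < p_climb
                correct = np.where(climbed, rng.random(n_flies) < p_learn, False)
                for c, corr in zip(climbed, correct):
                    rows.append((ril, vial, odor, "learning",
                                 int(c), int(corr) if c else None))
                # memory retest of learning CS+ choosers
                n_retest = int(correct.sum())
                m_climbed = rng.random(n_retest) < p_climb
                m_correct = np.where(m_climbed, rng.random(n_retest) < p_mem, False)
                for c, corr in zip(m_climbed, m_correct):
                    rows.append((ril, vial, odor, "memory",
                                 int(c), int(corr) if c else None))

    flies = pd.DataFrame(
        rows, columns=["ril", "replicate", "trained_odor", "assay", "climbed", "correct"])
    flies["correct"] = flies.correct.astype("Int64")
    truth = {
        "ril_intercepts": pd.DataFrame({
            "ril": haps.ril_ids, "a_climb": a_climb, "a_correct": a_corr}),
        "vial_intercepts": pd.DataFrame(truth_vials),
        "effects": effects_to_frame(effects),
    }
    return flies, truth


def effects_to_frame(effects: list[QTLEffectSpec]) -> pd.DataFrame:
    """Ground-truth sidecar table: one row per (effect position, founder)."""
    rows = []
    for eff in effects:
        for founder, value in eff.effects.items():
            rows.append({
                "chrom": eff.chromosome, "pos": eff.position_index,
                "founder": founder, "effect": value,
                "odor_scope": eff.odor_scope, "phenotype_scope": eff.phenotype_scope,
            })
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "founder", "effect", "odor_scope", "phenotype_scope"])


def simulate_acuity_and_preference(
        haps: RILHaplotypeMap, config: SimStudyConfig,
        pref_beta: tuple[float, float] = (12.0, 12.0),
        odor_acuity_beta: tuple[float, float] = (6.0, 6.0),
        sugar_acuity_beta: tuple[float, float] = (9.0, 6.0),
        censor_prob: float = 0.1) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate untrained baseline-preference and acuity count tables.

    Per RIL, latent proportions are drawn once from Beta distributions
    (defaults centred near the neutral 0.5 for OCT-vs-MCH preference and
    odor acuity, and above 0.5 for sucrose acuity of starved flies) and
    counts drawn binomially around them for each replicate.  Baseline and
    odor-acuity runs include a no-choice count via the climbing predictor;
    sugar-acuity plates include a censored count (lid / boundary flies),
    present in the schema even when zero.

    Returns ``(counts, latents)`` where counts follows the chamber-count
    table schema (baseline rows store the OCT arm in ``n_plus``).
    """
    rng = config.rng(_STREAM_ACUITY)
    lo, hi = config.flies_per_vial
    a_climb = rng.normal(0.0, config.sd_ril, size=haps.n_rils)

    latents = pd.DataFrame({
        "ril": haps.ril_ids,
        "pref_oct": rng.beta(*pref_beta, size=haps.n_rils),
        "acuity_oct": rng.beta(*odor_acuity_beta, size=haps.n_rils),
        "acuity_mch": rng.beta(*odor_acuity_beta, size=haps.n_rils),
        "acuity_sugar": rng.beta(*sugar_acuity_beta, size=haps.n_rils),
    })

    rows = []
    for i, ril in enumerate(haps.ril_ids):
        p_climb = _invlogit(config.baseline_climb_logit + a_climb[i])
        for rep in range(1, config.n_replicates + 1):
            # untrained OCT-vs-MCH preference
            n = int(rng.integers(lo, hi + 1))
            climbers = rng.binomial(n, p_climb)
            n_oct = rng.binomial(climbers, latents.pref_oct[i])
            rows.append((ril, f"{ril}_base_r{rep}", "none", "baseline",
                         n_oct, climbers - n_oct, n - climbers, 0))
            # odor vs odor-free arm, one run per odor
            for odor, p_ac in (("OCT", latents.acuity_oct[i]),
                               ("MCH", latents.acuity_mch[i])):
                n = int(rng.integers(lo, hi + 1))
                climbers = rng.binomial(n, p_climb)
                n_odor = rng.binomial(climbers, p_ac)
                rows.append((ril, f"{ril}_ac{odor}_r{rep}", odor, "odor_acuity",
                             n_odor, climbers - n_odor, n - climbers, 0))
            # split sucrose plate with censoring
            n = int(rng.integers(lo, hi + 1))
            censored = rng.binomial(n, censor_prob)
            on_sugar = rng.binomial(n - censored, latents.acuity_sugar[i])
            rows.append((ril, f"{ril}_sugar_r{rep}", "none", "sugar_acuity",
                         on_sugar, n - censored - on_sugar, 0, censored))

    counts = pd.DataFrame(rows, columns=[
        "ril", "replicate", "trained_odor", "assay",
        "n_plus", "n_minus", "n_nc", "n_censored"])
    return counts, latents
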