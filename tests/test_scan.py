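"""Genome-scan surfaces: drop rule, determinism, peaks, haplotype means."""

import numpy as np
import pandas as pd
import pytest

from ymazeqtl import (FounderPanel, SimStudyConfig, build_design,
                      differential_peaks, genome_scan, haplotype_means,
                      phenotype_table, simulate_fly_outcomes,
                      simulate_ril_haplotypes)
from ymazeqtl.synthetic import RILHaplotypeMap


def _hard_map(assignments):
    """RILHaplotypeMap from an (n_ril, n_pos) founder-index array."""
    a = np.asarray(assignments)
    probs = np.zeros((*a.shape, 8))
    np.put_along_axis(probs, a[:, :, None], 1.0, axis=2)
    positions = pd.DataFrame({"chrom": ["2"] * a.shape[1],
                              "pos": list(range(a.shape[1]))})
    return RILHaplotypeMap(probs, [f"r{i}" for i in range(a.shape[0])], positions)


def test_four_ril_drop_rule_boundary():
    # founder 1 carried by exactly 3 RILs at pos 0, exactly 4 at pos 1
    a = np.zeros((12, 2), dtype=int)
    a[:3, 0] = 1
    a[:4, 1] = 1
    haps = _hard_map(a)
    d0 = build_design(haps, "2", 0, min_ril_count=4)
    assert "A2" not in d0.included_founders  # index 1 -> label A2
    d1 = build_design(haps, "2", 1, min_ril_count=4)
    assert "A2" in d1.included_founders


def test_all_founders_included_when_common():
    a = np.tile(np.arange(8), (5, 1)).T.reshape(8, 5).repeat(4, axis=0)  # 32 RILs
    haps = _hard_map(a)
    d = build_design(haps, "2", 0, min_ril_count=4)
    assert d.n_hap == 8 and d.df == 8
    # hard one-hot rows sum to 1 -> drop-reference estimation
    assert d.reference_founder is not None and d.n_coef == 7


def test_design_counts_with_soft_probabilities():
    rng = np.random.default_rng(0)
    probs = rng.dirichlet(np.full(8, 0.3), size=(20, 1))
    positions = pd.DataFrame({"chrom": ["2"], "pos": [0]})
    haps = RILHaplotypeMap(probs, [f"r{i}" for i in range(20)], positions)
    d = build_design(haps, "2", 0, min_ril_count=1, harbor_threshold=0.5)
    carried = (probs[:, 0, :] > 0.5).sum(axis=0)
    assert d.n_hap == (carried >= 1).sum()


def test_missing_position_raises():
    haps = _hard_map(np.zeros((6, 2), dtype=int))
    with pytest.raises(KeyError):
        build_design(haps, "2", 99)


@pytest.fixture(scope="module")
def planted_scan(small_study):
    haps, flies = small_study["haps"], small_study["flies"]
    pheno = phenotype_table(flies, "OCT_learning")
    scan = genome_scan(haps, pheno, "OCT_learning")
    return haps, flies, pheno, scan


def test_scan_shape_and_determinism(planted_scan, small_study):
    haps, flies, pheno, scan = planted_scan
    assert len(scan) == haps.n_positions
    again = genome_scan(haps, pheno, "OCT_learning")
    pd.testing.assert_frame_equal(scan, again)


def test_scan_invariant_to_ril_row_order(planted_scan):
    haps, flies, pheno, scan = planted_scan
    shuffled = pheno.sample(frac=1.0, random_state=1).reset_index(drop=True)
    again = genome_scan(haps, shuffled, "OCT_learning")
    assert np.allclose(scan.lrt.to_numpy(), again.lrt.to_numpy(), atol=1e-6)


def test_planted_effect_detected_and_permutation_breaks_it(planted_scan):
    haps, flies, pheno, scan = planted_scan
    top = scan.loc[scan.neg_log10_p.idxmax()]
    assert abs(int(top.pos) - 20) <= 3
    assert top.neg_log10_p > 3.0
    # permuting RIL labels destroys genotype-phenotype linkage
    perm = pheno.copy()
    rils = perm.ril.unique()
    mapping = dict(zip(rils, np.random.default_rng(3).permutation(rils)))
    perm["ril"] = perm.ril.map(mapping)
    null_scan = genome_scan(haps, perm, "OCT_learning")
    assert null_scan.neg_log10_p.max() < scan.neg_log10_p.max()


def test_scan_rejects_disjoint_rils(planted_scan):
    haps, flies, pheno, _ = planted_scan
    renamed = pheno.copy()
    renamed["ril"] = "X" + renamed.ril.astype(str)
    with pytest.raises(ValueError, match="no RILs shared"):
        genome_scan(haps, renamed, "OCT_learning")


# ---------------------------------------------------------------------------
# differential peaks


def _scan_frame(d_values):
    pos = list(range(len(d_values)))
    a = pd.DataFrame({"chrom": "2", "pos": pos, "neg_log10_p": d_values})
    b = pd.DataFrame({"chrom": "2", "pos": pos, "neg_log10_p": 0.0})
    return a, b


def test_differential_threshold_is_strict():
    d = np.zeros(130)
    d[10], d[50], d[90], d[120] = 3.0, 2.5, 2.1, 1.9
    a, b = _scan_frame(d)
    peaks = differential_peaks(a, b, threshold=2.0, k=3, min_separation=10)
    assert peaks.pos.tolist() == [10, 50, 90]
    assert peaks["rank"].tolist() == [1, 2, 3]
    # exactly 2.0 is excluded
    d2 = np.zeros(30); d2[5] = 2.0; d2[20] = 2.1
    a2, b2 = _scan_frame(d2)
    p2 = differential_peaks(a2, b2, threshold=2.0, k=3, min_separation=3)
    assert p2.pos.tolist() == [20]


def _greedy_oracle(d, threshold, k, sep):
    left = [(dv, i) for i, dv in enumerate(d) if dv > threshold]
    chosen = []
    for dv, i in sorted(left, key=lambda t: (-t[0], t[1])):
        if all(abs(i - j) >= sep for _, j in chosen):
            chosen.append((dv, i))
        if len(chosen) == k:
            break
    return [i for _, i in chosen]


def test_adjacent_peaks_suppressed_matches_oracle():
    rng = np.random.default_rng(4)
    for _ in range(25):
        d = rng.random(100) * 4
        a, b = _scan_frame(d)
        peaks = differential_peaks(a, b, threshold=2.0, k=3, min_separation=10)
        assert peaks.pos.tolist() == _greedy_oracle(d, 2.0, 3, 10)


def test_differential_requires_matching_positions():
    a, b = _scan_frame(np.zeros(10))
    with pytest.raises(ValueError, match="different position"):
        differential_peaks(a, b.iloc[:-1], threshold=2.0)


# ---------------------------------------------------------------------------
# haplotype means


def test_haplotype_means_single_founder_degenerate():
    haps = _hard_map(np.zeros((5, 1), dtype=int))  # everyone A1
    pheno = pd.DataFrame({"ril": [f"r{i}" for i in range(5)],
                          "replicate": "v1", "successes": 6, "trials": 10})
    out = haplotype_means(haps, {"OCT": pheno}, "2", 0)
    assert len(out) == 1
    assert out.iloc[0]["mean"] == pytest.approx(0.6)
    assert out.iloc[0].se == pytest.approx(0.0)
    assert out.iloc[0].n_rils == 5


def test_haplotype_means_odor_specific_effect(small_study):
    haps, flies = small_study["haps"], small_study["flies"]
    pheno_by_odor = {o: phenotype_table(flies, f"{o}_learning") for o in ("OCT", "MCH")}
    means = haplotype_means(haps, pheno_by_odor, "2", 20)
    oct_m = means[means.trained_odor == "OCT"].set_index("founder")
    mch_m = means[means.trained_odor == "MCH"].set_index("founder")
    others = [f for f in oct_m.index if f != "A1"]
    assert "A1" in oct_m.index
    # planted OCT-only +2 on A1: carriers beat every other founder by > 2 SE
    for f in others:
        gap = oct_m.loc["A1", "mean"] - oct_m.loc[f, "mean"]
        se = np.hypot(oct_m.loc["A1", "se"], oct_m.loc[f, "se"])
        assert gap > 2 * se
    # MCH-trained panel shows no such dominance of A1
    mch_gap = mch_m.loc["A1", "mean"] - mch_m.loc[[f for f in others
                                                   if f in mch_m.index], "mean"].max()
    assert mch_gap < oct_m.loc["A1", "mean"] - oct_m.loc[others, "mean"].max()
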