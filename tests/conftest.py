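import numpy as np
import pytest

from ymazeqtl import (FounderPanel, QTLEffectSpec, SimStudyConfig,
                      simulate_fly_outcomes, simulate_ril_haplotypes)


def effect(chrom, pos, founder, value, odor_scope="both", phenotype_scope="learning"):
    """QTLEffectSpec with zeros for the other seven founders."""
    from ymazeqtl.synthetic import DEFAULT_FOUNDERS
    return QTLEffectSpec(chrom, pos,
                         {f: (value if f == founder else 0.0) for f in DEFAULT_FOUNDERS},
                         odor_scope, phenotype_scope)


@pytest.fixture(scope="session")
def small_study():
    """A compact seeded study shared by scan-level tests: 48 RILs, one
    40-position chromosome, a planted +2 OCT-learning effect on A1 (which
    enough lines carry at the planted position for its design column to
    survive the 4-RIL drop rule)."""
    panel = FounderPanel(chromosomes=(("2", 40),))
    cfg = SimStudyConfig(n_rils=48, flies_per_vial=(50, 60), n_replicates=3,
                         recomb_prob=0.2, seed=42)
    haps = simulate_ril_haplotypes(panel, cfg)
    effects = [effect("2", 20, "A1", 2.0, odor_scope="OCT_only")]
    flies, truth = simulate_fly_outcomes(haps, effects, cfg)
    return {"panel": panel, "config": cfg, "haps": haps,
            "effects": effects, "flies": flies, "truth": truth}
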