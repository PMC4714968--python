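import numpy as np
import pandas as pd
import pytest

from ibdpheno import (GenotypeMatrix, PhenotypeTable, SimulationConfig,
                      Variant, simulate_cohort)


@pytest.fixture(scope="session")
def small_cohort():
    """A 4000-sample default-structure cohort shared across read-only tests."""
    cfg = SimulationConfig(n_samples=4000, seed=42)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def clean_cohort():
    """No missingness, no misdiagnosis: every phenotype invariant must hold."""
    cfg = SimulationConfig(n_samples=3000, seed=7, missing_rates={},
                           misdiagnosis_rate=0.0)
    return simulate_cohort(cfg)


@pytest.fixture
def tiny_matrix():
    variants = [Variant(id="v1", chrom="1", pos=100, ref="A", alt="G"),
                Variant(id="v2", chrom="1", pos=200, ref="C", alt="T")]
    dos = np.array([[0.0, 1.0], [1.0, 2.0], [2.0, np.nan]])
    return GenotypeMatrix(samples=["s1", "s2", "s3"], variants=variants,
                          dosages=dos)


def make_phenotypes(rows):
    """Build a PhenotypeTable from a list of dicts with defaults filled."""
    base = {"sample_id": None, "diagnosis": "CD", "site": "siteA",
            "followup_years": 10.0}
    recs = []
    for i, r in enumerate(rows):
        rec = dict(base)
        rec["sample_id"] = f"s{i}"
        rec.update(r)
        recs.append(rec)
    return PhenotypeTable(pd.DataFrame(recs), strict=False)


def null_config(n, seed=0, **kw):
    """All genetic effects zero, balanced classes, clean phenotypes."""
    defaults = dict(n_samples=n, seed=seed, background_or_range=(1.0, 1.0),
                    special_loci=[], subtype_base_probs=(1 / 3, 1 / 3, 1 / 3),
                    pc_effect_on_freq=0.0, pc_effect_on_class=0.0,
                    missing_rates={}, misdiagnosis_rate=0.0, ibdu_rate=0.0)
    defaults.update(kw)
    return SimulationConfig(**defaults)
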