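import numpy as np
import pandas as pd
import pytest

import pairedtumor as pt


def make_records(rows):
    """Variant-record DataFrame from (sample, tp, chrom, pos, ref, alt, refc, altc, qual) tuples."""
    return pd.DataFrame(
        [{"subject_id": "S01", "sample_id": s, "timepoint": tp, "chrom": c,
          "pos": p, "ref": r, "alt": a, "ref_count": rc, "alt_count": ac,
          "quality": q, "variant_class": "SNV"}
         for (s, tp, c, p, r, a, rc, ac, q) in rows]
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Three simulated subjects with default (moderate-selection) settings."""
    config = pt.SimulationConfig(n_subjects=3, seed=11)
    truths, records = pt.simulate_cohort(config)
    return config, truths, records


@pytest.fixture(scope="session")
def small_matrices(small_cohort):
    _, _, records = small_cohort
    return [pt.build_union_maf(grp) for _, grp in records.groupby("subject_id")]


@pytest.fixture
def rng():
    return np.random.default_rng(0)
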