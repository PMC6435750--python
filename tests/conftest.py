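import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import v4clades as v

settings.register_profile(
    "default", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

STUDY_SEED = 42


@pytest.fixture
def toy_clades():
    """Two clades over a 5-column alignment with one diagnostic column each."""
    aln = v.Alignment(
        (
            v.SeqRecord("x1", "ACGTA"),
            v.SeqRecord("x2", "ACGTA"),
            v.SeqRecord("y1", "ACCTA"),
            v.SeqRecord("y2", "ACCTT"),
        )
    )
    labels = {"x1": "X", "x2": "X", "y1": "Y", "y2": "Y"}
    return aln, labels


@pytest.fixture(scope="session")
def study():
    """The error-free synthetic study at the default survey conditions.

    Five V4-like clades (341 columns, 2 diagnostic columns each, 3 members),
    100 stations on a latitudinal gradient, mean depth 5000 group reads, two
    independently drawn datasets sharing the true haplotypes.
    """
    aln, labels, truth = v.gen_reference_clades(seed=STUDY_SEED)
    meta, props = v.gen_samples(truth, seed=STUDY_SEED)
    sims = v.gen_reads(truth, props, meta, error_rate=0.0, seed=STUDY_SEED)
    return {
        "alignment": aln,
        "labels": labels,
        "truth": truth,
        "meta": meta,
        "props": props,
        "sims": sims,
    }
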