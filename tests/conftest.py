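import numpy as np
import pandas as pd
import pytest

from mtcn.synthetic_cohort import CohortConfig


@pytest.fixture
def small_config():
    """A fast cohort: 3 plates, tiny depth regions, no QC-failure noise."""
    return CohortConfig(
        group_sizes={"G1/HS": 4, "G1/CTRL": 4, "G2/HS": 8, "G2/CTRL": 6,
                     "G3/HS": 6, "G3/CTRL": 4},
        n_plates=3,
        n_batches=2,
        nuclear_region_length=2000,
        total_snps=60,
        private_snp_counts={"L": 6},
        blood_subset_size=20,
        ntc_contamination_rate=0.0,
        amplification_failure_rate=0.0,
        seed=7,
    )


@pytest.fixture
def default_config():
    """The full paper-scale cohort (196 participants, 17 plates)."""
    return CohortConfig(seed=11)


def make_plate(plate_id="P1", batch_id="B1", ct_threshold=0.2,
               ref=(20.0, 25.0), samples=None, ntc=(39.5, 39.5)):
    """Build a minimal one-plate well table.

    ``ref`` is (MT_CYB, RNASEP) REF CT (each in triplicate); ``samples``
    maps sample_id -> ((cyb1, cyb2), (rnasep1, rnasep2)); ``ntc`` is the
    per-gene NTC CT (None for no NTC wells).
    """
    rows = []
    genes = ("MT_CYB", "RNASEP")
    for g, base in zip(genes, ref):
        for rep in range(1, 4):
            rows.append(dict(plate_id=plate_id, batch_id=batch_id, well="",
                             role="REF", sample_id="REF", gene=g,
                             replicate=rep, ct=base, ct_threshold=ct_threshold))
    if ntc is not None:
        for g, ct in zip(genes, ntc):
            rows.append(dict(plate_id=plate_id, batch_id=batch_id, well="",
                             role="NTC", sample_id="", gene=g, replicate=1,
                             ct=ct, ct_threshold=ct_threshold))
    for sid, (cyb, rnasep) in (samples or {}).items():
        for g, cts in zip(genes, (cyb, rnasep)):
            for rep, ct in enumerate(cts, start=1):
                rows.append(dict(plate_id=plate_id, batch_id=batch_id, well="",
                                 role="SAMPLE", sample_id=sid, gene=g,
                                 replicate=rep, ct=ct,
                                 ct_threshold=ct_threshold))
    return pd.DataFrame(rows)


@pytest.fixture
def plate_builder():
    return make_plate
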