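"""Shared fixtures: small hand-built cohorts and session-scoped synthetic fits."""

from __future__ import annotations

import numpy as np
import pytest

from gksurv.cohort import CohortTable, LesionRecord
from gksurv.forest import Hyperparams, fit_forest
from gksurv.preprocessing import fit_encoder, transform
from gksurv.synthetic import GeneratorParams, generate_cohort, strong_signal_params


def make_record(pid="P1", lid="L1", **kw) -> LesionRecord:
    defaults = dict(
        patient_id=pid,
        lesion_id=lid,
        time_months=12.0,
        event=0,
        age_years=60.0,
        sex="M",
        kps=80,
        volume_cm3=9.9,
        anatomic_loc=1,
        tumor_loc=1,
        dose_gy=14.0,
        isodose_pct=50.0,
        max_gy=28.0,
        coverage=0.96,
        mgmt="methyl",
        egfr="ampl",
        pten="mut",
        tert="mut",
        chr7p10q="yes",
    )
    defaults.update(kw)
    return LesionRecord(**defaults)


@pytest.fixture
def tiny_cohort() -> CohortTable:
    """Six lesions over four patients, two events, assorted missingness."""
    return CohortTable(
        [
            make_record("P1", "L1", time_months=5.0, event=1, dose_gy=12.0),
            make_record("P1", "L2", time_months=5.0, event=0, kps=None, volume_cm3=3.0),
            make_record("P2", "L1", time_months=9.0, event=1, mgmt="unmethyl", egfr=None),
            make_record("P2", "L2", time_months=9.0, event=0, sex="F", tert=None),
            make_record("P3", "L1", time_months=14.0, event=0, dose_gy=16.0, pten=None),
            make_record("P4", "L1", time_months=20.0, event=0, age_years=45.0),
        ],
        provenance="fixture",
    )


@pytest.fixture(scope="session")
def default_cohort() -> CohortTable:
    cohort, _ = generate_cohort(GeneratorParams(n_patients=120, seed=42))
    return cohort


@pytest.fixture(scope="session")
def signal_cohort() -> CohortTable:
    cohort, _ = generate_cohort(strong_signal_params(n_patients=120, seed=7))
    return cohort


@pytest.fixture(scope="session")
def signal_fit(signal_cohort):
    """Encoder + forest fitted once on the strong-signal cohort."""
    enc = fit_encoder(signal_cohort)
    fm = transform(enc, signal_cohort)
    hp = Hyperparams(
        n_trees=100, max_depth=5, min_samples_leaf=5, min_samples_split=10,
        max_features=0.58, seed=3,
    )
    return enc, fm, fit_forest(fm, hp)
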