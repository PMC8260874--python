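"""Shared fixtures and small-data builders."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import conservatome as cv


def make_matrix(values, protein_ids=None, sample_ids=None, scale_tag="log2") -> cv.AbundanceMatrix:
    values = np.asarray(values, dtype=float)
    protein_ids = protein_ids or [f"P{i:03d}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"S{i:03d}" for i in range(values.shape[1])]
    return cv.AbundanceMatrix(
        data=pd.DataFrame(values, index=protein_ids, columns=sample_ids), scale_tag=scale_tag
    )


def make_meta(sample_ids, **columns) -> cv.SampleTable:
    """Metadata table with sensible defaults for every required column."""
    n = len(sample_ids)
    base = {
        "sample_id": list(sample_ids),
        "subject_id": [f"subj{i}" for i in range(n)],
        "species": "human",
        "biofluid": "csf",
        "timepoint_h": 24.0,
        "group": "sci",
        "severity_grade": 1,
        "outcome_cont": 0.0,
        "outcome_bin": 0,
        "injury_level": "thoracic",
        "batch": "plate0",
    }
    base.update(columns)
    return cv.SampleTable(pd.DataFrame(base))


def species_view(matrix, samples, species):
    meta = samples.data[samples.data["species"] == species].reset_index(drop=True)
    return matrix.subset_samples(meta["sample_id"]), cv.SampleTable(meta)


def null_config(seed, n_proteins=200, timepoints=(24.0,), n_subjects=10):
    """Global-null study: no planted effects, no batch shifts, no censoring."""
    specs = {
        "human": cv.SpeciesSpec(
            name="human", groups={"control": 0, "sci": 1}, n_subjects=n_subjects,
            timepoints=timepoints, n_batches=2,
        ),
        "pig": cv.SpeciesSpec(
            name="pig", groups={"sham": 0, "sci": 1}, n_subjects=4,
            timepoints=timepoints, n_batches=2, paired_baseline=True,
            control_at_baseline_only=False,
        ),
    }
    return cv.SimConfig(
        n_proteins=n_proteins, species_specs=specs, de_fraction=0.0,
        batch_sd=0.0, lod_quantile=0.0, seed=seed,
    )


def injury_anytime_de(matrix, samples, paired):
    """Injury-status DE pooled over the time course: categorical injured-at-
    timepoint encoding against the uninjured arm, moderated F per protein."""
    md = samples.data.copy()
    md["tp_group"] = np.where(md["injured"] == 1, md["timepoint_h"].astype(str), "0_uninjured")
    sub = cv.filter_detection(matrix)
    return cv.fit_moderated_lm(
        sub,
        cv.SampleTable(md),
        cv.DesignSpec(
            outcome="tp_group",
            encoding="categorical",
            covariates=() if paired else ("batch",),
            paired_subject="subject_id" if paired else None,
        ),
    )


@pytest.fixture(scope="session")
def small_study():
    """One default-condition synthetic study shared across read-only tests."""
    cfg = cv.default_config(seed=0, n_proteins=150)
    human, pig, samples, truth = cv.generate_study(cfg)
    return cfg, human, pig, samples, truth
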