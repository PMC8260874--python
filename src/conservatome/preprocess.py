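"""Preprocessing chain for targeted-proteomics abundance matrices.

Order is enforced through the matrix ``scale_tag``:
log2 -> batch residualization -> detection filter -> half-minimum
imputation -> within-species z-scoring.  Batch residualization fits, per
protein, ordinary least squares on [preserved design | batch indicators]
over the observed entries only and subtracts the fitted batch component,
leaving any preserved biological design untouched (the classic
removeBatchEffect behaviour).  Missing values stay missing until the
imputation step, which replaces them with half of the protein's lowest
measured value on the linear scale, i.e. observed minimum minus one on
the log2 scale.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import AbundanceMatrix, SampleTable

__all__ = [
    "remove_batch_effect",
    "filter_detection",
    "impute_half_min",
    "zscore_within_species",
    "design_matrix",
]

log = logging.getLogger(__name__)


def design_matrix(
    samples: SampleTable,
    columns: Sequence[str],
    drop_first: bool = True,
) -> pd.DataFrame:
    """Expand metadata columns into a numeric design (indicator coding for
    categoricals, as-is for numerics), indexed by sample id."""
    meta = samples.data.set_index("sample_id")
    parts = []
    for col in columns:
        s = meta[col]
        if pd.api.types.is_numeric_dtype(s):
            parts.append(s.astype(float).to_frame(col))
        else:
            dummies = pd.get_dummies(s, prefix=col, drop_first=drop_first, dtype=float)
            parts.append(dummies)
    if not parts:
        return pd.DataFrame(index=meta.index)
    return pd.concat(parts, axis=1)


def remove_batch_effect(
    m: AbundanceMatrix,
    samples: SampleTable,
    preserve: Sequence[str] = (),
    batch_col: str = "batch",
) -> AbundanceMatrix:
    """Residualize per-protein batch shifts while preserving a biological
    design.

    For each protein, a least-squares fit of the observed values on
    ``[intercept | preserve design | centered batch indicators]`` is
    computed and only the batch component is subtracted.  Batch indicators
    are centered so the grand level is retained.  Missing entries remain
    missing.
    """
    if m.scale_tag != "log2":
        raise ValueError(f"remove_batch_effect requires scale_tag='log2', got {m.scale_tag!r}")
    meta = samples.aligned(m.sample_ids)
    batches = meta[batch_col]
    counts = batches.value_counts()
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValueError(f"batches with fewer than 2 samples: {small}")
    if batches.nunique() == 1:
        return m.with_data(m.data.copy(), "batch_corrected")

    batch_ind = pd.get_dummies(batches, dtype=float)
    batch_ind = batch_ind - batch_ind.mean(axis=0)  # centered: grand mean stays
    batch_ind = batch_ind.iloc[:, :-1]  # full-rank coding
    X_pres = design_matrix(samples, preserve).loc[m.sample_ids].to_numpy() if preserve else np.empty((m.n_samples, 0))
    intercept = np.ones((m.n_samples, 1))
    X = np.column_stack([intercept, X_pres, batch_ind.to_numpy()])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            "batch indicators are collinear with the preserved design "
            f"(rank {rank} < {X.shape[1]} columns: intercept+{list(preserve)}+batch)"
        )
    n_fixed = 1 + X_pres.shape[1]

    values = m.values.copy()
    Xb = X[:, n_fixed:]
    for i in range(values.shape[0]):
        obs = np.isfinite(values[i])
        if obs.sum() < X.shape[1]:
            log.warning("protein %s: too few observations for batch fit; left unchanged", m.protein_ids[i])
            continue
        beta, *_ = np.linalg.lstsq(X[obs], values[i, obs], rcond=None)
        values[i, obs] -= Xb[obs] @ beta[n_fixed:]
    out = pd.DataFrame(values, index=m.protein_ids, columns=m.sample_ids)
    return m.with_data(out, "batch_corrected")


def filter_detection(m: AbundanceMatrix, min_fraction: float = 1.0 / 3.0) -> AbundanceMatrix:
    """Keep proteins observed in at least ``min_fraction`` of samples
    (inclusive comparison); protein order preserved. Idempotent."""
    if not 0.0 <= min_fraction <= 1.0:
        raise ValueError(f"min_fraction must be in [0, 1], got {min_fraction}")
    frac = m.mask.mean(axis=1)
    keep = frac >= min_fraction
    if not keep.any():
        log.warning("detection filter removed every protein")
    return m.with_data(m.data.loc[keep])


def impute_half_min(m: AbundanceMatrix) -> AbundanceMatrix:
    """Replace missing entries with half the protein's lowest measured
    value on the linear scale (observed log2 minimum minus 1).  Proteins
    with no observed value are dropped.  Idempotent."""
    if m.scale_tag not in ("log2", "batch_corrected"):
        raise ValueError(f"impute_half_min requires log2/batch_corrected input, got {m.scale_tag!r}")
    data = m.data.copy()
    all_missing = data.isna().all(axis=1)
    if all_missing.any():
        log.warning("dropping %d fully missing proteins", int(all_missing.sum()))
        data = data.loc[~all_missing]
    mins = data.min(axis=1, skipna=True)
    fill = mins - 1.0  # log2(0.5 * min_linear)
    data = data.apply(lambda row: row.fillna(fill[row.name]), axis=1)
    return m.with_data(data)


def zscore_within_species(
    human: AbundanceMatrix,
    pig: AbundanceMatrix,
    shared_map: Mapping[str, str] | Iterable[tuple[str, str]],
) -> tuple[AbundanceMatrix, dict[str, list[str]]]:
    """Combine the two species over orthologous proteins, z-scoring each
    protein within each species' sample block.

    ``shared_map`` pairs human id -> pig id (an ortholog table); the
    combined matrix is indexed by the human id.  Proteins with zero
    within-species variance (or missing in either species) are dropped
    with a warning.  Returns the combined matrix and the per-species
    sample-id blocks.
    """
    pairs = dict(shared_map)
    pairs = {h: p for h, p in pairs.items() if h in human.protein_ids and p in pig.protein_ids}
    if not pairs:
        raise ValueError("no shared proteins between the two matrices")
    if not human.mask.values.all() or not pig.mask.values.all():
        raise ValueError("zscore_within_species requires imputed (complete) matrices")

    h = human.data.loc[list(pairs.keys())]
    p = pig.data.loc[[pairs[k] for k in pairs]]
    p.index = h.index

    def _z(block: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
        mu = block.mean(axis=1)
        sd = block.std(axis=1, ddof=1)
        return block.sub(mu, axis=0).div(sd, axis=0), sd

    hz, hsd = _z(h)
    pz, psd = _z(p)
    ok = (hsd > 0) & (psd > 0)
    if (~ok).any():
        log.warning("dropping %d zero-variance proteins before z-scoring", int((~ok).sum()))
    combined = pd.concat([hz.loc[ok], pz.loc[ok]], axis=1)
    blocks = {"human": h.columns.tolist(), "pig": p.columns.tolist()}
    out = AbundanceMatrix(data=combined, scale_tag="zscored")
    return out, blocks
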