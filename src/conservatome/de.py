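"""Moderated differential abundance for targeted-proteomics matrices.

Per protein, an ordinary least-squares fit of log2 abundance on the study
design is computed over that protein's observed samples (complete-case per
protein; no imputation at this stage).  Residual variances are then shrunk
toward a common prior by empirical Bayes: the prior (d0, s0^2) is obtained
by moment matching on the log residual variances, the posterior variance is

    s~_g^2 = (d0 * s0^2 + df_g * s_g^2) / (d0 + df_g)

and the moderated t-statistic t_g = beta_g / (s~_g * u_g) is referred to a
t distribution on df_g + d0 degrees of freedom (u_g is the unscaled
standard error from the design).  This is the standard shrinkage estimator
used for small-sample omics linear models.  Benjamini-Hochberg adjustment
is applied over the tested proteins only.

Outcome encodings: ``binary`` and ``continuous`` enter as a single numeric
column; ``ordinal_numeric`` maps ordered levels to equally-spaced scores
(a single trend coefficient); ``categorical`` expands to indicators and is
tested with a moderated F over the block.  A ``paired_subject`` column adds
subject fixed effects for repeated-measures (pre/post) designs.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

from .containers import AbundanceMatrix, SampleTable

__all__ = [
    "DesignSpec",
    "EBPrior",
    "DEResult",
    "fit_moderated_lm",
    "fit_eb_prior",
    "bh_adjust",
    "jaccard_de_overlap",
    "recurrent_associations",
    "trigamma_inverse",
]


@dataclasses.dataclass
class DesignSpec:
    outcome: str
    encoding: str = "continuous"  # binary | ordinal_numeric | continuous | categorical
    covariates: Sequence[str] = ()
    paired_subject: str | None = None

    def __post_init__(self) -> None:
        allowed = {"binary", "ordinal_numeric", "continuous", "categorical"}
        if self.encoding not in allowed:
            raise ValueError(f"encoding must be one of {sorted(allowed)}, got {self.encoding!r}")


@dataclasses.dataclass
class EBPrior:
    d0: float  # prior degrees of freedom, possibly inf
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 > 0):
            raise ValueError(f"d0 must be > 0, got {self.d0}")
        if not (self.s0_sq > 0):
            raise ValueError(f"s0_sq must be > 0, got {self.s0_sq}")


@dataclasses.dataclass
class DEResult:
    """Per-protein moderated statistics for one design.

    ``table`` columns: coef, se, df_residual, s_sq, t_mod, df_total, p, q,
    n_obs, testable (plus F for categorical designs).  q is computed over
    testable proteins only.
    """

    table: pd.DataFrame
    prior: EBPrior
    design: DesignSpec

    def significant(self, q_threshold: float = 0.05) -> set[str]:
        t = self.table
        return set(t.index[(t["testable"]) & (t["q"] < q_threshold)])


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration on 1/x scale)."""
    if y <= 0:
        raise ValueError("trigamma_inverse requires y > 0")
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(polygamma(2, x))
        x += dif
        if abs(dif / x) < 1e-10:
            break
    return x


def fit_eb_prior(s_sq: np.ndarray, df: np.ndarray) -> EBPrior:
    """Moment-matching estimate of the variance prior from per-protein
    residual variances.

    Uses the distribution of log s_g^2: under the hierarchical model the
    excess of var(log s_g^2) over trigamma(df_g/2) identifies d0 via the
    trigamma inverse, and the mean identifies s0^2.  Falls back to a
    complete-pooling prior (d0 = inf, s0^2 = mean variance) when the
    empirical excess is non-positive or fewer than 3 proteins are given.
    """
    s_sq = np.asarray(s_sq, dtype=float)
    df = np.asarray(df, dtype=float)
    if np.any(s_sq <= 0) or np.any(df < 1):
        keep = (s_sq > 0) & (df >= 1)
        s_sq, df = s_sq[keep], df[keep]
    if len(s_sq) < 3:
        return EBPrior(d0=math.inf, s0_sq=float(np.mean(s_sq)) if len(s_sq) else 1.0)
    e = np.log(s_sq) - digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(np.mean(polygamma(1, df / 2.0)))
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s0_sq = math.exp(emean + float(digamma(d0 / 2.0)) - math.log(d0 / 2.0))
        return EBPrior(d0=d0, s0_sq=s0_sq)
    return EBPrior(d0=math.inf, s0_sq=float(np.mean(s_sq)))


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must be finite and in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _encode_outcome(series: pd.Series, encoding: str) -> tuple[np.ndarray, list[str]]:
    if encoding in ("continuous",):
        return series.astype(float).to_numpy()[:, None], [series.name]
    if encoding == "binary":
        vals = series
        if not pd.api.types.is_numeric_dtype(vals):
            levels = sorted(vals.unique())
            if len(levels) != 2:
                raise ValueError(f"binary outcome {series.name!r} has {len(levels)} levels")
            vals = (vals == levels[1]).astype(float)
        u = set(np.unique(vals.astype(float)))
        if not u <= {0.0, 1.0}:
            raise ValueError(f"binary outcome {series.name!r} must be 0/1, got {sorted(u)}")
        return vals.astype(float).to_numpy()[:, None], [series.name]
    if encoding == "ordinal_numeric":
        if pd.api.types.is_numeric_dtype(series):
            return series.astype(float).to_numpy()[:, None], [series.name]
        levels = sorted(series.unique())
        scores = series.map({lv: i for i, lv in enumerate(levels)}).astype(float)
        return scores.to_numpy()[:, None], [series.name]
    # categorical
    dummies = pd.get_dummies(series, prefix=series.name, drop_first=True, dtype=float)
    if dummies.shape[1] == 0:
        raise ValueError(f"categorical outcome {series.name!r} has a single level")
    return dummies.to_numpy(), dummies.columns.tolist()


def _build_design(samples: SampleTable, sample_ids, design: DesignSpec) -> tuple[np.ndarray, slice, list[str]]:
    """Full design matrix [intercept | outcome block | covariates | subject FE];
    returns (X, slice of outcome columns, outcome column names)."""
    meta = samples.aligned(sample_ids)
    out_block, out_names = _encode_outcome(meta[design.outcome], design.encoding)
    parts = [np.ones((len(meta), 1)), out_block]
    for cov in design.covariates:
        s = meta[cov]
        if pd.api.types.is_numeric_dtype(s):
            parts.append(s.astype(float).to_numpy()[:, None])
        else:
            parts.append(pd.get_dummies(s, drop_first=True, dtype=float).to_numpy())
    if design.paired_subject is not None:
        parts.append(
            pd.get_dummies(meta[design.paired_subject], drop_first=True, dtype=float).to_numpy()
        )
    X = np.column_stack(parts)
    return X, slice(1, 1 + out_block.shape[1]), out_names


def fit_moderated_lm(
    m: AbundanceMatrix,
    samples: SampleTable,
    design: DesignSpec,
    d0_override: float | None = None,
) -> DEResult:
    """Fit the moderated linear model to every protein.

    ``d0_override`` forces the prior degrees of freedom (0 recovers the
    ordinary OLS t; inf gives complete pooling to s0^2).
    """
    X_full, out_slice, out_names = _build_design(samples, m.sample_ids, design)
    p_cols = X_full.shape[1]
    Y = m.values
    n_prot = Y.shape[0]
    obs = np.isfinite(Y)

    coef = np.full(n_prot, np.nan)
    unscaled = np.full(n_prot, np.nan)
    s_sq = np.full(n_prot, np.nan)
    dfres = np.full(n_prot, np.nan)
    n_obs = obs.sum(axis=1)
    testable = np.zeros(n_prot, dtype=bool)
    r = out_slice.stop - out_slice.start
    block_stat = np.full(n_prot, np.nan)  # beta' C^-1 beta for the outcome block

    # proteins sharing an observation pattern share one decomposition
    patterns, inverse = np.unique(obs, axis=0, return_inverse=True)
    for pat_idx in range(patterns.shape[0]):
        rows = np.flatnonzero(inverse == pat_idx)
        keep = patterns[pat_idx]
        if keep.sum() < p_cols + 1:
            continue
        Xo = X_full[keep]
        if np.linalg.matrix_rank(Xo) < p_cols:
            continue
        Yo = Y[np.ix_(rows, keep)]
        XtX_inv = np.linalg.inv(Xo.T @ Xo)
        beta = Yo @ (Xo @ XtX_inv)  # (G, p)
        resid = Yo - beta @ Xo.T
        df_g = keep.sum() - p_cols
        rss = np.einsum("ij,ij->i", resid, resid)
        C = XtX_inv[out_slice, out_slice]
        Cinv = np.linalg.inv(C)
        b_out = beta[:, out_slice]
        block_stat[rows] = np.einsum("ij,jk,ik->i", b_out, Cinv, b_out)
        coef[rows] = beta[:, out_slice.start]
        unscaled[rows] = math.sqrt(XtX_inv[out_slice.start, out_slice.start])
        s_sq[rows] = rss / df_g
        dfres[rows] = df_g
        testable[rows] = s_sq[rows] > 0

    if not testable.any():
        raise ValueError("no testable proteins: design is rank deficient or data too sparse")

    prior = fit_eb_prior(s_sq[testable], dfres[testable])
    d0 = prior.d0
    if d0_override is not None:
        d0 = float(d0_override)
        if d0 < 0:
            raise ValueError("d0_override must be >= 0")
        prior = EBPrior(d0=max(d0, np.finfo(float).tiny), s0_sq=prior.s0_sq)

    df_pooled = float(np.nansum(dfres[testable]))  # cap: df never exceeds the pooled total
    with np.errstate(invalid="ignore"):
        if math.isinf(d0):
            post_var = np.full(n_prot, prior.s0_sq)
            df_total = np.full(n_prot, df_pooled)
        elif d0 == 0:
            post_var = s_sq.copy()
            df_total = dfres.copy()
        else:
            post_var = (d0 * prior.s0_sq + dfres * s_sq) / (d0 + dfres)
            df_total = np.minimum(dfres + d0, df_pooled)
        se = np.sqrt(post_var) * unscaled
        t_mod = coef / se
        if r == 1:
            pvals = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
        else:
            F = block_stat / (r * post_var)
            pvals = stats.f.sf(F, r, df_total)

    q = np.full(n_prot, np.nan)
    q[testable] = bh_adjust(pvals[testable])

    table = pd.DataFrame(
        {
            "coef": coef,
            "se": se,
            "df_residual": dfres,
            "s_sq": s_sq,
            "t_mod": t_mod,
            "df_total": df_total,
            "p": np.where(testable, pvals, np.nan),
            "q": q,
            "n_obs": n_obs,
            "testable": testable,
        },
        index=m.protein_ids,
    )
    if r > 1:
        table["F"] = block_stat / (r * post_var)
    return DEResult(table=table, prior=prior, design=design)


def jaccard_de_overlap(de_sets: Mapping) -> pd.DataFrame:
    """Pairwise Jaccard index between differential-protein sets (keys are
    e.g. timepoints).  Two empty sets have J = 1 by convention."""
    keys = list(de_sets)
    mat = pd.DataFrame(np.eye(len(keys)), index=keys, columns=keys)
    for i, a in enumerate(keys):
        for j, b in enumerate(keys):
            if j <= i:
                continue
            A, B = set(de_sets[a]), set(de_sets[b])
            union = len(A | B)
            val = 1.0 if union == 0 else len(A & B) / union
            mat.iloc[i, j] = mat.iloc[j, i] = val
    return mat


def recurrent_associations(
    results: Mapping[tuple, DEResult],
    q_threshold: float = 0.05,
    min_count: int = 2,
) -> pd.DataFrame:
    """Count significant (outcome, timepoint) cells per protein and return
    proteins with at least ``min_count`` recurrent associations, most
    recurrent first."""
    cols = {}
    for key, res in results.items():
        name = "|".join(map(str, key)) if isinstance(key, tuple) else str(key)
        t = res.table
        cols[name] = (t["testable"] & (t["q"] < q_threshold)).astype(int)
    hits = pd.DataFrame(cols).fillna(0).astype(int)
    hits["n_significant"] = hits.sum(axis=1)
    hits = hits[hits["n_significant"] >= min_count]
    return hits.sort_values("n_significant", ascending=False)
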