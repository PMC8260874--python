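"""Cross-species conservation suite.

Four complementary views of how well two species' proteomic responses
agree:

* **pi1** — Storey-style estimate of the fraction of true associations in
  a p-value collection; applied to "test in species B the proteins altered
  in species A" designs it estimates the shared-response fraction without
  a significance threshold in B.
* **RRHO** — rank-rank hypergeometric overlap: both species' proteins are
  ranked by signed differential-abundance strength and the hypergeometric
  enrichment of every pair of top-list prefixes forms a significance grid;
  the grid maximum is calibrated by label-permutation refits.
* **NACC** — neighborhood analysis of conserved coexpression: a protein's
  k nearest coexpression neighbors in one species should remain correlated
  with it in the other species; the symmetrized mean neighbor correlation
  is compared with random neighbor sets, per protein and per gene set.
* **DTW** — dynamic time warping of the two species' whole-proteome
  trajectories (after local-polynomial smoothing) recovers the temporal
  offset between the species' injury responses.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .containers import AbundanceMatrix, SampleTable
from .de import DEResult, DesignSpec, fit_moderated_lm

__all__ = [
    "Pi0Estimate",
    "RankedList",
    "RRHOResult",
    "NACCResult",
    "AlignmentResult",
    "estimate_pi0",
    "rank_by_de",
    "rrho_map",
    "rrho_permutation_test",
    "nacc_scores",
    "nacc_permutation_test",
    "nacc_gene_set_test",
    "smooth_profiles",
    "dtw_align",
    "path_slope",
]

log = logging.getLogger(__name__)

P_FLOOR = np.finfo(float).tiny


@dataclasses.dataclass
class Pi0Estimate:
    pi0: float
    lambda_grid: np.ndarray
    pi0_lambda: np.ndarray
    method: str = "cubic-smoother"

    @property
    def pi1(self) -> float:
        return 1.0 - self.pi0


def estimate_pi0(p: Sequence[float], lambda_grid: Sequence[float] | None = None) -> Pi0Estimate:
    """Estimate the proportion of true nulls pi0 from a p-value collection.

    pi0(lambda) = #{p > lambda} / (n (1 - lambda)) is computed on the grid
    (default 0.05..0.95 by 0.05) and extrapolated to lambda -> 1 with a
    cubic smoother, clipped to [0, 1].
    """
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must be in [0, 1]")
    if lambda_grid is None:
        lambda_grid = np.arange(0.05, 0.96, 0.05)
    lam = np.asarray(lambda_grid, dtype=float)
    if np.allclose(p, p[0]):
        log.warning("degenerate p-value collection; returning conservative pi0 = 1")
        return Pi0Estimate(pi0=1.0, lambda_grid=lam, pi0_lambda=np.ones_like(lam))
    pi0_lam = np.array([(p > l).sum() / (len(p) * (1.0 - l)) for l in lam])
    # cubic trend fit: the high-penalty limit of a natural cubic smoothing
    # spline, robust on a 19-point grid
    coefs = np.polyfit(lam, pi0_lam, deg=3)
    pi0 = float(np.clip(np.polyval(coefs, lam.max()), 0.0, 1.0))
    return Pi0Estimate(pi0=pi0, lambda_grid=lam, pi0_lambda=pi0_lam)


@dataclasses.dataclass
class RankedList:
    """Protein ids ordered by signed DE strength, strongest positive first."""

    ids: list[str]
    scores: np.ndarray  # aligned with ids; -log10(p) * sign(coef)


def rank_by_de(de: DEResult, universe: Sequence[str] | None = None) -> RankedList:
    """Rank proteins by signed significance, -log10(p) * sign(coef),
    descending; ties broken by |coef| (descending) then id."""
    t = de.table[de.table["testable"]]
    if universe is not None:
        t = t.loc[t.index.intersection(universe)]
    p = np.maximum(t["p"].to_numpy(float), P_FLOOR)
    sign = np.sign(t["coef"].to_numpy(float))
    sign[sign == 0] = 1.0
    score = -np.log10(p) * sign
    order = sorted(
        range(len(t)),
        key=lambda i: (-score[i], -abs(t["coef"].iloc[i]), t.index[i]),
    )
    return RankedList(ids=[t.index[i] for i in order], scores=score[order])


@dataclasses.dataclass
class RRHOResult:
    step: int
    prefix_a: np.ndarray
    prefix_b: np.ndarray
    grid: pd.DataFrame  # -log10 hypergeometric upper-tail p per prefix pair
    observed_max: float
    perm_p: float | None = None
    perm_maxima: np.ndarray | None = None


def rrho_map(a: RankedList, b: RankedList, step: int = 1) -> RRHOResult:
    """Hypergeometric overlap grid between prefixes of two rankings over an
    identical protein universe."""
    if step < 1:
        raise ValueError("step must be >= 1")
    ua, ub = set(a.ids), set(b.ids)
    if ua != ub:
        raise ValueError(
            f"rankings cover different universes; only in a: {sorted(ua - ub)[:5]}, "
            f"only in b: {sorted(ub - ua)[:5]}"
        )
    n = len(a.ids)
    pos_b = {pid: i for i, pid in enumerate(b.ids)}
    # overlap counts for all prefix pairs via a 2D cumulative sum
    point = np.zeros((n + 1, n + 1))
    for ia, pid in enumerate(a.ids):
        point[ia + 1, pos_b[pid] + 1] = 1.0
    cum = point.cumsum(axis=0).cumsum(axis=1)
    prefixes = np.arange(step, n + 1, step)
    if prefixes[-1] != n:
        prefixes = np.append(prefixes, n)
    o = cum[np.ix_(prefixes, prefixes)]
    I, J = np.meshgrid(prefixes, prefixes, indexing="ij")
    pvals = hypergeom.sf(o - 1, n, I, J)
    grid = -np.log10(np.maximum(pvals, P_FLOOR))
    df = pd.DataFrame(grid, index=prefixes, columns=prefixes)
    return RRHOResult(
        step=step,
        prefix_a=prefixes,
        prefix_b=prefixes,
        grid=df,
        observed_max=float(grid.max()),
    )


def _permute_outcome(
    samples: SampleTable, design: DesignSpec, rng: np.random.Generator
) -> SampleTable:
    """Permute the outcome labels: within subjects when a paired design is
    declared, across subjects when the outcome is a subject-level
    attribute, across samples otherwise."""
    meta = samples.data.copy()
    col = design.outcome
    if design.paired_subject is not None:
        for _, idx in meta.groupby(design.paired_subject).groups.items():
            vals = meta.loc[idx, col].to_numpy()
            meta.loc[idx, col] = vals[rng.permutation(len(vals))]
    else:
        per_subject = meta.groupby("subject_id")[col].nunique()
        if (per_subject <= 1).all():
            subjects = meta["subject_id"].unique()
            sub_vals = meta.drop_duplicates("subject_id").set_index("subject_id")[col]
            shuffled = pd.Series(
                sub_vals.to_numpy()[rng.permutation(len(subjects))], index=subjects
            )
            meta[col] = meta["subject_id"].map(shuffled)
        else:
            meta[col] = meta[col].to_numpy()[rng.permutation(len(meta))]
    if meta[col].nunique() < 2:
        raise ValueError(f"outcome {col!r} is constant; permutation test undefined")
    return SampleTable(meta)


def rrho_permutation_test(
    human_m: AbundanceMatrix,
    pig_m: AbundanceMatrix,
    human_samples: SampleTable,
    pig_samples: SampleTable,
    human_design: DesignSpec,
    pig_design: DesignSpec,
    shared_map: Mapping[str, str],
    step: int = 1,
    n_perm: int = 1000,
    seed: int = 0,
) -> RRHOResult:
    """RRHO with a max-statistic permutation null.

    The observed grid compares the two species' DE rankings over their
    shared (ortholog-mapped) universe.  Each permutation independently
    shuffles the outcome labels within each species, refits both DE
    models, rebuilds the grid, and records its maximum; perm_p uses the
    add-one estimator."""
    pairs = {h: p for h, p in dict(shared_map).items()
             if h in set(human_m.protein_ids) and p in set(pig_m.protein_ids)}
    if not pairs:
        raise ValueError("no shared proteins between species matrices")

    def _grids(hs: SampleTable, ps: SampleTable) -> RRHOResult:
        de_h = fit_moderated_lm(human_m, hs, human_design)
        de_p = fit_moderated_lm(pig_m, ps, pig_design)
        ok_h = set(de_h.table.index[de_h.table["testable"]])
        ok_p = set(de_p.table.index[de_p.table["testable"]])
        shared = sorted(h for h, p in pairs.items() if h in ok_h and p in ok_p)
        ra = rank_by_de(de_h, universe=shared)
        # express pig ranking in human (ortholog) ids
        inv = {p: h for h, p in pairs.items()}
        rb = rank_by_de(de_p, universe=[pairs[h] for h in shared])
        rb = RankedList(ids=[inv[pid] for pid in rb.ids], scores=rb.scores)
        return rrho_map(ra, rb, step=step)

    observed = _grids(human_samples, pig_samples)
    if n_perm == 0:
        return observed
    rng = np.random.default_rng(seed)
    maxima = np.empty(n_perm)
    for b in range(n_perm):
        hs = _permute_outcome(human_samples, human_design, rng)
        ps = _permute_outcome(pig_samples, pig_design, rng)
        maxima[b] = _grids(hs, ps).observed_max
    perm_p = (1.0 + np.sum(maxima >= observed.observed_max)) / (1.0 + n_perm)
    return dataclasses.replace(observed, perm_p=float(perm_p), perm_maxima=maxima)


# ---------------------------------------------------------------------------
# NACC


@dataclasses.dataclass
class NACCResult:
    table: pd.DataFrame  # per protein: nacc_score (+ null_mean, null_sd, z, perm_p)
    k: int
    corr: dict[str, pd.DataFrame] | None = None  # per-species coexpression matrices


def nacc_scores(
    combined: AbundanceMatrix,
    species_blocks: Mapping[str, Sequence[str]],
    k: int = 10,
) -> NACCResult:
    """Symmetric neighborhood-conservation score per protein.

    For each protein g, its k most-correlated partners in the human
    network are looked up in the pig network (and vice versa); the score
    is the mean of the two cross-species mean neighbor correlations.
    """
    if len(species_blocks) != 2:
        raise ValueError("species_blocks must name exactly two species")
    (sa, cols_a), (sb, cols_b) = species_blocks.items()
    n = combined.n_proteins
    if n < k + 1:
        raise ValueError(f"need at least k+1 = {k + 1} proteins, have {n}")
    corr = {}
    for sp, cols in ((sa, cols_a), (sb, cols_b)):
        if len(cols) < 3:
            raise ValueError(f"species {sp!r} needs >= 3 samples")
        c = np.corrcoef(combined.data.loc[:, list(cols)].to_numpy())
        corr[sp] = pd.DataFrame(c, index=combined.protein_ids, columns=combined.protein_ids)

    def _direction(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
        scores = np.empty(n)
        masked = src.copy()
        np.fill_diagonal(masked, -np.inf)
        nbrs = np.argpartition(-masked, k - 1, axis=1)[:, :k]
        for g in range(n):
            scores[g] = dst[g, nbrs[g]].mean()
        return scores

    A, B = corr[sa].to_numpy(), corr[sb].to_numpy()
    score = 0.5 * (_direction(A, B) + _direction(B, A))
    table = pd.DataFrame({"nacc_score": score}, index=combined.protein_ids)
    return NACCResult(table=table, k=k, corr=corr)


def nacc_permutation_test(
    result: NACCResult,
    n_perm: int = 1000,
    seed: int = 0,
) -> NACCResult:
    """Per-protein random-neighbor null: the observed score is compared to
    scores of k uniform random 'neighbors' (excluding self) drawn in both
    directions; one-sided (conservation) add-one permutation p."""
    if result.corr is None:
        raise ValueError("nacc_scores must be run with correlation matrices retained")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    (A, B) = (c.to_numpy() for c in result.corr.values())
    n = A.shape[0]
    k = result.k
    if k >= n - 1:
        raise ValueError(f"k = {k} must be smaller than the universe minus one ({n - 1})")
    rng = np.random.default_rng(seed)
    obs = result.table["nacc_score"].to_numpy()
    null_mean = np.empty(n)
    null_sd = np.empty(n)
    perm_p = np.empty(n)
    for g in range(n):
        draws = rng.integers(0, n - 1, size=(2, n_perm, k))
        draws[draws >= g] += 1  # exclude self
        null = 0.5 * (B[g, draws[0]].mean(axis=1) + A[g, draws[1]].mean(axis=1))
        null_mean[g] = null.mean()
        null_sd[g] = null.std(ddof=1)
        perm_p[g] = (1.0 + np.sum(null >= obs[g])) / (1.0 + n_perm)
    table = result.table.copy()
    table["null_mean"] = null_mean
    table["null_sd"] = null_sd
    with np.errstate(divide="ignore", invalid="ignore"):
        table["z"] = np.where(null_sd > 0, (obs - null_mean) / null_sd, np.nan)
    table["perm_p"] = perm_p
    return NACCResult(table=table, k=k, corr=result.corr)


def nacc_gene_set_test(
    result: NACCResult,
    gene_sets: Mapping[str, Sequence[str]],
    size_bounds: tuple[int, int] = (3, 50),
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Gene-set level conservation: statistic = mean member NACC score,
    null = means of size-matched random protein sets.  Both tails are
    reported (conserved: observed >= null; divergent: observed <= null)."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    scores = result.table["nacc_score"]
    universe = scores.index
    lo, hi = size_bounds
    rng = np.random.default_rng(seed)
    rows = []
    vals = scores.to_numpy()
    for set_id, genes in gene_sets.items():
        members = universe.intersection(genes)
        size = len(members)
        if not lo <= size <= hi:
            continue
        obs = float(scores.loc[members].mean())
        draws = np.array(
            [vals[rng.choice(len(vals), size=size, replace=False)].mean() for _ in range(n_perm)]
        )
        sd = draws.std(ddof=1)
        rows.append(
            {
                "set_id": set_id,
                "size": size,
                "mean_score": obs,
                "null_mean": float(draws.mean()),
                "null_sd": float(sd),
                "z": (obs - draws.mean()) / sd if sd > 0 else np.nan,
                "p_conserved": (1.0 + np.sum(draws >= obs)) / (1.0 + n_perm),
                "p_divergent": (1.0 + np.sum(draws <= obs)) / (1.0 + n_perm),
            }
        )
    if not rows:
        log.warning("no gene sets within size bounds %s", size_bounds)
        return pd.DataFrame(
            columns=["set_id", "size", "mean_score", "null_mean", "null_sd", "z",
                     "p_conserved", "p_divergent"]
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# temporal alignment


def smooth_profiles(
    timepoints: Sequence[float],
    values: pd.DataFrame,
    upsample_factor: int = 10,
    bandwidth: float | None = None,
) -> pd.DataFrame:
    """Local-polynomial (degree 2, tricube weights) smoothing of per-protein
    time courses, evaluated on a dense grid between the endpoints only
    (interpolation, no extrapolation).

    ``bandwidth`` is in time units; the default spans half the time range
    and is widened locally whenever fewer than 3 timepoints carry weight.
    """
    t = np.asarray(timepoints, dtype=float)
    if len(t) < 3:
        raise ValueError("need at least 3 timepoints for local-polynomial smoothing")
    if values.shape[1] != len(t):
        raise ValueError("values must have one column per timepoint")
    Y = values.to_numpy(dtype=float)
    grid = np.linspace(t[0], t[-1], upsample_factor * (len(t) - 1) + 1)
    h0 = bandwidth if bandwidth is not None else (t[-1] - t[0]) / 2.0
    out = np.empty((Y.shape[0], len(grid)))
    for gi, x in enumerate(grid):
        h = h0
        while np.sum(np.abs(t - x) < h) < 3:
            h *= 1.5
        u = np.clip(np.abs(t - x) / h, 0.0, 1.0)
        w = (1.0 - u**3) ** 3
        w[w <= 0] = 1e-12
        A = np.column_stack([np.ones_like(t), t - x, (t - x) ** 2])
        Aw = A * w[:, None]
        beta = np.linalg.solve(A.T @ Aw, Aw.T @ Y.T)  # (3, G)
        out[:, gi] = beta[0]
    return pd.DataFrame(out, index=values.index, columns=grid)


@dataclasses.dataclass
class AlignmentResult:
    human_grid: np.ndarray
    pig_grid: np.ndarray
    cost: pd.DataFrame  # local Euclidean distance, human x pig timepoints
    path: list[tuple[int, int]]
    total_cost: float


def dtw_align(human_profiles: pd.DataFrame, pig_profiles: pd.DataFrame) -> AlignmentResult:
    """Globally align two species' proteome time courses.

    Columns are timepoints; rows the shared protein universe.  The local
    cost of pairing human time i with pig time j is the Euclidean distance
    between the two all-protein abundance vectors; the optimal monotone,
    boundary-anchored path (steps (1,0), (0,1), (1,1)) is found by dynamic
    programming.
    """
    shared = human_profiles.index.intersection(pig_profiles.index)
    if len(shared) == 0:
        raise ValueError("no shared proteins between the species' profiles")
    H = human_profiles.loc[shared].to_numpy(dtype=float)
    P = pig_profiles.loc[shared].to_numpy(dtype=float)
    nh, npig = H.shape[1], P.shape[1]
    diff = H.T[:, None, :] - P.T[None, :, :]
    cost = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))

    acc = np.full((nh, npig), np.inf)
    acc[0, 0] = cost[0, 0]
    move = np.zeros((nh, npig), dtype=int)  # 0=diag, 1=up(i-1), 2=left(j-1)
    for i in range(nh):
        for j in range(npig):
            if i == 0 and j == 0:
                continue
            candidates = []
            if i > 0 and j > 0:
                candidates.append((acc[i - 1, j - 1], 0))
            if i > 0:
                candidates.append((acc[i - 1, j], 1))
            if j > 0:
                candidates.append((acc[i, j - 1], 2))
            best, mv = min(candidates)  # diagonal preferred on ties
            acc[i, j] = cost[i, j] + best
            move[i, j] = mv
    path = [(nh - 1, npig - 1)]
    while path[-1] != (0, 0):
        i, j = path[-1]
        mv = move[i, j]
        path.append((i - 1, j - 1) if mv == 0 else (i - 1, j) if mv == 1 else (i, j - 1))
    path.reverse()
    hgrid = human_profiles.columns.to_numpy(dtype=float)
    pgrid = pig_profiles.columns.to_numpy(dtype=float)
    return AlignmentResult(
        human_grid=hgrid,
        pig_grid=pgrid,
        cost=pd.DataFrame(cost, index=hgrid, columns=pgrid),
        path=path,
        total_cost=float(acc[nh - 1, npig - 1]),
    )


def path_slope(alignment: AlignmentResult) -> float:
    """Least-squares slope of human time on pig time along the warp path —
    the recovered speed-up factor of the faster species."""
    ht = np.array([alignment.human_grid[i] for i, _ in alignment.path])
    pt = np.array([alignment.pig_grid[j] for _, j in alignment.path])
    slope = np.polyfit(pt, ht, deg=1)[0]
    return float(slope)
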