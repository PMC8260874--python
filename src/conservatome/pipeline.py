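"""End-to-end workflows.

Two orchestrated analyses over a single JSON-style configuration:

* :func:`run_within_species` — preprocessing, per-timepoint moderated DE
  for each outcome, DE-set summaries (counts, Jaccard overlap, recurrent
  associations) and consensus clustering of trajectories.
* :func:`run_cross_species` — within-species z-normalization, shared-
  timepoint modularity, the RRHO timepoint battery, NACC protein/set
  tables, pi1 estimation, and DTW temporal alignment.

Every written table starts with ``#`` provenance lines (package version,
seed, stage parameters) so outputs are auditable and bit-reproducible for
a fixed config and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__ as VERSION
from .containers import AbundanceMatrix, SampleTable, read_abundance, read_gmt, write_gmt
from .simulate import SimConfig, SpeciesSpec, default_config, generate_gene_sets, generate_study
from .preprocess import filter_detection, impute_half_min, remove_batch_effect, zscore_within_species
from .de import DEResult, DesignSpec, fit_moderated_lm, jaccard_de_overlap, recurrent_associations
from .netmod import modularity_curve
from .consensus import cluster_enrichment, consensus_kmeans, logfc_trajectories, prune_small_clusters
from .xspecies import (
    dtw_align,
    estimate_pi0,
    nacc_gene_set_test,
    nacc_permutation_test,
    nacc_scores,
    path_slope,
    rank_by_de,
    rrho_map,
    smooth_profiles,
)

__all__ = ["PipelineConfig", "run_within_species", "run_cross_species"]

log = logging.getLogger(__name__)

SHARED_TIMEPOINTS = (24.0, 48.0, 72.0, 120.0)


@dataclasses.dataclass
class PipelineConfig:
    """Single-document pipeline configuration.

    Exactly one of ``inputs`` (paths to abundance/metadata TSVs per
    species) or ``simulate`` (overrides for the synthetic generator) must
    be provided.
    """

    out_dir: str
    seed: int = 0
    simulate: Mapping | None = None
    inputs: Mapping | None = None  # {"human": {"abundance":..., "metadata":...}, "pig": {...}}
    stages: Mapping | None = None  # toggles, e.g. {"clustering": False}
    params: Mapping | None = None  # per-stage overrides

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(**doc)

    def validate(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise ValueError("config must provide exactly one of 'simulate' or 'inputs'")

    def stage_on(self, name: str) -> bool:
        return bool((self.stages or {}).get(name, True))

    def param(self, stage: str, name: str, default):
        return ((self.params or {}).get(stage) or {}).get(name, default)


def _provenance(cfg: PipelineConfig, stage: str, **params) -> list[str]:
    items = " ".join(f"{k}={v}" for k, v in params.items())
    return [f"conservatome v{VERSION}", f"stage={stage} seed={cfg.seed} {items}".rstrip()]


def _write(df: pd.DataFrame, path: Path, cfg: PipelineConfig, stage: str, index=True, **params) -> None:
    with open(path, "w") as fh:
        for line in _provenance(cfg, stage, **params):
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=index)
    log.info("stage=%s wrote=%s rows=%d", stage, path.name, len(df))


def _sim_config(cfg: PipelineConfig) -> SimConfig:
    overrides = dict(cfg.simulate or {})
    specs = overrides.pop("species_specs", None)
    sim = default_config(seed=cfg.seed, **overrides)
    if specs is not None:
        sim = dataclasses.replace(
            sim, species_specs={k: SpeciesSpec(**v) for k, v in specs.items()}
        )
    return sim


def _load_study(cfg: PipelineConfig):
    """Returns (human matrix, pig matrix, combined SampleTable, truth|None)."""
    if cfg.simulate is not None:
        return generate_study(_sim_config(cfg))
    human = read_abundance(cfg.inputs["human"]["abundance"], cfg.inputs["human"]["metadata"])
    pig = read_abundance(cfg.inputs["pig"]["abundance"], cfg.inputs["pig"]["metadata"])
    meta = pd.concat([human[1].data, pig[1].data], ignore_index=True)
    return human[0], pig[0], SampleTable(meta), None


def _species_view(matrix: AbundanceMatrix, samples: SampleTable, species: str):
    meta = samples.data[samples.data["species"] == species].reset_index(drop=True)
    return matrix.subset_samples(meta["sample_id"]), SampleTable(meta)


def _per_timepoint_designs(
    matrix: AbundanceMatrix, samples: SampleTable, timepoints, paired: bool
) -> dict[tuple[str, float], tuple[AbundanceMatrix, SampleTable, DesignSpec]]:
    """The within-species univariate battery: injury status vs controls,
    severity grade among injured, continuous recovery among injured, at
    each timepoint; batch always as covariate."""
    meta = samples.data
    if "injured" not in meta:
        meta = meta.copy()
        meta["injured"] = ((meta["severity_grade"] > 0) & (meta["timepoint_h"] > 0)).astype(int)
        samples = SampleTable(meta)
    out: dict[tuple[str, float], tuple] = {}
    control = meta["injured"] == 0
    for t in timepoints:
        at_t = meta["timepoint_h"] == t
        inj_t = at_t & ~control
        # injury status: injured at t vs the uninjured/control arm
        sel = inj_t | control
        sub_meta = SampleTable(meta[sel].reset_index(drop=True))
        sub = matrix.subset_samples(sub_meta.data["sample_id"])
        design = DesignSpec(
            outcome="injured",
            encoding="binary",
            covariates=("batch",) if not paired else (),
            paired_subject="subject_id" if paired else None,
        )
        out[("injury", t)] = (sub, sub_meta, design)
        # severity and recovery among injured samples at t
        sub_meta2 = SampleTable(meta[inj_t].reset_index(drop=True))
        sub2 = matrix.subset_samples(sub_meta2.data["sample_id"])
        out[("severity", t)] = (sub2, sub_meta2, DesignSpec(
            outcome="severity_grade", encoding="ordinal_numeric", covariates=("batch",)))
        out[("recovery", t)] = (sub2, sub_meta2, DesignSpec(
            outcome="outcome_cont", encoding="continuous",
            covariates=("injury_level", "batch")))
    return out


def run_within_species(cfg: PipelineConfig) -> dict:
    """Within-species biomarker workflow; returns a report dict and writes
    per-stage TSVs under cfg.out_dir."""
    cfg.validate()
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    species = cfg.param("within", "species", "human")
    q_thr = cfg.param("de", "q_threshold", 0.05)

    human, pig, samples, truth = _load_study(cfg)
    matrix, meta = _species_view(human if species == "human" else pig, samples, species)
    if truth is not None:
        truth.to_json(out_dir / "truth.json")

    stage = "preprocess"
    matrix = filter_detection(matrix, cfg.param("preprocess", "min_fraction", 1 / 3))
    paired = bool(cfg.param("de", "paired", species == "pig"))
    timepoints = sorted(t for t in meta.data["timepoint_h"].unique() if t > 0)

    report: dict = {"species": species, "timepoints": timepoints}
    results: dict[tuple[str, float], DEResult] = {}
    for key, (sub, sub_meta, design) in _per_timepoint_designs(matrix, meta, timepoints, paired).items():
        try:
            res = fit_moderated_lm(filter_detection(sub), sub_meta, design)
        except ValueError as exc:
            log.warning("DE fit skipped for %s: %s", key, exc)
            continue
        results[key] = res
        _write(res.table, out_dir / f"de_{key[0]}_t{int(key[1]):04d}.tsv", cfg, "de",
               outcome=key[0], timepoint=key[1])

    inj_sets = {t: results[("injury", t)].significant(q_thr)
                for t in timepoints if ("injury", t) in results}
    counts = pd.DataFrame({"timepoint_h": list(inj_sets), "n_de": [len(s) for s in inj_sets.values()]})
    _write(counts, out_dir / "de_counts.tsv", cfg, "de_counts", index=False)
    jac = jaccard_de_overlap(inj_sets)
    _write(jac, out_dir / "jaccard.tsv", cfg, "jaccard")
    rec = recurrent_associations(results, q_threshold=q_thr)
    rec.columns = ["_".join(map(str, c)) if isinstance(c, tuple) else c for c in rec.columns]
    _write(rec, out_dir / "recurrent_associations.tsv", cfg, "recurrent")
    report.update(
        de_counts=dict(zip(counts["timepoint_h"], counts["n_de"])),
        jaccard=jac,
        recurrent=rec,
        de_results=results,
    )

    if cfg.stage_on("clustering"):
        control = cfg.param("cluster", "control_group", "control" if species == "human" else "sham")
        imputed = impute_half_min(remove_batch_effect(matrix, meta))
        traj = logfc_trajectories(imputed, meta, control_group=control)
        res = consensus_kmeans(
            traj,
            k_range=list(range(2, cfg.param("cluster", "kmax", 8) + 1)),
            n_subsamples=cfg.param("cluster", "n_subsamples", 100),
            seed=cfg.seed,
        )
        assignment = prune_small_clusters(res.chosen_assignment)
        _write(assignment.rename("cluster").to_frame(), out_dir / "clusters.tsv", cfg,
               "cluster", chosen_k=res.chosen_k)
        report.update(trajectories=traj, consensus=res, assignment=assignment)
        gmt = cfg.param("cluster", "gmt", None)
        if gmt:
            enr = cluster_enrichment(assignment[assignment > 0], read_gmt(gmt),
                                     background=list(traj.index))
            _write(enr, out_dir / "enrichment.tsv", cfg, "enrichment", index=False)
            report["enrichment"] = enr
    return report


def run_cross_species(cfg: PipelineConfig) -> dict:
    """Cross-species conservation workflow."""
    cfg.validate()
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    q_thr = cfg.param("de", "q_threshold", 0.05)
    k = cfg.param("nacc", "k", 10)
    n_perm = cfg.param("perm", "n_perm", 1000)

    human, pig, samples, truth = _load_study(cfg)
    if truth is not None:
        truth.to_json(out_dir / "truth.json")
    hmat, hmeta = _species_view(human, samples, "human")
    pmat, pmeta = _species_view(pig, samples, "pig")

    # preprocessing chain per species
    def _prep(m: AbundanceMatrix, meta: SampleTable) -> AbundanceMatrix:
        m = remove_batch_effect(m, meta)
        m = filter_detection(m, cfg.param("preprocess", "min_fraction", 1 / 3))
        return impute_half_min(m)

    hprep, pprep = _prep(hmat, hmeta), _prep(pmat, pmeta)
    shared_ids = hprep.protein_ids.intersection(pprep.protein_ids)
    shared_map = {pid: pid for pid in shared_ids}
    combined, blocks = zscore_within_species(hprep, pprep, shared_map)
    meta_all = SampleTable(pd.concat([hmeta.data, pmeta.data], ignore_index=True))

    report: dict = {"n_shared_proteins": combined.n_proteins}

    # modularity at shared timepoints, species vs time grouping
    shared_t = cfg.param("modularity", "timepoints", list(SHARED_TIMEPOINTS))
    densities = cfg.param("modularity", "densities", [0.05, 0.1, 0.2, 0.3, 0.4, 0.5])
    curves = modularity_curve(combined, meta_all, ["species", "timepoint_h"], densities,
                              restrict_timepoints=shared_t)
    curve_df = pd.concat(
        [pd.DataFrame({"grouping": c.grouping, "density": c.densities, "Q": c.q_values})
         for c in curves], ignore_index=True)
    _write(curve_df, out_dir / "modularity.tsv", cfg, "modularity", index=False)
    report["modularity"] = curves

    # per-timepoint-pair RRHO battery over the injury-status contrast
    paired_pig = bool(cfg.param("de", "paired", True))
    h_designs = _per_timepoint_designs(hprep, hmeta,
                                       [t for t in shared_t if t in set(hmeta.data["timepoint_h"])],
                                       paired=False)
    p_tp = sorted(t for t in pmeta.data["timepoint_h"].unique()
                  if 0 < t <= cfg.param("dtw", "max_pig_hours", 120.0))
    p_designs = _per_timepoint_designs(pprep, pmeta, p_tp, paired=paired_pig)
    h_de = {t: fit_moderated_lm(*h_designs[("injury", t)])
            for t in shared_t if ("injury", t) in h_designs}
    p_de = {t: fit_moderated_lm(*p_designs[("injury", t)]) for t in p_tp}
    battery = {}
    step = cfg.param("rrho", "step", None)
    for th, de_h in h_de.items():
        for tp, de_p in p_de.items():
            uni = sorted(set(de_h.table.index[de_h.table["testable"]])
                         & set(de_p.table.index[de_p.table["testable"]]))
            s = step or max(1, len(uni) // 100)
            battery[(th, tp)] = rrho_map(rank_by_de(de_h, uni), rank_by_de(de_p, uni), step=s)
    rrho_df = pd.DataFrame(
        [{"human_t": th, "pig_t": tp, "max_neglog10p": r.observed_max}
         for (th, tp), r in battery.items()])
    _write(rrho_df, out_dir / "rrho_battery.tsv", cfg, "rrho", index=False)
    report["rrho_battery"] = battery

    # NACC protein and gene-set tables
    nacc = nacc_scores(combined, blocks, k=k)
    if n_perm > 0:
        nacc = nacc_permutation_test(nacc, n_perm=n_perm, seed=cfg.seed)
    _write(nacc.table, out_dir / "nacc_proteins.tsv", cfg, "nacc", k=k)
    report["nacc"] = nacc
    gmt = cfg.param("nacc", "gmt", None)
    gene_sets = read_gmt(gmt) if gmt else None
    if gene_sets is None and truth is not None:
        gene_sets = generate_gene_sets(
            list(combined.protein_ids), n_sets=30, size_range=(3, 50),
            overlap_with_modules=0.3, seed=cfg.seed, modules=truth.modules())
        write_gmt(gene_sets, out_dir / "gene_sets.gmt")
    if gene_sets and n_perm > 0:
        set_table = nacc_gene_set_test(nacc, gene_sets, n_perm=n_perm, seed=cfg.seed)
        _write(set_table, out_dir / "nacc_gene_sets.tsv", cfg, "nacc_sets", index=False)
        alpha = cfg.param("nacc", "alpha", 0.05)
        report["nacc_gene_sets"] = set_table
        report["n_conserved_sets"] = int((set_table["p_conserved"] < alpha).sum())
        report["n_divergent_sets"] = int((set_table["p_divergent"] < alpha).sum())

    # pi1: test in pig the proteins altered in human (matched timepoints)
    pi1_rows = []
    for t in shared_t:
        if t not in h_de or t not in p_de:
            continue
        hits = h_de[t].significant(q_thr)
        pig_p = p_de[t].table.loc[sorted(hits & set(p_de[t].table.index)), "p"].dropna()
        if len(pig_p) >= 10:
            pi1_rows.append({"timepoint_h": t, "n": len(pig_p),
                             "pi1": estimate_pi0(pig_p.to_numpy()).pi1})
    pi1_df = pd.DataFrame(pi1_rows)
    _write(pi1_df, out_dir / "pi1.tsv", cfg, "pi1", index=False)
    report["pi1"] = pi1_df

    # DTW alignment of the smoothed whole-proteome time courses
    zh = combined.subset_samples(blocks["human"])
    zp = combined.subset_samples(blocks["pig"])
    h_traj = _mean_by_timepoint(zh, hmeta, max_hours=None)
    p_traj = _mean_by_timepoint(zp, pmeta, max_hours=cfg.param("dtw", "max_pig_hours", 120.0))
    upsample = cfg.param("dtw", "upsample_factor", 10)
    hs = smooth_profiles(h_traj.columns.to_numpy(float), h_traj, upsample_factor=upsample)
    ps = smooth_profiles(p_traj.columns.to_numpy(float), p_traj, upsample_factor=upsample)
    alignment = dtw_align(hs, ps)
    path_df = pd.DataFrame(
        [{"human_t": alignment.human_grid[i], "pig_t": alignment.pig_grid[j]}
         for i, j in alignment.path])
    _write(path_df, out_dir / "dtw_path.tsv", cfg, "dtw",
           total_cost=round(alignment.total_cost, 6))
    report["alignment"] = alignment
    report["warp_slope"] = path_slope(alignment)
    return report


def _mean_by_timepoint(m: AbundanceMatrix, samples: SampleTable, max_hours: float | None) -> pd.DataFrame:
    """Per-protein mean abundance per injured timepoint (controls and, when
    ``max_hours`` is set, chronic timepoints are excluded)."""
    meta = samples.aligned(m.sample_ids).set_index("sample_id")
    injured = (meta["severity_grade"] > 0) & (meta["timepoint_h"] > 0)
    tps = sorted(meta.loc[injured, "timepoint_h"].unique())
    if max_hours is not None:
        tps = [t for t in tps if t <= max_hours]
    cols = {}
    for t in tps:
        ids = meta.index[injured & (meta["timepoint_h"] == t)]
        cols[t] = m.data.loc[:, ids].mean(axis=1)
    return pd.DataFrame(cols)
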