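"""Synthetic two-species time-course proteomics generator.

Emulates the data structure of a paired human/pig biofluid study: targeted
protein panels measured across post-injury timepoints in graded-severity
cohorts, with planted injury effects following parametric temporal profiles,
correlated coexpression modules that are either conserved or divergent
across species, plate batch shifts, left-censored missingness at a
detection limit, and a known linear time warp between the species' injury
responses.  Every planted quantity is recorded in a :class:`SyntheticTruth`
ledger so downstream stages can be tested for parameter recovery.

Model for the latent log2 abundance of protein g in sample j::

    y_gj = baseline_g
         + injured_j * effect_g * profile_g(warp * t_j)
         + injured_j * severity_slope_g * grade_j
         + injured_j * outcome_slope_g * outcome_j
         + batch_offset_{batch_j, g}
         + noise_sd * (sqrt(rho) * load_g * F_{m(g), j} + sqrt(1-rho) * eps_gj)

where ``warp`` is ``warp_factor`` for the pig (its response runs
``warp_factor`` times faster) and 1 for the human, ``rho`` is the
within-module correlation, F a per-module latent factor, and ``load_g`` a
+/-1 loading.  Conserved modules keep their membership and loadings in both
species; divergent modules re-draw their pig membership from module-free
proteins, so the reference members carry no pig coexpression structure.
Values below the per-species ``lod_quantile`` of the latent distribution
are censored to missing.
"""

from __future__ import annotations

import dataclasses
import json
import math
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import AbundanceMatrix, SampleTable

__all__ = [
    "SpeciesSpec",
    "SimConfig",
    "SyntheticTruth",
    "ConfigError",
    "generate_study",
    "generate_gene_sets",
    "default_config",
    "TEMPORAL_PROFILES",
]


class ConfigError(ValueError):
    """A simulation parameter is outside its admissible range."""


# Temporal response shapes, all anchored to 0 at t=0 (no effect pre-injury)
# and with unit-magnitude extrema over the first five days.
TEMPORAL_PROFILES: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "hyperacute_spike": lambda t: (t / 12.0) * np.exp(1.0 - t / 12.0),
    "early_spike": lambda t: (t / 24.0) * np.exp(1.0 - t / 24.0),
    "delayed_rise": lambda t: (
        1.0 / (1.0 + np.exp(-(t - 72.0) / 18.0)) - 1.0 / (1.0 + np.exp(72.0 / 18.0))
    ) / (1.0 - 1.0 / (1.0 + np.exp(72.0 / 18.0))),
    "monotone_decline": lambda t: -(1.0 - np.exp(-t / 24.0)),
    "sustained": lambda t: 1.0 - np.exp(-t / 12.0),
}


@dataclasses.dataclass
class SpeciesSpec:
    """Design of one species' cohort.

    ``groups`` maps group label -> ordinal severity grade; the grade-0
    group is the uninjured control/sham arm.  ``paired_baseline`` adds a
    pre-injury (t=0) sample for every injured subject, mirroring a
    repeated-measures animal design; otherwise the control arm supplies
    independent uninjured subjects sampled once.
    """

    name: str
    groups: dict[str, int]
    n_subjects: int
    timepoints: Sequence[float]
    n_batches: int = 2
    paired_baseline: bool = False
    control_at_baseline_only: bool = True
    dropout_rate: float = 0.0


@dataclasses.dataclass
class SimConfig:
    n_proteins: int = 350
    shared_protein_fraction: float = 0.8
    species_specs: dict[str, SpeciesSpec] = dataclasses.field(default_factory=dict)
    module_sizes: Sequence[int] = (25, 25, 25, 25)
    within_module_corr: float = 0.6
    conserved_module_fraction: float = 0.5
    de_fraction: float = 0.35
    effect_size_sd: float = 1.0
    severity_slope_sd: float = 0.3
    severity_assoc_fraction: float = 0.2
    outcome_assoc_fraction: float = 0.1
    outcome_severity_corr: float = 0.6
    shared_effect_fraction: float = 0.7
    batch_sd: float = 0.3
    noise_sd: float = 0.5
    lod_quantile: float = 0.05
    warp_factor: float = 2.0
    biofluid: str = "csf"
    seed: int = 0

    def validate(self) -> None:
        for field in (
            "shared_protein_fraction",
            "severity_assoc_fraction",
            "conserved_module_fraction",
            "de_fraction",
            "outcome_assoc_fraction",
            "shared_effect_fraction",
            "lod_quantile",
            "within_module_corr",
        ):
            v = getattr(self, field)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{field} must be in [0, 1], got {v}")
        if self.n_proteins < 1:
            raise ConfigError(f"n_proteins must be positive, got {self.n_proteins}")
        if sum(self.module_sizes) > self.n_proteins:
            raise ConfigError(
                f"module_sizes sum {sum(self.module_sizes)} exceeds n_proteins {self.n_proteins}"
            )
        if self.warp_factor <= 0:
            raise ConfigError(f"warp_factor must be > 0, got {self.warp_factor}")
        if not self.species_specs:
            raise ConfigError("species_specs must name at least one species")
        for sp in self.species_specs.values():
            tps = list(sp.timepoints)
            if any(b <= a for a, b in zip(tps, tps[1:])):
                raise ConfigError(f"timepoints for {sp.name} must be strictly increasing: {tps}")
            if any(t <= 0 for t in tps):
                raise ConfigError(f"timepoints for {sp.name} must be > 0 (baseline is implicit)")
            if 0 not in sp.groups.values():
                raise ConfigError(f"species {sp.name} needs a grade-0 control/sham group")
            if not 0.0 <= sp.dropout_rate < 1.0:
                raise ConfigError(f"dropout_rate for {sp.name} must be in [0, 1)")


@dataclasses.dataclass
class SyntheticTruth:
    """Ground-truth ledger for one generated study."""

    de_proteins: dict[str, dict[str, dict]]  # species -> protein -> {effect, profile}
    severity_assoc: dict[str, dict[str, float]]  # species -> protein -> slope
    outcome_assoc: dict[str, dict[str, float]]
    module_membership: dict[str, int]  # shared protein -> module id (reference species)
    pig_module_membership: dict[str, int]  # module realization in the second species
    module_conserved: dict[int, bool]
    batch_offsets: dict[str, dict[str, list[float]]]  # species -> batch -> per-protein shift
    warp_map: dict  # {"type": "linear", "warp_factor": w}; pig state at t = human profile at w*t
    censoring_threshold: dict[str, float]
    seed: int

    def modules(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for pid, m in self.module_membership.items():
            out.setdefault(m, []).append(pid)
        return out

    def to_json(self, path) -> None:
        d = dataclasses.asdict(self)
        d["module_conserved"] = {str(k): v for k, v in d["module_conserved"].items()}
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)


def default_config(seed: int = 0, **overrides) -> SimConfig:
    """Study-scale default: a ~100-patient-like human arm with 3 severity
    grades over five daily timepoints, and a paired-baseline pig arm with
    sham + 3 contusion severities over six timepoints out to 12 weeks."""
    specs = {
        "human": SpeciesSpec(
            name="human",
            groups={"control": 0, "gradeC": 1, "gradeB": 2, "gradeA": 3},
            n_subjects=12,
            timepoints=(24.0, 48.0, 72.0, 96.0, 120.0),
            n_batches=4,
            paired_baseline=False,
        ),
        "pig": SpeciesSpec(
            name="pig",
            groups={"sham": 0, "mild": 1, "moderate": 2, "severe": 3},
            n_subjects=10,
            timepoints=(12.0, 24.0, 48.0, 72.0, 120.0, 2016.0),
            n_batches=3,
            paired_baseline=True,
            control_at_baseline_only=False,
        ),
    }
    if "module_sizes" not in overrides:
        # four modules of ~7% of the panel each (25 proteins at the
        # default 350), so module structure scales with panel size
        n = overrides.get("n_proteins", 350)
        overrides["module_sizes"] = (max(4, round(0.07 * n)),) * 4
    cfg = SimConfig(species_specs=specs, seed=seed)
    return dataclasses.replace(cfg, **overrides)


def _draw_slopes(rng: np.random.Generator, n: int, scale: float) -> np.ndarray:
    """Planted slopes: random sign, magnitude uniform in [0.5, 2] x scale.

    A mean-zero draw would plant 'positives' of arbitrarily small size,
    making recovery against the truth ledger ill-defined; every planted
    association is a genuine signal by construction.
    """
    sign = rng.choice([-1.0, 1.0], size=n)
    return sign * scale * rng.uniform(0.5, 2.0, size=n)


def _sample_frame(cfg: SimConfig, sp: SpeciesSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Build the per-sample metadata rows for one species."""
    rows = []
    levels = ["cervical", "thoracic", "lumbar"]
    subj_idx = 0
    for group, grade in sp.groups.items():
        for i in range(sp.n_subjects):
            subj = f"{sp.name[:3]}_subj{subj_idx:03d}"
            subj_idx += 1
            level = levels[int(rng.integers(len(levels)))]
            rows.append((subj, group, grade, level))
    subjects = pd.DataFrame(rows, columns=["subject_id", "group", "severity_grade", "injury_level"])

    # continuous recovery outcome linked (negatively) to severity grade
    grades = subjects["severity_grade"].to_numpy(float)
    gsd = grades.std()
    zg = (grades - grades.mean()) / gsd if gsd > 0 else np.zeros_like(grades)
    r = cfg.outcome_severity_corr
    subjects["outcome_cont"] = -r * zg + math.sqrt(1.0 - r * r) * rng.standard_normal(len(grades))
    subjects["outcome_bin"] = (subjects["outcome_cont"] > 0).astype(int)

    samples = []
    for _, s in subjects.iterrows():
        is_control_arm = s["severity_grade"] == 0
        if is_control_arm and sp.control_at_baseline_only:
            tps = [0.0]
        elif is_control_arm:
            tps = [0.0] + list(sp.timepoints) if sp.paired_baseline else list(sp.timepoints)
        else:
            tps = list(sp.timepoints)
            if sp.paired_baseline:
                tps = [0.0] + tps
        for t in tps:
            injured = (s["severity_grade"] > 0) and (t > 0)
            if injured and sp.dropout_rate > 0 and rng.uniform() < sp.dropout_rate:
                continue
            samples.append(
                {
                    "sample_id": f"{s['subject_id']}_t{int(t):05d}",
                    "subject_id": s["subject_id"],
                    "species": sp.name,
                    "biofluid": cfg.biofluid,
                    "timepoint_h": float(t),
                    "group": s["group"],
                    "severity_grade": int(s["severity_grade"]),
                    "outcome_cont": float(s["outcome_cont"]),
                    "outcome_bin": int(s["outcome_bin"]),
                    "injury_level": s["injury_level"],
                    "batch": "",
                    "injured": bool(injured),
                }
            )
    frame = pd.DataFrame(samples)
    # plate assignment: deterministic round-robin after a seeded shuffle
    order = rng.permutation(len(frame))
    batch_labels = np.empty(len(frame), dtype=object)
    for pos, idx in enumerate(order):
        batch_labels[idx] = f"{sp.name[:3]}_plate{pos % sp.n_batches}"
    frame["batch"] = batch_labels
    return frame


def generate_study(
    config: SimConfig,
) -> tuple[AbundanceMatrix, AbundanceMatrix, SampleTable, SyntheticTruth]:
    """Generate paired two-species abundance matrices, a combined sample
    table, and the ground-truth ledger.  Deterministic given config.seed."""
    config.validate()
    if set(config.species_specs) != {"human", "pig"}:
        raise ConfigError("species_specs must contain exactly 'human' and 'pig'")
    rng = np.random.default_rng(config.seed)

    n = config.n_proteins
    n_shared = int(round(config.shared_protein_fraction * n))
    shared_ids = [f"P{i:04d}" for i in range(n_shared)]
    human_ids = shared_ids + [f"HUM{i:04d}" for i in range(n - n_shared)]
    pig_ids = shared_ids + [f"PIG{i:04d}" for i in range(n - n_shared)]

    # --- modules (over shared proteins only) ------------------------------
    module_sizes = list(config.module_sizes)
    if sum(module_sizes) > n_shared:
        raise ConfigError("module_sizes sum exceeds the shared protein count")
    pool = rng.permutation(n_shared)
    module_membership: dict[str, int] = {}
    pos = 0
    for m, size in enumerate(module_sizes):
        for j in pool[pos : pos + size]:
            module_membership[shared_ids[j]] = m
        pos += size
    n_conserved = int(round(config.conserved_module_fraction * len(module_sizes)))
    conserved_ids = rng.choice(len(module_sizes), size=n_conserved, replace=False)
    module_conserved = {m: bool(m in set(conserved_ids.tolist())) for m in range(len(module_sizes))}

    # human loadings; conserved modules keep membership and loadings in pig,
    # divergent modules re-draw their pig membership from module-free
    # proteins, so the original members carry no pig coexpression structure
    loads_h = {pid: float(rng.choice([-1.0, 1.0])) for pid in module_membership}
    pig_membership: dict[str, int] = {}
    loads_p: dict[str, float] = {}
    free = [pid for pid in shared_ids if pid not in module_membership]
    free_pos = 0
    for m, size in enumerate(module_sizes):
        members = [pid for pid, mm in module_membership.items() if mm == m]
        if module_conserved[m]:
            for pid in members:
                pig_membership[pid] = m
                loads_p[pid] = loads_h[pid]
        else:
            if free_pos + size > len(free):
                raise ConfigError(
                    "not enough module-free shared proteins to re-draw divergent pig modules; "
                    "reduce module_sizes or raise shared_protein_fraction"
                )
            for pid in free[free_pos : free_pos + size]:
                pig_membership[pid] = m
                loads_p[pid] = float(rng.choice([-1.0, 1.0]))
            free_pos += size

    # --- planted effects ---------------------------------------------------
    profile_names = list(TEMPORAL_PROFILES)
    n_de = int(round(config.de_fraction * n))
    de_h = rng.choice(n, size=n_de, replace=False)
    de_h_ids = [human_ids[i] for i in sorted(de_h)]
    effects_h = _draw_slopes(rng, n_de, config.effect_size_sd)
    profiles_h = [profile_names[int(k)] for k in rng.integers(len(profile_names), size=n_de)]
    de_human = {
        pid: {"effect": float(e), "profile": pr}
        for pid, e, pr in zip(de_h_ids, effects_h, profiles_h)
    }

    # pig: shared DE proteins keep the human effect with prob shared_effect_fraction;
    # pig-only proteins get their own draws so the overall DE rate matches.
    de_pig: dict[str, dict] = {}
    shared_de = [pid for pid in de_h_ids if pid in set(shared_ids)]
    keep = rng.uniform(size=len(shared_de)) < config.shared_effect_fraction
    for pid, k in zip(shared_de, keep):
        if k:
            de_pig[pid] = dict(de_human[pid])
    n_extra = n_de - len(de_pig)
    candidates = [pid for pid in pig_ids if pid not in de_pig and pid not in de_human]
    extra = rng.choice(len(candidates), size=min(n_extra, len(candidates)), replace=False)
    extra_ids = [candidates[i] for i in sorted(extra)]
    effects_p = _draw_slopes(rng, len(extra_ids), config.effect_size_sd)
    profiles_p = [profile_names[int(k)] for k in rng.integers(len(profile_names), size=len(extra_ids))]
    for pid, e, pr in zip(extra_ids, effects_p, profiles_p):
        de_pig[pid] = {"effect": float(e), "profile": pr}

    # severity and outcome associations live on DE proteins only, so a
    # de_fraction=0 configuration is a clean global null for injury tests
    severity_assoc: dict[str, dict[str, float]] = {}
    outcome_assoc: dict[str, dict[str, float]] = {}
    for sp_name, de_map in (("human", de_human), ("pig", de_pig)):
        pids = sorted(de_map)
        sev_pick = rng.uniform(size=len(pids)) < config.severity_assoc_fraction
        sev_slopes = _draw_slopes(rng, len(pids), config.severity_slope_sd)
        severity_assoc[sp_name] = {
            pid: float(sl) for pid, p, sl in zip(pids, sev_pick, sev_slopes) if p
        }
        n_out = min(int(round(config.outcome_assoc_fraction * n)), len(pids))
        out_pick = rng.choice(len(pids), size=n_out, replace=False)
        out_slopes = _draw_slopes(rng, n_out, config.severity_slope_sd)
        outcome_assoc[sp_name] = {
            pids[i]: float(sl) for i, sl in zip(sorted(out_pick), out_slopes)
        }

    # --- assemble each species' matrix ------------------------------------
    matrices: dict[str, AbundanceMatrix] = {}
    frames: list[pd.DataFrame] = []
    batch_offsets: dict[str, dict[str, list[float]]] = {}
    censoring: dict[str, float] = {}
    baseline_shared = rng.uniform(6.0, 14.0, size=n_shared)

    for sp_name in ("human", "pig"):
        sp = config.species_specs[sp_name]
        ids = human_ids if sp_name == "human" else pig_ids
        de_map = de_human if sp_name == "human" else de_pig
        loads = loads_h if sp_name == "human" else loads_p
        membership = module_membership if sp_name == "human" else pig_membership
        warp = 1.0 if sp_name == "human" else config.warp_factor

        frame = _sample_frame(config, sp, rng)
        frames.append(frame)
        ns = len(frame)
        t = frame["timepoint_h"].to_numpy(float)
        injured = frame["injured"].to_numpy(bool).astype(float)
        grade = frame["severity_grade"].to_numpy(float)
        outcome = frame["outcome_cont"].to_numpy(float)

        baseline = np.concatenate([baseline_shared, rng.uniform(6.0, 14.0, size=n - n_shared)])
        latent = np.tile(baseline[:, None], (1, ns))

        idx = {pid: i for i, pid in enumerate(ids)}
        for pid, rec in de_map.items():
            shape = TEMPORAL_PROFILES[rec["profile"]](warp * t)
            latent[idx[pid]] += rec["effect"] * shape * injured
        for pid, slope in severity_assoc[sp_name].items():
            latent[idx[pid]] += slope * grade * injured
        for pid, slope in outcome_assoc[sp_name].items():
            latent[idx[pid]] += slope * outcome * injured

        # module factors + noise
        rho = config.within_module_corr
        factors = rng.standard_normal((len(module_sizes), ns))
        eps = rng.standard_normal((n, ns))
        resid = config.noise_sd * math.sqrt(1.0 - rho) * eps
        plain = np.ones(n, dtype=bool)
        for pid, m in membership.items():
            i = idx[pid]
            plain[i] = False
            latent[i] += config.noise_sd * (
                math.sqrt(rho) * loads[pid] * factors[m] + math.sqrt(1.0 - rho) * eps[i]
            )
        latent[plain] += config.noise_sd * eps[plain]

        # batch offsets
        offsets: dict[str, list[float]] = {}
        batches = frame["batch"].to_numpy()
        for b in sorted(set(batches)):
            shift = rng.normal(0.0, config.batch_sd, size=n) if config.batch_sd > 0 else np.zeros(n)
            offsets[b] = shift.tolist()
            latent[:, batches == b] += shift[:, None]
        batch_offsets[sp_name] = offsets

        # left-censoring at the detection limit
        thr = float(np.quantile(latent, config.lod_quantile)) if config.lod_quantile > 0 else -np.inf
        censoring[sp_name] = thr
        observed = np.where(latent >= thr, latent, np.nan)
        matrices[sp_name] = AbundanceMatrix(
            data=pd.DataFrame(observed, index=ids, columns=frame["sample_id"].tolist()),
            scale_tag="log2",
        )

    # `injured` is kept as a derived convenience column (severity_grade > 0
    # and timepoint_h > 0); paired-baseline samples are the uninjured arm
    meta = pd.concat(frames, ignore_index=True)
    meta["injured"] = meta["injured"].astype(int)
    truth = SyntheticTruth(
        de_proteins={"human": de_human, "pig": de_pig},
        severity_assoc=severity_assoc,
        outcome_assoc=outcome_assoc,
        module_membership=module_membership,
        pig_module_membership=pig_membership,
        module_conserved=module_conserved,
        batch_offsets=batch_offsets,
        warp_map={"type": "linear", "warp_factor": float(config.warp_factor)},
        censoring_threshold=censoring,
        seed=config.seed,
    )
    return matrices["human"], matrices["pig"], SampleTable(meta), truth


def generate_gene_sets(
    protein_ids: Sequence[str],
    n_sets: int,
    size_range: tuple[int, int],
    overlap_with_modules: float,
    seed: int,
    modules: Mapping[int, Sequence[str]] | None = None,
) -> dict[str, list[str]]:
    """Build a GMT-writable gene-set collection over ``protein_ids``.

    ``overlap_with_modules`` of the sets reproduce planted module
    memberships (positive controls); the remainder are uniform random
    draws with sizes uniform on ``size_range``.
    """
    lo, hi = size_range
    if lo < 2 or hi > len(protein_ids) or lo > hi:
        raise ConfigError(f"size_range {size_range} infeasible for {len(protein_ids)} proteins")
    if not 0.0 <= overlap_with_modules <= 1.0:
        raise ConfigError("overlap_with_modules must be in [0, 1]")
    rng = np.random.default_rng(seed)
    sets: dict[str, list[str]] = {}
    n_module_sets = int(round(overlap_with_modules * n_sets))
    if n_module_sets > 0:
        if not modules:
            raise ConfigError("overlap_with_modules > 0 requires planted modules")
        mod_ids = sorted(modules)
        for i in range(min(n_module_sets, len(mod_ids))):
            m = mod_ids[i]
            sets[f"SET_module{m}"] = sorted(modules[m])
    i = 0
    while len(sets) < n_sets:
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(protein_ids), size=size, replace=False)
        sets[f"SET_rand{i:03d}"] = sorted(protein_ids[j] for j in members)
        i += 1
    return sets
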