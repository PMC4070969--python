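"""End-to-end orchestration: simulate -> process -> type -> diversity ->
ordinate -> compare.

The default run emulates the field design the analysis was built for: a
2 x 2 factorial (cultivation system CS/SRI x compost amendment) in a
completely randomized design with three plot replicates, each plot profiled
by three replicate electropherogram runs and a 96-clone library.  Treatment
effects are imposed as smooth multiplicative tilts of the base community's
abundances, so the four treatment groups genuinely differ while sharing the
same phylotype pool.

Every stage writes plain-text outputs into the run directory and the run
manifest records the configuration, seed, and per-stage row counts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .digest import (FAM, HEX, assign_trfs, estimate_abundances,
                     phylotypes_present, rflp_pattern)
from .diversity import profile_diversity, rarefy, richness
from .factorial import tukey_kramer, two_way_anova
from .ordination import mds, pca
from .peaks import (abundance_filter, bin_peaks, consensus_profile,
                    filter_peaks, qc_dynamic_range)
from .synthetic import (GroundTruthCommunity, NoiseModel, generate_community,
                        sample_clone_library, simulate_profiles)

STAGES = ["simulate", "peak_processing", "typing", "diversity",
          "ordination", "anova"]

#: the bundled ground-truth fixture: 5 phylotypes with known, well-separated
#: abundances (all comfortably above the 1% area filter)
FIXTURE_ABUNDANCES = (0.35, 0.25, 0.18, 0.13, 0.09)


@dataclass
class RunConfig:
    """All pipeline thresholds, at the analysis' standard values."""

    out_dir: str = "trflp-run"
    seed: int = 42
    # community / simulation
    n_phylotypes: int = 5
    abundances: tuple[float, ...] | None = FIXTURE_ABUNDANCES
    min_trf_separation: float = 5.0
    jitter_sd: float = 0.15
    spurious_rate: float = 2.0
    area_cv: float = 0.05
    n_replicates: int = 3
    n_plots: int = 3
    n_clones: int = 96
    system_effect: float = 0.8
    amendment_effect: float = 0.5
    plot_sd: float = 0.1
    #: number of phylotypes restricted to SRI plots (mirrors taxa intolerant
    #: of continuous flooding; gives the binary incidence matrix variance)
    n_sri_only: int = 1
    # processing thresholds
    amplitude_threshold: float = 50.0
    min_size: float = 50.0
    max_size: float = 600.0
    bin_window: float = 1.2
    min_fraction: float = 0.01
    fluorescence_range: tuple[float, float] = (2000.0, 8000.0)
    # typing
    match_tolerance: float = 2.0
    dye_offsets: tuple[float, float] = (0.0, 0.0)
    # statistics
    alpha: float = 0.05
    # optional externally supplied peak table (overrides the simulated one)
    peaks_csv: str | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def fixture_community(config: RunConfig | None = None) -> GroundTruthCommunity:
    """The base ground-truth community of a run (the bundled fixture for
    default settings: 5 phylotypes, known abundances, seed 42)."""
    cfg = config or RunConfig()
    return generate_community(cfg.n_phylotypes,
                              min_trf_separation=cfg.min_trf_separation,
                              seed=cfg.seed, abundances=cfg.abundances)


def _tilted(community: GroundTruthCommunity, log_tilt: np.ndarray,
            seed: int) -> GroundTruthCommunity:
    ab = np.asarray(community.abundances) * np.exp(log_tilt)
    ab = ab / ab.sum()
    return GroundTruthCommunity(community.phylotype_ids,
                                tuple(float(x) for x in ab),
                                community.sequences, seed)


def _design(config: RunConfig) -> list[dict]:
    """Plot-level design rows: system x amendment x plot replicate."""
    rows = []
    for system in ("CS", "SRI"):
        for amendment in ("control", "compost"):
            for plot in range(1, config.n_plots + 1):
                rows.append({"system": system, "amendment": amendment,
                             "plot": plot,
                             "sample_id": f"{system}-{amendment}-p{plot}"})
    return rows


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in order and return the run manifest.

    Outputs land under ``config.out_dir``.  Any stage failure raises
    :class:`StageError` naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "stages": []}
    state: dict = {}

    def run_stage(name, fn):
        try:
            info = fn()
        except Exception as exc:
            raise StageError(name, exc) from exc
        manifest["stages"].append({"name": name, "status": "completed",
                                   **info})

    run_stage("simulate", lambda: _stage_simulate(config, out, state))
    run_stage("peak_processing", lambda: _stage_process(config, out, state))
    run_stage("typing", lambda: _stage_typing(config, out, state))
    run_stage("diversity", lambda: _stage_diversity(config, out, state))
    run_stage("ordination", lambda: _stage_ordination(config, out, state))
    run_stage("anova", lambda: _stage_anova(config, out, state))

    io.write_json(manifest, out / "manifest.json")
    return manifest


def _stage_simulate(config: RunConfig, out: Path, state: dict) -> dict:
    base = fixture_community(config)
    noise = NoiseModel(size_jitter_sd=config.jitter_sd,
                       spurious_peak_rate=config.spurious_rate,
                       area_cv=config.area_cv,
                       total_fluorescence_range=config.fluorescence_range)
    rng = np.random.default_rng(config.seed)
    n = base.n_phylotypes
    tilt_axis = np.linspace(-1.0, 1.0, n)
    design = _design(config)
    profiles, libraries, communities = [], {}, {}
    for row in design:
        log_tilt = (config.system_effect * tilt_axis
                    * (1.0 if row["system"] == "SRI" else -1.0)
                    + config.amendment_effect * (tilt_axis ** 2 - 0.5)
                    * (1.0 if row["amendment"] == "compost" else -1.0)
                    + rng.normal(0.0, config.plot_sd, size=n))
        sub_seed = int(rng.integers(0, 2 ** 31 - 1))
        comm = _tilted(base, log_tilt, sub_seed)
        if row["system"] == "CS" and config.n_sri_only > 0:
            ab = np.asarray(comm.abundances)
            ab[-config.n_sri_only:] = 0.0
            comm = GroundTruthCommunity(comm.phylotype_ids,
                                        tuple(ab / ab.sum()),
                                        comm.sequences, sub_seed)
        communities[row["sample_id"]] = comm
        profiles.extend(simulate_profiles(
            comm, noise, config.n_replicates, seed=sub_seed,
            sample_id=row["sample_id"], metadata=dict(row),
            dye_offsets=config.dye_offsets))
        libraries[row["sample_id"]] = sample_clone_library(
            comm, config.n_clones, seed=sub_seed, metadata=dict(row))
    io.write_peak_csv(profiles, out / "peaks.csv")
    io.write_fasta(base.amplicons(), out / "community.fasta")
    truth = {
        "seed": config.seed,
        "phylotype_ids": list(base.phylotype_ids),
        "base_abundances": list(base.abundances),
        "plot_abundances": {sid: list(c.abundances)
                            for sid, c in communities.items()},
        "predicted_trfs": {p.phylotype_id: [p.forward_trf_bp, p.reverse_trf_bp]
                           for p in base.predicted_trfs(config.dye_offsets)},
    }
    io.write_json(truth, out / "ground_truth.json")
    lib_dir = out / "clones"
    lib_dir.mkdir(exist_ok=True)
    for sid, lib in libraries.items():
        io.write_clone_library_tsv(lib, lib_dir / f"{sid}.tsv")
    state.update(base=base, design=design, profiles=profiles,
                 libraries=libraries, communities=communities)
    return {"n_samples": len(design), "n_profiles": len(profiles),
            "n_clones_per_library": config.n_clones}


def _stage_process(config: RunConfig, out: Path, state: dict) -> dict:
    if config.peaks_csv is not None:
        meta = {r["sample_id"]: r for r in state["design"]}
        raw = []
        for prof in io.read_peak_csv(config.peaks_csv):
            base_id = prof.sample_id.rsplit("-r", 1)[0]
            prof.metadata.update(meta.get(base_id, {}))
            raw.append(prof)
    else:
        raw = state["profiles"]
    by_sample: dict[str, list] = {}
    qc: dict[str, str] = {}
    for prof in raw:
        verdict = qc_dynamic_range(prof, config.fluorescence_range)
        qc[prof.sample_id] = verdict
        filtered = filter_peaks(prof, config.amplitude_threshold,
                                config.min_size, config.max_size)
        binned = abundance_filter(bin_peaks(filtered, config.bin_window),
                                  config.min_fraction)
        base_id = prof.sample_id.rsplit("-r", 1)[0]
        by_sample.setdefault(base_id, []).append(binned)
    consensus = {sid: consensus_profile(reps, config.bin_window)
                 for sid, reps in sorted(by_sample.items())}
    for sid, prof in consensus.items():
        prof.sample_id = sid
    io.write_profile_tsv(list(consensus.values()), out / "profiles.tsv")
    io.write_json(qc, out / "qc.json")
    state["consensus"] = consensus
    return {"n_runs": len(raw), "n_consensus_profiles": len(consensus),
            "n_rerun_flagged": sum(v == "rerun" for v in qc.values())}


def _stage_typing(config: RunConfig, out: Path, state: dict) -> dict:
    base: GroundTruthCommunity = state["base"]
    preds = base.predicted_trfs(config.dye_offsets)
    assignments, estimates = [], {}
    for sid, prof in state["consensus"].items():
        table = assign_trfs(prof, preds, tolerance=config.match_tolerance)
        assignments.append(table)
        estimates[sid] = estimate_abundances(table)
    assignment = pd.concat(assignments, ignore_index=True)
    assignment.to_csv(out / "assignments.tsv", sep="\t", index=False)
    est = pd.DataFrame(estimates).T.fillna(0.0).sort_index()
    est.index.name = "sample_id"
    est.to_csv(out / "abundances.tsv", sep="\t")
    state.update(assignment=assignment, estimates=est, predictions=preds)
    unassigned = int((assignment["assigned_to"] == "unassigned").sum())
    return {"n_bins": len(assignment), "n_unassigned_bins": unassigned}


def _stage_diversity(config: RunConfig, out: Path, state: dict) -> dict:
    rows = []
    for sid, prof in state["consensus"].items():
        stats = profile_diversity(prof, HEX)
        rows.append({"sample_id": sid, **prof.metadata,
                     "S": stats.S, "H_prime": stats.H_prime, "E": stats.E,
                     "richness_total": richness(prof)})
    div = pd.DataFrame(rows).drop(columns=["replicate"], errors="ignore")
    div.to_csv(out / "diversity.tsv", sep="\t", index=False)
    curves = []
    for sid, lib in state["libraries"].items():
        curve = rarefy(lib.count_vector(), method="analytic")
        curves.append(pd.DataFrame({
            "sample_id": sid, "n": curve.n, "expected_S": curve.expected,
            "lower95": curve.lower, "upper95": curve.upper}))
    pd.concat(curves, ignore_index=True).to_csv(
        out / "rarefaction.tsv", sep="\t", index=False)
    state["diversity"] = div
    return {"n_samples": len(div), "n_rarefaction_curves": len(curves)}


def _stage_ordination(config: RunConfig, out: Path, state: dict) -> dict:
    base: GroundTruthCommunity = state["base"]
    pattern_to_pid = {rflp_pattern(a): a.id for a in base.amplicons()}
    incidence = pd.DataFrame(
        {sid: {pattern_to_pid.get(pat, f"pat{hash(pat) % 997}"): 1
               for pat in lib.counts}
         for sid, lib in state["libraries"].items()}
    ).T.fillna(0).astype(int).sort_index(axis=0).sort_index(axis=1)
    pca_res = pca(incidence)
    area = state["estimates"]
    mds_res = mds(area, seed=config.seed)
    coords = pca_res.coordinates.add_prefix("pca_").join(
        mds_res.coordinates.add_prefix("mds_"))
    coords.index.name = "sample_id"
    coords.to_csv(out / "ordination.tsv", sep="\t")
    io.write_json({
        "pca_axis_importance": [float(v) for v in pca_res.axis_importance],
        "mds_axis_importance": [float(v) for v in mds_res.axis_importance],
        "mds_stress": float(mds_res.stress),
        "mds_iterations": int(len(mds_res.stress_history) - 1),
    }, out / "ordination.json")
    state.update(pca=pca_res, mds=mds_res)
    return {"n_samples": len(coords),
            "mds_stress": float(mds_res.stress)}


def _stage_anova(config: RunConfig, out: Path, state: dict) -> dict:
    div = state["diversity"]
    result = two_way_anova(div, "system", "amendment", "H_prime")
    result = tukey_kramer(result, alpha=config.alpha)
    result.table.to_csv(out / "anova.tsv", sep="\t")
    result.cell_means.to_csv(out / "group_means.tsv", sep="\t",
                             index_label="group")
    state["anova"] = result
    return {"n_groups": len(result.cell_means),
            "df_error": result.df_error}
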