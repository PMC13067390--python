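"""End-to-end orchestration: simulate -> qc -> fc -> states -> dynamics ->
graphs -> compare -> mediate -> report.

Every stage reads the delimited-text artifacts of the previous stage from
the run directory, writes its own artifact plus a JSON provenance record
(inputs, settings, seeds), and is a pure function of (inputs, config,
seed): rerunning with the same config reproduces the outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectivity import (
    qc_fd,
    read_timeseries,
    sliding_window_fc,
    static_fc,
    write_fc_matrix,
    write_windowed_fc,
    read_windowed_fc,
    read_fc_matrix,
)
from .graph import metrics_for_fc
from .mediation import mediate_candidates
from .states import (
    StatePool,
    StateSequence,
    assign_windows,
    dynamics_table,
    fit_states,
    matrix_from_vector,
    summarize_dynamics,
)
from .stats import compare_groups
from .synthetic import CohortSpec, MediationSpec, write_cohort

log = logging.getLogger("dynfc")

STAGE_ORDER = [
    "simulate", "qc", "fc", "states", "dynamics", "graphs", "compare", "mediate", "report",
]

#: one-sided test directions for the confirmatory (preregistered) hypotheses:
#: females higher Prev_S / MDT_S / modularity, males higher Var_I / efficiency;
#: group 1 is males, so "less" = males smaller
HYPOTHESIS_SIDEDNESS = {
    "prev_s": "less",
    "mdt_s": "less",
    "var_i": "greater",
    "global_efficiency": "greater",
    "modularity": "less",
}


@dataclass
class RunConfig:
    """Full pipeline configuration; defaults mirror a fast-TR acquisition
    (window 55 TRs at TR 0.720 s = 39.60 s, k-means with cosine distance,
    5000 bootstrap samples)."""

    out_dir: str = "dynfc_run"
    # data locations (filled by `simulate`, or pointed at exported real data)
    manifest: str | None = None
    timeseries_dir: str | None = None
    fd_dir: str | None = None
    behavior: str | None = None
    # analysis settings
    window_trs: int = 55
    fd_threshold_mm: float = 0.5
    fd_max_fraction: float = 0.075
    kmeans_n_init: int = 20
    kmeans_tol: float = 1e-6
    kmeans_max_iter: int = 300
    kmeans_seed: int = 0
    graph_gamma: float = 1.0
    graph_restarts: int = 20
    graph_seed: int = 0
    one_sided_hypotheses: bool = False
    n_boot: int = 5000
    mediation_seed: int = 0
    mediator_column: str = "prev_i"
    bonferroni_m: int = 66
    # synthetic-cohort block
    cohort: dict = field(default_factory=dict)
    mediation_model: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def cohort_spec(self) -> CohortSpec:
        kw = dict(self.cohort)
        if "switch_prob_by_sex" in kw:
            kw["switch_prob_by_sex"] = {
                int(k): tuple(v) for k, v in kw["switch_prob_by_sex"].items()
            }
        if "sex_labels" in kw and kw["sex_labels"] is not None:
            kw["sex_labels"] = np.asarray(kw["sex_labels"], int)
        return CohortSpec(**kw)

    def mediation_spec(self) -> MediationSpec:
        return MediationSpec(**self.mediation_model)


def _out(config: RunConfig) -> Path:
    p = Path(config.out_dir)
    p.mkdir(parents=True, exist_ok=True)
    return p


def _provenance(config: RunConfig, stage: str, **extra) -> None:
    prov_dir = _out(config) / "provenance"
    prov_dir.mkdir(exist_ok=True)
    record = {"stage": stage, "version": __version__, "settings": asdict(config)}
    record.update(extra)
    with open(prov_dir / f"{stage}.json", "w") as fh:
        json.dump(record, fh, indent=1, default=str)


def _require(path: Path | str | None, stage: str, needed_by: str) -> Path:
    if path is None or not Path(path).exists():
        raise FileNotFoundError(
            f"stage '{needed_by}' needs an artifact from stage '{stage}' "
            f"({path}); rerun '{stage}' first"
        )
    return Path(path)


def _manifest(config: RunConfig, needed_by: str) -> pd.DataFrame:
    path = config.manifest or str(_out(config) / "cohort" / "manifest.tsv")
    return pd.read_csv(_require(path, "simulate", needed_by), sep="\t")


def _qc_table(config: RunConfig, needed_by: str) -> pd.DataFrame:
    return pd.read_csv(_require(_out(config) / "qc.tsv", "qc", needed_by), sep="\t")


def stage_simulate(config: RunConfig) -> None:
    cohort_dir = _out(config) / "cohort"
    spec = config.cohort_spec()
    write_cohort(spec, cohort_dir, mediation=config.mediation_spec())
    config.manifest = str(cohort_dir / "manifest.tsv")
    config.timeseries_dir = str(cohort_dir / "timeseries")
    config.fd_dir = str(cohort_dir / "fd")
    config.behavior = str(cohort_dir / "behavior.tsv")
    log.info("simulate: %d subjects, %d frames", spec.n_subjects, spec.n_frames)
    _provenance(config, "simulate", seed=spec.seed, n_subjects=spec.n_subjects)


def stage_qc(config: RunConfig) -> None:
    manifest = _manifest(config, "qc")
    fd_dir = _require(config.fd_dir, "simulate", "qc")
    rows = []
    for sid in manifest["subject_id"]:
        fd = np.loadtxt(fd_dir / f"{sid}.txt")
        res = qc_fd(fd, config.fd_threshold_mm, config.fd_max_fraction, subject_id=sid)
        rows.append(
            {
                "subject_id": sid, "passed": res.passed,
                "high_motion_fraction": res.high_motion_fraction,
                "median_fd": res.median_fd,
            }
        )
    qc = pd.DataFrame(rows)
    qc.to_csv(_out(config) / "qc.tsv", sep="\t", index=False)
    log.info("qc: %d/%d subjects pass", int(qc["passed"].sum()), len(qc))
    _provenance(config, "qc", n_pass=int(qc["passed"].sum()), n_total=len(qc))


def _passing_subjects(config: RunConfig, needed_by: str) -> pd.DataFrame:
    manifest = _manifest(config, needed_by)
    qc = _qc_table(config, needed_by)
    merged = manifest.merge(qc[["subject_id", "passed"]], on="subject_id")
    return merged[merged["passed"]].reset_index(drop=True)


def stage_fc(config: RunConfig) -> None:
    subjects = _passing_subjects(config, "fc")
    ts_dir = _require(config.timeseries_dir, "simulate", "fc")
    sdir = _out(config) / "static_fc"
    wdir = _out(config) / "windows"
    sdir.mkdir(exist_ok=True)
    wdir.mkdir(exist_ok=True)
    for _, row in subjects.iterrows():
        ts = read_timeseries(
            ts_dir / f"{row.subject_id}.tsv", row.subject_id, float(row.tr_seconds)
        )
        write_fc_matrix(static_fc(ts), sdir / f"{row.subject_id}.tsv")
        write_windowed_fc(sliding_window_fc(ts, config.window_trs), wdir / f"{row.subject_id}.tsv")
    log.info("fc: wrote static + windowed FC for %d subjects", len(subjects))
    _provenance(config, "fc", window_trs=config.window_trs, n_subjects=len(subjects))


def _load_windows(config: RunConfig, needed_by: str):
    subjects = _passing_subjects(config, needed_by)
    wdir = _require(_out(config) / "windows", "fc", needed_by)
    out = []
    for _, row in subjects.iterrows():
        path = _require(wdir / f"{row.subject_id}.tsv", "fc", needed_by)
        out.append(
            read_windowed_fc(path, config.window_trs, float(row.tr_seconds), row.subject_id)
        )
    return subjects, out


def stage_states(config: RunConfig) -> None:
    subjects, windowed = _load_windows(config, "states")
    pool = StatePool.from_windowed(windowed)
    model = fit_states(
        pool, n_init=config.kmeans_n_init, max_iter=config.kmeans_max_iter,
        tol=config.kmeans_tol, seed=config.kmeans_seed,
    )
    state_dir = _out(config) / "states"
    state_dir.mkdir(exist_ok=True)
    for name, centroid in (("I", model.centroid_i), ("S", model.centroid_s)):
        np.savetxt(state_dir / f"centroid_{name}.tsv", matrix_from_vector(centroid), delimiter="\t")
    with open(state_dir / "model.json", "w") as fh:
        json.dump(
            {"inertia": model.inertia, "label_metrics": model.label_metrics,
             "k": 2, "distance": "cosine", "n_pool": pool.n_rows},
            fh, indent=1,
        )
    for wfc in windowed:
        seq = assign_windows(model, wfc)
        np.savetxt(state_dir / f"labels_{wfc.subject_id}.txt", seq.labels, fmt="%s")
    log.info("states: pooled %d windows from %d subjects", pool.n_rows, len(windowed))
    _provenance(config, "states", n_pool=pool.n_rows, inertia=model.inertia)


def stage_dynamics(config: RunConfig) -> None:
    subjects, windowed = _load_windows(config, "dynamics")
    state_dir = _require(_out(config) / "states", "states", "dynamics")
    summaries = []
    for wfc in windowed:
        labels = np.loadtxt(state_dir / f"labels_{wfc.subject_id}.txt", dtype=str)
        seq = StateSequence(wfc.subject_id, labels, wfc.tr_seconds)
        summaries.append(summarize_dynamics(seq, wfc))
    table = dynamics_table(summaries)
    table.to_csv(_out(config) / "dynamics.tsv", sep="\t", index=False)
    log.info("dynamics: %d subjects summarized", len(table))
    _provenance(config, "dynamics", n_subjects=len(table))


def stage_graphs(config: RunConfig) -> None:
    subjects = _passing_subjects(config, "graphs")
    sdir = _require(_out(config) / "static_fc", "fc", "graphs")
    rows = []
    for sid in subjects["subject_id"]:
        fc = read_fc_matrix(sdir / f"{sid}.tsv")
        met = metrics_for_fc(
            fc, gamma=config.graph_gamma, n_repeats=config.graph_restarts,
            seed=config.graph_seed,
        )
        rows.append({"subject_id": sid, **met})
    pd.DataFrame(rows).to_csv(_out(config) / "static_metrics.tsv", sep="\t", index=False)
    log.info("graphs: metrics for %d subjects", len(rows))
    _provenance(config, "graphs", n_subjects=len(rows))


def stage_compare(config: RunConfig) -> None:
    manifest = _manifest(config, "compare")
    dyn = pd.read_csv(_require(_out(config) / "dynamics.tsv", "dynamics", "compare"), sep="\t")
    met = pd.read_csv(
        _require(_out(config) / "static_metrics.tsv", "graphs", "compare"), sep="\t"
    )
    table = dyn.merge(met, on="subject_id").merge(
        manifest[["subject_id", "sex"]], on="subject_id"
    )
    sidedness = HYPOTHESIS_SIDEDNESS if config.one_sided_hypotheses else {}
    params = [c for c in table.columns if c not in ("subject_id", "sex")]
    comp = compare_groups(table, table["sex"], params, sidedness_by_param=sidedness)
    comp.to_csv(_out(config) / "comparisons.tsv", sep="\t", index=False)
    log.info("compare: %d parameters", len(comp))
    _provenance(config, "compare", n_parameters=len(comp))


def stage_mediate(config: RunConfig) -> None:
    manifest = _manifest(config, "mediate")
    behavior = pd.read_csv(_require(config.behavior, "simulate", "mediate"), sep="\t")
    dyn = pd.read_csv(_require(_out(config) / "dynamics.tsv", "dynamics", "mediate"), sep="\t")
    merged = manifest[["subject_id", "sex"]].merge(dyn, on="subject_id").merge(
        behavior, on="subject_id"
    )
    result = mediate_candidates(
        merged, merged["sex"], merged[config.mediator_column].to_numpy(float),
        m=config.bonferroni_m, n_boot=config.n_boot, seed=config.mediation_seed,
    )
    result.to_csv(_out(config) / "mediation.tsv", sep="\t", index=False)
    log.info("mediate: %d variables screened, %d candidates",
             len(result), int(result["candidate"].sum()) if len(result) else 0)
    _provenance(config, "mediate", n_variables=len(result))


def stage_report(config: RunConfig) -> None:
    out = _out(config)
    report: dict = {"version": __version__}
    qc_path = out / "qc.tsv"
    if qc_path.exists():
        qc = pd.read_csv(qc_path, sep="\t")
        report["qc"] = {"n_total": len(qc), "n_pass": int(qc["passed"].sum())}
    comp_path = out / "comparisons.tsv"
    if comp_path.exists():
        comp = pd.read_csv(comp_path, sep="\t")
        report["comparisons"] = comp[["parameter", "t", "p_t", "d"]].to_dict("records")
    med_path = out / "mediation.tsv"
    if med_path.exists():
        med = pd.read_csv(med_path, sep="\t")
        report["mediation"] = med.to_dict("records")
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=str)
    _provenance(config, "report")


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "qc": stage_qc,
    "fc": stage_fc,
    "states": stage_states,
    "dynamics": stage_dynamics,
    "graphs": stage_graphs,
    "compare": stage_compare,
    "mediate": stage_mediate,
    "report": stage_report,
}


def run_pipeline(config: RunConfig, stages: list[str] | None = None) -> Path:
    """Run the requested stages in canonical order; returns the run dir."""
    stages = stages or STAGE_ORDER
    unknown = set(stages) - set(STAGE_ORDER)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    for stage in STAGE_ORDER:
        if stage in stages:
            log.info("running stage: %s", stage)
            _STAGE_FUNCS[stage](config)
    return _out(config)


# ---------------------------------------------------------------------------
# fast in-memory cohort analysis (no file round-trips); used for replicated
# parameter-recovery experiments
# ---------------------------------------------------------------------------

def analyze_cohort_dynamics(
    spec: CohortSpec,
    window_trs: int = 55,
    kmeans_n_init: int = 5,
    kmeans_seed: int = 0,
) -> pd.DataFrame:
    """Simulate a cohort and recover the per-subject dynamics table in memory.

    Returns the dynamics summaries joined with sex and each subject's true
    (generative) segregated-state frame occupancy, for parameter-recovery
    checks.
    """
    from .synthetic import SEGREGATED, simulate_subject

    windowed, true_occ = [], []
    for i in range(spec.n_subjects):
        ts, states = simulate_subject(spec, i)
        windowed.append(sliding_window_fc(ts, window_trs))
        true_occ.append(float(np.mean(states == SEGREGATED)))
    pool = StatePool.from_windowed(windowed)
    model = fit_states(pool, n_init=kmeans_n_init, seed=kmeans_seed)
    summaries = [summarize_dynamics(assign_windows(model, w), w) for w in windowed]
    table = dynamics_table(summaries)
    table["sex"] = spec.sex_labels
    table["true_occupancy_s"] = true_occ
    return table
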