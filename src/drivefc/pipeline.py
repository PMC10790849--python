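"""Cohort orchestration: generate (or load) sessions, preprocess, compute
behavior and connectivity, run the hyperparameter grid per participant,
and cluster the significant models' edge patterns.

The cohort report mirrors the per-participant result-table structure
(held-out rho and p, window/NB/BP/FP, sample count, average feature count,
MAE) plus cohort-level aggregates (mean MAE, number of significant models,
cluster composition over the significant models only).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .behavior import analyze_events
from .connectivity import build_trialsets
from .interpretation import (
    ClusterTree,
    EdgePattern,
    cluster_common_edges,
    upgma_cluster,
)
from .modeling import (
    BrtRegression,
    CVResult,
    GridResult,
    GridSpec,
    REDUCED_GRID,
    SelectionParams,
)
from .preprocess import PreprocessConfig, preprocess_hb
from .synthetic import GroundTruth, Session, SynthConfig, cohort_configs


@dataclass
class RunConfig:
    """Everything needed to reproduce a cohort run."""

    n_participants: int = 12
    synth: SynthConfig = field(default_factory=SynthConfig)
    grid: GridSpec = field(default_factory=lambda: REDUCED_GRID)
    criterion: str = "test"  # which chosen model the report focuses on
    n_clusters: int = 5
    seed: int = 0
    preprocess: PreprocessConfig = field(
        default_factory=lambda: PreprocessConfig(
            apply_bandpass=False, apply_ssr=True
        )
    )
    pattern_source: str = "full_fit"  # or "fold_union"
    outdir: str | None = None


@dataclass
class ParticipantResult:
    participant: str
    seed: int
    n_trials: int
    behavior: pd.DataFrame
    grid_result: GridResult
    chosen_params: tuple
    cv: CVResult
    pattern: EdgePattern
    truth: GroundTruth | None = None
    audit: list[str] = field(default_factory=list)


@dataclass
class CohortReport:
    participants: list[ParticipantResult]
    table: pd.DataFrame
    cluster_tree: ClusterTree | None
    common_edges: dict | None
    config: RunConfig
    manifest: dict

    def summary(self) -> str:
        s = summarize(self)
        lines = [
            "Cohort report",
            "-------------",
            f"participants:        {s['n_participants']}",
            f"significant models:  {s['n_significant']} (held-out p < 0.05)",
            f"mean MAE:            {s['mean_mae_ms']:.1f} ms",
            f"median held-out rho: {s['median_test_rho']:.3f}",
        ]
        if s["cluster_sizes"]:
            lines.append(f"cluster sizes:       {s['cluster_sizes']}")
        return "\n".join(lines)


def analyze_session(
    session: Session,
    windows,
    preprocess_cfg: PreprocessConfig,
) -> tuple[pd.DataFrame, dict, np.ndarray, list[str]]:
    """Behavior table and per-window trial matrices for usable trials.

    Usable trials are valid (a credited brake within 3 s), not BRT
    outliers, and have full pre-stimulus history in every window; the
    same trial set is used for all windows so combinations are comparable.
    """
    audit: list[str] = []
    behavior = analyze_events(session.beep_times, session.brake_onsets)
    oxy = preprocess_hb(
        session.oxy,
        session.short_oxy,
        session.fs,
        session.ssr_pairing,
        preprocess_cfg,
    )
    trialsets = build_trialsets(
        oxy, session.time, session.beep_times, windows
    )
    usable = behavior.index[behavior["valid"] & ~behavior["outlier"]]
    for w, ts in trialsets.items():
        for d in ts.dropped:
            audit.append(f"window {w:g}s: beep {d} dropped (no history)")
    n_out = int(behavior["outlier"].sum())
    if n_out:
        audit.append(f"{n_out} BRT outlier trial(s) removed")
    n_inv = int((~behavior["valid"]).sum())
    if n_inv:
        audit.append(f"{n_inv} trial(s) without a credited brake")
    common = set(usable)
    for ts in trialsets.values():
        common &= set(ts.trial_index.tolist())
    keep = sorted(common)
    mats = {}
    for w, ts in trialsets.items():
        pos = {t: k for k, t in enumerate(ts.trial_index)}
        mats[w] = ts.X[[pos[t] for t in keep]]
    y = behavior.loc[keep, "brt_ms"].to_numpy(dtype=float)
    return behavior, mats, y, audit


def run_participant(
    session: Session,
    config: RunConfig,
    participant: str,
    seed: int,
    truth: GroundTruth | None = None,
) -> ParticipantResult:
    behavior, mats, y, audit = analyze_session(
        session, config.grid.windows, config.preprocess
    )
    model = BrtRegression(mats, y, seed=seed)
    grid_result = model.grid_search(config.grid)
    chosen = (
        grid_result.chosen_by_training
        if config.criterion == "training"
        else grid_result.chosen_by_test
    )
    cv = grid_result.cv[chosen]
    w, nb, bp, fp = chosen
    params = SelectionParams(nb=nb, bp=bp, fp=fp, seed=seed)
    if config.pattern_source == "fold_union":
        edges = sorted(
            set(
                int(e)
                for i in range(model.n_trials)
                for e in _fold_edges(model, chosen, i)
            )
        )
        from .interpretation import edges_to_region_matrix

        pattern = edges_to_region_matrix(
            edges, session.montage, participant=participant
        )
    else:
        fit = model.fit(params, window_s=w)
        pattern = fit.edge_pattern(session.montage, participant=participant)
    return ParticipantResult(
        participant=participant,
        seed=seed,
        n_trials=model.n_trials,
        behavior=behavior,
        grid_result=grid_result,
        chosen_params=chosen,
        cv=cv,
        pattern=pattern,
        truth=truth,
        audit=audit,
    )


def _fold_edges(model: BrtRegression, chosen: tuple, fold: int):
    from .selection import edge_frequencies, select_by_frequency

    w, nb, bp, fp = chosen
    X = model.trial_matrices[float(w)]
    train = np.delete(np.arange(model.n_trials), fold)
    w_idx = sorted(model.trial_matrices).index(float(w))
    ss = np.random.SeedSequence(
        [model.seed, w_idx, nb, int(round(bp * 100)), fold]
    )
    freq = edge_frequencies(
        X[train], model.y[train], nb, bp, 0.05, np.random.default_rng(ss)
    )
    return select_by_frequency(freq, fp)


def run_cohort(config: RunConfig | None = None) -> CohortReport:
    """Run the full pipeline on a synthetic cohort.

    Participants failing any stage are excluded with a logged reason; the
    run continues.  Clustering is performed over the significant models
    only (held-out p < 0.05) and skipped with a warning when fewer than
    two qualify.
    """
    config = config or RunConfig()
    configs = cohort_configs(
        config.synth, config.n_participants, config.seed
    )
    participants: list[ParticipantResult] = []
    from .synthetic import generate_session

    for pid, synth_cfg in enumerate(configs):
        name = f"P{pid + 1:02d}"
        try:
            session, truth = generate_session(synth_cfg)
            participants.append(
                run_participant(
                    session, config, name, seed=synth_cfg.seed, truth=truth
                )
            )
        except Exception as exc:  # noqa: BLE001 — keep the cohort running
            warnings.warn(f"participant {name} excluded: {exc}")

    rows = []
    for p in participants:
        w, nb, bp, fp = p.chosen_params
        rows.append(
            {
                "participant": p.participant,
                "test_rho": p.cv.test_rho,
                "test_p": p.cv.test_p,
                "avg_training_rho": p.cv.avg_training_rho,
                "window_s": w,
                "nb": nb,
                "bp": bp,
                "fp": fp,
                "n_samples": p.n_trials,
                "avg_n_features": p.cv.avg_n_features,
                "mae_ms": p.cv.mae_ms,
                "mae_sd_ms": p.cv.mae_sd_ms,
                "significant": p.cv.test_p < 0.05,
            }
        )
    table = pd.DataFrame(rows)

    tree = common = None
    sig = [p for p in participants if p.cv.test_p < 0.05]
    if len(sig) >= 2:
        tree = upgma_cluster(
            [p.pattern for p in sig],
            n_clusters=min(config.n_clusters, len(sig)),
        )
        common = cluster_common_edges(tree)
    else:
        warnings.warn("fewer than 2 significant models; clustering skipped")

    manifest = {
        "seed": config.seed,
        "criterion": config.criterion,
        "n_participants": config.n_participants,
        "participant_seeds": [p.seed for p in participants],
        "grid": {
            "windows": list(config.grid.windows),
            "nb": list(config.grid.nb),
            "bp": list(config.grid.bp),
            "fp": list(config.grid.fp),
        },
        "synth": asdict(config.synth),
        "pattern_source": config.pattern_source,
    }
    report = CohortReport(
        participants=participants,
        table=table,
        cluster_tree=tree,
        common_edges=common,
        config=config,
        manifest=manifest,
    )
    if config.outdir:
        write_report(report, config.outdir)
    return report


def summarize(report: CohortReport) -> dict:
    """Cohort-level metrics: mean MAE, significant count, clusters."""
    t = report.table
    if len(t) == 0:
        raise ValueError("empty cohort report")
    sizes = {}
    if report.cluster_tree is not None:
        a = report.cluster_tree.assignments
        sizes = {int(c): int((a == c).sum()) for c in sorted(set(a))}
    return {
        "n_participants": int(len(t)),
        "mean_mae_ms": float(t["mae_ms"].mean()),
        "n_significant": int(t["significant"].sum()),
        "median_test_rho": float(t["test_rho"].median()),
        "cluster_sizes": sizes,
    }


def write_report(report: CohortReport, outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    report.table.to_csv(out / "cohort_table.csv", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(report.manifest, fh, indent=2)
    with open(out / "summary.json", "w") as fh:
        json.dump(summarize(report), fh, indent=2)
    for p in report.participants:
        pdir = out / p.participant
        pdir.mkdir(exist_ok=True)
        p.behavior.to_csv(pdir / "behavior.csv", index=False)
        p.grid_result.table.to_csv(pdir / "grid_metrics.csv", index=False)
        pd.DataFrame(
            {"measured_ms": p.cv.measured, "predicted_ms": p.cv.predicted}
        ).to_csv(pdir / "predictions.csv", index=False)
        with open(pdir / "audit.log", "w") as fh:
            fh.write("\n".join(p.audit))
    if report.common_edges is not None:
        serial = {
            str(cid): [
                {
                    "regions": list(r["regions"]),
                    "networks": list(r["networks"]),
                }
                for r in recs
            ]
            for cid, recs in report.common_edges.items()
        }
        with open(out / "cluster_common_edges.json", "w") as fh:
            json.dump(serial, fh, indent=2)
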