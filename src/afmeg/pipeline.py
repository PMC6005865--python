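"""End-to-end orchestration of the synthetic experiment and its analysis.

``run_all`` executes simulate -> behavior -> sensor ERF -> cluster ->
source -> report with a single top-level seed, hierarchically spawned into
per-stage generators so each stage is independently reproducible.  Analysis
defaults are the emulated study's parameters: 5000 Monte-Carlo
rearrangements for behavioral and source permutation tests, 1000 cluster
iterations at 0.025 family-wise error per tail, two-stage adaptive FDR at
q = 0.05, the 0.15-0.37 s analysis window tiled into four 55-ms segments,
and the 5-keystroke error horizon.  All windows are half-open
[start, end) seconds relative to the keystroke at t = 0.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, clusterstats, erf, io, permstats, sourcemne, synthgen
from .sourcemne import SEGMENTS

__all__ = ["RunConfig", "run_all", "behavioral_analysis", "sensor_analysis",
           "cluster_analysis", "source_analysis"]

logger = logging.getLogger(__name__)

CONTRASTS = (
    ("AF-Bo", "NF-Bo"),
    ("AF-In", "NF-In"),
    ("NF-Bo", "NF-In"),
    ("AF-Bo", "AF-In"),
)


@dataclass
class RunConfig:
    """All stage parameters of a full pipeline run."""

    simulation: synthgen.SimulationConfig = field(
        default_factory=synthgen.SimulationConfig)
    # analysis constants (study defaults)
    n_rearrangements: int = 5000
    cluster_iterations: int = 1000
    q: float = 0.05
    fwe_alpha: float = 0.025
    cluster_window: tuple[float, float] = (0.15, 0.37)
    sanity_window: tuple[float, float] = (-0.2, 0.15)
    segments: tuple = SEGMENTS
    horizon: int = 5
    epoch_window: tuple[float, float] = (-1.0, 1.0)
    baseline_window: tuple[float, float] = (-0.2, -0.1)
    inverse_snr: float = 3.0
    # neural-stage problem sizes
    neural_blocks: int = 1        # sequence patterns entering the MEG stages
    sensor_pairs: int = 16
    n_grid: int = 250
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["simulation"] = self.simulation.to_dict()
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str)
            .encode()).hexdigest()[:16]


def _stage_rngs(seed: int, names: tuple[str, ...]) -> dict:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


# ---------------------------------------------------------------------------
# behavioral stage
# ---------------------------------------------------------------------------

def _pairwise(table: pd.DataFrame, value: str, cond_a: str, cond_b: str,
              n_re: int, rng) -> dict:
    wide = table.pivot(index="subject", columns="condition", values=value)
    res = permstats.paired_permutation_test(
        wide[cond_a].to_numpy(), wide[cond_b].to_numpy(),
        n_rearrangements=n_re, rng=rng)
    return {"contrast": f"{cond_a} vs {cond_b}", "variable": value,
            **res.to_dict()}


def behavioral_analysis(events: pd.DataFrame, config: RunConfig,
                        rng: np.random.Generator) -> dict:
    """The 2x2 factorials, pairwise post-hocs and learning comparisons."""
    summary = behavior.condition_summary(events, horizon=config.horizon)
    out: dict = {"condition_tables": summary}

    factorials = {}
    for name, value in (("d_ioi", "mean_d_ioi"), ("error_rate", "error_rate")):
        cells, _ = behavior.factorial_cells(summary[name], value)
        factorials[name] = permstats.factorial_2x2_permutation(
            cells, n_rearrangements=config.n_rearrangements, rng=rng).to_dict()
    out["factorials"] = factorials

    posthocs = [
        _pairwise(summary["d_ioi"], "mean_d_ioi", a, b,
                  config.n_rearrangements, rng)
        for a, b in (("AF-Bo", "AF-In"), ("NF-Bo", "NF-In"),
                     ("AF-Bo", "NF-Bo"), ("AF-In", "NF-In"))
    ]
    posthocs.append(_pairwise(summary["error_rate"], "error_rate",
                              "AF-Bo", "AF-In", config.n_rearrangements, rng))
    out["posthoc"] = posthocs

    curves = behavior.learning_curves(events)
    pairs = curves["pairs"]
    learning = {}
    for name, col_b, col_a in (("cv_first_vs_last", "cv_last", "cv_first"),
                               ("ioi_halves", "mean_ioi_second_half",
                                "mean_ioi_first_half")):
        res = permstats.paired_permutation_test(
            pairs[col_a].to_numpy(), pairs[col_b].to_numpy(),
            n_rearrangements=config.n_rearrangements, rng=rng)
        learning[name] = res.to_dict()
    out["learning"] = learning

    all_p = [p["p_value"] for p in posthocs] + \
        [v["p_value"] for v in learning.values()]
    p_thr, _ = permstats.fdr_two_stage(np.array(all_p), q=config.q)
    out["p_thr_behavioral"] = p_thr
    return out


# ---------------------------------------------------------------------------
# sensor stage
# ---------------------------------------------------------------------------

def _subject_condition_erfs(rec: synthgen.ContinuousRecording,
                            layout: synthgen.SensorLayout,
                            config: RunConfig,
                            rng: np.random.Generator) -> tuple[dict, np.ndarray]:
    """One subject: filter, select events, epoch, average per condition.

    Altered-feedback epochs are all correct AF keystrokes; normal-feedback
    controls are matched per ordinal class in preceding IOI and velocity,
    after excluding NF events at +1/+2 after an AF.  Returns the raw
    (uncombined) condition-average ERFs and the subject's noise covariance
    from the filtered pre-trial baselines.
    """
    data = erf.bandpass(rec.data, rec.sfreq)
    ev = rec.events.copy()
    ev["prev_ioi"] = ev.groupby("trial")["onset_ms"].diff()
    post_af = np.zeros(len(ev), dtype=bool)
    af = (ev["feedback"] == "AF").to_numpy()
    for lag in (1, 2):
        shifted = ev.assign(af=af).groupby("trial")["af"].shift(
            lag, fill_value=False).to_numpy()
        post_af |= shifted.astype(bool)

    correct = ~ev["is_error"].astype(bool).to_numpy()
    has_cov = ev["prev_ioi"].notna().to_numpy()
    selected = np.zeros(len(ev), dtype=bool)
    for cls in ("Bo", "In"):
        is_cls = (ev["position_class"] == cls).to_numpy()
        af_mask = af & is_cls & correct & has_cov
        pool_mask = (~af) & is_cls & correct & has_cov & ~post_af
        selected |= af_mask
        af_rows = ev[af_mask]
        pool_rows = ev[pool_mask]
        if len(af_rows) == 0 or len(pool_rows) < len(af_rows):
            raise ValueError(f"insufficient events for class {cls}")
        chosen = erf.select_matched_controls(pool_rows, af_rows)
        selected[np.nonzero(pool_mask)[0][chosen]] = True

    idx = np.nonzero(selected)[0]
    epochs = erf.epoch(
        data, rec.sfreq, rec.triggers[idx],
        latency_correction_ms=config.simulation.midi_trigger_delay,
        window=config.epoch_window,
        conditions=ev["condition"].to_numpy()[idx],
        covariates=ev.iloc[idx][["prev_ioi", "velocity"]],
        sensor_names=rec.sensor_names)
    epochs = erf.baseline_correct(epochs, config.baseline_window)
    erfs, counts = erf.condition_average(epochs)

    baselines = [data[:, s0:s1] for s0, s1 in rec.baseline_segments
                 if s1 > s0]
    cov = sourcemne.estimate_noise_covariance(baselines)
    return {"erfs": erfs, "counts": counts}, cov


def sensor_analysis(events: pd.DataFrame, layout: synthgen.SensorLayout,
                    config: RunConfig, rng: np.random.Generator) -> dict:
    """Simulate recordings subject by subject and build condition ERFs."""
    sim = config.simulation
    subjects = np.sort(events["subject"].unique())
    per_subject, covs, counts = [], [], []
    for subject in subjects:
        rec = synthgen.generate_recording(events, int(subject), layout,
                                          sim, rng)
        res, cov = _subject_condition_erfs(rec, layout, config, rng)
        per_subject.append(res["erfs"])
        counts.append(res["counts"])
        covs.append(cov)
        del rec

    conds = sorted({c for e in per_subject for c in e})
    raw = {c: np.stack([e[c] for e in per_subject]) for c in conds}
    combined = {c: erf.combine_planar(raw[c], layout) for c in conds}
    n_t = next(iter(raw.values())).shape[-1]
    times = np.linspace(config.epoch_window[0], config.epoch_window[1], n_t)
    return {"raw": raw, "combined": combined, "covariances": covs,
            "times": times, "counts": pd.DataFrame(counts),
            "subjects": subjects}


# ---------------------------------------------------------------------------
# cluster stage
# ---------------------------------------------------------------------------

def _cluster_rows(name: str, result: clusterstats.ClusterTestResult,
                  times: np.ndarray) -> list[dict]:
    rows = []
    for i, c in enumerate(result.clusters):
        t_sel = result.times[c.members[:, 1]]
        rows.append({"contrast": name, "cluster": i, "sign": c.sign,
                     "mass": c.mass, "p_value": c.p_value,
                     "t_start": float(t_sel.min()),
                     "t_end": float(t_sel.max()),
                     "n_points": len(c.members),
                     "positions": sorted(set(c.members[:, 0].tolist()))})
    return rows


def cluster_analysis(sensor: dict, layout: synthgen.SensorLayout,
                     config: RunConfig, rng: np.random.Generator) -> dict:
    """Pointwise 2x2 factorial with FDR plus the four pairwise cluster tests."""
    combined = sensor["combined"]
    times = sensor["times"]
    window_mask = (times >= config.cluster_window[0]) & \
        (times < config.cluster_window[1])

    # pointwise factorial over the analysis window, FDR-corrected
    cells = np.stack([
        np.stack([combined["AF-Bo"][..., window_mask],
                  combined["AF-In"][..., window_mask]], axis=1),
        np.stack([combined["NF-Bo"][..., window_mask],
                  combined["NF-In"][..., window_mask]], axis=1),
    ], axis=1)  # (n_subj, 2, 2, n_pos, n_t)
    n_subj = cells.shape[0]
    c_a = (cells[:, 0, 0] + cells[:, 0, 1] - cells[:, 1, 0] - cells[:, 1, 1]) / 2
    c_b = (cells[:, 0, 0] - cells[:, 0, 1] + cells[:, 1, 0] - cells[:, 1, 1]) / 2
    c_ab = cells[:, 0, 0] - cells[:, 0, 1] - cells[:, 1, 0] + cells[:, 1, 1]
    factorial = {}
    for name, contrast in (("feedback", c_a), ("position", c_b),
                           ("interaction", c_ab)):
        _, p = permstats.sign_flip_pvalues(
            contrast.reshape(n_subj, -1),
            n_rearrangements=config.n_rearrangements, rng=rng)
        p_thr, mask = permstats.fdr_two_stage(p, q=config.q)
        factorial[name] = {"p_thr": p_thr,
                           "n_significant": int(mask.sum()),
                           "n_points": int(mask.size)}

    rows, sanity_rows = [], []
    results = {}
    for a, b in CONTRASTS:
        name = f"{a} - {b}"
        res = clusterstats.cluster_permutation_test(
            combined[a], combined[b], layout.adjacency, times,
            window=config.cluster_window,
            n_iterations=config.cluster_iterations,
            fwe_alpha=config.fwe_alpha, rng=rng)
        results[name] = res
        rows += _cluster_rows(name, res, times)
        sanity = clusterstats.sanity_window_test(
            combined[a], combined[b], layout.adjacency, times,
            window=config.sanity_window,
            n_iterations=config.cluster_iterations,
            fwe_alpha=config.fwe_alpha, rng=rng)
        sanity_rows += _cluster_rows(f"{name} (sanity)", sanity, times)

    return {"factorial": factorial,
            "cluster_table": pd.DataFrame(rows),
            "sanity_table": pd.DataFrame(sanity_rows),
            "results": results}


# ---------------------------------------------------------------------------
# source stage
# ---------------------------------------------------------------------------

def source_analysis(sensor: dict, fm: synthgen.ForwardModel,
                    config: RunConfig, rng: np.random.Generator) -> dict:
    """Per-subject minimum-norm estimates and segment-wise contrasts."""
    raw = sensor["raw"]
    times = sensor["times"]
    lam = sourcemne.default_lambda(fm.leadfield, snr=config.inverse_snr)

    seg_means = {c: [] for c in raw}
    for i, cov in enumerate(sensor["covariances"]):
        op = sourcemne.build_inverse(fm.leadfield, cov, lam)
        for cond in raw:
            est = sourcemne.apply_inverse(op, raw[cond][i], times)
            seg_means[cond].append(est.segment_means(config.segments))
    seg_means = {c: np.stack(v) for c, v in seg_means.items()}

    p_thr_rows = []
    reports = {}
    for a, b in CONTRASTS:
        name = f"{a} - {b}"
        res = sourcemne.segment_contrast_test(
            seg_means[a], seg_means[b],
            n_rearrangements=config.n_rearrangements, q=config.q, rng=rng)
        reports[name] = sourcemne.region_report(res["masks"],
                                                res["differences"], fm)
        p_thr_rows.append({"contrast": name,
                           **{f"S{i+1}": res["p_thr"][i]
                              for i in range(len(config.segments))}})
    return {"lambda": lam, "p_thr_table": pd.DataFrame(p_thr_rows),
            "region_reports": reports}


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def run_all(config: RunConfig, outdir=None) -> dict:
    """Execute every stage and assemble the report bundle.

    Stage failures abort with the failing stage named; artifacts written so
    far are retained in ``outdir``.
    """
    rngs = _stage_rngs(config.seed, ("simulate", "behavior", "recordings",
                                     "cluster", "source", "forward"))
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    report: dict = {"provenance": {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "versions": {m.__name__: m.__version__
                     for m in (np, pd)},
    }}

    stage = "simulate"
    try:
        events = synthgen.generate_performance(config.simulation,
                                               rngs["simulate"])
        if out is not None:
            io.write_events_csv(events, out / "events.csv")

        stage = "behavior"
        beh = behavioral_analysis(events, config, rngs["behavior"])
        report["behavior"] = {
            "factorials": beh["factorials"],
            "posthoc": beh["posthoc"],
            "learning": beh["learning"],
            "p_thr_behavioral": beh["p_thr_behavioral"],
        }

        stage = "erf"
        sim = config.simulation
        neural_events = events[events["block"] <= config.neural_blocks]
        layout = synthgen.generate_sensor_layout(config.sensor_pairs)
        sensor = sensor_analysis(neural_events, layout, config,
                                 rngs["recordings"])
        report["erf_trial_counts"] = sensor["counts"].mean().to_dict()

        stage = "cluster"
        clus = cluster_analysis(sensor, layout, config, rngs["cluster"])
        report["cluster"] = {
            "factorial": clus["factorial"],
            "n_significant": {
                name: len(res.significant_clusters)
                for name, res in clus["results"].items()},
        }

        stage = "source"
        fm = synthgen.generate_forward(config.n_grid, layout,
                                       rngs["forward"])
        src = source_analysis(sensor, fm, config, rngs["source"])
        report["source"] = {
            "lambda": src["lambda"],
            "p_thr_table": src["p_thr_table"].to_dict("records"),
            "regions": {k: v.to_dict("records")
                        for k, v in src["region_reports"].items()},
        }

        stage = "report"
        if out is not None:
            io.write_json(report, out / "summary.json")
            clus["cluster_table"].to_csv(out / "clusters.csv", index=False)
            clus["sanity_table"].to_csv(out / "clusters_sanity.csv",
                                        index=False)
            src["p_thr_table"].to_csv(out / "p_thr.csv", index=False)
            for name, rep in src["region_reports"].items():
                safe = name.replace(" ", "").replace("-", "_")
                rep.to_csv(out / f"regions_{safe}.csv", index=False)
            beh["condition_tables"]["d_ioi"].to_csv(
                out / "behavior_d_ioi.csv", index=False)
            beh["condition_tables"]["error_rate"].to_csv(
                out / "behavior_error_rate.csv", index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") \
            from exc

    return report
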