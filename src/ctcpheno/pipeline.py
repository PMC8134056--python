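"""End-to-end orchestration: simulate/ingest -> gate -> cluster -> diversity
-> survival -> report.

One top-level seed deterministically derives a seed per stage (SHA-256 of
``"<seed>:<stage>"``), so a run is reproducible bit-for-bit from its config.
Every stage writes RFC-4180 CSV (UTF-8, '.' decimal, fixed column order,
10-significant-digit floats) plus a ``manifest.json`` with the config hash,
per-stage status and SHA-256 checksums of all outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import AnalysisConfig, config_hash
from .diversity import diversity_table, si_trajectory
from .gating import classify_dynamics, classify_events, enumerate_samples
from .phenotyping import (assign, cluster_presence, compare_centroid_distances,
                          fit_kmeans, standardize)
from .reporting import (cohort_summary, manual_vs_automated, paired_shift_tests,
                        write_markdown_report, write_summary_json)
from .survival import (baseline_covariate_table, concordance_index, cox_fit,
                       km_estimate, logrank, select_multivariable)

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "run_stage", "stage_seed", "PipelineError"]

_FLOAT_FMT = "%.17g"  # 17 significant digits: exact float64 round-trip


class PipelineError(RuntimeError):
    """A pipeline stage failed; the manifest records which."""


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the run seed (< 2^31)."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def _read_csv(path) -> pd.DataFrame:
    # round_trip parsing pairs with %.17g writes for exact float64 recovery
    return pd.read_csv(path, float_precision="round_trip")


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    # %.17g floats: deterministic and lossless, so feature_table mode
    # reproduces simulate mode bit-for-bit
    df.to_csv(path, index=False, float_format=_FLOAT_FMT, lineterminator="\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: AnalysisConfig) -> dict:
    """Run all stages; returns (and writes) the run manifest.

    On stage failure the completed stages' outputs are kept, the manifest
    records the failing stage and error, and :class:`PipelineError` is raised.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "ctcpheno_version": __version__,
        "seed": cfg.seed,
        "config_hash": config_hash(cfg),
        "stage_seeds": {s: stage_seed(cfg.seed, s) for s in
                        ("simulate", "cluster")},
        "stages": {},
        "outputs": {},
        "counts": {},
    }
    state: dict = {}
    stages = [
        ("ingest", _stage_ingest),
        ("gate", _stage_gate),
        ("cluster", _stage_cluster),
        ("diversity", _stage_diversity),
        ("survival", _stage_survival),
        ("report", _stage_report),
    ]
    try:
        for name, fn in stages:
            logger.info("stage %s: starting", name)
            fn(cfg, outdir, state, manifest)
            manifest["stages"][name] = "ok"
            logger.info("stage %s: ok", name)
    except Exception as exc:
        manifest["stages"][name] = f"failed: {exc}"
        _finalize(outdir, manifest)
        raise PipelineError(f"stage {name!r} failed: {exc}") from exc
    _finalize(outdir, manifest)
    return manifest


def _finalize(outdir: Path, manifest: dict) -> None:
    for f in sorted(outdir.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            manifest["outputs"][f.name] = _sha256(f)
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")


_STATE_FILES = {
    "patients": "patients.csv",
    "samples": "samples.csv",
    "events": "events.csv",
    "classified": "events_classified.csv",
    "sample_counts": "sample_counts.csv",
    "assignments": "assignments.csv",
    "composition": "composition.csv",
    "diversity": "diversity.csv",
    "baseline_table": "baseline_table.csv",
}


def run_stage(cfg: AnalysisConfig, stage: str) -> dict:
    """Run one named stage against an existing pipeline output directory.

    Prior stages' outputs are loaded from ``cfg.outdir``; the stage's own
    outputs are (re)written there.  Useful for the per-stage CLI commands.
    """
    fns = {"ingest": _stage_ingest, "gate": _stage_gate, "cluster": _stage_cluster,
           "diversity": _stage_diversity, "survival": _stage_survival,
           "report": _stage_report}
    if stage not in fns:
        raise ValueError(f"unknown stage {stage!r}; choose from {sorted(fns)}")
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    state: dict = {}
    for key, fname in _STATE_FILES.items():
        f = outdir / fname
        if f.exists():
            state[key] = _read_csv(f)
    manifest: dict = {"stages": {}, "outputs": {}, "counts": {}}
    fns[stage](cfg, outdir, state, manifest)
    return manifest


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_ingest(cfg: AnalysisConfig, outdir: Path, state: dict, manifest: dict) -> None:
    if cfg.mode == "simulate":
        from .simulate import generate_cohort
        scenario = cfg.scenario.model_copy(update={"seed": stage_seed(cfg.seed, "simulate")})
        cohort = generate_cohort(scenario)
        state["patients"], state["samples"], state["events"] = (
            cohort.patients, cohort.samples, cohort.events)
        _write_csv(cohort.truth.objects, outdir / "truth_objects.csv")
        _write_csv(cohort.truth.patients, outdir / "truth_patients.csv")
    elif cfg.mode == "feature_table":
        state["events"] = _read_csv(cfg.events_path)
        state["samples"] = _read_csv(cfg.samples_path)
        state["patients"] = _read_csv(cfg.patients_path)
    else:  # images
        from .imaging import extract_features, read_image_stack, segment_channel
        state["samples"] = _read_csv(cfg.samples_path)
        state["patients"] = _read_csv(cfg.patients_path)
        frames = []
        for tiff in sorted(Path(cfg.images_dir).glob("*.tif*")):
            stack = read_image_stack(tiff)
            masks = {ch: segment_channel(r, abs_floor=15.0)
                     for ch, r in stack.channels.items()}
            frames.append(extract_features(masks, stack, sample_id=tiff.stem))
        state["events"] = (pd.concat(frames, ignore_index=True) if frames
                           else pd.DataFrame())
    _write_csv(state["patients"], outdir / "patients.csv")
    _write_csv(state["samples"], outdir / "samples.csv")
    _write_csv(state["events"], outdir / "events.csv")
    manifest["counts"]["objects_in"] = int(len(state["events"]))
    manifest["counts"]["samples"] = int(len(state["samples"]))
    manifest["counts"]["patients"] = int(len(state["patients"]))


def _stage_gate(cfg: AnalysisConfig, outdir: Path, state: dict, manifest: dict) -> None:
    classified = classify_events(state["events"], cfg.gating)
    counts = enumerate_samples(classified, state["samples"], cfg.gating)
    dynamics = classify_dynamics(counts, cfg.gating)
    state["classified"], state["sample_counts"], state["dynamics"] = classified, counts, dynamics
    _write_csv(classified, outdir / "events_classified.csv")
    _write_csv(counts, outdir / "sample_counts.csv")
    _write_csv(dynamics, outdir / "dynamics.csv")
    for cls in ("ctc", "tdev", "other"):
        manifest["counts"][f"n_{cls}"] = int((classified["event_class"] == cls).sum())


def _stage_cluster(cfg: AnalysisConfig, outdir: Path, state: dict, manifest: dict) -> None:
    ph = cfg.phenotyping
    ctcs = state["classified"][state["classified"]["event_class"] == "ctc"]
    if len(ctcs) < ph.k:
        raise ValueError(f"only {len(ctcs)} CTCs; cannot fit k={ph.k} clusters")
    scaling, z = standardize(ctcs, ph.features)
    model = fit_kmeans(z, scaling, k=ph.k, seed=stage_seed(cfg.seed, "cluster"),
                       n_restarts=ph.n_restarts)
    assignments = assign(model, z, event_ids=ctcs["event_id"])
    assignments.insert(1, "sample_id", ctcs["sample_id"].to_numpy())
    composition = cluster_presence(assignments, state["samples"], k=ph.k)
    state["cluster_model"], state["assignments"], state["composition"] = (
        model, assignments, composition)
    model.save(outdir / "cluster_model.json")
    _write_csv(assignments, outdir / "assignments.csv")
    _write_csv(composition, outdir / "composition.csv")
    heat = pd.DataFrame(z, columns=model.feature_names)
    heat.insert(0, "event_id", ctcs["event_id"].to_numpy())
    heat["cluster"] = assignments["cluster"].to_numpy()
    heat.to_csv(outdir / "heatmap_matrix.tsv", sep="\t", index=False,
                lineterminator="\n")
    manifest["counts"]["n_clusters_nonempty"] = int(assignments["cluster"].nunique())


def _stage_diversity(cfg: AnalysisConfig, outdir: Path, state: dict, manifest: dict) -> None:
    div = diversity_table(state["composition"], cfg.diversity, k=cfg.phenotyping.k)
    state["diversity"] = div
    _write_csv(div, outdir / "diversity.csv")
    extras = {}
    try:
        extras["trajectory"] = si_trajectory(div, state["samples"])
    except ValueError as exc:
        extras["trajectory"] = {"error": str(exc)}
    try:
        merged_counts = state["sample_counts"]
        extras["centroid_distance_test"] = compare_centroid_distances(
            state["assignments"], merged_counts)
    except ValueError as exc:
        extras["centroid_distance_test"] = {"error": str(exc)}
    (outdir / "diversity_tests.json").write_text(
        json.dumps(extras, indent=2, sort_keys=True, default=float) + "\n")
    manifest["counts"]["samples_with_defined_si"] = int((div["n_ctc"] > 0).sum())


def _stage_survival(cfg: AnalysisConfig, outdir: Path, state: dict, manifest: dict) -> None:
    sv = cfg.survival
    base = baseline_covariate_table(state["patients"], state["sample_counts"],
                                    state.get("diversity"))
    state["baseline_table"] = base
    _write_csv(base, outdir / "baseline_table.csv")

    km_rows, test_rows, cox_rows = [], [], []
    concordance: dict = {}
    table1_sections: dict = {}
    for endpoint in sv.endpoints:
        tcol, ecol = f"{endpoint}_time", f"{endpoint}_event"
        # --- dichotomized biomarker strata: KM + log-rank ------------------
        for strat in ("ctc_group", "tdev_group", "si_group"):
            data = base[base[strat].isin(["favorable", "unfavorable"])]
            for group, sub in data.groupby(strat):
                curve = km_estimate(sub, tcol, ecol)
                for _, r in curve.table.iterrows():
                    km_rows.append({"endpoint": endpoint, "stratifier": strat,
                                    "group": group, **r.to_dict()})
                test_rows.append({"endpoint": endpoint, "stratifier": strat,
                                  "group": group, "n": curve.n,
                                  "n_events": curve.n_events,
                                  "median_survival": curve.median_label})
            if data[strat].nunique() == 2 and data[ecol].sum() > 0:
                lr = logrank(data, strat, tcol, ecol)
                bin_cov = (data[strat] == "unfavorable").astype(int)
                cox_bin = cox_fit(data.assign(unfavorable=bin_cov), ["unfavorable"],
                                  tcol, ecol, sv.ties_method)
                row = cox_bin.table.iloc[0]
                test_rows.append({"endpoint": endpoint, "stratifier": strat,
                                  "group": "unfavorable_vs_favorable",
                                  "n": int(len(data)), "n_events": int(data[ecol].sum()),
                                  "logrank_chi2": lr.statistic, "logrank_df": lr.df,
                                  "logrank_p": lr.p_value, "hr": row["hr"],
                                  "hr_ci_low": row["ci_low"], "hr_ci_high": row["ci_high"],
                                  "hr_p": row["p"]})
        # --- uni/multivariable Cox over the candidate covariates -----------
        uv = {}
        for cov in sv.candidate_covariates:
            try:
                uv[cov] = cox_fit(base, [cov], tcol, ecol, sv.ties_method)
            except ValueError as exc:
                logger.warning("UV Cox for %s/%s skipped: %s", endpoint, cov, exc)
        for cov, res in uv.items():
            r = res.table.iloc[0]
            cox_rows.append({"endpoint": endpoint, "model": "univariable",
                             "covariate": cov, **{k: r[k] for k in
                             ("coef", "hr", "ci_low", "ci_high", "z", "p")},
                             "n": res.n, "n_events": res.n_events,
                             "converged": res.converged})
        selected = select_multivariable(uv, sv.alpha)
        mv = None
        if selected:
            mv = cox_fit(base, selected, tcol, ecol, sv.ties_method)
            for _, r in mv.table.iterrows():
                cox_rows.append({"endpoint": endpoint, "model": "multivariable",
                                 "covariate": r["covariate"], **{k: r[k] for k in
                                 ("coef", "hr", "ci_low", "ci_high", "z", "p")},
                                 "n": mv.n, "n_events": mv.n_events,
                                 "converged": mv.converged})
        table1_sections[endpoint] = _table1_markdown(endpoint, uv, mv)

        # --- C-index comparison: CTC-based vs tdEV-based model -------------
        concordance[endpoint] = {}
        for marker in ("n_ctc", "n_tdev"):
            covs = [c if c != "n_ctc" else marker for c in selected] if selected else [marker]
            covs = list(dict.fromkeys(covs))
            if marker not in covs:
                covs = [marker if c == "n_ctc" else c for c in covs]
                if marker not in covs:
                    covs.append(marker)
            try:
                fit = cox_fit(base, covs, tcol, ecol, sv.ties_method)
                sub = base[[tcol, ecol, *covs]].dropna()
                risk = sub[covs].to_numpy() @ fit.table["coef"].to_numpy()
                concordance[endpoint][f"{marker}_model"] = {
                    "covariates": covs,
                    "c_index": concordance_index(risk, sub, tcol, ecol),
                    "n": int(len(sub)),
                }
            except ValueError as exc:
                concordance[endpoint][f"{marker}_model"] = {"error": str(exc)}

    _write_csv(pd.DataFrame(km_rows), outdir / "km_curves.csv")
    _write_csv(pd.DataFrame(test_rows), outdir / "survival_tests.csv")
    _write_csv(pd.DataFrame(cox_rows), outdir / "cox_results.csv")
    (outdir / "concordance.json").write_text(
        json.dumps(concordance, indent=2, sort_keys=True, default=float) + "\n")
    (outdir / "table1.md").write_text(
        "# Cox proportional hazards regression (baseline biomarkers)\n\n"
        + "\n\n".join(table1_sections.values()) + "\n")
    state["survival_tests"] = pd.DataFrame(test_rows)
    state["concordance"] = concordance
    manifest["counts"]["baseline_patients"] = int(len(base))


_COVARIATE_LABELS = {
    "age": "Age (continuous, years)",
    "chemo_pretreated": "Chemotherapy status (naive vs. pretreated)",
    "prior_arsi_yes": "Prior ARSi exposure (no vs. yes)",
    "visceral_metastases": "Metastases (non-visceral/nodal vs. visceral)",
    "psa": "Baseline PSA (continuous, ng/mL)",
    "ldh": "Baseline LDH (continuous, U/L)",
    "n_ctc": "Baseline CTC (/7.5 mL, continuous)",
    "n_tdev": "Baseline tdEV (/7.5 mL, continuous)",
    "si": "Baseline SI (continuous, nats)",
}


def _fmt_p(p: float) -> str:
    return "<0.0001" if p < 1e-4 else f"{p:.3g}"


def _table1_markdown(endpoint: str, uv: dict, mv) -> str:
    mv_map = {}
    if mv is not None:
        mv_map = {r["covariate"]: r for _, r in mv.table.iterrows()}
    lines = [f"## {endpoint.upper()}", "",
             "| Variable | UV HR (95% CI) | UV P | MV HR (95% CI) | MV P |",
             "|---|---|---|---|---|"]
    for cov, res in uv.items():
        r = res.table.iloc[0]
        uv_cell = f"{r['hr']:.3f} ({r['ci_low']:.3f}-{r['ci_high']:.3f})"
        if cov in mv_map:
            m = mv_map[cov]
            mv_cell = f"{m['hr']:.3f} ({m['ci_low']:.3f}-{m['ci_high']:.3f})"
            mv_p = _fmt_p(m["p"])
        else:
            mv_cell, mv_p = "-", "-"
        lines.append(f"| {_COVARIATE_LABELS.get(cov, cov)} | {uv_cell} | "
                     f"{_fmt_p(r['p'])} | {mv_cell} | {mv_p} |")
    return "\n".join(lines)


def _stage_report(cfg: AnalysisConfig, outdir: Path, state: dict, manifest: dict) -> None:
    counts = state["sample_counts"]
    samples = state["samples"]
    manual = None
    mva = None
    if "manual_ctc" in samples.columns:
        merged = counts.merge(samples[["sample_id", "manual_ctc"]], on="sample_id")
        manual = merged["manual_ctc"]
        try:
            mva = manual_vs_automated(merged["manual_ctc"], merged["n_ctc"])
        except ValueError as exc:
            logger.warning("manual-vs-automated summary skipped: %s", exc)
    summary = cohort_summary(counts, manual)
    write_summary_json(outdir / "cohort_summary.json", summary)
    try:
        shifts = paired_shift_tests(counts)
    except ValueError:
        shifts = pd.DataFrame()
    if len(shifts):
        _write_csv(shifts, outdir / "paired_shifts.csv")
    write_markdown_report(outdir / "report.md", summary, shifts if len(shifts) else None, mva)
    if cfg.make_figures:
        _figures(outdir, state, mva)


def _figures(outdir: Path, state: dict, mva: dict | None) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    plt.rcParams["svg.hashsalt"] = "ctcpheno"

    base = state.get("baseline_table")
    if base is not None and len(base):
        fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
        for ax, endpoint in zip(axes, ("pfs", "os")):
            tcol, ecol = f"{endpoint}_time", f"{endpoint}_event"
            for group, color in (("favorable", "tab:green"), ("unfavorable", "tab:red")):
                sub = base[base["ctc_group"] == group]
                if len(sub) == 0:
                    continue
                curve = km_estimate(sub, tcol, ecol)
                t = np.concatenate([[0.0], curve.table["time"].to_numpy()])
                s = np.concatenate([[1.0], curve.table["survival"].to_numpy()])
                ax.step(t, s, where="post", color=color,
                        label=f"{group} (n={curve.n})")
            ax.set_xlabel("months")
            ax.set_title(endpoint.upper())
            ax.set_ylim(0, 1.02)
            ax.legend(fontsize=8)
        axes[0].set_ylabel("survival probability")
        fig.suptitle("Baseline CTC <5 vs >=5 per 7.5 mL")
        fig.tight_layout()
        fig.savefig(outdir / "km_ctc_groups.svg", metadata={"Date": None})
        plt.close(fig)
        base[["patient_id", "pfs_time", "pfs_event", "os_time", "os_event",
              "ctc_group"]].to_csv(outdir / "km_ctc_groups.csv", index=False,
                                   float_format=_FLOAT_FMT, lineterminator="\n")

    if mva is not None:
        merged = state["sample_counts"].merge(
            state["samples"][["sample_id", "manual_ctc"]], on="sample_id")
        fig, ax = plt.subplots(figsize=(4.5, 4.5))
        ax.scatter(merged["n_ctc"], merged["manual_ctc"], s=8, alpha=0.5)
        lim = max(merged["n_ctc"].max(), merged["manual_ctc"].max(), 1)
        ax.plot([0, lim], [0, lim], "k--", lw=0.8)
        ax.set_xscale("symlog")
        ax.set_yscale("symlog")
        ax.set_xlabel("automated CTC count")
        ax.set_ylabel("manual CTC count")
        ax.set_title(f"slope {mva['slope']:.2f}, Spearman r {mva['spearman_r']:.2f}")
        fig.tight_layout()
        fig.savefig(outdir / "manual_vs_automated.svg", metadata={"Date": None})
        plt.close(fig)
        merged[["sample_id", "n_ctc", "manual_ctc"]].to_csv(
            outdir / "manual_vs_automated.csv", index=False, lineterminator="\n")
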