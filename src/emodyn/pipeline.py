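"""Orchestration: generation -> dynamics fits -> behaviour fits -> report.

One :class:`RunConfig` (YAML-serializable) drives a fully reproducible run:
a single master seed deterministically spawns one seed per stage, every
dataset is written as CSV with a sidecar manifest, fit tables are written as
CSV and fit objects as JSON, and a run manifest records the hash of every
artifact.  Each stage can also be run standalone on the CSV interfaces via
the command-line entry points in :mod:`emodyn.cli`.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .fit_behavior import (
    classify_writing_records,
    fit_feedback,
    fit_hinge_participation,
    fit_logistic_expression,
)
from .fit_dynamics import (
    binned_rates,
    event_deltas,
    fit_nls,
    posterior_sample,
    residual_diagnostics,
    select_subset,
)
from .params import ModelParams, reference_expression_coeffs, reference_params
from .synth import (
    ReadingStudyDesign,
    generate_reading_study,
    generate_writing_study,
    write_dataset,
)

log = logging.getLogger("emodyn")

__all__ = ["RunConfig", "RunReport", "run_pipeline", "make_figures"]


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    seed: int = 0
    out_dir: str = "results/run"
    params_path: Optional[str] = None  # None -> packaged reference estimates
    reading: dict = field(default_factory=dict)  # ReadingStudyDesign overrides
    n_writing_participants: int = 65
    n_posterior: int = 10_000
    run_posterior: bool = True
    make_figures: bool = False

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def load_params(self) -> ModelParams:
        if self.params_path is None:
            return reference_params()
        return ModelParams.from_json(self.params_path)

    def reading_design(self, seed: int) -> ReadingStudyDesign:
        kwargs = dict(self.reading)
        if "thread_counts" in kwargs:
            kwargs["thread_counts"] = tuple(kwargs["thread_counts"])
        if kwargs.get("noise") is not None:
            kwargs["noise"] = tuple(kwargs["noise"])
        kwargs["seed"] = seed
        return ReadingStudyDesign(**kwargs)


@dataclass
class RunReport:
    """Artifacts of one pipeline run."""

    out_dir: Path
    tables: dict  # name -> DataFrame
    fits: dict  # name -> fit object
    recovery: pd.DataFrame
    manifest_path: Path


def _stage_seeds(master: int, n: int = 6) -> list[int]:
    # one 31-bit seed per stage so any stage can be re-run standalone
    return [int(s) for s in np.random.default_rng(master).integers(0, 2**31 - 1, n)]


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute generate -> fit-dynamics -> fit-behaviour -> report.

    Idempotent for a fixed config: identical seeds produce byte-identical
    tables.  Any stage failure aborts with an error naming the stage.
    """
    out = Path(config.out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise RuntimeError(f"output directory {out} is not writable: {exc}") from exc
    if config.params_path is not None and not Path(config.params_path).exists():
        raise FileNotFoundError(f"parameter file not found: {config.params_path}")

    params = config.load_params()
    coeffs = reference_expression_coeffs()
    seeds = _stage_seeds(config.seed)
    tables: dict = {}
    fits: dict = {}
    manifest: dict = {"seed": config.seed, "stages": {}, "files": {}}

    def record(path: Path) -> None:
        manifest["files"][str(path.relative_to(out))] = _hash_file(path)

    def run_stage(name, fn):
        t0 = time.perf_counter()
        log.info("stage %s: start", name)
        try:
            fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        elapsed = time.perf_counter() - t0
        manifest["stages"][name] = round(elapsed, 3)
        log.info("stage %s: done in %.2fs", name, elapsed)

    state: dict = {}

    def stage_generate() -> None:
        design = config.reading_design(seeds[0])
        reading = generate_reading_study(design, params)
        writing = generate_writing_study(
            config.n_writing_participants, params, coeffs, seed=seeds[1]
        )
        write_dataset(reading, out / "reading_study.csv", seeds[0], design.to_dict())
        write_dataset(
            writing, out / "writing_study.csv", seeds[1],
            {"n_participants": config.n_writing_participants},
        )
        record(out / "reading_study.csv")
        record(out / "writing_study.csv")
        state["reading"], state["writing"] = reading, writing

    def stage_fit_dynamics() -> None:
        deltas = event_deltas(state["reading"])
        deltas.to_csv(out / "event_deltas.csv", index=False)
        record(out / "event_deltas.csv")
        rows = []
        for target in ("valence", "arousal"):
            spec = select_subset(deltas, target)
            fit = fit_nls(deltas, spec)
            fits[f"dynamics_{target}"] = fit
            fit.to_json(out / f"fit_{target}.json")
            record(out / f"fit_{target}.json")
            nfr2, w = residual_diagnostics(fit.residuals)
            for name, est in fit.estimates.items():
                rows.append(
                    {
                        "target": target,
                        "parameter": name,
                        "estimate": est,
                        "se": fit.standard_errors[name],
                        "r_squared": fit.r_squared,
                        "n": fit.n,
                        "resid_normal_r2": nfr2,
                        "shapiro_w": w,
                    }
                )
            summary = binned_rates(deltas, target)
            summary.to_csv(out / f"binned_rates_{target}.csv", index=False)
            record(out / f"binned_rates_{target}.csv")
            if config.run_posterior:
                post = posterior_sample(
                    deltas, spec, n_samples=config.n_posterior, seed=seeds[2]
                )
                fits[f"posterior_{target}"] = post
                post.to_json(out / f"posterior_{target}.json")
                record(out / f"posterior_{target}.json")
        tables["dynamics"] = pd.DataFrame(rows)
        state["deltas"] = deltas

    def stage_fit_behavior() -> None:
        reading, writing = state["reading"], state["writing"]
        part = fit_hinge_participation(reading["a_post"], reading["intention"])
        fits["participation"] = part
        part.to_json(out / "fit_participation.json")
        record(out / "fit_participation.json")
        tables["participation"] = pd.DataFrame(
            [
                {
                    "p0": part.p0, "alpha": part.alpha, "tau": part.tau,
                    "r_squared": part.r_squared, "n": part.n,
                }
            ]
        )

        flagged = classify_writing_records(writing, method="strength")
        rows = []
        for which, flag_col in (("pos", "is_pos"), ("neg", "is_neg")):
            for pred_name, pred_col in (("valence", "v_pre"), ("arousal", "a_pre")):
                lf = fit_logistic_expression(
                    flagged[pred_col], flagged[flag_col], pred_name
                )
                fits[f"logistic_{which}_{pred_name}"] = lf
                rows.append(
                    {
                        "model": which,
                        "predictor": pred_name,
                        "intercept": lf.intercept,
                        "slope": lf.slope,
                        "loglik": lf.loglik,
                        "deviance": lf.deviance,
                        "n": lf.n,
                    }
                )
        tables["expression"] = pd.DataFrame(rows)

        fb = fit_feedback(writing)
        fits["feedback"] = fb
        tables["feedback"] = pd.DataFrame(
            [
                {"kind": k, "c0": f.c0, "c1": f.c1, "r_squared": f.r_squared, "n": f.n}
                for k, f in fb.items()
            ]
        )
        state["writing_flagged"] = flagged

    def stage_report() -> None:
        gen = params.to_flat_dict()
        rows = []
        for target in ("valence", "arousal"):
            for name, est in fits[f"dynamics_{target}"].estimates.items():
                rows.append(
                    {
                        "quantity": name,
                        "generating": gen.get(name, 0.0),
                        "estimate": est,
                        "delta": est - gen.get(name, 0.0),
                    }
                )
        part = fits["participation"]
        for name, est in (("p0", part.p0), ("alpha", part.alpha), ("tau_p", part.tau)):
            rows.append(
                {
                    "quantity": name,
                    "generating": gen[name],
                    "estimate": est,
                    "delta": est - gen[name],
                }
            )
        for which in ("pos", "neg"):
            lf = fits[f"logistic_{which}_valence"]
            for kind, est in (("intercept", lf.intercept), ("slope", lf.slope)):
                truth = coeffs[which][kind]
                rows.append(
                    {
                        "quantity": f"{which}_{kind}",
                        "generating": truth,
                        "estimate": est,
                        "delta": est - truth,
                    }
                )
        recovery = pd.DataFrame(rows)
        state["recovery"] = recovery
        for name, table in {**tables, "recovery": recovery}.items():
            path = out / f"table_{name}.csv"
            table.to_csv(path, index=False)
            record(path)
        if config.make_figures:
            figure_files = make_figures(
                out, state["deltas"], fits, state["reading"], state["writing"]
            )
            for p in figure_files:
                record(p)
        config.to_yaml(out / "config.yaml")
        record(out / "config.yaml")

    run_stage("generate", stage_generate)
    run_stage("fit_dynamics", stage_fit_dynamics)
    run_stage("fit_behavior", stage_fit_behavior)
    run_stage("report", stage_report)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")

    return RunReport(
        out_dir=out,
        tables=tables,
        fits=fits,
        recovery=state["recovery"],
        manifest_path=out / "manifest.json",
    )


def make_figures(out_dir, deltas, fits, reading, writing) -> list[Path]:
    """Render the run's diagnostic figures; each figure's data is also
    written as CSV next to the image.

    Figures: binned mean rate vs pre-state per field charge with the fitted
    drift overlaid (dashed); posterior histograms with Sturges bins; the
    participation hinge; the feedback-of-expression scatter.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .core import arousal_drift, valence_drift
    from .params import ArousalParams, ValenceParams

    out = Path(out_dir)
    files: list[Path] = []

    def save(fig, name: str) -> None:
        path = out / name
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        files.append(path)

    # --- binned rates + fitted drift -------------------------------------
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    grid = np.linspace(-1, 1, 101)
    for ax, target in zip(axes, ("valence", "arousal")):
        summary = binned_rates(deltas, target)
        if summary.empty:
            continue
        fit = fits.get(f"dynamics_{target}")
        est = fit.estimates if fit else {}
        for h, color in ((-1.0, "tab:red"), (0.0, "tab:gray"), (1.0, "tab:green")):
            sub = summary[summary["h"] == h]
            ax.errorbar(
                sub["state"], sub["mean_rate"], yerr=sub["se_rate"],
                fmt="o", ms=3, color=color, label=f"h={h:+.0f}",
            )
            if fit:
                if target == "valence":
                    p = ValenceParams(
                        gamma_v=est["gamma_v"], b=est["b"],
                        b0=est.get("b0", 0), b1=est.get("b1", 0),
                        b2=est.get("b2", 0), b3=est.get("b3", 0),
                    )
                    ax.plot(grid, valence_drift(grid, h, p), "--", color=color, lw=1)
                else:
                    p = ArousalParams(
                        gamma_a=est["gamma_a"], d=est["d"],
                        d0=est.get("d0", 0), d1=est.get("d1", 0),
                        d2=est.get("d2", 0), d3=est.get("d3", 0),
                    )
                    ax.plot(grid, arousal_drift(grid, h, p), "--", color=color, lw=1)
        ax.axhline(0, color="k", lw=0.5)
        ax.set_xlabel(f"{target} before reading")
        ax.set_ylabel(f"mean d{target[0]}/dt (per min)")
        ax.legend(fontsize=7)
    save(fig, "fig_dynamics.png")

    # --- posterior histograms --------------------------------------------
    for target in ("valence", "arousal"):
        post = fits.get(f"posterior_{target}")
        if post is None:
            continue
        names = list(post.samples)
        fig, axes = plt.subplots(1, len(names), figsize=(2.6 * len(names), 2.6))
        axes = np.atleast_1d(axes)
        rows = []
        for ax, nm in zip(axes, names):
            draws = post.samples[nm]
            ax.hist(draws, bins=post.bin_count, color="tab:blue", alpha=0.8)
            ax.set_title(nm, fontsize=9)
            rows.append(
                {"parameter": nm, "mean": draws.mean(), "sd": draws.std(ddof=1)}
            )
        save(fig, f"fig_posterior_{target}.png")
        pd.DataFrame(rows).to_csv(out / f"fig_posterior_{target}.csv", index=False)
        files.append(out / f"fig_posterior_{target}.csv")

    # --- participation hinge ----------------------------------------------
    part = fits.get("participation")
    if part is not None:
        fig, ax = plt.subplots(figsize=(4, 3))
        agg = (
            reading.groupby("a_post")["intention"].agg(["mean", "sem", "size"])
            if reading["a_post"].nunique() <= 15
            else reading.assign(
                a_bin=pd.cut(reading["a_post"], 10).map(lambda iv: iv.mid).astype(float)
            ).groupby("a_bin")["intention"].agg(["mean", "sem", "size"])
        )
        ax.errorbar(agg.index, agg["mean"], yerr=agg["sem"], fmt="o", ms=3)
        grid_a = np.linspace(-1, 1, 101)
        ax.plot(
            grid_a,
            part.p0 + part.alpha * grid_a * (grid_a >= part.tau),
            "--", color="tab:orange",
        )
        ax.set_xlabel("reported arousal")
        ax.set_ylabel("participation intention")
        save(fig, "fig_participation.png")
        agg.reset_index().to_csv(out / "fig_participation.csv", index=False)
        files.append(out / "fig_participation.csv")

    # --- feedback of expression -------------------------------------------
    fb = fits.get("feedback")
    if fb:
        fig, ax = plt.subplots(figsize=(4, 3))
        kinds = writing["task"].astype(str).str.startswith("reply")
        for mask, lbl, color in (
            (kinds, "reply", "tab:purple"),
            (~kinds, "first", "tab:cyan"),
        ):
            sub = writing[mask]
            ax.scatter(
                sub["a_pre"], sub["a_post"] - sub["a_pre"], s=6, alpha=0.5,
                color=color, label=lbl,
            )
            f = fb.get(lbl)
            if f:
                xs = np.linspace(-1, 1, 2)
                ax.plot(xs, f.c0 + f.c1 * xs, "--", color=color)
        ax.axhline(0, color="k", lw=0.5)
        ax.set_xlabel("arousal before writing")
        ax.set_ylabel("arousal change")
        ax.legend(fontsize=7)
        save(fig, "fig_feedback.png")

    mapping = {
        "fig_dynamics": ("valence", "arousal"),
    }
    for target in mapping["fig_dynamics"]:
        summary = binned_rates(deltas, target)
        summary.to_csv(out / f"fig_dynamics_{target}.csv", index=False)
        files.append(out / f"fig_dynamics_{target}.csv")
    return files
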