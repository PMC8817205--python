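"""Automated analysis workflow: raw time courses to potency report.

One call runs, for every configured readout: half-LLOQ substitution,
median replicate aggregation, optional normalization to the time-matched
control, AUCE summarization, sigmoid fitting with hockey-stick fallback,
derived PA/ECx concentrations, per-time-point static fits for
comparison, and a cross-readout EC50 fold-ratio table.  Every decision
(fallbacks, substitution counts, failures) is logged and recorded so the
run is auditable; a failure in one readout does not stop the others.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from .auce import auce_table, summarize_effects
from .datasets import Compound, TimeCourseDataset, read_timecourse, write_parameter_table
from .dose_response import (
    HockeyStickFit,
    SigmoidFit,
    compare_potencies,
    derive_pa,
    fit_hockey_stick,
    fit_sigmoid,
    fit_static,
)
from .mabel import DEFAULT_PLASMA_VOLUME_ML, mabel_report, pm_to_ng_per_ml
from .preprocessing import aggregate_replicates, normalize_to_control, substitute_lloq

__all__ = ["load_config", "run_pipeline", "run_mabel"]

logger = logging.getLogger(__name__)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


def _compound_from_config(cfg: Mapping[str, Any]) -> Compound | None:
    c = cfg.get("compound")
    if not c:
        return None
    return Compound(
        name=c.get("name", "compound"),
        molecular_weight=float(c["molecular_weight"]),
        kd_ta=float(c.get("kd_ta", "nan")),
        kd_cd3=float(c.get("kd_cd3", "nan")),
    )


def analyze_readout(
    ds: TimeCourseDataset,
    readout: str,
    direction: str = "auto",
    normalize: str | None = None,
    metric: str = "AUCE",
    activity_percent: float = 30.0,
    static_fits: bool = True,
    decisions: list[str] | None = None,
):
    """AUCE dose-response analysis of a single readout.

    Returns a dict with the effect summaries, the primary fit (sigmoid,
    or hockey-stick fallback when no sigmoidal relationship can be
    established) and the static per-time-point fits.
    """
    log = decisions if decisions is not None else []
    work = substitute_lloq(ds)
    work = aggregate_replicates(work, method="median")
    if normalize:
        work = normalize_to_control(work, readout, mode=normalize)
        log.append(f"{readout}: normalized as {normalize}")
    summaries = summarize_effects(work, readout)
    table = auce_table(work, readout, metric=metric)

    fit: SigmoidFit | HockeyStickFit
    fallback = None
    try:
        fit = fit_sigmoid(table, direction=direction, readout=readout)
        sigmoid_ok = fit.converged
    except ValueError as exc:
        if "variance" not in str(exc):
            raise
        log.append(f"{readout}: degenerate (flat) dose-response")
        sigmoid_ok = False
    if not sigmoid_ok:
        log.append(f"{readout}: no sigmoidal relationship -> hockey-stick fallback")
        fallback = fit_hockey_stick(table, readout=readout)
        fit = fallback

    derived: dict[str, float] = {}
    if isinstance(fit, SigmoidFit) and fit.converged:
        derived[f"pa{activity_percent:g}_pm"] = derive_pa(fit, activity_percent)
        derived["ec90_pm"] = derive_pa(fit, 90.0)

    statics: dict[float, SigmoidFit] = {}
    if static_fits:
        for t in work.times(readout):
            try:
                statics[float(t)] = fit_static(work, readout, float(t),
                                               direction=direction)
            except ValueError as exc:
                log.append(f"{readout}: static fit at {t:g} h failed: {exc}")

    return {
        "readout": readout,
        "effect_summaries": summaries,
        "dose_response_table": table,
        "fit": fit,
        "fallback_used": fallback is not None,
        "derived": derived,
        "static_fits": statics,
    }


def _plot_readout(result, work_ds, out_dir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    readout = result["readout"]
    table = result["dose_response_table"]
    fit = result["fit"]
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))

    sub = work_ds.select(readout)
    for conc, grp in sub.groupby("concentration_pm"):
        grp = grp.sort_values("time_h")
        axes[0].plot(grp["time_h"], grp["value"], "o-", ms=3,
                     label=f"{conc:g} pM")
    axes[0].set_xlabel("time (h)")
    axes[0].set_ylabel(work_ds.readout_units.get(readout, "value"))
    axes[0].set_title(f"{readout}: time course")
    axes[0].legend(fontsize=5, ncol=2)

    pos = table.concentrations[table.concentrations > 0]
    axes[1].semilogx(np.clip(table.concentrations, pos.min() / 10, None),
                     table.values, "ko", label=table.metric_name)
    grid = np.geomspace(pos.min() / 10, pos.max() * 10, 200)
    axes[1].semilogx(grid, fit.predict(grid), "b-",
                     label=fit.model_name)
    axes[1].set_xlabel("concentration (pM)")
    axes[1].set_ylabel(table.metric_units)
    axes[1].set_title(f"{readout}: dose-response")
    axes[1].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out_dir / f"{readout}_doseresponse.png", dpi=120)
    plt.close(fig)


def run_pipeline(
    input_path: str | Path,
    config: str | Path | Mapping[str, Any],
    out_dir: str | Path | None = None,
    make_plots: bool = True,
) -> dict:
    """Run the full automated workflow on a tidy time-course CSV.

    ``config`` is a YAML path or mapping with optional keys ``readouts``
    (per-readout settings: direction, normalize, lloq, metric),
    ``column_map``, ``compound`` and ``mabel``.  Returns a result dict;
    per-readout failures are collected under ``errors`` rather than
    raised, so remaining readouts still run.
    """
    cfg = load_config(config) if isinstance(config, (str, Path)) else dict(config)
    readout_cfg: dict[str, dict] = cfg.get("readouts") or {}
    lloq = {r: float(c["lloq"]) for r, c in readout_cfg.items()
            if c and c.get("lloq") is not None}
    ds = read_timecourse(
        input_path,
        column_map=cfg.get("column_map"),
        lloq=lloq,
        concentration_unit=cfg.get("concentration_unit", "pM"),
        compound=_compound_from_config(cfg),
    )
    targets = list(readout_cfg) or ds.readouts

    decisions: list[str] = []
    results: dict[str, dict] = {}
    errors: dict[str, str] = {}
    for readout in targets:
        rc = readout_cfg.get(readout) or {}
        try:
            results[readout] = analyze_readout(
                ds, readout,
                direction=rc.get("direction", "auto"),
                normalize=rc.get("normalize"),
                metric=rc.get("metric", "AUCE"),
                activity_percent=float(cfg.get("activity_percent", 30.0)),
                decisions=decisions,
            )
        except Exception as exc:  # isolate per-readout failures
            logger.exception("analysis failed for %r", readout)
            errors[readout] = str(exc)
            decisions.append(f"{readout}: FAILED ({exc})")

    sig = {r: res["fit"] for r, res in results.items()
           if isinstance(res["fit"], SigmoidFit) and res["fit"].converged}
    comparison = compare_potencies(sig) if len(sig) >= 2 else None

    summary = {
        "input": str(input_path),
        "readouts": {
            r: {
                "model": res["fit"].model_name,
                "fallback_used": res["fallback_used"],
                "parameters": {
                    name: est for name, est, _, _ in res["fit"].parameter_rows()
                },
                "rse_percent": dict(res["fit"].rse_percent),
                "derived_pm": res["derived"],
                "static_ec50_pm": {
                    f"{t:g}": f.ec50 for t, f in res["static_fits"].items()
                    if f.converged
                },
            }
            for r, res in results.items()
        },
        "errors": errors,
        "decisions": decisions,
    }
    if comparison is not None:
        summary["ec50_fold_ratios"] = comparison.to_dict(orient="records")

    out = {
        "results": results,
        "comparison": comparison,
        "summary": summary,
        "errors": errors,
        "decisions": decisions,
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        fits = [res["fit"] for res in results.values()]
        if fits:
            write_parameter_table(fits, out_dir / "parameters.csv")
        if comparison is not None:
            comparison.to_csv(out_dir / "ec50_fold_ratios.csv", index=False)
        with open(out_dir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=float)
        if make_plots:
            work = aggregate_replicates(substitute_lloq(ds))
            for r, res in results.items():
                rc = readout_cfg.get(r) or {}
                plot_ds = work
                if rc.get("normalize"):
                    plot_ds = normalize_to_control(work, r, rc["normalize"])
                try:
                    _plot_readout(res, plot_ds, out_dir)
                except Exception:
                    logger.exception("plotting failed for %r", r)
    return out


def run_mabel(config: str | Path | Mapping[str, Any]) -> dict:
    """Potency-to-first-in-human-dose report (one row per readout).

    Config keys: ``compound`` (name, molecular_weight), ``plasma_volume_ml``
    (default 3000), ``activity_percent`` (default 30) and ``potencies`` — a
    mapping readout -> {ec50_pm, hill}.  The row with the lowest dose is
    flagged as the MABEL candidate.
    """
    cfg = load_config(config) if isinstance(config, (str, Path)) else dict(config)
    compound = _compound_from_config(cfg)
    if compound is None:
        raise ValueError("mabel config requires a compound with molecular_weight")
    volume = float(cfg.get("plasma_volume_ml", DEFAULT_PLASMA_VOLUME_ML))
    activity = float(cfg.get("activity_percent", 30.0))
    potencies = cfg.get("potencies") or {}
    if not potencies:
        raise ValueError("mabel config requires potencies entries")

    rows = []
    for readout, spec in potencies.items():
        fit = SigmoidFit(
            e0=0.0, emax=1.0,
            ec50=float(spec["ec50_pm"]), gamma=float(spec.get("hill", 1.0)),
            readout=readout,
        )
        rep = mabel_report(fit, compound, activity_percent=activity,
                           plasma_volume=volume)
        rep["ec50_ng_per_ml"] = pm_to_ng_per_ml(fit.ec50,
                                                compound.molecular_weight)
        rows.append(rep)
    min_dose = min(r["mabel_dose_ug"] for r in rows)
    for r in rows:
        r["is_mabel_candidate"] = r["mabel_dose_ug"] == min_dose
    return {
        "compound": compound.name,
        "plasma_volume_ml": volume,
        "activity_percent": activity,
        "rows": rows,
        "mabel_dose_ug": min_dose,
    }
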