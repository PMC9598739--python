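"""One-shot analysis pipeline: simulate -> life tables -> r -> thresholds.

Runs the full chain on simulated (or previously written) individual records
and writes one CSV per stage plus a JSON report of the qualitative summary
(threshold brackets, Monod fits, interaction signs, permutation p-values).
Every stage is deterministic given the configured seed.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import demography, inference, lifetables, monod, simulate

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]

STAGES = ("simulate", "lifetable", "demography", "monod", "hazard", "permtest")

#: Terms for the reproduction-output permutation tests (log-Ca scale;
#: the Ca x temperature interaction is not in this model).
REPRO_TERMS = ("log_ca", "food", "temp", "log_ca:food", "food:temp",
               "log_ca:food:temp")
#: Terms for the growth-rate permutation tests (no three-way interaction).
GROWTH_TERMS = ("log_ca", "food", "temp", "log_ca:food", "log_ca:temp",
                "food:temp")


@dataclass(frozen=True)
class PipelineConfig:
    """What to run, where to write it, and with which seeds/tolerances."""

    sim: simulate.SimConfig = field(
        default_factory=lambda: simulate.default_config())
    stages: tuple[str, ...] = STAGES
    out_dir: Optional[str] = None
    tol: float = demography.DEFAULT_TOL
    n_permutations: int = 3000
    min_positive_for_monod: int = 2

    def __post_init__(self) -> None:
        order = {s: i for i, s in enumerate(STAGES)}
        idx = sorted(order[s] for s in self.stages)
        if idx != list(range(len(idx))) or (idx and idx[0] != 0):
            raise ValueError(
                f"stages must form a prefix of {STAGES}, got {self.stages}")


def _treatment_groups(records):
    groups: dict[tuple[float, float, float], list] = {}
    for r in records:
        groups.setdefault(r.treatment.key(), []).append(r)
    return dict(sorted(groups.items()))


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the requested stage prefix and return the report bundle.

    The bundle maps stage names to DataFrames/objects; when ``out_dir`` is
    set, each table is also written as CSV and the summary as report.json.
    """
    bundle: dict = {"seed": config.sim.seed, "log": []}
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    horizon = config.sim.horizon_days
    records = simulate.simulate_experiment(config.sim)
    bundle["records"] = records
    bundle["events"] = simulate.records_to_events(records, horizon)
    bundle["summary"] = simulate.records_to_summary(records)
    bundle["log"].append(f"simulate: {len(records)} individuals, "
                         f"{len(bundle['events'])} event rows, seed "
                         f"{config.sim.seed}")
    if out:
        simulate.write_tables(records, out, config.sim)
    if "lifetable" not in config.stages:
        return _finish(bundle, out, config)

    groups = _treatment_groups(records)
    lt_frames = []
    tables = {}
    for (ca, food, temp), recs in groups.items():
        lt = lifetables.build_life_table(recs, horizon=horizon)
        tables[(ca, food, temp)] = lt
        frame = lifetables.life_table_frame(lt)
        frame.insert(0, "ca", ca)
        frame.insert(1, "food", food)
        frame.insert(2, "temp", temp)
        lt_frames.append(frame)
    bundle["life_tables"] = tables
    bundle["life_table_frame"] = pd.concat(lt_frames, ignore_index=True)
    bundle["traits"] = lifetables.traits_table(records)
    bundle["log"].append(f"lifetable: {len(tables)} treatment tables")
    if out:
        bundle["life_table_frame"].to_csv(out / "life_tables.csv", index=False)
        bundle["traits"].to_csv(out / "traits.csv", index=False)

    # Descriptive Ca thresholds -------------------------------------------
    thresh_rows = []
    for food in sorted({k[1] for k in groups}):
        for temp in sorted({k[2] for k in groups}):
            summaries = {}
            for (ca, f, t), recs in groups.items():
                if f == food and t == temp:
                    surv = sum(1 for r in recs if r.censored) / len(recs)
                    repro = any(r.total_offspring() > 0 for r in recs)
                    summaries[ca] = (surv, repro)
            if len(summaries) >= 2:
                br = lifetables.survival_threshold_bracket(summaries)
                thresh_rows.append({
                    "food": food, "temp": temp, "criterion": br.criterion,
                    "lower": br.lower, "upper": br.upper,
                    "ambiguous": br.ambiguous,
                })
    saturation = {}
    for food in sorted({k[1] for k in groups}):
        outputs: dict[float, list[float]] = {}
        for (ca, f, t), recs in groups.items():
            if f == food:
                outputs.setdefault(ca, []).extend(
                    float(r.total_offspring()) for r in recs)
        if len(outputs) >= 2 and any(
                np.any(np.asarray(v) > 0) for v in outputs.values()):
            saturation[food] = lifetables.reproduction_saturation_point(
                outputs, n_permutations=config.n_permutations,
                seed=config.sim.seed + 101)
        else:
            saturation[food] = None
    bundle["thresholds"] = pd.DataFrame(thresh_rows)
    bundle["saturation"] = saturation
    if out:
        bundle["thresholds"].to_csv(out / "thresholds.csv", index=False)
    if "demography" not in config.stages:
        return _finish(bundle, out, config)

    # Intrinsic rate of increase ------------------------------------------
    demo_rows = []
    pseudo_frames = []
    for (ca, food, temp), recs in groups.items():
        est = demography.jackknife_r(recs, tol=config.tol, horizon=horizon)
        demo_rows.append({
            "ca": ca, "food": food, "temp": temp, "n": est.n,
            "r_hat": est.r_hat, "se": est.se, "r_full": est.r_full,
            "method": est.method, "mixed_methods": est.mixed_methods,
        })
        pf = pd.DataFrame({
            "individual_id": [r.individual_id for r in recs],
            "ca": ca, "food": food, "temp": temp,
            "box_id": [r.treatment.box_id for r in recs],
            "pseudo_value": est.pseudo_values,
        })
        pseudo_frames.append(pf)
    bundle["demography"] = pd.DataFrame(demo_rows)
    bundle["pseudo_values"] = pd.concat(pseudo_frames, ignore_index=True)
    bundle["log"].append(f"demography: {len(demo_rows)} treatment estimates")
    if out:
        bundle["demography"].to_csv(out / "demography.csv", index=False)
        bundle["pseudo_values"].to_csv(out / "pseudo_values.csv", index=False)
    if "monod" not in config.stages:
        return _finish(bundle, out, config)

    # Threshold-Monod fits per food x temperature --------------------------
    demo = bundle["demography"]
    monod_rows = []
    fits = {}
    for (food, temp), grp in demo.groupby(["food", "temp"]):
        grp = grp.sort_values("ca")
        n_pos = int((grp["r_hat"] > 0).sum())
        row = {"food": food, "temp": temp, "n_points": len(grp),
               "n_positive": n_pos}
        if n_pos < config.min_positive_for_monod:
            row.update({"fitted": False,
                        "note": "skipped: most mean r values non-positive, "
                                "zero-growth threshold not estimable"})
            bundle["log"].append(
                f"monod: skipped food={food} temp={temp} ({n_pos} positive r)")
        else:
            fit = monod.fit_monod_threshold(grp["ca"].to_numpy(),
                                            grp["r_hat"].to_numpy())
            fits[(food, temp)] = fit
            row.update({
                "fitted": fit.refused is None,
                "note": fit.refused or "",
                "r_max": fit.r_max, "ca_zpg": fit.ca_zpg, "k_s": fit.k_s,
                "se_ca_zpg": fit.se_ca_zpg,
                "ci_ca_zpg_lo": fit.ci_ca_zpg[0],
                "ci_ca_zpg_hi": fit.ci_ca_zpg[1],
                "p_ca_zpg": fit.p_ca_zpg,
                "converged": fit.converged, "rss": fit.rss,
            })
        monod_rows.append(row)
    bundle["monod"] = pd.DataFrame(monod_rows)
    bundle["monod_fits"] = fits
    if out:
        bundle["monod"].to_csv(out / "monod.csv", index=False)
    if "hazard" not in config.stages:
        return _finish(bundle, out, config)

    # Discrete-time hazard model -------------------------------------------
    pp = inference.expand_person_period(records, horizon)
    bundle["person_period"] = pp
    hz = inference.fit_cloglog_hazard(pp, inference.HAZARD_TERMS)
    bundle["hazard"] = hz
    bundle["hazard_frame"] = hz.summary_frame()
    lrt_stat, lrt_p, lrt_df = inference.lrt_random_screen(pp)
    bundle["box_screen"] = {"chi2": lrt_stat, "p": lrt_p, "df": lrt_df}
    bundle["log"].append(
        f"hazard: {hz.n_rows} person-period rows, {hz.n_events} events; "
        f"box LRT chi2={lrt_stat:.3f} (df={lrt_df}, p={lrt_p:.3f})")
    if hz.separation_flag:
        bundle["log"].append("hazard: separation warning raised")
    if out:
        bundle["hazard_frame"].to_csv(out / "hazard.csv")
    if "permtest" not in config.stages:
        return _finish(bundle, out, config)

    # Null-model permutation tests -----------------------------------------
    # Predictors are mean-centered so that main effects remain interpretable
    # (and testable) in the presence of interaction terms; without centering,
    # food:temp is nearly collinear with food on the raw deg-C scale.
    traits = bundle["traits"].copy()
    traits["log_ca"] = np.log(traits["ca"])
    pv = bundle["pseudo_values"].copy()
    pv["log_ca"] = np.log(pv["ca"])
    for df_ in (traits, pv):
        for col in ("log_ca", "food", "temp"):
            df_[col] = df_[col] - df_[col].mean()
    perm_rows = []
    for resp_name, df, terms in (
            ("reproduction_output", traits, REPRO_TERMS),
            ("r_pseudo", pv.rename(columns={"pseudo_value": "r_pseudo"}),
             GROWTH_TERMS)):
        for i, term in enumerate(terms):
            res = inference.permutation_test_fixed_effect(
                df, resp_name, terms, term,
                n_permutations=config.n_permutations,
                seed=config.sim.seed + 1000 + i
                     + (0 if resp_name == "reproduction_output" else 500))
            perm_rows.append({
                "response": resp_name, "term": term,
                "chi_square": res.statistic, "B": res.n_permutations,
                "p_perm": res.p_perm,
            })
    bundle["permutation"] = pd.DataFrame(perm_rows)
    bundle["log"].append(f"permtest: {len(perm_rows)} term tests, "
                         f"B={config.n_permutations}")
    if out:
        bundle["permutation"].to_csv(out / "permutation.csv", index=False)
    return _finish(bundle, out, config)


def _finish(bundle: dict, out: Optional[Path],
            config: PipelineConfig) -> dict:
    report = {"seed": config.sim.seed, "stages": list(config.stages),
              "log": bundle["log"]}
    if "thresholds" in bundle:
        report["survival_thresholds"] = bundle["thresholds"].to_dict("records")
        report["saturation_point_by_food"] = {
            str(k): v for k, v in bundle["saturation"].items()}
    if "monod" in bundle:
        report["monod"] = _jsonable(bundle["monod"].to_dict("records"))
    if "hazard" in bundle:
        hf = bundle["hazard_frame"]
        report["hazard"] = {term: {"estimate": float(hf.loc[term, "estimate"]),
                                   "wald_z": float(hf.loc[term, "wald_z"])}
                            for term in hf.index}
        report["box_screen"] = bundle["box_screen"]
    if "permutation" in bundle:
        report["permutation"] = bundle["permutation"].to_dict("records")
    bundle["report"] = report
    if out:
        (out / "report.json").write_text(json.dumps(_jsonable(report),
                                                    indent=2, sort_keys=True))
    return bundle


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if math.isnan(f) else f
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj
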