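"""Orchestration: simulate -> process -> analyse with a validated config.

A :class:`RunConfig` (pydantic, unknown keys rejected) drives the three
stages.  ``run_pipeline`` executes the requested stages in order, passes
intermediates in memory, writes CSV/JSON artefacts into the output
directory, and finishes with a provenance block (config hash, seeds,
package versions) plus a short human-readable report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import __version__, reference as ref
from .accel import AccelConfig, process_recording
from .coda import DEFAULT_PARTS, SCHOOL_PARTS, compositional_mean, pivot_basis, variation_matrix, zero_replace
from .inference import (
    CompositionalMANCOVA,
    IlrRegression,
    bootstrap_logratio_differences,
    chi_square_table,
)
from .simulate import CohortSpec, generate_cohort, render_week

log = logging.getLogger("coda24")


class StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateConfig(StrictModel):
    n_participants: int = 69
    prop_sdcd: float = 30 / 69
    logratio_sd: float = 0.25
    outcome_noise_sd: float = ref.DEFAULT_OUTCOME_NOISE_SD
    days: int = 7
    sample_rate_hz: float = 20.0
    noise_sd_mg: float = 3.0
    render_signals: bool = True
    #: raw signal is rendered for the first k participants only (None = all);
    #: the rest carry their true compositions forward
    n_signal_participants: int | None = 2
    nonwear_minutes_per_day: int = 0
    write_signal_csv: bool = False


class ProcessConfig(StrictModel):
    calibrate: bool = True
    accel: dict = Field(default_factory=dict)  # AccelConfig overrides


class AnalyseConfig(StrictModel):
    segment: str = "total"
    bootstrap_b: int = 2000
    ism_max_minutes: int = 30
    ism_step_minutes: int = 5
    covariates: list[str] = Field(default_factory=lambda: ["age", "sex_male", "deprivation"])
    zero_delta_min: float = 1.0
    plots: bool = False


class RunConfig(StrictModel):
    stages: list[str] = Field(default_factory=lambda: ["simulate", "process", "analyse"])
    seed: int = 0
    out_dir: str = "coda24_out"
    signals_dir: str | None = None  # input for a stand-alone process stage
    compositions_csv: str | None = None  # input for a stand-alone analyse stage
    cohort_csv: str | None = None
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)
    process: ProcessConfig = Field(default_factory=ProcessConfig)
    analyse: AnalyseConfig = Field(default_factory=AnalyseConfig)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.model_validate(json.load(fh))


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# stages


def stage_simulate(config: RunConfig, out: Path) -> dict:
    sim = config.simulate
    spec = CohortSpec(
        n_participants=sim.n_participants,
        prop_sdcd=sim.prop_sdcd,
        logratio_sd=sim.logratio_sd,
        outcome_noise_sd=sim.outcome_noise_sd,
        seed=config.seed,
    )
    truth = generate_cohort(spec)
    truth.table.to_csv(out / "cohort.csv", index=False)
    log.info("simulate: %d participants (%d sDCD)", len(truth.table), (truth.table["group"] == "sdcd").sum())

    recordings = {}
    if sim.render_signals:
        k = sim.n_signal_participants or len(truth.table)
        plan = (
            {d: sim.nonwear_minutes_per_day for d in range(sim.days)}
            if sim.nonwear_minutes_per_day
            else None
        )
        for i, row in truth.table.head(k).iterrows():
            minutes = {p: row[p] for p in DEFAULT_PARTS}
            rec, sched, labels = render_week(
                minutes,
                days=sim.days,
                sample_rate_hz=sim.sample_rate_hz,
                seed=np.random.default_rng([config.seed, 1, i]),
                noise_sd_mg=sim.noise_sd_mg,
                nonwear_plan=plan,
                participant=row["id"],
            )
            recordings[row["id"]] = rec
            if sim.write_signal_csv:
                rec.to_csv(out / f"signal_{row['id']}.csv")
            log.debug("simulate: rendered %s (%d samples)", row["id"], rec.n_samples)
    return {"truth": truth, "recordings": recordings}


def stage_process(config: RunConfig, out: Path, recordings: dict) -> pd.DataFrame:
    accel_cfg = AccelConfig(**config.process.accel)
    rows = []
    days_frames = []
    for pid, rec in recordings.items():
        res = process_recording(rec, accel_cfg, calibrate=config.process.calibrate)
        log.debug("process: %s included=%s", pid, res["included"])
        d = res["days"].copy()
        d.insert(0, "id", pid)
        days_frames.append(d)
        if not res["included"]:
            continue
        for seg, comp in res["compositions"].items():
            rows.append({"id": pid, "segment": seg, **{f"{k}_min": v for k, v in comp.items()}})
    comps = pd.DataFrame(rows)
    comps.to_csv(out / "compositions.csv", index=False)
    if days_frames:
        pd.concat(days_frames, ignore_index=True).to_csv(out / "day_summaries.csv", index=False)
    return comps


def _segment_compositions(config: RunConfig, comps: pd.DataFrame | None, truth_table: pd.DataFrame) -> pd.DataFrame:
    """Merge processed compositions (where available) with true ones."""
    seg = config.analyse.segment
    parts = SCHOOL_PARTS if seg == "school" else DEFAULT_PARTS
    base = truth_table[["id", "group", "sfdc", "age", "sex_male", "deprivation"]].copy()
    if seg == "school":
        # true school-time composition is not defined at cohort level;
        # school analyses need processed signal
        if comps is None or comps.empty:
            raise ValueError("school segment requires processed recordings")
        merged = comps[comps["segment"] == seg].merge(base, on="id")
        for p in parts:
            merged[p] = merged[f"{p}_min"]
        return merged
    out = base.copy()
    for p in parts:
        out[p] = truth_table[p].to_numpy()
    if comps is not None and not comps.empty:
        proc = comps[comps["segment"] == seg].set_index("id")
        for pid in out["id"]:
            if pid in proc.index:
                out.loc[out["id"] == pid, list(parts)] = proc.loc[
                    pid, [f"{p}_min" for p in parts]
                ].to_numpy(dtype=float)
    return out


def stage_analyse(config: RunConfig, out: Path, data: pd.DataFrame) -> dict:
    ana = config.analyse
    seg = ana.segment
    parts = SCHOOL_PARTS if seg == "school" else DEFAULT_PARTS
    total = 390.0 if seg == "school" else 1440.0
    comp = zero_replace(data[list(parts)].to_numpy(), ana.zero_delta_min, total=total)
    basis = pivot_basis(parts, parts[0])
    covs = data[ana.covariates] if ana.covariates else None
    group = data["group"].to_numpy()

    results: dict = {"segment": seg, "n": int(len(data))}
    results["group_means"] = {
        g: dict(zip(parts, np.round(compositional_mean(comp[group == g], total), 2)))
        for g in ("td", "sdcd")
    }
    results["variation_matrix"] = {
        "parts": list(parts),
        "values": np.round(variation_matrix(comp), 4).tolist(),
    }

    man = CompositionalMANCOVA(comp, group, covs, basis=basis, parts=parts).fit()
    results["mancova"] = {
        "wilks_lambda": man.wilks_lambda,
        "f": man.f_value,
        "df_num": man.df_num,
        "df_den": man.df_den,
        "p": man.p_value,
    }

    diff = bootstrap_logratio_differences(
        comp[group == "td"],
        comp[group == "sdcd"],
        n_boot=ana.bootstrap_b,
        seed=config.seed,
        parts=parts,
        total=total,
    )
    results["group_differences_pct"] = diff.table.round(3).to_dict(orient="records")
    diff.table.to_csv(out / f"group_differences_{seg}.csv", index=False)

    fit = IlrRegression(
        comp, data["sfdc"].to_numpy(), covs, basis=basis, parts=parts, total=total,
        outcome_name="sfdc",
    ).fit()
    chi2, dfc, pc = fit.composition_test()
    results["regression"] = {
        "r_squared": fit.rsquared,
        "composition_wald_chi2": chi2,
        "composition_df": dfc,
        "composition_p": pc,
        "coefficients": {k: float(v) for k, v in fit.params.items()},
    }

    grid = np.arange(-ana.ism_max_minutes, ana.ism_max_minutes + 1, ana.ism_step_minutes)
    ism_frames = []
    for a in parts:
        for b in parts:
            if a != b:
                g = fit.isotemporal(a, b, minutes_grid=grid)
                ism_frames.append(g)
    ism = pd.concat(ism_frames, ignore_index=True)
    ism.to_csv(out / f"isotemporal_{seg}.csv", index=False)
    five = ism[(ism["minutes"] == 5.0)]
    results["isotemporal_5min"] = five.round(4).to_dict(orient="records")

    results["lifestyle_chi2"] = {}
    life_cols = [c for c in data.columns if c.startswith("lifestyle_")]
    for col in life_cols:
        tab = pd.crosstab(data["group"], data[col])
        try:
            c2, dfx, p = chi_square_table(tab.to_numpy())
            results["lifestyle_chi2"][col.removeprefix("lifestyle_")] = {
                "chi2": c2, "df": dfx, "p": p,
            }
        except ValueError as e:
            results["lifestyle_chi2"][col.removeprefix("lifestyle_")] = {"error": str(e)}

    if ana.plots:
        from . import plots

        plots.group_difference_plot(diff, out / f"fig_differences_{seg}.png")
        plots.reallocation_plot(ism, out / f"fig_isotemporal_{seg}.png")
    return results


def _report_text(results: dict) -> str:
    lines = [f"coda24 analysis report (segment: {results['segment']}, n = {results['n']})", ""]
    lines.append("Group compositional means (min/day):")
    for g, m in results["group_means"].items():
        lines.append(f"  {g:<5} " + "  ".join(f"{k}={v:.1f}" for k, v in m.items()))
    man = results["mancova"]
    lines.append(
        f"MANCOVA group effect: Wilks lambda={man['wilks_lambda']:.4f}, "
        f"F({man['df_num']:.0f},{man['df_den']:.0f})={man['f']:.3f}, p={man['p']:.4f}"
    )
    lines.append("Percent differences (sDCD vs TD) with bootstrap 95% CI:")
    for r in results["group_differences_pct"]:
        lines.append(
            f"  {r['part']:<6} {r['percent']:+6.1f}% [{r['ci_low_pct']:+6.1f}, {r['ci_high_pct']:+6.1f}]"
        )
    reg = results["regression"]
    lines.append(
        f"ilr regression of motor competence: R^2={reg['r_squared']:.3f}, "
        f"composition Wald chi2({reg['composition_df']})={reg['composition_wald_chi2']:.2f}, "
        f"p={reg['composition_p']:.4f}"
    )
    lines.append("5-min reallocation effects (score units):")
    for r in results["isotemporal_5min"]:
        lines.append(
            f"  {r['from_part']}->{r['to_part']}: {r['delta_outcome']:+.3f} "
            f"[{r['ci_low']:+.3f}, {r['ci_high']:+.3f}]"
        )
    if results.get("lifestyle_chi2"):
        lines.append("Lifestyle chi-square tests:")
        for k, v in results["lifestyle_chi2"].items():
            if "p" in v:
                lines.append(f"  {k}: chi2={v['chi2']:.2f} (df {v['df']}), p={v['p']:.4f}")
    return "\n".join(lines) + "\n"


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the results bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}
    truth = None
    comps = None
    recordings: dict = {}

    try:
        if "simulate" in config.stages:
            sim_out = stage_simulate(config, out)
            truth = sim_out["truth"]
            recordings = sim_out["recordings"]
    except Exception:
        log.exception("stage 'simulate' failed")
        raise
    try:
        if "process" in config.stages:
            if not recordings and config.signals_dir:
                from .accel import TriaxialRecording

                for f in sorted(Path(config.signals_dir).glob("signal_*.csv")):
                    pid = f.stem.removeprefix("signal_")
                    recordings[pid] = TriaxialRecording.from_csv(f, participant=pid)
            comps = stage_process(config, out, recordings)
    except Exception:
        log.exception("stage 'process' failed")
        raise
    try:
        if "analyse" in config.stages:
            if truth is None:
                if not config.cohort_csv:
                    raise ValueError("analyse stage needs a cohort table (cohort_csv)")
                table = pd.read_csv(config.cohort_csv)
                data = table
                if config.compositions_csv:
                    comps = pd.read_csv(config.compositions_csv)
                data = _segment_compositions(config, comps, table)
            else:
                data = _segment_compositions(config, comps, truth.table)
            results = stage_analyse(config, out, data)
            bundle["results"] = results
            (out / "results.json").write_text(json.dumps(results, indent=2))
            (out / "report.txt").write_text(_report_text(results))
    except Exception:
        log.exception("stage 'analyse' failed")
        raise

    provenance = {
        "coda24_version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    bundle["provenance"] = provenance
    return bundle
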