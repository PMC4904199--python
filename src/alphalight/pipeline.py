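"""End-to-end pipeline: simulate -> alpha -> select -> screen -> model
-> mediate, under one seed and one configuration.

Sessions are processed one at a time (the epoched EEG of a session is
released before the next is generated) and the per-trial alpha
summaries are appended to the study-level trial table, which then feeds
the multilevel analyses.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as _stats

from . import alphapower, mediation, models, screening, synth
from .containers import LIGHT_LEVELS, write_trials
from .electrodes import SelectionResult, select_electrodes
from .montage import CANDIDATES

logger = logging.getLogger("alphalight")


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Everything a full run needs; defaults are the study conditions."""

    n_participants: int = 24
    seed: int = 0
    schedule: synth.ScheduleConfig = field(
        default_factory=synth.ScheduleConfig)
    params: synth.GeneratorParams = field(
        default_factory=synth.GeneratorParams)
    rt_bounds_ms: tuple[float, float] = (200.0, 1000.0)
    artifact_uv: float = 100.0
    outlier_k: float = 3.0
    band_hz: tuple[float, float] = (8.0, 13.0)
    selection_k: int = 4
    selection_criterion: str = "signed"
    contrast_adjustment: str = "max-t"
    mediation_random_slope: bool = True
    simulate_eeg: bool = True

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None
                  ) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sched = synth.ScheduleConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in raw.pop("schedule", {}).items()})
        params = synth.GeneratorParams(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in raw.pop("params", {}).items()})
        for key in ("rt_bounds_ms", "band_hz"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        cfg = cls(schedule=sched, params=params, **raw)
        if seed is not None:
            cfg.seed = seed
        return cfg


def _schedule_seed(session_seed: int) -> int:
    return int(np.random.SeedSequence([session_seed, 1])
               .generate_state(1)[0] % (2 ** 31))


def process_session(spec: synth.SessionSpec, config: PipelineConfig
                    ) -> tuple[pd.DataFrame, SelectionResult, dict]:
    """Simulate one session and attach measured alpha summaries.

    Returns the session trial table (with ``alpha_*``, ``log_alpha_*``,
    ``artifact_pretarget`` and ``artifact_desync`` columns), the
    electrode selection, and the desync-screen filter report.
    """
    schedule = synth.make_schedule(config.schedule,
                                   _schedule_seed(spec.seed))
    epochs, trials = synth.simulate_session(spec, config.params, schedule,
                                            eeg=config.simulate_eeg)
    if epochs is None:
        trials["artifact_pretarget"] = False
        trials["artifact_desync"] = False
        empty = SelectionResult(session_id=spec.session_id,
                                chosen={h: list(CANDIDATES[h][:4])
                                        for h in ("left", "right")},
                                metrics={h: {} for h in ("left", "right")})
        return trials, empty, {}

    epochs = alphapower.baseline_epochs(epochs)
    filtered = alphapower.bandpass_alpha(epochs, band=config.band_hz)
    series = alphapower.alpha_envelope(filtered)

    trials["artifact_pretarget"] = screening.artifact_mask(
        epochs, trials, "pretarget", config.artifact_uv)
    trials["artifact_desync"] = screening.artifact_mask(
        epochs, trials, "desync", config.artifact_uv)

    # electrode selection uses the desync-screened trial average; the
    # artifact flags above are reused rather than rescanning the epochs
    kept, report = screening.filter_trials(
        trials, None, purpose="desync", rt_bounds_ms=config.rt_bounds_ms)
    drop = kept["artifact_desync"].to_numpy(bool)
    report.artifact_desync_window = int(drop.sum())
    report.surviving -= report.artifact_desync_window
    kept = kept.loc[~drop]
    if len(kept) == 0:
        raise PipelineError("select", f"no trials survive the desync "
                                      f"screen in {spec.session_id}")
    sub = series.values[kept.index.to_numpy()]
    sub_series = type(series)(values=sub,
                              grid_times_ms=series.grid_times_ms,
                              channel_labels=series.channel_labels,
                              band_hz=series.band_hz, win_ms=series.win_ms)
    desync = alphapower.posttarget_desync(
        sub_series, kept, CANDIDATES["left"] + CANDIDATES["right"])
    selection = select_electrodes(desync, CANDIDATES,
                                  k=config.selection_k,
                                  session_id=spec.session_id,
                                  criterion=config.selection_criterion)

    summaries = alphapower.pretarget_alpha(series, selection.chosen)
    for col in summaries.columns:
        trials[col] = summaries[col].to_numpy()
    return trials, selection, report.to_dict()


def run_study(config: PipelineConfig
              ) -> tuple[pd.DataFrame, list[SelectionResult], list[dict]]:
    """Simulate and process every session of the study."""
    specs = synth.build_study(config.n_participants, config.seed)
    tables, selections, reports = [], [], []
    for spec in specs:
        t0 = time.time()
        trials, sel, rep = process_session(spec, config)
        tables.append(trials)
        selections.append(sel)
        reports.append(rep)
        logger.info("session %s done in %.1fs", spec.session_id,
                    time.time() - t0)
    study = pd.concat(tables, ignore_index=True)
    study = models.add_trial_norm(study, n_max=config.schedule.n_trials)
    return study, selections, reports


# ---------------------------------------------------------------------------
# analysis stages
# ---------------------------------------------------------------------------

def screen_for_rt(study: pd.DataFrame, config: PipelineConfig,
                  require_alpha: bool = False
                  ) -> tuple[pd.DataFrame, dict]:
    """Behaviour screen: RT bounds, pre-target artifact flag, then the
    3-SD RT outlier pass within participant x light cells."""
    rep = screening.FilterReport(n_input=len(study))
    rt = study["rt_ms"].to_numpy(float)
    responded = study["responded"].to_numpy(bool)
    lo, hi = config.rt_bounds_ms
    miss = ~responded
    rt_low = responded & (rt < lo)
    rt_high = responded & (rt > hi)
    keep = ~(miss | rt_low | rt_high)
    rep.no_response = int(miss.sum())
    rep.rt_low = int(rt_low.sum())
    rep.rt_high = int(rt_high.sum())
    if "artifact_pretarget" in study.columns:
        bad = study["artifact_pretarget"].to_numpy(bool)
        rep.artifact_pretarget = int((bad & keep).sum())
        keep &= ~bad
    out = study.loc[keep].copy()
    if require_alpha and "log_alpha_pooled" not in out.columns:
        raise PipelineError("screen", "alpha summaries missing")
    if len(out) == 0:
        rep.surviving = 0
        return out, rep.to_dict()
    out, removed = screening.remove_outliers(
        out, "rt_ms", ["participant_id", "light_condition"],
        k=config.outlier_k)
    rep.rt_outlier = len(removed)
    rep.surviving = len(out)
    return out, rep.to_dict()


def alpha_long_table(study: pd.DataFrame, config: PipelineConfig
                     ) -> tuple[pd.DataFrame, dict]:
    """Long-format alpha table (one row per trial x hemisphere) with the
    pre-target artifact screen and the 3-SD outlier pass on log alpha
    within participant x light x hemisphere cells."""
    keep = ~study["artifact_pretarget"].to_numpy(bool)
    base = study.loc[keep]
    rep = {"n_input": 2 * len(study),
           "artifact_pretarget": 2 * int((~keep).sum())}
    rows = []
    for hemi in ("left", "right"):
        sub = base[["session_id", "participant_id", "condition_order",
                    "light_condition", "trial_number", "trial_norm",
                    "hemifield"]].copy()
        sub["hemisphere"] = hemi
        sub["log_alpha"] = base[f"log_alpha_{hemi}"].to_numpy()
        rows.append(sub)
    long = pd.concat(rows, ignore_index=True)
    long, removed = screening.remove_outliers(
        long, "log_alpha",
        ["participant_id", "light_condition", "hemisphere"],
        k=config.outlier_k)
    rep["alpha_outlier"] = len(removed)
    rep["surviving"] = len(long)
    return long, rep


def analyse(study: pd.DataFrame, config: PipelineConfig) -> dict:
    """Multilevel inference on the processed study table."""
    report: dict = {}

    rt_data, rt_rep = screen_for_rt(study, config)
    report["screen_rt"] = rt_rep
    if len(rt_data) == 0:
        raise PipelineError("model", "no surviving trials after screening")

    # --- RT: Light x Target-hemifield -------------------------------------
    rt_spec = models.ModelSpec(
        outcome="rt_ms",
        fixed=("light_condition", "hemifield",
               "light_condition:hemifield", "vertical_field",
               "trial_norm"),
        groups="participant_id", re_terms=("1", "hemifield"))
    lrt_int, full_rt, _ = models.lrt_fixed_term(
        rt_spec, rt_data, "light_condition:hemifield")
    no_int = rt_spec.drop_fixed("light_condition:hemifield")
    lrt_light, _, _ = models.lrt_fixed_term(no_int, rt_data,
                                            "light_condition")
    lrt_hemif, _, _ = models.lrt_fixed_term(no_int, rt_data, "hemifield")
    report["rt_model"] = {
        "fit": full_rt.to_dict(),
        "lrt": [lrt_light.to_dict(), lrt_hemif.to_dict(),
                lrt_int.to_dict()],
    }

    # follow-up: light contrasts separately per hemifield
    report["rt_contrasts"] = {}
    for hemif in ("left", "right"):
        sub = rt_data[rt_data["hemifield"] == hemif]
        fit = models.fit_mixed(
            models.ModelSpec(outcome="rt_ms", fixed=("light_condition",),
                             groups="participant_id"), sub)
        cons = models.pairwise_contrasts(
            fit, "light_condition", adjustment=config.contrast_adjustment)
        report["rt_contrasts"][hemif] = {
            "means": {lev: float(sub.loc[sub.light_condition == lev,
                                         "rt_ms"].mean())
                      for lev in LIGHT_LEVELS},
            "contrasts": [c.to_dict() for c in cons],
        }

    has_alpha = "log_alpha_pooled" in study.columns
    if has_alpha:
        # --- alpha: Light x Hemisphere -------------------------------------
        long, alpha_rep = alpha_long_table(study, config)
        report["screen_alpha"] = alpha_rep
        a_spec = models.ModelSpec(
            outcome="log_alpha",
            fixed=("light_condition", "hemisphere",
                   "light_condition:hemisphere", "trial_norm"),
            groups="participant_id", re_terms=("1",),
            vc_terms=("hemisphere",))
        lrt_aint, full_a, _ = models.lrt_fixed_term(
            a_spec, long, "light_condition:hemisphere")
        no_aint = a_spec.drop_fixed("light_condition:hemisphere")
        lrt_alight, _, _ = models.lrt_fixed_term(no_aint, long,
                                                 "light_condition")
        lrt_tot, _, _ = models.lrt_fixed_term(no_aint, long, "trial_norm")
        report["alpha_model"] = {
            "fit": full_a.to_dict(),
            "lrt": [lrt_alight.to_dict(), lrt_aint.to_dict(),
                    lrt_tot.to_dict()],
        }
        report["alpha_contrasts"] = {}
        for hemi in ("left", "right"):
            sub = long[long["hemisphere"] == hemi]
            fit = models.fit_mixed(
                models.ModelSpec(outcome="log_alpha",
                                 fixed=("light_condition",),
                                 groups="participant_id"), sub)
            cons = models.pairwise_contrasts(
                fit, "light_condition",
                adjustment=config.contrast_adjustment)
            report["alpha_contrasts"][hemi] = [c.to_dict() for c in cons]

        # --- RT ~ alpha coupling, moderated by light -----------------------
        ar_spec = models.ModelSpec(
            outcome="rt_ms",
            fixed=("light_condition", "hemifield",
                   "light_condition:hemifield", "log_alpha_pooled",
                   "light_condition:log_alpha_pooled"),
            groups="participant_id",
            re_terms=("1", "hemifield", "log_alpha_pooled"))
        lrt_slope_int, full_ar, _ = models.lrt_fixed_term(
            ar_spec, rt_data, "light_condition:log_alpha_pooled")
        no_sint = ar_spec.drop_fixed("light_condition:log_alpha_pooled")
        lrt_slope, _, _ = models.lrt_fixed_term(no_sint, rt_data,
                                                "log_alpha_pooled")
        slope_contrasts = []
        for hi, lo in (("medium", "low"), ("high", "medium"),
                       ("high", "low")):
            w: dict[str, float] = {}
            for lev, s in ((hi, 1.0), (lo, -1.0)):
                if lev != "low":
                    col = f"light_condition[{lev}]:log_alpha_pooled"
                    w[col] = w.get(col, 0.0) + s
            est, se = models.linear_contrast(full_ar, w)
            z = est / se
            slope_contrasts.append({
                "name": f"{hi} - {lo}", "estimate": est, "se": se,
                "statistic": z,
                "p_value": float(2 * _stats.norm.sf(abs(z)))})
        report["alpha_rt_model"] = {
            "fit": full_ar.to_dict(),
            "lrt": [lrt_slope.to_dict(), lrt_slope_int.to_dict()],
            "slope_contrasts": slope_contrasts,
        }

        # --- mediation -----------------------------------------------------
        med_data = rt_data[(rt_data["hemifield"] == "left")
                           & rt_data["light_condition"].isin(
                               ("low", "high"))]
        med = mediation.mediation_sobel(
            med_data, mediator_col="log_alpha_right",
            random_slope_mediator=config.mediation_random_slope)
        report["mediation"] = med.to_dict()
        report["mediation_summary"] = med.summary()
    return report


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None
                 ) -> dict:
    """Execute every stage and assemble (optionally write) the report."""
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    t_start = time.time()
    timings = {}
    try:
        t0 = time.time()
        study, selections, sess_reports = run_study(config)
        timings["study_s"] = round(time.time() - t0, 3)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage attribution
        raise PipelineError("synth", str(exc)) from exc

    if out is not None:
        write_trials(study, out / "trials.csv")
        (out / "selections.json").write_text(json.dumps(
            {"config_hash": chash,
             "sessions": [s.to_dict() for s in selections]}, indent=1))

    t0 = time.time()
    report = analyse(study, config)
    timings["analysis_s"] = round(time.time() - t0, 3)
    timings["total_s"] = round(time.time() - t_start, 3)

    report["config_hash"] = chash
    report["seed"] = config.seed
    report["n_sessions"] = int(study["session_id"].nunique())
    report["session_screens"] = sess_reports
    report["selection_counts"] = _selection_counts(selections)
    full = {"report": report, "timing": timings}
    if out is not None:
        (out / "report.json").write_text(json.dumps(full, indent=1))
    return full


def _selection_counts(selections: list[SelectionResult]) -> dict:
    counts: dict[str, dict[str, int]] = {"left": {}, "right": {}}
    for sel in selections:
        for hemi, labs in sel.chosen.items():
            for lab in labs:
                counts[hemi][lab] = counts[hemi].get(lab, 0) + 1
    return counts
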