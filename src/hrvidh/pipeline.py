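"""End-to-end study orchestration.

``run_study`` executes the whole analysis chain — cohort simulation or file
ingestion, ectopic filtering, night segmentation, time- and
frequency-domain HRV, index scoring, session/patient outcomes, and the
evaluation suite — and writes a reproducible report bundle:

* ``hrv_params.csv`` — night-averaged HRV parameters per patient and test
* ``patient_index.csv`` — index values, dysfunction flags, outcome labels
* ``sessions.csv`` — the session table with nadir and IDH classification
* ``evaluation.json`` — incidence, ROC/Youden, metrics, odds ratios,
  multivariate model and diagnostics
* ``roc_coordinates.csv`` — the ROC curve of the index for any-IDH
* ``reproducibility.csv`` — Spearman rho of test 1 vs test 2 parameters
* ``manifest.json`` — config, seed, versions, warnings, overridden defaults

Identical config and seed produce a byte-identical bundle.
"""

from __future__ import annotations

import dataclasses
import json
import warnings as _warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .evaluation import (ContingencyTable2x2, classification_metrics,
                         group_compare, logistic_diagnostics, odds_ratio_ci,
                         roc_auroc, spearman_rho)
from .index import (ANY_IDH_CUTOFF, PUBLISHED_MODEL, REPEATED_IDH_CUTOFF,
                    SeparationError, classify_dysfunction, fit_logistic,
                    hrv_idh_index)
from .io import read_rr_file, read_sessions, write_sessions
from .outcomes import classify_session, cohort_incidence, patient_outcome
from .simulate import CohortSimConfig, simulate_cohort
from .spectral import spectral_params
from .time_domain import (HRVParams, aggregate_night, filter_ectopic,
                          night_segments, time_domain)

INDEX_FEATURES = ("nn50", "tp", "vlf", "lf", "lf_hf_ratio")


@dataclass
class PipelineConfig:
    """One flat configuration object driving ``run_study``.

    Defaults follow the analysis conventions throughout: 00:00-04:00 night
    window, 300-s segments, 4-Hz/64-s/75 % Welch settings, index cutoffs
    0.544 and 0.576.
    """

    # either a simulation block ...
    simulation: Optional[CohortSimConfig] = field(default_factory=CohortSimConfig)
    # ... or all three input files
    rr_dir: Optional[str] = None          # <patient_id>_test<k>.txt files
    sessions_file: Optional[str] = None
    covariates_file: Optional[str] = None

    night_start_hour: int = 0
    night_end_hour: int = 4
    segment_s: float = 300.0
    any_idh_cutoff: float = ANY_IDH_CUTOFF
    repeated_idh_cutoff: float = REPEATED_IDH_CUTOFF
    seed: int = 0
    out_dir: str = "hrvidh_report"
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.segment_s <= 0:
            raise ValueError("segment_s must be positive")
        if not 0 < self.any_idh_cutoff < 1 or not 0 < self.repeated_idh_cutoff < 1:
            raise ValueError("cutoffs must lie in (0, 1)")
        if not 0 <= self.night_start_hour < self.night_end_hour <= 24:
            raise ValueError("night window hours must satisfy 0 <= start < end <= 24")
        if self.simulation is None:
            for name in ("rr_dir", "sessions_file", "covariates_file"):
                if getattr(self, name) is None:
                    raise FileNotFoundError(
                        f"no simulation block and missing input: {name}")

    def overridden_defaults(self) -> dict:
        ref = PipelineConfig()
        out = {}
        for f in dataclasses.fields(self):
            if f.name in ("simulation", "out_dir", "seed"):
                continue
            if getattr(self, f.name) != getattr(ref, f.name):
                out[f.name] = getattr(self, f.name)
        return out

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulation = CohortSimConfig(**sim)
        return cfg


def extract_night_hrv(series, segment_s: float = 300.0) -> HRVParams:
    """Full single-recording chain: ectopic filter -> night segmentation ->
    per-segment time + spectral parameters -> night average."""
    filtered = filter_ectopic(series)
    seg_result = night_segments(filtered, segment_s=segment_s)
    if seg_result.status != "ok":
        raise ValueError("recording covers no complete night segment")
    per_seg = []
    for seg in seg_result.segments:
        td = time_domain(seg)
        sp = spectral_params(seg)
        td.tp, td.vlf, td.lf, td.hf = sp.tp, sp.vlf, sp.lf, sp.hf
        td.lf_hf_ratio = sp.lf_hf_ratio
        per_seg.append(td)
    return aggregate_night(per_seg)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")


def run_study(config: PipelineConfig) -> dict:
    """Run the study replica and write the report bundle to
    ``config.out_dir``; returns the evaluation summary."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    with _warnings.catch_warnings(record=True) as caught:
        _warnings.simplefilter("always")
        bundle = _run(config, out)
        bundle["manifest"]["n_warnings"] = len(caught)
        bundle["manifest"]["warnings"] = sorted(
            {str(w.message) for w in caught})
    (out / "manifest.json").write_text(
        json.dumps(bundle["manifest"], indent=2, default=_json_default) + "\n")
    return bundle["summary"]


def _run(config: PipelineConfig, out: Path) -> dict:
    if config.simulation is not None:
        sim_cfg = dataclasses.replace(config.simulation, seed=config.seed)
        cohort = simulate_cohort(sim_cfg)
        sessions = cohort.sessions
        covariates = cohort.patients
        recordings = cohort.rri          # (patient_id, test) -> RRISeries
        write_sessions(sessions, out / "sessions_input.csv")
    else:
        rr_dir = Path(config.rr_dir)
        sessions = read_sessions(config.sessions_file)
        covariates = pd.read_csv(config.covariates_file)
        recordings = {}
        for pid in covariates["patient_id"]:
            for test in (1, 2):
                f = rr_dir / f"{pid}_test{test}.txt"
                if not f.exists():
                    raise FileNotFoundError(f"missing RR recording: {f}")
                recordings[(pid, test)] = read_rr_file(f)

    # --- HRV extraction -------------------------------------------------
    hrv_rows = []
    for (pid, test), series in recordings.items():
        params = extract_night_hrv(series, segment_s=config.segment_s)
        hrv_rows.append({"patient_id": pid, "test": test, **params.as_dict(),
                         "n_segments": params.n_segments_averaged})
    hrv = pd.DataFrame(hrv_rows).sort_values(["patient_id", "test"])
    hrv["index"] = [
        hrv_idh_index({k: r[k] for k in INDEX_FEATURES}) for _, r in hrv.iterrows()]
    hrv.to_csv(out / "hrv_params.csv", index=False, float_format="%.6f")

    # --- outcomes -------------------------------------------------------
    sess_rows = []
    by_patient = {}
    for s in sessions:
        idh, nadir = classify_session(s)
        by_patient.setdefault(s.patient_id, []).append(s)
        sess_rows.append({"patient_id": s.patient_id, "session_id": s.session_id,
                          "pre_sbp": s.pre_sbp, "nadir": nadir, "idh": int(idh)})
    pd.DataFrame(sess_rows).to_csv(out / "sessions.csv", index=False,
                                   float_format="%.2f")
    outcomes = {pid: patient_outcome(ss) for pid, ss in by_patient.items()}
    incidence = cohort_incidence(list(outcomes.values()))

    # --- patient-level table -------------------------------------------
    idx1 = hrv[hrv["test"] == 1].set_index("patient_id")["index"]
    idx2 = hrv[hrv["test"] == 2].set_index("patient_id")["index"]
    pats = sorted(outcomes)
    pt = pd.DataFrame({
        "patient_id": pats,
        "index_test1": [idx1.get(p, np.nan) for p in pats],
        "index_test2": [idx2.get(p, np.nan) for p in pats],
        "any_idh": [int(outcomes[p].any_idh) for p in pats],
        "repeated_idh": [int(outcomes[p].repeated_idh) for p in pats],
        "n_idh": [outcomes[p].n_idh for p in pats],
    })
    pt["dysfunction"] = [
        int(classify_dysfunction(v, config.any_idh_cutoff)) if np.isfinite(v)
        else 0 for v in pt["index_test1"]]
    pt.to_csv(out / "patient_index.csv", index=False, float_format="%.6f")

    # --- evaluation -----------------------------------------------------
    y_any = pt["any_idh"].to_numpy()
    y_rep = pt["repeated_idh"].to_numpy()
    scores = pt["index_test1"].to_numpy()
    summary = {"incidence": incidence, "cutoffs": {
        "any_idh": config.any_idh_cutoff,
        "repeated_idh": config.repeated_idh_cutoff}}

    if 0 < y_any.sum() < len(y_any):
        roc_any = roc_auroc(scores, y_any)
        cm = classification_metrics(pt["dysfunction"], y_any)
        summary["roc_any_idh"] = {
            "auroc": roc_any.auroc, "youden_cutoff": roc_any.youden_cutoff,
            "youden_index": roc_any.youden_index}
        summary["metrics_at_cutoff"] = {
            "accuracy": cm.accuracy, "recall": cm.recall,
            "precision": cm.precision, "f1": cm.f1,
            "specificity": cm.specificity}
        pd.DataFrame({
            "threshold": roc_any.thresholds,
            "sensitivity": roc_any.sensitivity,
            "specificity": roc_any.specificity,
        }).to_csv(out / "roc_coordinates.csv", index=False, float_format="%.6f")
    if 0 < y_rep.sum() < len(y_rep):
        summary["roc_repeated_idh"] = {
            "auroc": roc_auroc(scores, y_rep).auroc}

    # univariate odds ratios for binary covariates
    cov = covariates.set_index("patient_id")
    or_rows = {}
    candidates = ["dysfunction"] + [c for c in ("age65", "female", "dm", "htn", "chf")
                                    if c in cov.columns]
    exposures = pt.set_index("patient_id").join(
        cov[[c for c in candidates if c in cov.columns]], how="left")
    for name in candidates:
        x = exposures[name].to_numpy()
        t = ContingencyTable2x2(
            a=int(np.sum((x == 1) & (y_any == 1))),
            b=int(np.sum((x == 1) & (y_any == 0))),
            c=int(np.sum((x == 0) & (y_any == 1))),
            d=int(np.sum((x == 0) & (y_any == 0))))
        try:
            orv, (lo, hi) = odds_ratio_ci(t)
            _, p, test_name = group_compare(None, table=t)
            or_rows[name] = {"or": orv, "ci_low": lo, "ci_high": hi,
                             "p": p, "test": test_name}
        except ValueError as e:
            or_rows[name] = {"error": str(e)}
    summary["univariate_or"] = or_rows

    # multivariate logistic: dysfunction plus available covariates
    multi_cols = [c for c in ("dysfunction", "dm", "female") if c in exposures.columns]
    if len(multi_cols) >= 1 and 0 < y_any.sum() < len(y_any):
        X = exposures[multi_cols].astype(float)
        try:
            model = fit_logistic(X, y_any)
            diag = logistic_diagnostics(model, X, y_any)
            summary["multivariate"] = {
                "features": multi_cols,
                "or_dysfunction": float(np.exp(model.coefficients["dysfunction"])),
                "coefficients": dict(model.coefficients),
                "nagelkerke_r2": diag["nagelkerke_r2"],
                "hl_p": diag["hl_p"],
            }
        except SeparationError:
            summary["multivariate"] = {"error": "separation"}

    # reproducibility of test 1 vs test 2
    rep_rows = []
    both = hrv.pivot(index="patient_id", columns="test",
                     values=list(INDEX_FEATURES) + ["index"])
    for name in list(INDEX_FEATURES) + ["index"]:
        rho = spearman_rho(both[(name, 1)].to_numpy(), both[(name, 2)].to_numpy())
        rep_rows.append({"parameter": name,
                         "spearman_rho": np.nan if rho is None else rho})
    rep = pd.DataFrame(rep_rows)
    rep.to_csv(out / "reproducibility.csv", index=False, float_format="%.6f")
    summary["reproducibility"] = {
        r["parameter"]: r["spearman_rho"] for r in rep_rows}

    (out / "evaluation.json").write_text(
        json.dumps(summary, indent=2, default=_json_default) + "\n")

    manifest = {
        "package": "hrvidh",
        "version": __version__,
        "seed": config.seed,
        "mode": "simulation" if config.simulation is not None else "files",
        "config": {
            f.name: getattr(config, f.name) for f in dataclasses.fields(config)
            if f.name not in ("simulation", "out_dir")},
        "simulation": (dataclasses.asdict(dataclasses.replace(
            config.simulation, seed=config.seed))
            if config.simulation is not None else None),
        "overridden_defaults": config.overridden_defaults(),
    }
    return {"summary": summary, "manifest": manifest}
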