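"""End-to-end orchestration: simulate -> process -> features -> kinetics
-> group statistics, with reproducible, seeded outputs.

The pipeline streams the cohort one session at a time (raw waveforms are
never all in memory), accumulates the patient x session feature table,
and then runs the longitudinal analysis on it.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Union

import numpy as np
import pandas as pd
import yaml

from . import ecg as ecgmod
from . import features as featmod
from . import kinetics as kinmod
from . import stats as statmod
from .io import COHORT_COLUMNS, write_cohort_table
from .simulate import (
    CohortSpec,
    EXPECTED_ATTENDANCE,
    RESPONSE_THRESHOLD_M,
    SessionRecord,
    iter_cohort,
)
from .types import BeatSeries, Recording, ValidationError

log = logging.getLogger(__name__)

#: Parameters entering the Table-2-style longitudinal analysis.
ANOVA_PARAMS = [
    "distance",
    "hr_rest",
    "hr_peak",
    "hr_peak_dist",
    "hr_rec1",
    "hr_rec2",
    "hr_rec3",
    "hr_rec4",
    "hr_rec5",
    "effort",
    "compliance",
    "a_poly_walk",
    "b_poly_walk",
    "a_poly_rec",
    "b_poly_rec",
]


@dataclass
class PipelineConfig:
    """Configuration for a full run. All defaults mirror the protocol:
    five sessions, 300/360/300 s phases, nine expected attendances per
    interval, and the published 90 m response threshold."""

    spec: CohortSpec = field(default_factory=lambda: CohortSpec(seed=0))
    out_dir: Union[str, Path] = "walkbeat_out"
    threshold: Union[float, str] = RESPONSE_THRESHOLD_M
    window_s: float = 16.0
    stride_s: float = 4.0
    sphericity_correction: bool = False
    contrast_method: str = "t"
    fit_all_families: bool = True
    make_plots: bool = True

    @classmethod
    def from_yaml(cls, path, seed: Optional[int] = None, out=None):
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort_raw = raw.pop("cohort", {})
        if seed is not None:
            cohort_raw["seed"] = seed
        from .io import load_cohort_spec  # reuse profile parsing
        import tempfile

        with tempfile.NamedTemporaryFile("w", suffix=".yaml", delete=False) as fh:
            yaml.safe_dump(cohort_raw, fh)
            spec = load_cohort_spec(fh.name)
        Path(fh.name).unlink()
        if out is not None:
            raw["out_dir"] = out
        return cls(spec=spec, **raw)


@dataclass
class SessionResult:
    row: dict
    walk_fits: Dict[str, "kinmod.KineticsFit"]
    rec_fits: Dict[str, "kinmod.KineticsFit"]
    beats: BeatSeries


def process_session(
    rec: Recording,
    window_s: float = 16.0,
    stride_s: float = 4.0,
    fit_all: bool = True,
) -> SessionResult:
    """One recording -> beat series, static parameters and kinetics fits."""
    mask = ecgmod.detect_artifacts(rec.ecg, rec.fs_ecg)
    beats = ecgmod.correct_beats(ecgmod.detect_rpeaks(rec.ecg, rec.fs_ecg, mask=mask))
    lay = rec.phases
    acc_phases = ecgmod.segment_phases(rec, channel="accel")
    sp = featmod.static_params(
        beats, lay, rec.distance_m, accel_walk=acc_phases.walk.samples
    )
    walk_series = featmod.hr_series(
        beats, window_s, stride_s, span=(lay.rest_s, lay.rest_s + lay.walk_s),
        phase="walk",
    )
    rec_series = featmod.hr_series(
        beats, window_s, stride_s, span=(lay.rest_s + lay.walk_s, lay.total_s),
        phase="recovery",
    )

    def fits_for(series):
        if len(series) < 5:
            return {}
        if fit_all:
            return kinmod.fit_all_families(series)
        return {kinmod.QUADRATIC: kinmod.fit_family(series, kinmod.QUADRATIC)}

    walk_fits = fits_for(walk_series)
    rec_fits = fits_for(rec_series)
    row = {
        "patient": rec.patient_id,
        "session": rec.session,
        "group": "",
        "attendance": rec.attendance,
        "compliance": (
            statmod.compliance_rate(rec.attendance, EXPECTED_ATTENDANCE)
            if not np.isnan(rec.attendance)
            else float("nan")
        ),
        **sp.as_dict(),
    }
    for tag, fits in (("walk", walk_fits), ("rec", rec_fits)):
        quad = fits.get(kinmod.QUADRATIC)
        if quad is not None and quad.success:
            row[f"a_poly_{tag}"] = quad.coefficients["a_poly"]
            row[f"b_poly_{tag}"] = quad.coefficients["b_poly"]
            row[f"c_poly_{tag}"] = quad.coefficients["c_poly"]
            row[f"r2_{tag}"] = quad.r2
        else:
            for name in ("a_poly", "b_poly", "c_poly", "r2"):
                row[f"{name}_{tag}"] = float("nan")
    return SessionResult(row=row, walk_fits=walk_fits, rec_fits=rec_fits, beats=beats)


def build_cohort_table(
    sessions: Iterable[SessionRecord],
    window_s: float = 16.0,
    stride_s: float = 4.0,
    threshold: Union[float, str] = RESPONSE_THRESHOLD_M,
    fit_all: bool = True,
    collect_fits: bool = False,
):
    """Process a stream of recordings into the cohort feature table.

    Returns (table, all_fits) where all_fits maps (patient, session,
    phase) -> {family: fit} when ``collect_fits`` is set.
    """
    rows: List[dict] = []
    all_fits: Dict = {}
    n = 0
    for sr in sessions:
        res = process_session(
            sr.recording, window_s=window_s, stride_s=stride_s, fit_all=fit_all
        )
        rows.append(res.row)
        if collect_fits:
            all_fits[(sr.recording.patient_id, sr.recording.session, "walk")] = (
                res.walk_fits
            )
            all_fits[(sr.recording.patient_id, sr.recording.session, "recovery")] = (
                res.rec_fits
            )
        n += 1
        if n % 50 == 0:
            log.info("processed %d sessions", n)
    table = pd.DataFrame(rows)
    # Response-group assignment from the final-minus-baseline distance.
    wide = table.pivot(index="patient", columns="session", values="distance")
    gains = wide[wide.columns.max()] - wide[wide.columns.min()]
    assignment = statmod.assign_groups(gains, threshold=threshold)
    table["group"] = table["patient"].map(assignment.groups)
    table = table.reindex(columns=COHORT_COLUMNS)
    return (table, all_fits) if collect_fits else (table, None)


def longitudinal_analysis(
    table: pd.DataFrame,
    params: Optional[List[str]] = None,
    sphericity_correction: bool = False,
    contrast_method: str = "t",
) -> dict:
    """Table-2-style analysis of every parameter in the cohort table.

    Per parameter: boxplot-rule outlier removal within each group x
    session cell, per-parameter listwise deletion, two-way mixed ANOVA,
    repeated-measures follow-up within each group, and per-session group
    contrasts.
    """
    params = params or ANOVA_PARAMS
    anova_rows, followup_rows, contrast_rows = [], [], []
    for param in params:
        if param not in table.columns:
            continue
        long = table[["patient", "group", "session", param]].rename(
            columns={param: "value"}
        )
        long = long.dropna(subset=["value"])
        if long.empty or long["session"].nunique() < 2:
            continue
        # Outlier removal per group x session cell (boxplot rule).
        keep_mask = pd.Series(True, index=long.index)
        for _, cell in long.groupby(["group", "session"]):
            if len(cell) >= 4:
                _, removed = statmod.remove_outliers(cell["value"].to_numpy())
                keep_mask.loc[cell.index[removed]] = False
        n_out = int((~keep_mask).sum())
        long = long[keep_mask]
        long = statmod.listwise_delete(long)
        if long["patient"].nunique() < 4 or long["group"].nunique() < 2:
            continue
        res = statmod.mixed_anova(long, sphericity_correction=sphericity_correction)
        for effect, r in res.items():
            anova_rows.append(
                {
                    "parameter": param,
                    "effect": effect,
                    "df_main": r.df_main,
                    "df_error": r.df_error,
                    "F": r.F,
                    "p": r.p,
                    "partial_eta_sq": r.partial_eta_sq,
                    "n_outliers_removed": n_out,
                }
            )
        if res["interaction"].p < statmod.ALPHA:
            for g, sub in long.groupby("group"):
                fr = statmod.rm_anova_within_group(
                    sub, sphericity_correction=sphericity_correction
                )
                followup_rows.append(
                    {
                        "parameter": param,
                        "group": g,
                        "df_main": fr.df_main,
                        "df_error": fr.df_error,
                        "F": fr.F,
                        "p": fr.p,
                        "partial_eta_sq": fr.partial_eta_sq,
                    }
                )
        for session, sub in long.groupby("session"):
            lo = sub.loc[sub["group"] == "low", "value"]
            hi = sub.loc[sub["group"] == "high", "value"]
            if len(lo) < 2 or len(hi) < 2:
                continue
            try:
                stat, p = statmod.group_contrast_at_session(lo, hi, contrast_method)
            except ValidationError:
                continue
            contrast_rows.append(
                {
                    "parameter": param,
                    "session": session,
                    "statistic": stat,
                    "p": p,
                    "method": contrast_method,
                }
            )
    return {
        "anova": pd.DataFrame(anova_rows),
        "followups": pd.DataFrame(followup_rows),
        "contrasts": pd.DataFrame(contrast_rows),
    }


def make_baseline_table(table: pd.DataFrame) -> pd.DataFrame:
    """Baseline (session 0) group comparison of the continuous features."""
    base = table[table["session"] == table["session"].min()]
    cols = ["distance", "hr_rest", "hr_peak", "effort", "group"]
    return statmod.baseline_table(base[cols])


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _plot_outputs(table, analysis, out_dir: Path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plots = []
    for param in ("distance", "hr_rest", "hr_peak", "hr_rec1", "b_poly_walk"):
        if param not in table.columns:
            continue
        fig, ax = plt.subplots(figsize=(5, 3.5))
        for g, sub in table.groupby("group"):
            agg = sub.groupby("session")[param].agg(["mean", "std"])
            ax.errorbar(
                agg.index, agg["mean"], yerr=agg["std"], marker="o", capsize=3,
                label=f"{g}-response",
            )
        ax.set_xlabel("session")
        ax.set_ylabel(param)
        ax.legend()
        fig.tight_layout()
        p = out_dir / f"trajectory_{param}.png"
        fig.savefig(p, dpi=110)
        plt.close(fig)
        plots.append(p)
    return plots


def run_pipeline(config: PipelineConfig) -> dict:
    """Full run: simulate, process, analyze, and write the report bundle.

    Outputs in ``config.out_dir``: cohort.csv (feature table),
    anova.csv / followups.csv / contrasts.csv, baseline.csv, manifest.json
    (seed, config and a content hash per file) and trajectory plots.
    Identical seed + config give identical numeric outputs.
    """
    out_dir = Path(config.out_dir)
    if not out_dir.exists():
        log.info("creating output directory %s", out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    completed = []
    manifest_path = out_dir / "manifest.json"
    try:
        table, _ = build_cohort_table(
            iter_cohort(config.spec),
            window_s=config.window_s,
            stride_s=config.stride_s,
            threshold=config.threshold,
            fit_all=config.fit_all_families,
        )
        write_cohort_table(table, out_dir / "cohort.csv")
        completed.append("cohort")
        log.info(
            "cohort: %d patients, %d rows",
            table["patient"].nunique(),
            len(table),
        )
        analysis = longitudinal_analysis(
            table,
            sphericity_correction=config.sphericity_correction,
            contrast_method=config.contrast_method,
        )
        analysis["anova"].to_csv(out_dir / "anova.csv", index=False)
        analysis["followups"].to_csv(out_dir / "followups.csv", index=False)
        analysis["contrasts"].to_csv(out_dir / "contrasts.csv", index=False)
        completed.append("analysis")
        baseline = make_baseline_table(table)
        baseline.to_csv(out_dir / "baseline.csv", index=False)
        completed.append("baseline")
        if config.make_plots:
            _plot_outputs(table, analysis, out_dir)
            completed.append("plots")
    finally:
        files = sorted(p for p in out_dir.iterdir() if p.name != "manifest.json")
        manifest = {
            "seed": config.spec.seed,
            "completed_stages": completed,
            "config": {
                "threshold": config.threshold,
                "window_s": config.window_s,
                "stride_s": config.stride_s,
                "sphericity_correction": config.sphericity_correction,
            },
            "files": {p.name: _sha256(p) for p in files if p.is_file()},
        }
        manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return {
        "table": table,
        "analysis": analysis,
        "baseline": baseline,
        "out_dir": out_dir,
    }
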