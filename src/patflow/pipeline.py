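"""End-to-end orchestration: synth -> extract -> aggregate -> analyze -> report.

A run is fully determined by a :class:`~patflow.config.PipelineConfig` and
its seed: the report JSON is canonical and contains no wall-clock state, so
identical (config, seed) pairs produce byte-identical reports.  Per-stage
counts (generated, extracted beats, excluded sessions) are written to a run
log for flow accounting.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .aggregate import (
    align,
    apply_exclusions,
    compute_changes,
    detect_idh_drops,
    period_averages,
    period_bounds,
)
from .analysis import CohortAnalysis
from .config import PipelineConfig
from .core import PERIODS, SessionData
from .extract import extract_beats
from .io import REPORT_SCHEMA_VERSION, write_report
from .synth import SynthSession, generate_cohort

__all__ = ["run_pipeline", "PipelineResult"]


@dataclass
class PipelineResult:
    report: dict[str, Any]
    sessions: list[SessionData] = field(default_factory=list)
    changes: pd.DataFrame | None = None


def _session_from_synth(s: SynthSession, config: PipelineConfig) -> SessionData:
    if s.waveforms is not None:
        res = extract_beats(
            s.waveforms,
            bounds=config.filters,
            window_s=config.analysis.smoothing_window_s,
        )
        return align(
            res.smoothed,
            s.readings,
            s.covariates,
            session_id=s.session_id,
            valid_beat_fraction=res.valid_fraction,
        )
    assert s.session_data is not None
    return align(
        s.session_data.smoothed,
        s.readings,
        s.covariates,
        session_id=s.session_id,
        valid_beat_fraction=1.0,
    )


def run_pipeline(
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
    sessions: list[SessionData] | None = None,
    log: bool = True,
) -> PipelineResult:
    """Run the full pipeline and (optionally) write the report bundle.

    Without ``sessions`` a synthetic cohort is generated from the config
    (waveform rendering plus extraction when ``config.render_waveforms``,
    otherwise the generator's beat-level PAT path).  The report always
    contains the exclusion log; the statistical analysis is present only when
    at least one session survives the exclusion rules.
    """
    config = config or PipelineConfig()
    t_start = time.time()
    log_lines: list[str] = []

    if sessions is None:
        synth_sessions = generate_cohort(
            config.n_decliner,
            config.n_stable,
            config.n_riser,
            config.synth,
            seed=config.seed,
            render=config.render_waveforms,
            smoothing_window_s=config.analysis.smoothing_window_s,
        )
        log_lines.append(f"synth: generated {len(synth_sessions)} sessions")
        sessions = [_session_from_synth(s, config) for s in synth_sessions]

    retained, exclusions = apply_exclusions(sessions, config.analysis, config.periods)
    log_lines.append(
        f"exclusions: {len(exclusions)} dropped, {len(retained)} retained"
    )

    observations = []
    period_rows = []
    idh = {}
    for s in retained:
        bounds = period_bounds(s.smoothed.span, config.periods)
        pa = period_averages(s, bounds)
        observations.extend(compute_changes(pa, s.session_id))
        for p in PERIODS:
            period_rows.append(
                {
                    "session_id": s.session_id,
                    "period": p,
                    "mean_sbp": pa.mean_sbp[p],
                    "mean_dbp": pa.mean_dbp[p],
                    "mean_pat": pa.mean_pat[p],
                    "n_pat": pa.n_pat[p],
                    "n_bp": pa.n_bp[p],
                }
            )
        idh[s.session_id] = detect_idh_drops(s, bounds)

    covariates = {s.session_id: s.covariates for s in retained}
    report: dict[str, Any] = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "provenance": {
            "version": __version__,
            "config_hash": config.config_hash(),
            "seed": config.seed,
        },
        "counts": {
            "sessions_in": len(sessions),
            "sessions_retained": len(retained),
            "observations": len(observations),
        },
        "exclusions": dict(sorted(exclusions.excluded.items())),
        "idh": {
            "n_sessions_with_drop": sum(1 for v in idh.values() if v["n_drops"]),
            "n_drops_total": sum(v["n_drops"] for v in idh.values()),
            "per_session": {
                k: {"initial_sbp": v["initial_sbp"], "flags": v["flags"]}
                for k, v in sorted(idh.items())
            },
        },
        "analysis": None,
    }

    changes_df = None
    fitted = None
    if observations:
        from .core import changes_to_frame

        changes_df = changes_to_frame(observations, covariates)
        period_df = pd.DataFrame(period_rows)
        fitted = CohortAnalysis(changes_df, period_df, config.analysis).fit()
        report["analysis"] = fitted.to_dict()
        log_lines.append(
            f"analysis: {len(observations)} observations from {len(retained)} sessions"
        )
    else:
        log_lines.append("analysis: skipped (no retained observations)")

    result = PipelineResult(report=report, sessions=retained, changes=changes_df)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_report(report, out / "report.json")
        if changes_df is not None:
            changes_df.to_csv(
                out / "changes.tsv", sep="\t", index=False, float_format="%.9g"
            )
            pd.DataFrame(period_rows).to_csv(
                out / "period_averages.tsv", sep="\t", index=False, float_format="%.9g"
            )
        with open(out / "exclusions.tsv", "w") as fh:
            fh.write("session_id\treason\n")
            for sid, reason in sorted(exclusions.excluded.items()):
                fh.write(f"{sid}\t{reason}\n")
        if fitted is not None:
            (out / "summary.txt").write_text(fitted.summary() + "\n")
        if log:
            elapsed = time.time() - t_start
            log_lines.append(f"elapsed_s: {elapsed:.1f}")
            (out / "run.log").write_text(
                "\n".join([time.strftime("%Y-%m-%dT%H:%M:%S")] + log_lines) + "\n"
            )
        (out / "config.json").write_text(
            json.dumps(config.to_dict(), sort_keys=True, indent=1, default=_json_default)
            + "\n"
        )
    return result


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
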