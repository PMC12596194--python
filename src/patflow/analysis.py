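"""Cohort-level analysis model.

:class:`CohortAnalysis` is built from a table of per-interval change
observations (and, optionally, the per-session hour-period means); its
:meth:`~CohortAnalysis.fit` runs the full statistical battery — TOST
equivalence of iCPAT vs BP changes, Spearman correlation, concurrence rate,
uni-/multivariable regression, one-way ANOVA across periods, and
decliner-detection classification metrics — and returns a
:class:`CohortAnalysisResults` carrying every statistic with its n, plus a
``summary()`` table and a JSON-able ``to_dict()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .classify import confusion, label_bp_class, predict_decliner, roc_auc
from .config import AnalysisConfig
from .core import PERIODS, ChangeObservation, changes_to_frame
from .stats import (
    concurrence_rate,
    oneway_anova,
    ols_regression,
    spearman,
    tost_paired,
)

__all__ = ["CohortAnalysis", "CohortAnalysisResults"]

_COVARIATES = ("age", "height", "weight", "sex")


class CohortAnalysis:
    """Statistical model of the PAT-BP relationship across a cohort.

    Parameters
    ----------
    changes : DataFrame
        One row per (session, interval) with columns ``session_id``,
        ``interval``, ``d_sbp``, ``d_dbp``, ``d_pat``, ``icpat``,
        ``rel_sbp``, ``rel_dbp``, ``rel_pat`` and optionally the covariates
        ``age``, ``height``, ``weight``, ``sex`` (0/1 indicator).
    period_means : DataFrame, optional
        One row per (session, period) with ``mean_sbp``, ``mean_dbp``,
        ``mean_pat`` — enables the across-period ANOVA.
    config : AnalysisConfig
        Equivalence margin (mmHg), alpha, class threshold (% BP change) and
        predictor threshold (% PAT change).
    """

    def __init__(
        self,
        changes: pd.DataFrame,
        period_means: pd.DataFrame | None = None,
        config: AnalysisConfig | None = None,
    ):
        required = {"session_id", "interval", "d_sbp", "d_dbp", "d_pat",
                    "icpat", "rel_sbp", "rel_dbp", "rel_pat"}
        missing = required - set(changes.columns)
        if missing:
            raise ValueError(f"changes table missing columns: {sorted(missing)}")
        if len(changes) == 0:
            raise ValueError("empty changes table")
        self.changes = changes.reset_index(drop=True)
        self.period_means = period_means
        self.config = config or AnalysisConfig()

    @classmethod
    def from_observations(
        cls,
        observations: list[ChangeObservation],
        covariates: dict[str, dict[str, float]] | None = None,
        period_means: pd.DataFrame | None = None,
        config: AnalysisConfig | None = None,
    ) -> "CohortAnalysis":
        return cls(changes_to_frame(observations, covariates), period_means, config)

    # ------------------------------------------------------------------
    def _per_variable(self, var: str) -> dict[str, Any]:
        cfg = self.config
        df = self.changes
        d_bp = df[f"d_{var}"].to_numpy()
        rel_bp = df[f"rel_{var}"].to_numpy()
        d_pat = df["d_pat"].to_numpy()
        icpat = df["icpat"].to_numpy()
        rel_pat = df["rel_pat"].to_numpy()

        labels = label_bp_class(rel_bp, cfg.class_threshold)
        subgroup = labels != "stable"

        out: dict[str, Any] = {}
        if d_bp.size < 3:
            out["tost"] = {"n": int(d_bp.size), "mean_diff": None, "sd_diff": None,
                           "margin": cfg.margin, "p1": None, "p2": None,
                           "equivalent": None}
        elif cfg.pooled:
            t = tost_paired(icpat, d_bp, cfg.margin, cfg.alpha)
            out["tost"] = _tost_dict(t)
        else:
            out["tost"] = {
                interval: _tost_dict(
                    tost_paired(
                        icpat[df["interval"] == interval],
                        d_bp[df["interval"] == interval],
                        cfg.margin,
                        cfg.alpha,
                    )
                )
                for interval in df["interval"].unique()
            }

        if d_bp.size >= 3:
            rho, p = spearman(d_pat, d_bp)
            out["spearman_all"] = {"rho": rho, "p": p, "n": int(d_bp.size)}
        else:
            out["spearman_all"] = {"rho": None, "p": None, "n": int(d_bp.size)}
        if int(subgroup.sum()) >= 3 and np.ptp(d_pat[subgroup]) > 0:
            rho_s, p_s = spearman(d_pat[subgroup], d_bp[subgroup])
            out["spearman_subgroup"] = {
                "rho": rho_s, "p": p_s, "n": int(subgroup.sum()),
            }
        else:
            out["spearman_subgroup"] = {"rho": None, "p": None, "n": int(subgroup.sum())}

        c_all = concurrence_rate(d_pat, d_bp)
        out["ccr_all"] = {"ccr": c_all.ccr, "n": c_all.n_total,
                          "n_opposite": c_all.n_opposite}
        if subgroup.any():
            c_sub = concurrence_rate(d_pat, d_bp, subgroup_mask=subgroup,
                                     subgroup="risers_decliners")
            out["ccr_subgroup"] = {"ccr": c_sub.ccr, "n": c_sub.n_total,
                                   "n_opposite": c_sub.n_opposite}
        else:
            out["ccr_subgroup"] = {"ccr": None, "n": 0, "n_opposite": 0}

        out["regression"] = self._regressions(var, d_bp, d_pat)
        out["classification"] = self._classification(labels, rel_pat)
        out["class_counts"] = {
            c: int(np.sum(labels == c)) for c in ("decliner", "stable", "riser")
        }
        return out

    def _regressions(self, var: str, d_bp, d_pat) -> dict[str, Any]:
        try:
            uni = ols_regression(
                d_bp, pd.DataFrame({"d_pat": d_pat}), model_type="univariate"
            )
            result = {"univariate": _regression_dict(uni)}
        except ValueError:
            return {"univariate": None, "adjusted": None}
        if all(c in self.changes.columns for c in _COVARIATES):
            X = pd.DataFrame({"d_pat": d_pat})
            for c in _COVARIATES:
                X[c] = self.changes[c].to_numpy()
            try:
                adj = ols_regression(d_bp, X, model_type="adjusted")
                result["adjusted"] = _regression_dict(adj)
            except ValueError:
                result["adjusted"] = None
        else:
            result["adjusted"] = None
        return result

    def _classification(self, labels, rel_pat) -> dict[str, Any]:
        y = labels == "decliner"
        yhat = predict_decliner(rel_pat, self.config.predictor_threshold)
        metrics: dict[str, Any] = {}
        if y.any() and (~y).any():
            cm = confusion(y, yhat)
            roc = roc_auc(rel_pat, y)
            metrics["confusion"] = {"tp": cm.tp, "fn": cm.fn, "fp": cm.fp, "tn": cm.tn}
            metrics["sensitivity"] = cm.sensitivity
            metrics["specificity"] = cm.specificity
            metrics["precision"] = cm.precision
            metrics["f1"] = cm.f1
            metrics["auc"] = roc.auc
        else:
            metrics = {"confusion": None, "sensitivity": None, "specificity": None,
                       "precision": None, "f1": None, "auc": None}
        return metrics

    def _anova(self) -> dict[str, Any]:
        if self.period_means is None:
            return {}
        out = {}
        for var in ("sbp", "dbp", "pat"):
            col = f"mean_{var}"
            groups = [
                self.period_means.loc[self.period_means["period"] == p, col]
                .dropna()
                .to_numpy()
                for p in PERIODS
            ]
            if all(g.size >= 2 for g in groups):
                f, p = oneway_anova(groups)
                out[var] = {"F": f, "p": p}
        return out

    def fit(self) -> "CohortAnalysisResults":
        per_var = {var: self._per_variable(var) for var in ("sbp", "dbp")}
        return CohortAnalysisResults(
            sbp=per_var["sbp"],
            dbp=per_var["dbp"],
            anova=self._anova(),
            n_sessions=int(self.changes["session_id"].nunique()),
            n_observations=int(len(self.changes)),
            config=self.config,
        )


def _tost_dict(t) -> dict[str, Any]:
    return {
        "n": t.n, "mean_diff": t.mean_diff, "sd_diff": t.sd_diff,
        "margin": t.margin, "p1": t.p1, "p2": t.p2, "equivalent": t.equivalent,
    }


def _regression_dict(r) -> dict[str, Any]:
    return {
        "model_type": r.model_type,
        "n": r.n,
        "r_squared": r.r_squared,
        "coefficients": {
            k: {
                "estimate": float(r.params[k]),
                "se": float(r.bse[k]),
                "t": float(r.tvalues[k]),
                "p": float(r.pvalues[k]),
            }
            for k in r.params.index
        },
    }


@dataclass
class CohortAnalysisResults:
    """Fitted cohort statistics, JSON-able and printable."""

    sbp: dict[str, Any]
    dbp: dict[str, Any]
    anova: dict[str, Any]
    n_sessions: int
    n_observations: int
    config: AnalysisConfig
    extra: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return {
            "n_sessions": self.n_sessions,
            "n_observations": self.n_observations,
            "config": {
                "margin": self.config.margin,
                "alpha": self.config.alpha,
                "class_threshold": self.config.class_threshold,
                "predictor_threshold": self.config.predictor_threshold,
                "pooled": self.config.pooled,
            },
            "sbp": self.sbp,
            "dbp": self.dbp,
            "anova": self.anova,
            **self.extra,
        }

    def summary(self) -> str:
        """Human-readable summary of the fitted statistics."""
        lines = [
            "Cohort PAT-BP analysis",
            "=" * 54,
            f"sessions: {self.n_sessions}   observations: {self.n_observations}",
            f"TOST margin: +/-{self.config.margin} mmHg   alpha: {self.config.alpha}",
            "",
        ]
        for var in ("sbp", "dbp"):
            r = getattr(self, var)
            lines.append(f"[{var.upper()} changes vs PAT changes]")
            t = r["tost"]
            if t.get("p1") is not None:
                lines.append(
                    f"  TOST (iCPAT vs d{var.upper()}): mean diff "
                    f"{t['mean_diff']:+.2f}, p1={t['p1']:.4g}, p2={t['p2']:.4g}"
                    f" -> {'equivalent' if t['equivalent'] else 'not equivalent'}"
                )
            sp = r["spearman_all"]
            lines.append(
                f"  Spearman rho = {sp['rho']:+.3f} (p = {sp['p']:.3g}, n = {sp['n']})"
            )
            lines.append(
                f"  CCR = {r['ccr_all']['ccr']:.3f} (all), "
                + (
                    f"{r['ccr_subgroup']['ccr']:.3f} (risers+decliners)"
                    if r["ccr_subgroup"]["ccr"] is not None
                    else "n/a (risers+decliners)"
                )
            )
            cc = r["class_counts"]
            lines.append(
                f"  classes: {cc['decliner']} decliner / {cc['stable']} stable / "
                f"{cc['riser']} riser"
            )
            cl = r["classification"]
            if cl["f1"] is not None:
                lines.append(
                    f"  decliner detection: F1 = {cl['f1']:.3f}, "
                    f"sens = {cl['sensitivity']:.3f}, spec = {cl['specificity']:.3f}, "
                    f"AUC = {cl['auc']:.3f}"
                )
            lines.append("")
        if self.anova:
            parts = [
                f"{v}: F = {d['F']:.2f}, p = {d['p']:.3g}"
                for v, d in self.anova.items()
            ]
            lines.append("ANOVA across periods  " + "; ".join(parts))
        return "\n".join(lines)
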