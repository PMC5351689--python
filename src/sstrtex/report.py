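"""Report tables and Kaplan-Meier plots for the stratification results.

``build_report`` produces, per feature and outcome, a Cox row (from the
joint multivariable fit), a ROC row (AUC, CI, Youden cut-off,
sensitivity/specificity, p) and — for features whose AUC confidence
interval excludes 0.5 — a Kaplan-Meier row (log-rank chi-square, p, and
the per-group hazard-ratio pair of the low- and high-risk groups).
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .errors import ConvergenceError, StratificationError
from .survival import (
    DEFAULT_FEATURES,
    KmResult,
    cox_multivariable,
    dichotomize,
    event_labels,
    km_logrank,
    roc_youden,
)

ROC_COLUMNS = [
    "feature", "outcome", "auc", "ci_low", "ci_high",
    "sensitivity_pct", "specificity_pct", "cutoff", "direction", "p_value", "significant",
]
KM_COLUMNS = [
    "feature", "outcome", "chi2", "p_value",
    "hr_low_risk", "hr_low_ci_low", "hr_low_ci_high",
    "hr_high_risk", "hr_high_ci_low", "hr_high_ci_high",
    "n_low_risk", "n_high_risk",
]
COX_COLUMNS = ["feature", "outcome", "coef", "hr", "se", "z", "p"]


def holm_adjust(pvals: Sequence[float]) -> np.ndarray:
    p = np.asarray(pvals, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


def build_report(
    patient_features: pd.DataFrame,
    cohort: pd.DataFrame,
    features: Sequence[str] = DEFAULT_FEATURES,
    outcomes: Sequence[str] = ("pfs", "os"),
    alpha: float = 0.05,
    correction: Optional[str] = None,
    outdir: Optional[str | Path] = None,
) -> dict[str, pd.DataFrame]:
    """Run Cox + ROC (+ KM for ROC-significant features) per outcome.

    ``patient_features`` has one row per patient (patient_id + feature
    columns); ``cohort`` carries the survival columns.  Returns a dict
    with 'cox', 'roc_table' and 'km_table' frames; when ``outdir`` is
    given, the tables are written as CSV (table2_analog.csv,
    table3_analog.csv, cox_results.csv) and one KM plot per
    significant feature x outcome is rendered with a number-at-risk
    table.
    """
    df = patient_features.merge(cohort, on="patient_id", how="inner", suffixes=("", "_cohort"))
    if df.empty:
        raise StratificationError("no overlap between feature table and cohort table")

    cox_rows, roc_rows, km_rows = [], [], []
    km_results: dict[tuple[str, str], tuple[KmResult, np.ndarray]] = {}
    for outcome in outcomes:
        try:
            cox = cox_multivariable(df, list(features), outcome)
            for feat in features:
                row = cox.table.loc[feat]
                cox_rows.append(
                    dict(feature=feat, outcome=outcome.upper(), coef=row.coef, hr=row.hr,
                         se=row.se, z=row.z, p=row.p)
                )
        except (ConvergenceError, StratificationError) as exc:
            # a separated or under-determined multivariable fit must not
            # block the per-feature ROC/KM stages; report NaN Cox rows
            for feat in features:
                cox_rows.append(
                    dict(feature=feat, outcome=outcome.upper(), coef=np.nan, hr=np.nan,
                         se=np.nan, z=np.nan, p=np.nan)
                )
            import warnings

            warnings.warn(f"Cox fit failed for {outcome.upper()}: {exc}", stacklevel=2)
        labels = event_labels(df, outcome)
        for feat in features:
            roc = roc_youden(df[feat].to_numpy(), labels)
            roc_rows.append(
                dict(
                    feature=feat, outcome=outcome.upper(), auc=roc.auc,
                    ci_low=roc.ci_low, ci_high=roc.ci_high,
                    sensitivity_pct=roc.sensitivity_pct,
                    specificity_pct=roc.specificity_pct,
                    cutoff=roc.cutoff, direction=roc.direction,
                    p_value=roc.p_value, significant=roc.significant,
                )
            )
            if not roc.significant:
                continue
            try:
                groups = dichotomize(df[feat].to_numpy(), roc)
            except StratificationError:
                continue
            km = km_logrank(
                df[f"{outcome}_months"].to_numpy(),
                df[f"{outcome}_event"].to_numpy(dtype=bool),
                groups,
            )
            hr_lo = km.hazard_ratios.get("low_risk", (np.nan,) * 3)
            hr_hi = km.hazard_ratios.get("high_risk", (np.nan,) * 3)
            km_rows.append(
                dict(
                    feature=feat, outcome=outcome.upper(), chi2=km.chi2,
                    p_value=km.p_value,
                    hr_low_risk=hr_lo[0], hr_low_ci_low=hr_lo[1], hr_low_ci_high=hr_lo[2],
                    hr_high_risk=hr_hi[0], hr_high_ci_low=hr_hi[1], hr_high_ci_high=hr_hi[2],
                    n_low_risk=int((groups == "low_risk").sum()),
                    n_high_risk=int((groups == "high_risk").sum()),
                )
            )
            km_results[(feat, outcome)] = (km, groups)

    roc_table = pd.DataFrame(roc_rows, columns=ROC_COLUMNS)
    km_table = pd.DataFrame(km_rows, columns=KM_COLUMNS)
    cox_table = pd.DataFrame(cox_rows, columns=COX_COLUMNS)
    if correction in ("holm", "bonferroni"):
        for tbl, col in ((roc_table, "p_value"), (km_table, "p_value"), (cox_table, "p")):
            if len(tbl):
                if correction == "holm":
                    tbl["p_adjusted"] = holm_adjust(tbl[col].to_numpy())
                else:
                    tbl["p_adjusted"] = np.minimum(tbl[col].to_numpy() * len(tbl), 1.0)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        roc_table.to_csv(outdir / "table2_analog.csv", index=False)
        km_table.to_csv(outdir / "table3_analog.csv", index=False)
        cox_table.to_csv(outdir / "cox_results.csv", index=False)
        for (feat, outcome), (km, _groups) in km_results.items():
            plot_km(km, title=f"{feat} ({outcome.upper()})",
                    path=outdir / f"km_{feat}_{outcome}.png")
    return {"cox": cox_table, "roc_table": roc_table, "km_table": km_table}


def plot_km(km: KmResult, title: str, path: str | Path) -> None:
    """Step-function KM plot with a number-at-risk table below the axes."""
    fig, ax = plt.subplots(figsize=(6, 4.8))
    tmax = max((c.times.max() if len(c.times) else 1.0) for c in km.curves.values())
    ticks = np.linspace(0, tmax, 6)
    styles = {"low_risk": "-", "high_risk": "--"}
    for name, curve in sorted(km.curves.items()):
        t = np.concatenate([[0.0], curve.times])
        s = np.concatenate([[1.0], curve.survival])
        ax.step(t, s, where="post", linestyle=styles.get(name, "-"),
                label=f"{name} (n={curve.n})")
    ax.set_xlabel("months")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.set_title(f"{title}\nlog-rank chi2={km.chi2:.2f}, p={km.p_value:.3g}")
    ax.legend(loc="lower left", fontsize=8)
    # number-at-risk annotations (at-risk count at the next event time)
    y = -0.18
    for name, curve in sorted(km.curves.items()):
        txt = "  ".join(
            str(int(curve.at_risk[np.searchsorted(curve.times, t, side='left')])
                if np.searchsorted(curve.times, t, side='left') < len(curve.at_risk)
                else 0)
            for t in ticks
        )
        ax.annotate(f"at risk {name}: {txt}", xy=(0, y), xycoords="axes fraction", fontsize=7)
        y -= 0.06
    fig.tight_layout()
    fig.savefig(path, dpi=110, bbox_inches="tight")
    plt.close(fig)
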