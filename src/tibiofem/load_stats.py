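"""Group-level load-change statistics over per-subject contact-area tables.

Mirrors the cohort analysis of a paired loading study: per-subject change
and percentage change between the unloaded (0 N) and loaded (400 N)
acquisitions, compartment contrasts, the medial-to-lateral area ratio,
Shapiro-Wilk normality checks of the paired differences and two-sided
paired t-tests.

Conventions (deliberate, config-overridable where noted):

* the group percentage change is the mean of the per-subject percentage
  changes, not the percentage change of the group means — the only
  convention consistent with reporting "+64 mm^2 (+11.6%)" against a
  615 mm^2 baseline;
* standard deviations use the n-1 denominator;
* tests are two-sided with no multiple-testing correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .contact import COMPARTMENTS, INTERFACES, ContactAreaTable

log = logging.getLogger(__name__)

CONDITIONS = ("unloaded", "loaded")

#: measures reported row-wise: (interface, compartment-or-total)
MEASURES = tuple(
    (itf, comp) for itf in INTERFACES for comp in ("total",) + COMPARTMENTS
) + tuple(
    ("cartilage_meniscus", comp) for comp in ("total",) + COMPARTMENTS
)


@dataclass
class StatsConfig:
    alpha: float = 0.05
    normality_test: str = "shapiro-wilk"
    paired_test: str = "t-test"
    two_sided: bool = True

    def __post_init__(self):
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class LoadChangeReport:
    """Descriptive and inferential results of one cohort."""

    measures: pd.DataFrame  # one row per measure
    ratios: pd.DataFrame  # medial-to-lateral ratio per condition
    contrasts: pd.DataFrame  # paired contrasts (medial-lateral, mf-mt)
    n_subjects: int = 0
    excluded: list = field(default_factory=list)
    config: StatsConfig = field(default_factory=StatsConfig)

    def formatted(self) -> pd.DataFrame:
        """Rows rendered as 'mean change (mean percentage change) +/- SD'."""
        m = self.measures
        out = m[["interface", "compartment"]].copy()
        out["unloaded"] = [
            f"{a:.0f} mm2 +/- {s:.0f} mm2"
            for a, s in zip(m["mean_unloaded"], m["sd_unloaded"])
        ]
        out["loaded"] = [
            f"{a:.0f} mm2 +/- {s:.0f} mm2"
            for a, s in zip(m["mean_loaded"], m["sd_loaded"])
        ]
        out["change"] = [
            f"{c:+.0f} mm2 ({p:+.1f}%) +/- {s:.0f} mm2"
            for c, p, s in zip(m["mean_change"], m["mean_pct_change"], m["sd_change"])
        ]
        return out


def _measure_value(table: ContactAreaTable, condition: str, itf: str, comp: str):
    """One measure from one subject's table (totals are medial + lateral)."""
    if itf == "cartilage_meniscus":
        return sum(
            _measure_value(table, condition, i, comp)
            for i in ("meniscofemoral", "meniscotibial")
        )
    if comp == "total":
        return table.areas[(condition, itf, "medial")] + table.areas[
            (condition, itf, "lateral")
        ]
    return table.areas[(condition, itf, comp)]


def _matrix(tables, condition, itf, comp):
    return np.array([_measure_value(t, condition, itf, comp) for t in tables])


def change_metrics(
    tables: list[ContactAreaTable], config: StatsConfig | None = None
) -> LoadChangeReport:
    """Descriptive cohort statistics for every measure.

    Per subject: change = loaded - unloaded and percentage change =
    100 * change / unloaded; group values are means and n-1 SDs of the
    per-subject values.  Subjects with a zero unloaded area are excluded
    from that measure's percentage change (and logged), never fabricated.
    """
    config = config or StatsConfig()
    if len(tables) < 2:
        raise ValueError("change metrics need at least 2 subjects")
    rows = []
    excluded = []
    for itf, comp in MEASURES:
        a0 = _matrix(tables, "unloaded", itf, comp)
        a1 = _matrix(tables, "loaded", itf, comp)
        change = a1 - a0
        ok = a0 > 0
        if not ok.all():
            bad = [tables[i].subject for i in np.nonzero(~ok)[0]]
            excluded.append((itf, comp, bad))
            log.warning(
                "zero unloaded area for %s/%s in subjects %s; excluded from "
                "percentage change", itf, comp, bad,
            )
        pct = 100.0 * change[ok] / a0[ok]
        rows.append(
            {
                "interface": itf,
                "compartment": comp,
                "n": len(tables),
                "mean_unloaded": a0.mean(),
                "sd_unloaded": a0.std(ddof=1),
                "mean_loaded": a1.mean(),
                "sd_loaded": a1.std(ddof=1),
                "mean_change": change.mean(),
                "sd_change": change.std(ddof=1),
                "mean_pct_change": pct.mean() if len(pct) else np.nan,
                "sd_pct_change": pct.std(ddof=1) if len(pct) > 1 else np.nan,
            }
        )
    report = LoadChangeReport(
        measures=pd.DataFrame(rows),
        ratios=ml_ratio(tables),
        contrasts=pd.DataFrame(),
        n_subjects=len(tables),
        excluded=excluded,
        config=config,
    )
    return report


def ml_ratio(tables: list[ContactAreaTable]) -> pd.DataFrame:
    """Medial-to-lateral contact-area ratio, averaged over subjects.

    The ratio is formed per subject and then averaged (so two subjects with
    ratios 3.0 and 1.0 report 2.0, not the 1.8 a ratio of group means would
    give).  Subjects with a zero lateral area are excluded and logged.
    """
    rows = []
    for itf in INTERFACES + ("cartilage_meniscus",):
        for cond in CONDITIONS:
            med = _matrix(tables, cond, itf, "medial")
            lat = _matrix(tables, cond, itf, "lateral")
            ok = lat > 0
            if not ok.all():
                log.warning(
                    "zero lateral area for %s (%s); %d subject(s) excluded "
                    "from the M/L ratio", itf, cond, int((~ok).sum()),
                )
            r = med[ok] / lat[ok]
            rows.append(
                {
                    "interface": itf,
                    "condition": cond,
                    "n": int(ok.sum()),
                    "mean_ratio": r.mean() if len(r) else np.nan,
                    "sd_ratio": r.std(ddof=1) if len(r) > 1 else np.nan,
                }
            )
    return pd.DataFrame(rows)


def paired_t(differences: np.ndarray):
    """Two-sided paired t-test from a difference vector (closed form).

    t = mean / (SD / sqrt(n)) with the Student t CDF on n-1 degrees of
    freedom.  A zero-variance difference vector is degenerate: no statistic
    is fabricated (returns NaNs with the degenerate flag set).
    """
    d = np.asarray(differences, float)
    n = len(d)
    sd = d.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        return {"t": np.nan, "p": np.nan, "df": n - 1, "degenerate": True}
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    return {"t": float(t), "p": float(p), "df": n - 1, "degenerate": False}


def paired_tests(
    tables: list[ContactAreaTable], config: StatsConfig | None = None
) -> pd.DataFrame:
    """Normality and paired significance tests for the cohort.

    For every measure: Shapiro-Wilk on the per-subject load differences and
    a paired t-test of loaded vs unloaded; additionally the between-measure
    contrasts (medial vs lateral, meniscofemoral vs meniscotibial) per
    condition, paired within subjects.
    """
    config = config or StatsConfig()
    if len(tables) < 3:
        raise ValueError("paired tests need at least 3 subjects")
    rows = []

    def add_row(name, itf, comp, diffs):
        res = paired_t(diffs)
        if res["degenerate"]:
            sw_w, sw_p = np.nan, np.nan
        else:
            sw_w, sw_p = sps.shapiro(diffs)
        rows.append(
            {
                "test": name,
                "interface": itf,
                "compartment": comp,
                "mean_diff": float(np.mean(diffs)),
                "sd_diff": float(np.std(diffs, ddof=1)),
                "shapiro_W": float(sw_w) if np.isfinite(sw_w) else np.nan,
                "shapiro_p": float(sw_p) if np.isfinite(sw_p) else np.nan,
                "t": res["t"],
                "p": res["p"],
                "df": res["df"],
                "degenerate": res["degenerate"],
                "significant": bool(res["p"] < config.alpha)
                if not res["degenerate"]
                else False,
            }
        )

    for itf, comp in MEASURES:
        a0 = _matrix(tables, "unloaded", itf, comp)
        a1 = _matrix(tables, "loaded", itf, comp)
        add_row("load_change", itf, comp, a1 - a0)
    for itf in INTERFACES + ("cartilage_meniscus",):
        for cond in CONDITIONS:
            med = _matrix(tables, cond, itf, "medial")
            lat = _matrix(tables, cond, itf, "lateral")
            add_row(f"medial_vs_lateral_{cond}", itf, "contrast", med - lat)
    for comp in ("total",) + COMPARTMENTS:
        for cond in CONDITIONS:
            mf = _matrix(tables, cond, "meniscofemoral", comp)
            mt = _matrix(tables, cond, "meniscotibial", comp)
            add_row(f"mf_vs_mt_{cond}", "cartilage_meniscus", comp, mf - mt)
    return pd.DataFrame(rows)


def cohort_report(
    tables: list[ContactAreaTable], config: StatsConfig | None = None
) -> LoadChangeReport:
    """Full report: descriptive metrics, ratios and paired tests."""
    config = config or StatsConfig()
    report = change_metrics(tables, config)
    report.contrasts = paired_tests(tables, config)
    return report
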