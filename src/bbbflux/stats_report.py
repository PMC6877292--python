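"""Group statistics and report generation.

Two-group comparisons follow the normality-gated scheme used for the
in-vivo data: each group is screened with the omnibus (skewness +
kurtosis) normality test; if every group passes at alpha the comparison
is an unpaired two-tailed Welch t-test, otherwise a Mann-Whitney test.
Morphometry (electron-microscopy) tables are log-transformed and compared
with one-way ANOVA followed by Tukey's multiple-comparison test. All
summary errors are SEM (sd/sqrt(n)).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .errors import ConfigError

MIN_N_FOR_NORMALITY = 8  # omnibus test is unreliable below this


@dataclass(frozen=True)
class NormalityGate:
    normal: dict  # group name -> bool
    p_values: dict  # group name -> float or None
    notes: list = field(default_factory=list)

    @property
    def all_normal(self) -> bool:
        return all(self.normal.values())


@dataclass(frozen=True)
class GroupComparisonResult:
    test_name: str  # "welch_t" | "mann_whitney" | "anova_log_tukey"
    statistic: float
    p_value: float
    group_summaries: dict  # group -> {"n", "mean", "sem"}
    normality_p: dict | None = None
    tukey: list | None = None  # pairwise rows for the ANOVA route

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError("p_value outside [0, 1]")

    def to_dict(self) -> dict:
        d = {
            "test_name": self.test_name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "group_summaries": self.group_summaries,
        }
        if self.normality_p is not None:
            d["normality_p"] = self.normality_p
        if self.tukey is not None:
            d["tukey"] = self.tukey
        return d


def _summary(x: np.ndarray) -> dict:
    n = int(x.size)
    sem = float(np.std(x, ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
    return {"n": n, "mean": float(np.mean(x)), "sem": sem}


def normality_gate(samples_per_group: dict, alpha: float = 0.05
                   ) -> NormalityGate:
    """Omnibus normality screen per group.

    Groups with n < 8 or zero variance default to non-normal with a note;
    a group is declared normal iff its omnibus p exceeds alpha.
    """
    normal, pvals, notes = {}, {}, []
    for name, sample in samples_per_group.items():
        x = np.asarray(sample, dtype=float)
        if x.size < MIN_N_FOR_NORMALITY:
            normal[name], pvals[name] = False, None
            notes.append(f"{name}: n={x.size} < {MIN_N_FOR_NORMALITY}, "
                         "gate defaults to non-normal")
            continue
        if np.ptp(x) == 0:
            normal[name], pvals[name] = False, None
            notes.append(f"{name}: constant sample, treated as non-normal")
            continue
        p = float(sps.normaltest(x).pvalue)
        normal[name] = p > alpha
        pvals[name] = p
    return NormalityGate(normal=normal, p_values=pvals, notes=notes)


def compare_two_groups(a, b, alpha: float = 0.05,
                       names: tuple[str, str] = ("a", "b")
                       ) -> GroupComparisonResult:
    """Normality-gated two-tailed comparison of two independent samples."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ConfigError("need n >= 2 per group")
    gate = normality_gate({names[0]: a, names[1]: b}, alpha)
    summaries = {names[0]: _summary(a), names[1]: _summary(b)}
    if gate.all_normal:
        res = sps.ttest_ind(a, b, equal_var=False)
        return GroupComparisonResult(
            "welch_t", float(res.statistic), float(res.pvalue), summaries,
            normality_p=gate.p_values,
        )
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        # total ties: midrank convention, no evidence of difference
        return GroupComparisonResult(
            "mann_whitney", float(a.size * b.size / 2.0), 1.0, summaries,
            normality_p=gate.p_values,
        )
    res = sps.mannwhitneyu(a, b, alternative="two-sided")
    return GroupComparisonResult(
        "mann_whitney", float(res.statistic), float(res.pvalue), summaries,
        normality_p=gate.p_values,
    )


def compare_morphometry(groups: dict, alpha: float = 0.05
                        ) -> GroupComparisonResult:
    """Log-transform one-way ANOVA with Tukey HSD over >= 3 groups.

    All values must be strictly positive (the log applies); a non-positive
    value raises an error naming the offending group and index.
    """
    if len(groups) < 3:
        raise ConfigError("ANOVA route expects >= 3 groups")
    logged = {}
    for name, sample in groups.items():
        x = np.asarray(sample, dtype=float)
        bad = np.nonzero(x <= 0)[0]
        if bad.size:
            raise ConfigError(
                f"group {name!r} has non-positive value at index {bad[0]} "
                f"({x[bad[0]]}); log-transform requires positive data"
            )
        logged[name] = np.log(x)
    names = sorted(logged)
    f, p = sps.f_oneway(*(logged[n] for n in names))
    values = np.concatenate([logged[n] for n in names])
    labels = np.concatenate([[n] * logged[n].size for n in names])
    tk = pairwise_tukeyhsd(values, labels, alpha=alpha)
    tukey_rows = [
        {
            "group1": str(r[0]),
            "group2": str(r[1]),
            "p_adj": float(r[3]),
            "reject": bool(r[6]),
        }
        for r in tk.summary().data[1:]
    ]
    summaries = {n: _summary(np.asarray(groups[n], dtype=float)) for n in names}
    return GroupComparisonResult(
        "anova_log_tukey", float(f), float(p), summaries, tukey=tukey_rows
    )


def percent_difference(mean_test: float, mean_ref: float) -> float:
    """100 * (mean_test - mean_ref) / mean_ref."""
    if mean_ref <= 0:
        raise ConfigError("reference mean must be > 0")
    return 100.0 * (mean_test - mean_ref) / mean_ref


def fold_ratio(mean_a: float, mean_b: float) -> float:
    """mean_a / mean_b."""
    if mean_b <= 0:
        raise ConfigError("denominator mean must be > 0")
    return mean_a / mean_b


# ---------------------------------------------------------------------------
# Report bundle


def render_report(
    permeability_by_group: dict | None = None,
    density_records_by_group: dict | None = None,
    comparisons: dict | None = None,
) -> dict:
    """Assemble a deterministic machine-readable summary.

    ``permeability_by_group`` maps group -> {tracer -> list of AUC values};
    ``density_records_by_group`` maps group -> list of
    :class:`~bbbflux.transcytosis.VesicleDensityRecord`; ``comparisons``
    maps label -> :class:`GroupComparisonResult`. Any subset may be given;
    keys are emitted in sorted order so re-rendering identical inputs is
    byte-identical.
    """
    from .transcytosis import category_aggregate

    report: dict = {"auc": {}, "vesicle_density": {}, "comparisons": {}}
    for group in sorted(permeability_by_group or {}):
        report["auc"][group] = {}
        for tracer in sorted(permeability_by_group[group]):
            vals = np.asarray(permeability_by_group[group][tracer], dtype=float)
            report["auc"][group][tracer] = _summary(vals) if vals.size else {}
    for group in sorted(density_records_by_group or {}):
        agg = category_aggregate(density_records_by_group[group])
        report["vesicle_density"][group] = [
            {
                "category": row["category"],
                "time_min": float(row["time_min"]),
                "n_vessels": int(row["n_vessels"]),
                "mean": float(row["mean"]),
                "sem": float(row["sem"]) if np.isfinite(row["sem"]) else None,
            }
            for _, row in agg.sort_values(["category", "time_min"]).iterrows()
        ]
    for label in sorted(comparisons or {}):
        report["comparisons"][label] = comparisons[label].to_dict()
    return report


def write_report(report: dict, out_dir) -> None:
    """Write report.json plus CSV tables for AUC and density summaries."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, allow_nan=True)
    )
    auc_rows = [
        {"group": g, "tracer": t, **summ}
        for g, by_tracer in report.get("auc", {}).items()
        for t, summ in by_tracer.items()
        if summ
    ]
    pd.DataFrame(auc_rows).to_csv(out / "auc_summary.csv", index=False)
    dens_rows = [
        {"group": g, **row}
        for g, rows in report.get("vesicle_density", {}).items()
        for row in rows
    ]
    pd.DataFrame(dens_rows).to_csv(out / "density_summary.csv", index=False)
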