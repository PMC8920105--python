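"""Cohort-level statistics: outlier classification, group comparisons,
correlations, and the end-to-end report pipeline.

Patients are classified per PK parameter as inside or outside the
mean +/- 1.96 SD band of the cohort's own empirical normal fit; the two
groups are then compared on demographics and anticoagulation indices
(Mann-Whitney U for numeric variables, Pearson chi-square for
categorical), and Pearson correlations are computed among PK parameters
and against predicted liver weight. No multiple-testing correction is
applied to the primary p-values; a Holm-adjusted column is emitted
alongside for transparency.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import PipelineError
from .estimation import PopulationPrior, fit_cohort
from .metrics import compute_indices
from .simulate import GeneratorConfig, generate_cohort, score_recovery

logger = logging.getLogger(__name__)

__all__ = [
    "OutlierClassification",
    "classify_outliers",
    "compare_groups",
    "correlations",
    "DEFAULT_CORRELATION_PAIRS",
    "run_pipeline",
]

# the study's correlation set: C_max against the other PK parameters,
# and CL / V_d against predicted liver weight
DEFAULT_CORRELATION_PAIRS = (
    ("c_max", "cl"),
    ("c_max", "v_d"),
    ("c_max", "k"),
    ("cl", "liver_weight"),
    ("v_d", "liver_weight"),
)

DEFAULT_AGE_BINS = (65.0, 75.0, 85.0)  # <65 / 65-74 / 75-84 / >=85


@dataclass
class OutlierClassification:
    """Per-patient inside/outside flags for one parameter's normal band."""

    parameter: str
    flags: np.ndarray  # "within" / "outside" per patient
    lower: float
    upper: float
    n_within: int
    n_outside: int


def classify_outliers(
    values: Sequence[float],
    z: float = 1.96,
    sided: Literal["two", "lower", "upper"] = "two",
    parameter: str = "",
) -> OutlierClassification:
    """Flag values outside the empirical mean +/- z*SD band.

    ``sided="two"`` (default) flags both tails; ``"lower"``/``"upper"``
    flag only one tail (the opposite boundary becomes infinite). The
    band is computed from the same values being classified. Under a
    normal generator with z=1.96 the expected two-sided outside fraction
    is 2*(1 - Phi(1.96)) ~ 5 %.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3 or not np.all(np.isfinite(x)):
        raise ValueError("classify_outliers needs >= 3 finite values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero SD: outlier band undefined")
    mean = x.mean()
    lower = mean - z * sd if sided in ("two", "lower") else -np.inf
    upper = mean + z * sd if sided in ("two", "upper") else np.inf
    outside = (x < lower) | (x > upper)
    flags = np.where(outside, "outside", "within")
    return OutlierClassification(
        parameter=parameter,
        flags=flags,
        lower=float(lower),
        upper=float(upper),
        n_within=int((~outside).sum()),
        n_outside=int(outside.sum()),
    )


def compare_groups(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    numeric_vars: Sequence[str] = (),
    categorical_vars: Sequence[str] = (),
) -> pd.DataFrame:
    """Two-group comparison table.

    Numeric variables: two-sided Mann-Whitney U p-value plus group
    means (SD). Categorical variables: Pearson chi-square (no continuity
    correction) on the contingency table plus group counts. A numeric
    variable with fewer than two finite observations in either group is
    skipped with a warning. Returns columns: variable, kind, mean_a,
    sd_a, mean_b, sd_b, statistic, p_value, p_holm.
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be non-empty")
    rows = []
    for var in numeric_vars:
        a = group_a[var].dropna().to_numpy(dtype=float)
        b = group_b[var].dropna().to_numpy(dtype=float)
        if a.size < 2 or b.size < 2:
            logger.warning("compare_groups: skipping %r (<2 observations in a group)", var)
            continue
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        rows.append(
            {"variable": var, "kind": "numeric",
             "mean_a": a.mean(), "sd_a": a.std(ddof=1),
             "mean_b": b.mean(), "sd_b": b.std(ddof=1),
             "statistic": float(stat), "p_value": float(p)}
        )
    for var in categorical_vars:
        a = group_a[var].dropna()
        b = group_b[var].dropna()
        levels = sorted(set(a) | set(b))
        table = np.array(
            [[int((a == lv).sum()) for lv in levels],
             [int((b == lv).sum()) for lv in levels]]
        )
        if table.shape[1] < 2 or np.any(table.sum(axis=0) == 0):
            logger.warning("compare_groups: skipping %r (degenerate contingency table)", var)
            continue
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        rows.append(
            {"variable": var, "kind": "categorical",
             "mean_a": float(a.mean()) if a.dtype != object else np.nan,
             "sd_a": np.nan,
             "mean_b": float(b.mean()) if b.dtype != object else np.nan,
             "sd_b": np.nan,
             "statistic": float(chi2), "p_value": float(p)}
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["p_holm"] = multipletests(df["p_value"], method="holm")[1]
    return df


def correlations(
    table: pd.DataFrame,
    pairs: Sequence[tuple[str, str]] = DEFAULT_CORRELATION_PAIRS,
) -> pd.DataFrame:
    """Pearson r with two-sided p for each requested column pair."""
    rows = []
    for x_name, y_name in pairs:
        sub = table[[x_name, y_name]].dropna()
        if len(sub) < 3:
            raise ValueError(f"correlation {x_name}~{y_name}: need >= 3 paired values")
        x = sub[x_name].to_numpy(dtype=float)
        y = sub[y_name].to_numpy(dtype=float)
        if x.std() == 0 or y.std() == 0:
            raise ValueError(f"correlation {x_name}~{y_name}: constant vector, r undefined")
        r, p = stats.pearsonr(x, y)
        rows.append({"var_x": x_name, "var_y": y_name,
                     "r": float(r), "p_value": float(p), "n": len(sub)})
    return pd.DataFrame(rows)


def _age_group(age: float, bins=DEFAULT_AGE_BINS) -> str:
    labels = ("<65", "65-74", "75-84", ">=85")
    for bound, label in zip(bins, labels):
        if age < bound:
            return label
    return labels[-1]


_FLOAT_FORMAT = "%.6f"  # fixed decimal format so report bundles are byte-stable


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FORMAT)


def _jsonable(df: pd.DataFrame):
    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].round(6)
    return json.loads(out.to_json(orient="records"))


def run_pipeline(
    config,
    outdir: str | Path,
    patients=None,
    truth: pd.DataFrame | None = None,
) -> dict:
    """End-to-end cohort analysis: simulate (or accept) -> fit -> indices
    -> outlier classification -> group comparisons -> correlations.

    ``config`` is a :class:`~warfarin_pkpd.config.PipelineConfig`. When
    ``patients`` is None a synthetic cohort is generated from
    ``config.generator``. Writes the report bundle (summary.tsv,
    outliers_<param>.tsv, comparisons.tsv, correlations.tsv,
    report.json) under ``outdir`` and returns the report dict.
    Deterministic given the generator seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    try:
        if patients is None:
            patients, truth = generate_cohort(config.generator)
    except Exception as exc:
        raise PipelineError(f"[simulate] {exc}") from exc

    try:
        fitted = fit_cohort(
            patients, config.prior, m=config.model.m, consts=config.model.pd_constants,
            last_n=config.estimation.last_n, multistart=config.estimation.multistart,
        )
    except Exception as exc:
        raise PipelineError(f"[fit] {exc}") from exc

    try:
        indices = compute_indices(
            patients,
            low=config.metrics.range_low, high=config.metrics.range_high,
            max_gap_days=config.metrics.max_gap_days,
            wcm_convention=config.metrics.wcm_convention,
        )
    except Exception as exc:
        raise PipelineError(f"[metrics] {exc}") from exc

    demo = pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in patients],
            "age": [p.age for p in patients],
            "body_weight": [p.body_weight for p in patients],
            "sex": [p.sex for p in patients],
            "interacting_drug": [int(p.interacting_drug) for p in patients],
        }
    )
    merged = demo.merge(fitted, on="patient_id").merge(indices, on="patient_id")

    try:
        # cohort summary: mean/SD of each PK parameter and PD index
        summary_vars = ["c_max", "k", "cl", "v_d", "age", "body_weight",
                        "wsi", "ttr", "log_inr_var", "wcm", "liver_weight"]
        summary = pd.DataFrame(
            {
                "variable": summary_vars,
                "mean": [merged[v].mean() for v in summary_vars],
                "sd": [merged[v].std(ddof=1) for v in summary_vars],
                "n": [int(merged[v].notna().sum()) for v in summary_vars],
            }
        )
        age_counts = merged["age"].map(_age_group).value_counts()
        age_table = pd.DataFrame(
            {"age_group": ["<65", "65-74", "75-84", ">=85"]}
        )
        age_table["n"] = [int(age_counts.get(g, 0)) for g in age_table["age_group"]]

        comparison_frames = []
        outlier_tables = {}
        for param in ("c_max", "k", "cl", "v_d"):
            cls = classify_outliers(
                merged[param], z=config.analysis.z, sided=config.analysis.sided,
                parameter=param,
            )
            out_df = pd.DataFrame(
                {"patient_id": merged["patient_id"], "value": merged[param],
                 "flag": cls.flags}
            )
            outlier_tables[param] = (cls, out_df)
            within = merged[cls.flags == "within"]
            outside = merged[cls.flags == "outside"]
            if len(outside) >= 2:
                comp = compare_groups(
                    within, outside,
                    numeric_vars=("age", "body_weight", "ttr", "wsi",
                                  "log_inr_var", "wcm"),
                    categorical_vars=("interacting_drug",),
                )
                comp.insert(0, "parameter", param)
                comp.insert(1, "n_within", cls.n_within)
                comp.insert(2, "n_outside", cls.n_outside)
                comparison_frames.append(comp)
            else:
                logger.info(
                    "pipeline: %s has %d outlier(s); too few for group comparison",
                    param, len(outside),
                )
        comparisons = (
            pd.concat(comparison_frames, ignore_index=True)
            if comparison_frames else pd.DataFrame()
        )
        corr = correlations(merged, DEFAULT_CORRELATION_PAIRS)
    except (ValueError, KeyError) as exc:
        raise PipelineError(f"[analysis] {exc}") from exc

    try:
        _write_tsv(summary, outdir / "summary.tsv")
        _write_tsv(comparisons, outdir / "comparisons.tsv")
        _write_tsv(corr, outdir / "correlations.tsv")
        _write_tsv(fitted, outdir / "parameters.tsv")
        _write_tsv(indices, outdir / "indices.tsv")
        _write_tsv(age_table, outdir / "age_groups.tsv")
        for param, (cls, out_df) in outlier_tables.items():
            _write_tsv(out_df, outdir / f"outliers_{param}.tsv")
        if truth is not None:
            _write_tsv(truth, outdir / "truth.tsv")
            _write_tsv(score_recovery(truth, fitted), outdir / "recovery.tsv")

        report = {
            "config": config.to_dict(),
            "n_patients": len(patients),
            "summary": _jsonable(summary),
            "age_groups": _jsonable(age_table),
            "outliers": {
                param: {
                    "lower": round(cls.lower, 6), "upper": round(cls.upper, 6),
                    "n_within": cls.n_within, "n_outside": cls.n_outside,
                }
                for param, (cls, _) in outlier_tables.items()
            },
            "comparisons": _jsonable(comparisons),
            "correlations": _jsonable(corr),
        }
        if truth is not None:
            report["recovery"] = _jsonable(score_recovery(truth, fitted))
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
    except OSError as exc:
        raise PipelineError(f"[write] {exc}") from exc

    return report
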