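"""Multicenter screening-study pipeline.

Takes a patient-record table (one endoscopy per row), applies the
bowel-preparation exclusion rules, and produces per-cohort biofilm
prevalences, odds ratios versus healthy controls (crude and
center-adjusted), the anatomical distribution of biofilms, and the
endoscopic-versus-microscopic concordance report.

Expected record columns: patient_id, center, cohort, bbps, prep_type,
cecum_reached, biofilm_status ('BF+'/'BF-'), biofilm_locations
(';'-separated, empty for BF−) and optionally microscopic_biofilm and
bloom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats as bstats

__all__ = [
    "ExclusionRules",
    "apply_exclusions",
    "prevalence_table",
    "or_report",
    "location_distribution",
    "concordance_report",
    "records_from_counts",
    "round_half_away",
]


@dataclass(frozen=True)
class ExclusionRules:
    """Screening exclusions: insufficient prep, non-PEG prep, cecum missed."""

    min_bbps: int = 6
    require_peg: bool = True
    require_cecum: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.min_bbps <= 9:
            raise ValueError("min_bbps must be in 0..9")


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def apply_exclusions(records: pd.DataFrame,
                     rules: ExclusionRules = ExclusionRules()
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split records into kept and excluded, with a per-record reason log.

    A record is kept iff its bowel-prep score meets ``min_bbps`` AND the
    prep was PEG-based AND the cecum was reached. The log records the first
    failing rule, evaluated in that fixed order (bbps, prep, cecum).
    """
    df = records.reset_index(drop=True)
    reason = pd.Series([""] * len(df), dtype=object)
    bad_bbps = df["bbps"].astype(int) < rules.min_bbps
    bad_prep = (df["prep_type"] != "PEG") if rules.require_peg \
        else pd.Series(False, index=df.index)
    bad_cecum = ~df["cecum_reached"].astype(bool) if rules.require_cecum \
        else pd.Series(False, index=df.index)
    reason[bad_cecum] = "cecum"
    reason[bad_prep] = "prep"
    reason[bad_bbps] = "bbps"  # bbps evaluated first, wins on overlap
    excluded = reason != ""
    log = pd.DataFrame({
        "patient_id": df.loc[excluded, "patient_id"],
        "reason": reason[excluded],
    }).reset_index(drop=True)
    return df[~excluded].reset_index(drop=True), log


def _bf_pos(df: pd.DataFrame) -> pd.Series:
    return df["biofilm_status"] == "BF+"


def records_from_counts(counts: dict[str, dict[str, tuple[int, int]]]
                        ) -> pd.DataFrame:
    """Expand published (positive, total) counts into individual records.

    ``counts`` maps cohort -> center -> (biofilm-positive, total). The
    expansion lets table-level summary data from a report flow through the
    same record-level pipeline as raw data. All records are marked as
    passing the exclusion rules (published counts are post-exclusion).
    """
    rows = []
    pid = 0
    for cohort, centers in counts.items():
        for center, (pos, total) in centers.items():
            if not 0 <= pos <= total:
                raise ValueError(f"{cohort}/{center}: need 0 <= pos <= total")
            for k in range(total):
                pid += 1
                rows.append({
                    "patient_id": f"T{pid:05d}",
                    "center": center,
                    "cohort": cohort,
                    "bbps": 9,
                    "prep_type": "PEG",
                    "cecum_reached": True,
                    "biofilm_status": "BF+" if k < pos else "BF-",
                    "biofilm_locations": "",
                })
    return pd.DataFrame(rows)


def prevalence_table(records: pd.DataFrame,
                     by_center: bool = True) -> pd.DataFrame:
    """Per-cohort biofilm prevalence with a 'Total' row.

    Percent is rounded to the nearest integer, halves away from zero, and
    is NaN for an empty cohort. With ``by_center`` the per-center counts
    and percents are appended as extra columns.
    """
    df = records.copy()
    df["_pos"] = _bf_pos(df)

    def _summarise(sub: pd.DataFrame) -> dict:
        pos, tot = int(sub["_pos"].sum()), len(sub)
        pct = round_half_away(100.0 * pos / tot) if tot else float("nan")
        return {"bf_pos": pos, "total": tot, "percent": pct}

    cohorts = list(dict.fromkeys(df["cohort"]))
    rows = {}
    for cohort in cohorts:
        sub = df[df["cohort"] == cohort]
        row = _summarise(sub)
        if by_center:
            for center in sorted(df["center"].unique()):
                for k, v in _summarise(sub[sub["center"] == center]).items():
                    row[f"{k}_{center}"] = v
        rows[cohort] = row
    total_row = _summarise(df)
    if by_center:
        for center in sorted(df["center"].unique()):
            for k, v in _summarise(df[df["center"] == center]).items():
                total_row[f"{k}_{center}"] = v
    rows["Total"] = total_row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "cohort"
    return out


def or_report(records: pd.DataFrame,
              reference_cohort: str = "healthy-control",
              adjust_for_center: bool = False,
              mode: str = "joint",
              ci_level: float = 0.95) -> pd.DataFrame:
    """Per-cohort odds ratio of biofilm positivity versus a reference cohort.

    Crude mode computes the sample odds ratio from each cohort's 2×2 table
    against the reference. With ``adjust_for_center`` a grouped logistic
    regression with a center covariate is fitted instead — jointly over all
    cohorts (``mode='joint'``) or one cohort-vs-reference fit at a time
    (``mode='pairwise'``). ORs are additionally reported rounded to one
    decimal.
    """
    df = records.copy()
    df["_pos"] = _bf_pos(df)
    ref = df[df["cohort"] == reference_cohort]
    if len(ref) == 0 or ref["_pos"].nunique() < 2:
        raise ValueError(
            f"reference cohort {reference_cohort!r} must be nonempty with "
            "both outcomes")
    cohorts = [c for c in dict.fromkeys(df["cohort"]) if c != reference_cohort]

    rows = []
    if not adjust_for_center:
        for cohort in cohorts:
            sub = df[df["cohort"] == cohort]
            t = bstats.Contingency2x2(
                int(sub["_pos"].sum()), int((~sub["_pos"]).sum()),
                int(ref["_pos"].sum()), int((~ref["_pos"]).sum()))
            r = bstats.odds_ratio_2x2(t, ci_level)
            rows.append({"cohort": cohort, "odds_ratio": r.odds_ratio,
                         "or_rounded": round(r.odds_ratio, 1),
                         "ci_low": r.ci_low, "ci_high": r.ci_high,
                         "method": "crude"})
        return pd.DataFrame(rows)

    def _grouped(sub: pd.DataFrame, cohort_list: list[str]):
        g = (sub.groupby(["cohort", "center"], observed=True)
             .agg(successes=("_pos", "sum"), totals=("_pos", "size"))
             .reset_index())
        centers = sorted(sub["center"].unique())
        cols = [np.ones(len(g))]
        for c in cohort_list:
            cols.append((g["cohort"] == c).astype(float).to_numpy())
        for ctr in centers[1:]:
            cols.append((g["center"] == ctr).astype(float).to_numpy())
        X = np.column_stack(cols)
        return X, g["successes"].to_numpy(), g["totals"].to_numpy()

    if mode == "joint":
        X, s, n = _grouped(df, cohorts)
        fit = bstats.fit_grouped_logistic(X, s, n, ci_level)
        for k, cohort in enumerate(cohorts, start=1):
            rows.append({"cohort": cohort,
                         "odds_ratio": fit.odds_ratios[k],
                         "or_rounded": round(fit.odds_ratios[k], 1),
                         "ci_low": fit.ci_low[k], "ci_high": fit.ci_high[k],
                         "method": "adjusted (joint)"})
    elif mode == "pairwise":
        for cohort in cohorts:
            sub = df[df["cohort"].isin([cohort, reference_cohort])]
            X, s, n = _grouped(sub, [cohort])
            fit = bstats.fit_grouped_logistic(X, s, n, ci_level)
            rows.append({"cohort": cohort,
                         "odds_ratio": fit.odds_ratios[1],
                         "or_rounded": round(fit.odds_ratios[1], 1),
                         "ci_low": fit.ci_low[1], "ci_high": fit.ci_high[1],
                         "method": "adjusted (pairwise)"})
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return pd.DataFrame(rows)


def location_distribution(records: pd.DataFrame,
                          denominator: str = "patients") -> pd.Series:
    """Percent of biofilm-positive patients with a biofilm in each segment.

    Locations are multi-label, so percents need not sum to 100. With
    ``denominator='biofilms'`` the share of all reported biofilm locations
    is returned instead.
    """
    pos = records[_bf_pos(records)]
    if len(pos) == 0:
        return pd.Series(dtype=float, name="percent")
    loc_lists = (pos["biofilm_locations"].fillna("").astype(str)
                 .apply(lambda s: [t for t in s.split(";") if t]))
    counts: dict[str, int] = {}
    n_biofilms = 0
    for locs in loc_lists:
        n_biofilms += len(locs)
        for seg in set(locs):
            counts[seg] = counts.get(seg, 0) + 1
    denom = len(pos) if denominator == "patients" else n_biofilms
    ser = pd.Series({seg: 100.0 * c / denom for seg, c in counts.items()},
                    name="percent")
    return ser.sort_values(ascending=False)


def concordance_report(records: pd.DataFrame) -> dict:
    """Endoscopic-vs-microscopic concordance (microscopic as reference).

    Records missing either status are skipped and counted in
    ``n_skipped``. Returns the 2×2 cells plus accuracy, sensitivity and
    specificity of the endoscopic call against the microscopic criterion.
    """
    df = records.copy()
    ok = df["biofilm_status"].isin(["BF+", "BF-"]) \
        & df["microscopic_biofilm"].notna()
    skipped = int((~ok).sum())
    df = df[ok]
    endo = _bf_pos(df)
    micro = df["microscopic_biofilm"].astype(bool)
    tp = int((endo & micro).sum())
    fp = int((endo & ~micro).sum())
    fn = int((~endo & micro).sum())
    tn = int((~endo & ~micro).sum())
    out = {"tp": tp, "fn": fn, "fp": fp, "tn": tn, "n_skipped": skipped}
    out.update(bstats.confusion_metrics(tp, fn, fp, tn))
    return out
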