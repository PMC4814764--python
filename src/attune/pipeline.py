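"""End-to-end per-child and cohort analysis, report assembly, and exports.

``analyze_child`` runs the full chain for one child: rasterize both
streams onto a shared 1 Hz grid, map to tiers, build the CRP, compute
global, sensorimotor-tier and representational-tier measures with their
asymmetry scores, then the LOS profile with its measures and the RR_peak
permutation test. ``analyze_cohort`` aggregates rows into group
comparisons (permutation tests + Cohen's d) and a covariate correlation
table, and writes the CSV/JSON reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import los as los_mod
from . import recurrence as rec
from . import stats
from .events import (
    ChildMeta,
    CodedEvent,
    rasterize_child,
    read_events,
    read_metadata,
    series_frame,
    to_tiers,
)

logger = logging.getLogger("attune")

TIER_LABELS = {1: "S", 2: "R"}

COVARIATES = ["age_months", "math_score", "language_score", "avg_past_score"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Settings of one analysis run; defaults follow the reference protocol
    (60 s LOS window, minimum line length 2, 1000 permutations)."""

    window_s: int = 60
    min_line: int = 2
    n_perm: int = 1000
    seed: int = 0
    sidedness: str = "greater"
    rr_peak_null: str = "episode_shuffle"
    alpha_tau_exclude: float = 0.05
    out_dir: str | None = None

    @staticmethod
    def from_yaml(path: str | Path) -> "AnalysisConfig":
        with Path(path).open(encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return AnalysisConfig(**data)


@dataclass
class ChildResult:
    """Everything computed for one child."""

    child_id: str
    row: dict
    crp: rec.CrossRecurrencePlot | None = None
    profile: los_mod.LosProfile | None = None
    series: pd.DataFrame | None = None


def _measure_dict(m, prefix: str = "") -> dict:
    d = dataclasses.asdict(m)
    d.pop("tier", None)
    return {f"{prefix}{k}": v for k, v in d.items()}


def analyze_child(
    events: Sequence[CodedEvent],
    config: AnalysisConfig = AnalysisConfig(),
    child_id: str = "",
) -> ChildResult:
    """Run the full per-child analysis chain.

    With one stream empty the row is emitted with NaN analysis fields and
    a warning is logged. tau_peak is reported missing when the RR_peak
    permutation test is not significant at ``alpha_tau_exclude``.
    """
    streams_present = {e.stream for e in events}
    row: dict = {"child_id": child_id}
    if streams_present != {"gesture", "speech"}:
        logger.warning(
            "child %s: missing stream(s) %s; emitting empty row",
            child_id,
            sorted({"gesture", "speech"} - streams_present),
        )
        return ChildResult(child_id=child_id, row=row)

    gesture, speech = rasterize_child(events, child_id=child_id)
    g_tiers, s_tiers = to_tiers(gesture), to_tiers(speech)
    crp = rec.build_crp(g_tiers, s_tiers)
    logger.info("child %s: %d s, %d recurrent points", child_id, len(gesture), crp.n_recurrent())

    gm = rec.global_measures(crp, min_line=config.min_line)
    row.update(duration_s=len(gesture), **_measure_dict(gm))
    row.update(dataclasses.asdict(rec.asymmetry(gm)))

    for tier, label in TIER_LABELS.items():
        tm = rec.tier_measures(crp, tier, min_line=config.min_line)
        row.update(_measure_dict(tm, prefix=f"{label}_"))
        asym = rec.asymmetry(tm)
        row.update(
            {
                f"{label}_vh_lam": asym.vh_lam,
                f"{label}_vh_tt": asym.vh_tt,
                f"{label}_vh_maxl": asym.vh_maxl,
            }
        )

    window = min(config.window_s, len(gesture) - 1)
    if window < config.window_s:
        logger.warning(
            "child %s: series length %d too short for +/-%d s window; using +/-%d s",
            child_id,
            len(gesture),
            config.window_s,
            window,
        )
    profile = los_mod.compute_profile(crp, window_s=window)
    lm = los_mod.los_measures(profile)
    p = los_mod.rr_peak_significance(
        g_tiers,
        s_tiers,
        window_s=window,
        n_perm=config.n_perm,
        seed=config.seed,
        null=config.rr_peak_null,
    )
    tau = lm.tau_peak if p < config.alpha_tau_exclude else float("nan")
    if not math.isnan(lm.tau_peak) and math.isnan(tau):
        logger.info("child %s: RR_peak p=%.3f >= %.2f; tau_peak excluded", child_id, p, config.alpha_tau_exclude)
    row.update(
        pct_sync=lm.pct_sync,
        rr_peak=lm.rr_peak,
        tau_peak=tau,
        q_los=lm.q_los,
        rr_peak_p=p,
    )
    return ChildResult(
        child_id=child_id,
        row=row,
        crp=crp,
        profile=profile,
        series=series_frame(gesture, speech),
    )


@dataclass
class CohortReport:
    per_child: pd.DataFrame
    tier_s: pd.DataFrame
    tier_r: pd.DataFrame
    group_stats: list[dict]
    correlations: pd.DataFrame
    config: AnalysisConfig


def _grade_groups(df: pd.DataFrame, col: str) -> tuple[np.ndarray, np.ndarray]:
    kg = df.loc[df["grade"] == "KG", col].to_numpy(dtype=float)
    g1 = df.loc[df["grade"] == "1", col].to_numpy(dtype=float)
    return kg, g1


def _stat_entry(name: str, res: stats.PermTestResult, d: float | None = None) -> dict:
    entry = {
        "comparison": name,
        "observed": res.observed,
        "p": res.p_value,
        "n_perm": res.n_perm,
        "sided": res.sided,
    }
    if d is not None:
        entry["d"] = d
    return entry


def group_statistics(per_child: pd.DataFrame, config: AnalysisConfig) -> list[dict]:
    """Permutation comparisons over the per-child table.

    Mirrors the reference protocol: Q_LOS vs 1 and tau_peak vs 0,
    grade contrasts on Q_LOS and tau_peak, paired vertical-vs-horizontal
    contrasts of LAM/TT/MaxL (with Cohen's d), tier S vs R contrasts of
    every tier measure and asymmetry score. Requires >= 2 children per
    grade for group contrasts; otherwise those are skipped with a warning.
    """
    out: list[dict] = []
    seed = config.seed
    n_perm = config.n_perm

    def _seeded():
        nonlocal seed
        seed += 1
        return seed

    q = per_child["q_los"].to_numpy(dtype=float)
    tau = per_child["tau_peak"].to_numpy(dtype=float)
    out.append(
        _stat_entry(
            "q_los_vs_1",
            stats.perm_test_vs_value(q, 1.0, "greater", n_perm, _seeded()),
        )
    )
    out.append(
        _stat_entry(
            "tau_peak_vs_0",
            stats.perm_test_vs_value(tau, 0.0, "greater", n_perm, _seeded()),
        )
    )

    counts = per_child["grade"].value_counts()
    if counts.get("KG", 0) >= 2 and counts.get("1", 0) >= 2:
        for col in ("q_los", "tau_peak"):
            kg, g1 = _grade_groups(per_child, col)
            res = stats.perm_test_two_groups(g1, kg, "two", n_perm, _seeded())
            kg_c, g1_c = kg[~np.isnan(kg)], g1[~np.isnan(g1)]
            d = stats.cohens_d(g1_c, kg_c).d if min(kg_c.size, g1_c.size) >= 2 else float("nan")
            out.append(_stat_entry(f"{col}_grade1_vs_kg", res, d))
    else:
        logger.warning("fewer than 2 children in a grade; grade contrasts skipped")

    for base in ("lam", "tt", "maxl"):
        v = per_child[f"{base}_v"].to_numpy(dtype=float)
        h = per_child[f"{base}_h"].to_numpy(dtype=float)
        res = stats.perm_test_paired(v, h, "greater", n_perm, _seeded())
        out.append(_stat_entry(f"{base}_v_vs_h_paired", res, stats.cohens_d(v, h).d))

    for col in ("pct_rr", "lam_v", "lam_h", "tt_v", "tt_h", "maxl_v", "maxl_h",
                "vh_lam", "vh_tt", "vh_maxl"):
        s = per_child[f"S_{col}"].to_numpy(dtype=float)
        r = per_child[f"R_{col}"].to_numpy(dtype=float)
        res = stats.perm_test_paired(s, r, "two", n_perm, _seeded())
        out.append(_stat_entry(f"tier_S_vs_R_{col}", res, stats.cohens_d(s, r).d))
    return out


MEASURES_FOR_CORRELATION = [
    "pct_sync", "rr_peak", "q_los", "tau_peak",
    "S_pct_rr", "S_lam_v", "S_lam_h", "S_tt_v", "S_tt_h", "S_maxl_v", "S_maxl_h",
    "S_vh_lam", "S_vh_tt", "S_vh_maxl",
    "R_pct_rr", "R_lam_v", "R_lam_h", "R_tt_v", "R_tt_h", "R_maxl_v", "R_maxl_h",
    "R_vh_lam", "R_vh_tt", "R_vh_maxl",
]


def correlation_table(
    per_child: pd.DataFrame, meta: dict[str, ChildMeta], config: AnalysisConfig
) -> pd.DataFrame:
    """Covariate x measure permutation-correlation table (long format)."""
    rows = []
    seed = config.seed + 10_000
    merged = per_child.copy()
    for cov in COVARIATES:
        merged[cov] = [
            getattr(meta[cid], cov) if cid in meta else float("nan")
            for cid in merged["child_id"]
        ]
        missing = [cid for cid in merged["child_id"] if cid not in meta]
        if missing and cov == COVARIATES[0]:
            logger.warning("children missing metadata dropped from correlations: %s", missing)
    for cov in COVARIATES:
        x = merged[cov].astype(float)
        for measure in MEASURES_FOR_CORRELATION:
            if measure not in merged.columns:
                continue
            y = merged[measure].astype(float)
            keep = ~(x.isna() | y.isna())
            seed += 1
            if keep.sum() < 3 or x[keep].nunique() < 2 or y[keep].nunique() < 2:
                rows.append({"covariate": cov, "measure": measure, "r": float("nan"),
                             "n": int(keep.sum()), "p": float("nan"), "stars": ""})
                continue
            res = stats.correlate(x.to_numpy(), y.to_numpy(), n_perm=config.n_perm, seed=seed)
            rows.append({"covariate": cov, "measure": measure, "r": res.r,
                         "n": res.n, "p": res.p_value, "stars": res.stars})
    return pd.DataFrame(rows)


def analyze_cohort(
    events_by_child: dict[str, list[CodedEvent]],
    meta: dict[str, ChildMeta],
    config: AnalysisConfig = AnalysisConfig(),
) -> CohortReport:
    """Analyze every child and aggregate group statistics and correlations."""
    results: list[ChildResult] = []
    for child_id in sorted(events_by_child):
        cfg = dataclasses.replace(config, seed=config.seed + _child_seed_offset(child_id))
        results.append(analyze_child(events_by_child[child_id], cfg, child_id=child_id))

    rows = [r.row for r in results if "rr" in r.row]
    per_child = pd.DataFrame(rows)
    per_child.insert(
        1, "grade", [meta[c].grade if c in meta else "" for c in per_child["child_id"]]
    )

    group_stats = group_statistics(per_child, config)
    correlations = correlation_table(per_child, meta, config)
    tier_s = _tier_table(per_child, "S")
    tier_r = _tier_table(per_child, "R")
    report = CohortReport(
        per_child=per_child,
        tier_s=tier_s,
        tier_r=tier_r,
        group_stats=group_stats,
        correlations=correlations,
        config=config,
    )
    report._results = results  # noqa: SLF001 - kept for export
    return report


def _child_seed_offset(child_id: str) -> int:
    return sum(ord(c) for c in child_id) % 9973


def _tier_table(per_child: pd.DataFrame, label: str) -> pd.DataFrame:
    cols = ["child_id", "grade"] + [c for c in per_child.columns if c.startswith(f"{label}_")]
    df = per_child[cols].copy()
    df.columns = [c.removeprefix(f"{label}_") for c in df.columns]
    return _with_mean_rows(df)


def _with_mean_rows(df: pd.DataFrame) -> pd.DataFrame:
    """Append KG / grade-1 / overall mean rows, recomputed from the child rows."""
    numeric = df.select_dtypes(include=[np.number]).columns
    means = []
    for label, sub in (
        ("M_KG", df[df["grade"] == "KG"]),
        ("M_1", df[df["grade"] == "1"]),
        ("M_overall", df),
    ):
        if len(sub) == 0:
            continue
        row = {c: sub[c].mean() for c in numeric}
        row["child_id"] = label
        row["grade"] = ""
        means.append(row)
    return pd.concat([df, pd.DataFrame(means)], ignore_index=True)


def write_report(report: CohortReport, out_dir: str | Path) -> None:
    """Write per-child/tier CSVs, stats JSON, correlations, profiles and CRPs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _with_mean_rows(report.per_child).to_csv(out_dir / "per_child.csv", index=False)
    report.tier_s.to_csv(out_dir / "tier_S.csv", index=False)
    report.tier_r.to_csv(out_dir / "tier_R.csv", index=False)
    report.correlations.to_csv(out_dir / "correlations.csv", index=False)
    with (out_dir / "group_stats.json").open("w", encoding="utf-8") as fh:
        json.dump(report.group_stats, fh, indent=2)
    with (out_dir / "config.yaml").open("w", encoding="utf-8") as fh:
        yaml.safe_dump(dataclasses.asdict(report.config), fh, sort_keys=True)
    results = getattr(report, "_results", [])
    if results:
        (out_dir / "profiles").mkdir(exist_ok=True)
        (out_dir / "crp").mkdir(exist_ok=True)
        for res in results:
            if res.profile is not None:
                los_mod.export_profile(res.profile, out_dir / "profiles" / f"{res.child_id}.csv")
            if res.crp is not None:
                rec.export_crp(res.crp, out_dir / "crp" / f"{res.child_id}.csv")


def analyze_cohort_files(
    events_dir: str | Path,
    meta_path: str | Path,
    config: AnalysisConfig = AnalysisConfig(),
) -> CohortReport:
    """Load event CSVs (one or many files) and metadata, then analyze."""
    events_dir = Path(events_dir)
    events: dict[str, list[CodedEvent]] = {}
    paths = sorted(events_dir.glob("*.csv")) if events_dir.is_dir() else [events_dir]
    for path in paths:
        if path.name == "metadata.csv":
            continue
        for child_id, evs in read_events(path).items():
            events.setdefault(child_id, []).extend(evs)
    meta = read_metadata(meta_path)
    return analyze_cohort(events, meta, config)
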