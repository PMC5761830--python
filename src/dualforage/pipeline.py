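"""End-to-end orchestration: trips -> randomization -> combination -> growth.

`run_full_pipeline` reproduces the study's analysis order on any corpus (real
or synthetic): classify trips under the pooled variance-minimizing cut-off,
run both per-session randomization tests, combine session p-values per pair
and at study level (both aggregations: over all session p-values and over the
per-pair combined p-values), and fit the growth/PCA/mixed-model stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .combine import clamp_p
from .combine import combine as combine_pvalues
from .growth import fit_coordination_models, growth_params_table, growth_pca
from .randomize import feeding_series, run_randomization
from .trips import pair_sessions_from_records, trip_table

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Effective settings of one pipeline run; written alongside the outputs."""

    n_iter: int = 10_000
    seed: int = 0
    statistic: str = "both"  # st_lt_overlap | interfeed_cv | both
    cutoff_h: Optional[float] = None  # None = estimate from pooled durations
    min_class_size: int = 2
    partner_masking: bool = True
    mask_style: str = "span"  # span | whole_trip (diagnostic)
    combine_methods: tuple = ("stouffer_z", "fisher", "logit")
    p_rule: str = "mid"  # session p fed to combination: mid | paper (strict) | plus1
    sgr_convention: str = "paper_literal"
    fledge_offset_days: float = 1.5
    out_dir: Optional[str] = None


@dataclass
class ReportBundle:
    config: RunConfig
    cutoff: object
    trip_table: pd.DataFrame
    session_results: pd.DataFrame
    pair_combined: pd.DataFrame
    study_combined: pd.DataFrame
    summary: dict
    growth_params: Optional[pd.DataFrame] = None
    growth_pca_variance: Optional[np.ndarray] = None
    growth_scores: Optional[pd.DataFrame] = None
    model_report: Optional[pd.DataFrame] = None
    exclusions: dict = field(default_factory=dict)


def _session_stage(records, grids, config, faded=None):
    sessions, cutoff = pair_sessions_from_records(
        records,
        grids,
        cutoff_h=config.cutoff_h,
        min_class_size=config.min_class_size,
        faded=faded,
        partner_masking=config.partner_masking,
        mask_style=config.mask_style,
    )
    n_excluded = sum(s.excluded for s in sessions)
    log.info("sessions: %d total, %d excluded", len(sessions), n_excluded)
    return sessions, cutoff, n_excluded


def run_full_pipeline(
    records: pd.DataFrame,
    grids: Mapping,
    masses: Optional[pd.DataFrame] = None,
    nest_checks: Optional[pd.DataFrame] = None,
    session_meta: Optional[pd.DataFrame] = None,
    faded: Optional[set] = None,
    config: Optional[RunConfig] = None,
) -> ReportBundle:
    config = config or RunConfig()
    rng = np.random.default_rng(config.seed)

    ages: dict = {}
    chick_of: dict = {}
    if session_meta is not None:
        for r in session_meta.itertuples():
            key = (str(r.pair_id), str(r.session_id))
            if hasattr(r, "chick_age"):
                ages[key] = float(r.chick_age)
            chick_of[key] = str(getattr(r, "chick_id", r.pair_id))

    sessions, cutoff, n_excluded = _session_stage(records, grids, config, faded)
    ttable = trip_table(sessions)
    included = [s for s in sessions if not s.excluded]

    rows = []
    interval_pool = []
    for s in included:
        res = run_randomization(s, statistic=config.statistic,
                                n_iter=config.n_iter, rng=rng)
        fs = feeding_series(s)
        interval_pool.append(fs.intervals_min)
        unmasked = int((s.labels_female != 3).sum())
        for stat, r in res.items():
            rows.append(
                {
                    "pair_id": s.pair_id,
                    "session_id": s.session_id,
                    "statistic": stat,
                    "observed": r.observed,
                    "null_mean": r.null_mean,
                    "p_paper": r.p_value,
                    "p_mid": r.p_mid,
                    "p_plus1": r.p_plus1,
                    "index": r.index,
                    "n_iter": r.n_iter,
                    "n_valid_null": r.n_valid_null,
                    "degenerate": r.degenerate,
                    "n_unmasked_windows": unmasked,
                    "n_feedings": int(len(fs.event_windows)),
                    "chick_id": chick_of.get((s.pair_id, s.session_id), s.pair_id),
                    "chick_age": ages.get(
                        (s.pair_id, s.session_id), s.grid.chick_age_days
                    ),
                }
            )
    session_results = pd.DataFrame(rows)

    p_col = {"mid": "p_mid", "paper": "p_paper", "plus1": "p_plus1"}[config.p_rule]
    pair_rows, study_rows = [], []
    if len(session_results):
        usable = session_results[~session_results["degenerate"]]
        for stat, grp in usable.groupby("statistic"):
            clamped = [clamp_p(p, int(n)) for p, n in
                       zip(grp[p_col], grp["n_valid_null"])]
            for method in config.combine_methods:
                per_pair_ps = []
                def row_of(c):
                    return {"method": c.method, "combined_stat": c.statistic,
                            "p_combined": c.p_combined, "k": c.k}

                for pid, sub in grp.groupby("pair_id"):
                    ps = [clamp_p(p, int(n)) for p, n in
                          zip(sub[p_col], sub["n_valid_null"])]
                    c = combine_pvalues(ps, method, pair_id=pid)
                    pair_rows.append({"statistic": stat, "pair_id": pid, **row_of(c)})
                    per_pair_ps.append(c.p_combined)
                c_all = combine_pvalues(clamped, method)
                study_rows.append(
                    {"statistic": stat, "aggregation": "all_sessions", **row_of(c_all)}
                )
                per_pair_ps = [min(max(p, 1e-12), 1 - 1e-12) for p in per_pair_ps]
                c_pairs = combine_pvalues(per_pair_ps, method)
                study_rows.append(
                    {"statistic": stat, "aggregation": "per_pair", **row_of(c_pairs)}
                )
    pair_combined = pd.DataFrame(pair_rows)
    study_combined = pd.DataFrame(study_rows)

    # headline summary: overlap proportion, interval duration, trip durations
    summary: dict = {"n_sessions_total": len(sessions),
                     "n_sessions_excluded": n_excluded,
                     "n_sessions_included": len(included),
                     "n_pairs": int(session_results["pair_id"].nunique())
                     if len(session_results) else 0,
                     "cutoff_h": cutoff.cutoff_h}
    if len(session_results):
        ov = session_results[session_results["statistic"] == "st_lt_overlap"]
        if len(ov):
            prop = ov["observed"] / ov["n_unmasked_windows"]
            summary["overlap_prop_mean"] = float(prop.mean())
            summary["overlap_prop_sd"] = float(prop.std(ddof=1))
    if interval_pool:
        # session-level aggregation: mean interval per session, SD across sessions
        per_session = np.array([iv.mean() for iv in interval_pool if len(iv)])
        summary["interfeed_mean_min"] = float(per_session.mean())
        summary["interfeed_sd_min"] = float(per_session.std(ddof=1))
    classified = ttable[ttable["trip_type"].isin(["ST", "LT"])]
    for tt in ("ST", "LT"):
        sub = classified[classified["trip_type"] == tt]
        summary[f"{tt.lower()}_mean_h"] = float(sub["duration_h"].mean()) if len(sub) else float("nan")
        summary[f"n_{tt.lower()}"] = int(len(sub))

    bundle = ReportBundle(
        config=config,
        cutoff=cutoff,
        trip_table=ttable,
        session_results=session_results,
        pair_combined=pair_combined,
        study_combined=study_combined,
        summary=summary,
        exclusions={"excluded_sessions": n_excluded},
    )

    if masses is not None and len(session_results):
        gp = growth_params_table(masses, nest_checks,
                                 sgr_convention=config.sgr_convention,
                                 fledge_offset_days=config.fledge_offset_days)
        bundle.growth_params = gp
        try:
            pca = growth_pca(gp)
        except ValueError as exc:
            log.warning("growth PCA skipped: %s", exc)
            pca = None
        if pca is not None:
            bundle.growth_pca_variance = pca.variance_explained
            bundle.growth_scores = pca.scores
            summary["pc12_var_pct"] = float(pca.variance_explained[:2].sum() * 100)
            wide = _session_model_table(session_results)
            feeds = session_results.drop_duplicates(["pair_id", "session_id"])[
                ["pair_id", "session_id", "n_feedings"]
            ]
            bundle.model_report = fit_coordination_models(wide, pca.scores, feeds)

    if config.out_dir:
        _write_bundle(bundle, Path(config.out_dir))
    _check_internal_consistency(bundle)
    return bundle


def _session_model_table(session_results: pd.DataFrame) -> pd.DataFrame:
    """Wide per-session table for the mixed-model stage."""
    ov = session_results[session_results["statistic"] == "st_lt_overlap"]
    cv = session_results[session_results["statistic"] == "interfeed_cv"]
    keep = ["pair_id", "session_id", "index", "chick_age"]
    if "chick_id" in ov.columns:
        keep.insert(2, "chick_id")
    wide = ov[keep].rename(columns={"index": "coordination_level"})
    wide = wide.merge(
        cv[["pair_id", "session_id", "index"]].rename(columns={"index": "rel_cv"}),
        on=["pair_id", "session_id"],
        how="left",
    )
    return wide


def _check_internal_consistency(bundle: ReportBundle) -> None:
    """The shipped summary must be recomputable from the stage tables."""
    sr = bundle.session_results
    if not len(sr):
        return
    ov = sr[sr["statistic"] == "st_lt_overlap"]
    if len(ov):
        prop = ov["observed"] / ov["n_unmasked_windows"]
        assert abs(prop.mean() - bundle.summary["overlap_prop_mean"]) < 1e-12


def _write_bundle(bundle: ReportBundle, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle.trip_table.to_csv(out_dir / "trip_table.csv", index=False)
    bundle.session_results.to_csv(out_dir / "session_results.csv", index=False)
    bundle.pair_combined.to_csv(out_dir / "pair_combined.csv", index=False)
    bundle.study_combined.to_csv(out_dir / "study_combined.csv", index=False)
    manifest = {
        "config": asdict(bundle.config),
        "cutoff": asdict(bundle.cutoff) if hasattr(bundle.cutoff, "__dataclass_fields__")
        else vars(bundle.cutoff),
        "summary": bundle.summary,
        "exclusions": bundle.exclusions,
    }
    (out_dir / "run_manifest.json").write_text(json.dumps(manifest, indent=1))
    if bundle.growth_params is not None:
        bundle.growth_params.to_csv(out_dir / "growth_params.csv", index=False)
    if bundle.growth_scores is not None:
        bundle.growth_scores.to_csv(out_dir / "growth_pca_scores.csv", index=False)
    if bundle.model_report is not None:
        bundle.model_report.to_csv(out_dir / "model_report.csv", index=False)
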