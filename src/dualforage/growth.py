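"""Chick growth parameters, Specific Growth Rate, PCA reduction and mixed models.

Chick condition is summarized by eight discrete indicators per nest — mass on
day 14-16, peak mass and its day, fledging mass and day, mass recession
(peak − fledging), and two Specific Growth Rates (day-14-16 → peak and
peak → fledging).  Because the indicators are strongly intercorrelated they
are z-scored and reduced by PCA; the leading component scores are the
condition responses for the mixed-model stage.  All mixed models use maximum
likelihood with breeding pair as a random intercept.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

log = logging.getLogger(__name__)

SGR_CONVENTIONS = ("paper_literal", "percent_per_day")

GROWTH_VARS = [
    "mass_d14_16", "peak_mass", "fledge_mass", "mass_recession",
    "peak_day", "fledge_day", "sgr1", "sgr2",
]


def sgr(m1: float, m2: float, t1: float, t2: float,
        convention: str = "paper_literal") -> float:
    """Specific Growth Rate between two mass measurements.

    ``paper_literal`` divides the log-mass change by ``(t2 - t1) * 100``;
    ``percent_per_day`` is the conventional ``100 * (ln m2 - ln m1)/(t2 - t1)``.
    The two differ by exactly a factor of 10^4 and, because downstream PCA
    z-scales its inputs, the choice does not affect the PCA or model stage.
    """
    if convention not in SGR_CONVENTIONS:
        raise ValueError(f"unknown SGR convention {convention!r}")
    if m1 <= 0 or m2 <= 0:
        raise ValueError("masses must be positive")
    if t2 <= t1:
        raise ValueError(f"need t2 > t1, got t1={t1}, t2={t2}")
    slope = (np.log(m2) - np.log(m1)) / (t2 - t1)
    return float(slope / 100.0) if convention == "paper_literal" else float(slope * 100.0)


@dataclass
class GrowthParams:
    pair_id: str
    mass_d14_16: Optional[float]
    peak_mass: float
    fledge_mass: float
    mass_recession: float
    peak_day: int
    fledge_day: float
    sgr1: Optional[float]
    sgr2: Optional[float]
    sgr_convention: str = "paper_literal"


def derive_growth_params(
    masses: pd.DataFrame,
    nest_checks: Optional[pd.DataFrame] = None,
    sgr_convention: str = "paper_literal",
    fledge_offset_days: float = 1.5,
) -> GrowthParams:
    """Growth indicators for one chick from its mass trajectory.

    ``masses`` holds one chick's (day_of_life, mass_g) records.  Peak is the
    maximum mass (earliest day on ties); fledging mass is the last measurement.
    The fledging day is interval-censored by the every-3-days nest checks: with
    check records it is the midpoint between the last day the chick was seen
    and the first day it was missing (disappearance only counts after day 21);
    without checks it is the last measurement day plus ``fledge_offset_days``.
    A missing day-14-16 record leaves ``mass_d14_16`` (and SGR1) as missing
    values with a warning, not an error.
    """
    df = masses.sort_values("day_of_life").reset_index(drop=True)
    if len(df) < 2:
        raise ValueError("need at least 2 mass records")
    pair_id = str(df["pair_id"].iloc[0]) if "pair_id" in df else ""
    days = df["day_of_life"].to_numpy(dtype=float)
    mass = df["mass_g"].to_numpy(dtype=float)

    in_range = (days >= 14) & (days <= 16)
    if in_range.any():
        i0 = int(np.flatnonzero(in_range)[0])
        mass_d14_16: Optional[float] = float(mass[i0])
        d0 = float(days[i0])
    else:
        warnings.warn(f"chick {pair_id}: no mass record on day 14-16", stacklevel=2)
        mass_d14_16, d0 = None, None

    ipk = int(np.argmax(mass))  # argmax takes the earliest maximum
    peak_mass, peak_day = float(mass[ipk]), float(days[ipk])
    fledge_mass, last_day = float(mass[-1]), float(days[-1])
    recession = peak_mass - fledge_mass

    fledge_day = last_day + fledge_offset_days
    if nest_checks is not None and len(nest_checks):
        nc = nest_checks.sort_values("day_of_life")
        pres = nc["chick_present"].astype(bool)
        seen = nc.loc[pres, "day_of_life"].to_numpy(dtype=float)
        gone = nc.loc[~pres, "day_of_life"].to_numpy(dtype=float)
        gone = gone[gone > 21]  # disappearance before day 22 is not fledging
        if gone.size:
            first_gone = float(gone.min())
            last_seen = float(seen[seen < first_gone].max()) if (seen < first_gone).any() else last_day
            fledge_day = 0.5 * (last_seen + first_gone)

    sgr1 = (
        sgr(mass_d14_16, peak_mass, d0, peak_day, sgr_convention)
        if mass_d14_16 is not None and peak_day > d0
        else (0.0 if mass_d14_16 is not None and peak_mass == mass_d14_16 else None)
    )
    sgr2 = (
        sgr(peak_mass, fledge_mass, peak_day, last_day, sgr_convention)
        if last_day > peak_day
        else 0.0
    )
    return GrowthParams(
        pair_id=pair_id,
        mass_d14_16=mass_d14_16,
        peak_mass=peak_mass,
        fledge_mass=fledge_mass,
        mass_recession=recession,
        peak_day=int(peak_day),
        fledge_day=float(fledge_day),
        sgr1=sgr1,
        sgr2=sgr2,
        sgr_convention=sgr_convention,
    )


def growth_params_table(
    masses: pd.DataFrame,
    nest_checks: Optional[pd.DataFrame] = None,
    sgr_convention: str = "paper_literal",
    fledge_offset_days: float = 1.5,
) -> pd.DataFrame:
    id_col = "chick_id" if "chick_id" in masses.columns else "pair_id"
    rows = []
    for cid, chick in masses.groupby(id_col, sort=True):
        nc = None
        if nest_checks is not None:
            nc_id = id_col if id_col in nest_checks.columns else "pair_id"
            nc = nest_checks.loc[
                nest_checks[nc_id] == cid, ["day_of_life", "chick_present"]
            ]
        sub = chick[["day_of_life", "mass_g"]].copy()
        sub["pair_id"] = str(cid)
        gp = derive_growth_params(sub, nc, sgr_convention, fledge_offset_days)
        row = {id_col: str(cid)}
        if id_col == "chick_id":
            row["pair_id"] = str(chick["pair_id"].iloc[0])
        row.update({v: getattr(gp, v) for v in GROWTH_VARS})
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class GrowthPCA:
    scores: pd.DataFrame  # pair_id + PC1..PCm (retained components)
    variance_explained: np.ndarray  # all components, non-increasing, sums to 1
    loadings: pd.DataFrame  # variables x retained components
    dropped_rows: list = field(default_factory=list)
    dropped_vars: list = field(default_factory=list)


def growth_pca(params: pd.DataFrame, n_components: int = 2) -> GrowthPCA:
    """PCA of z-scored growth indicators (correlation-matrix decomposition).

    Complete-case rows only; zero-variance variables are dropped with a
    warning.  Component signs are fixed so each loading vector's
    largest-magnitude entry is positive, making scores reproducible.
    """
    id_cols = [c for c in ("chick_id", "pair_id") if c in params.columns]
    id_col = id_cols[0]
    cols = [c for c in GROWTH_VARS if c in params.columns]
    data = params[id_cols + cols].copy()
    complete = data.dropna()
    dropped_rows = sorted(set(data[id_col]) - set(complete[id_col]))
    if dropped_rows:
        log.info("PCA: dropped incomplete rows for pairs %s", dropped_rows)
    if len(complete) < 3:
        raise ValueError(f"need >= 3 complete chicks for PCA, got {len(complete)}")

    X = complete[cols].to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    dropped_vars = [c for c, k in zip(cols, keep) if not k]
    if dropped_vars:
        warnings.warn(f"PCA: dropping zero-variance variables {dropped_vars}",
                      stacklevel=2)
    cols = [c for c, k in zip(cols, keep) if k]
    X = X[:, keep]
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)

    n_comp_all = min(Z.shape)
    pca = PCA(n_components=n_comp_all)
    scores_all = pca.fit_transform(Z)
    # total variance normalization so proportions sum to 1 over all components
    var_ratio = pca.explained_variance_ratio_

    m = min(n_components, n_comp_all)
    comps = pca.components_[:m]
    flip = np.sign(comps[np.arange(m), np.argmax(np.abs(comps), axis=1)])
    comps = comps * flip[:, None]
    scores = scores_all[:, :m] * flip[None, :]

    score_df = pd.DataFrame(scores, columns=[f"PC{i+1}" for i in range(m)])
    for j, c in enumerate(id_cols):
        score_df.insert(j, c, complete[c].to_numpy())
    loadings = pd.DataFrame(comps.T, index=cols,
                            columns=[f"PC{i+1}" for i in range(m)])
    return GrowthPCA(score_df, var_ratio, loadings, dropped_rows, dropped_vars)


# ---------------------------------------------------------------------------
# mixed-model stage (thin contract over statsmodels)


@dataclass
class ModelResult:
    name: str
    response: str
    term: str
    estimate: float
    se: float
    f_value: float
    df_num: int
    df_den: int
    p_value: float
    converged: bool
    singular: bool
    note: Optional[str] = None


def _fit_lmm(
    df: pd.DataFrame, response: str, fixed: list[str], group: str, name: str
) -> list[ModelResult]:
    """ML linear mixed model with a random intercept per group.

    F statistics are Wald (estimate/SE)^2 with 1 numerator df; the denominator
    df convention is residual-style (n_obs - n_fixed - n_groups), reported so
    results can be re-referenced under another convention.
    """
    import statsmodels.formula.api as smf

    d = df.dropna(subset=[response] + fixed + [group]).copy()
    out: list[ModelResult] = []
    if d[response].nunique() <= 1:
        # constant response: slopes are identically zero
        for term in fixed:
            out.append(ModelResult(name, response, term, 0.0, float("nan"),
                                   0.0, 1, max(len(d) - len(fixed) - 1, 1),
                                   1.0, True, True, "constant response"))
        return out
    formula = f"{response} ~ " + " + ".join(fixed)
    singular = False
    note = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = smf.mixedlm(formula, d, groups=d[group])
            fit = model.fit(reml=False)
            converged = bool(fit.converged)
            re_var = float(np.asarray(fit.cov_re).ravel()[0])
            if re_var <= 1e-10:
                singular = True
                note = "random-intercept variance estimated at boundary (~0)"
        except Exception as exc:  # pragma: no cover - defensive
            for term in fixed:
                out.append(ModelResult(name, response, term, float("nan"),
                                       float("nan"), float("nan"), 1, 0,
                                       float("nan"), False, True, str(exc)))
            return out
    n_groups = d[group].nunique()
    df_den = max(len(d) - (len(fixed) + 1) - n_groups, 1)
    from scipy import stats as sps

    for term in fixed:
        est = float(fit.params[term])
        se = float(fit.bse[term])
        f = (est / se) ** 2 if se > 0 else float("nan")
        p = float(sps.f.sf(f, 1, df_den)) if np.isfinite(f) else float("nan")
        out.append(ModelResult(name, response, term, est, se, f, 1, df_den, p,
                               converged, singular, note))
    return out


def fit_coordination_models(
    session_df: pd.DataFrame,
    growth_scores: pd.DataFrame,
    feeding_counts: pd.DataFrame,
) -> pd.DataFrame:
    """The four mixed-model analyses of the coordination pipeline.

    (a) coordination level ~ chick age; (b) relative interval CV ~ coordination
    level; (c) PC1 and PC2 ~ coordination level + total feedings per 48 h;
    (d) PC1 and PC2 ~ relative interval CV + total feedings — all with breeding
    pair as random intercept, ML estimation.

    ``session_df`` needs columns pair_id, session_id, coordination_level,
    rel_cv, chick_age (plus chick_id when chicks are nested in pair-years);
    ``growth_scores`` holds the matching id column(s) + PC columns;
    ``feeding_counts`` pair_id, session_id, n_feedings.
    """
    d = session_df.merge(feeding_counts, on=["pair_id", "session_id"], how="left")
    if "chick_id" in d.columns and "chick_id" in growth_scores.columns:
        d = d.merge(growth_scores.drop(columns=["pair_id"], errors="ignore"),
                    on="chick_id", how="left")
    else:
        d = d.merge(growth_scores, on="pair_id", how="left")

    results: list[ModelResult] = []
    results += _fit_lmm(d, "coordination_level", ["chick_age"], "pair_id",
                        "a_coordination_vs_age")
    results += _fit_lmm(d, "rel_cv", ["coordination_level"], "pair_id",
                        "b_relcv_vs_coordination")
    for pc in [c for c in growth_scores.columns if c.startswith("PC")]:
        results += _fit_lmm(d, pc, ["coordination_level", "n_feedings"], "pair_id",
                            f"c_{pc.lower()}_vs_coordination")
        results += _fit_lmm(d, pc, ["rel_cv", "n_feedings"], "pair_id",
                            f"d_{pc.lower()}_vs_relcv")
    return pd.DataFrame([vars(r) for r in results])
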