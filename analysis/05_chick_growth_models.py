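"""Chick growth indicators, PCA reduction, and the four mixed-model analyses.

Derives the eight growth measures per chick (day-14-16 mass, peak and fledging
mass/day, mass recession, SGR1, SGR2), reduces them by PCA on z-scored
variables, and fits the four ML linear mixed models (pair as random
intercept): coordination ~ chick age; relative interval CV ~ coordination;
PC1/PC2 ~ coordination + feedings; PC1/PC2 ~ relative CV + feedings.
Writes growth_params.csv, growth_pca_scores.csv, model_report.csv and the
coordination-vs-CV scatter figure.
"""

from pathlib import Path

import pandas as pd

from dualforage import (
    fit_coordination_models,
    growth_params_table,
    growth_pca,
    read_chick_masses,
    read_nest_checks,
)
from dualforage.plots import plot_index_vs_cv

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    masses = read_chick_masses(ROOT / "corpus" / "chick_masses.csv")
    checks = read_nest_checks(ROOT / "corpus" / "nest_checks.csv")
    meta = pd.read_csv(ROOT / "corpus" / "sessions.csv",
                       dtype={"pair_id": str, "session_id": str})

    params = growth_params_table(masses, checks)
    params.to_csv(ROOT / "growth_params.csv", index=False)
    pca = growth_pca(params)
    pca.scores.to_csv(ROOT / "growth_pca_scores.csv", index=False)
    print(f"{len(params)} chicks; PC1+PC2 explain "
          f"{pca.variance_explained[:2].sum() * 100:.1f}% of growth variance")

    sr = pd.read_csv(ROOT / "session_results.csv",
                     dtype={"pair_id": str, "session_id": str})
    sr = sr[~sr.degenerate]
    ov = sr[sr.statistic == "st_lt_overlap"]
    cv = sr[sr.statistic == "interfeed_cv"]
    wide = ov[["pair_id", "session_id", "index", "n_feedings"]].rename(
        columns={"index": "coordination_level"})
    wide = wide.merge(cv[["pair_id", "session_id", "index"]].rename(
        columns={"index": "rel_cv"}), on=["pair_id", "session_id"], how="inner")
    wide = wide.merge(meta, on=["pair_id", "session_id"], how="left")

    report = fit_coordination_models(
        wide.drop(columns=["n_feedings"]),
        pca.scores,
        wide[["pair_id", "session_id", "n_feedings"]],
    )
    report.to_csv(ROOT / "model_report.csv", index=False)
    plot_index_vs_cv(sr, ROOT / "fig_index_vs_cv.png")
    for r in report.itertuples():
        print(f"{r.name:28s} {r.term:20s} est {r.estimate:+8.4f} "
              f"F(1,{r.df_den}) = {r.f_value:6.2f}  P = {r.p_value:.4f}")


if __name__ == "__main__":
    main()
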