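"""Combine the per-session randomization p-values: per pair and study level.

Sessions of the same pair are combined with Stouffer's Z (Fisher and logit as
checks) to avoid pseudoreplication; the study-level combination is reported
both over all session p-values and over the per-pair combined p-values.
Writes results/pair_combined.csv and results/study_combined.csv.
"""

from pathlib import Path

import pandas as pd

from dualforage.combine import METHODS, clamp_p, combine

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    df = pd.read_csv(ROOT / "session_results.csv")
    usable = df[~df["degenerate"]]
    pair_rows, study_rows = [], []
    for stat, grp in usable.groupby("statistic"):
        all_ps = [clamp_p(p, int(n)) for p, n in
                  zip(grp["p_mid"], grp["n_valid_null"])]
        for method in METHODS:
            per_pair = []
            for pid, sub in grp.groupby("pair_id"):
                ps = [clamp_p(p, int(n)) for p, n in
                      zip(sub["p_mid"], sub["n_valid_null"])]
                c = combine(ps, method, pair_id=pid)
                pair_rows.append({"statistic": stat, "pair_id": pid,
                                  "method": method, "combined_stat": c.statistic,
                                  "p_combined": c.p_combined, "k": c.k})
                per_pair.append(min(max(c.p_combined, 1e-12), 1 - 1e-12))
            c_all = combine(all_ps, method)
            c_pairs = combine(per_pair, method)
            study_rows.append({"statistic": stat, "method": method,
                               "aggregation": "all_sessions",
                               "combined_stat": c_all.statistic,
                               "p_combined": c_all.p_combined, "k": c_all.k})
            study_rows.append({"statistic": stat, "method": method,
                               "aggregation": "per_pair",
                               "combined_stat": c_pairs.statistic,
                               "p_combined": c_pairs.p_combined, "k": c_pairs.k})
    pd.DataFrame(pair_rows).to_csv(ROOT / "pair_combined.csv", index=False)
    study = pd.DataFrame(study_rows)
    study.to_csv(ROOT / "study_combined.csv", index=False)
    z = study[(study.method == "stouffer_z") & (study.aggregation == "all_sessions")]
    for r in z.itertuples():
        print(f"{r.statistic}: study-level Z = {r.combined_stat:.2f}, "
              f"P = {r.p_combined:.4f} (k = {r.k} sessions)")


if __name__ == "__main__":
    main()
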