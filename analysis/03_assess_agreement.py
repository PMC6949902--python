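"""Between-instrument agreement: Bland–Altman, bias regression, correlations.

Pairs total scores from both instruments, reports the mean FFQ−SDQ
difference with ±2SD limits of agreement and the proportional-bias
regression, tabulates age-stratified Pearson correlations per food group,
and the proportion of the cohort meeting each scored recommendation.
Writes agreement.json, correlations.csv, proportions.csv and a
Bland–Altman plot under results/agreement/.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from dietscreen import (
    bland_altman,
    bland_altman_plot,
    default_criteria,
    default_thresholds,
    frame_to_profiles,
    paired_scores,
    pearson,
    proportion_meeting,
    stratified_correlations,
)
from dietscreen.agreement import correlations_to_frame
from dietscreen.scoring import frame_to_scores

COHORT = Path(__file__).resolve().parents[1] / "results" / "cohort"
OUT = Path(__file__).resolve().parents[1] / "results" / "agreement"


def main() -> None:
    argparse.ArgumentParser(description=__doc__).parse_args()
    OUT.mkdir(parents=True, exist_ok=True)

    criteria, th = default_criteria(), default_thresholds()
    prof_ffq = frame_to_profiles(pd.read_csv(COHORT / "profiles_ffq.csv"))
    prof_sdq = frame_to_profiles(pd.read_csv(COHORT / "profiles_sdq.csv"))
    sc_ffq = frame_to_scores(pd.read_csv(COHORT / "scores_ffq.csv"))
    sc_sdq = frame_to_scores(pd.read_csv(COHORT / "scores_sdq.csv"))

    pairs = paired_scores(sc_ffq, sc_sdq)
    res = bland_altman(pairs["ffq_total"], pairs["sdq_total"],
                       multiplier=th.loa_sd_multiplier, alpha=th.alpha)
    r_total, p_total = pearson(pairs["ffq_total"], pairs["sdq_total"])

    report = res.to_dict() | {"total_score_r": r_total, "total_score_p": p_total}
    (OUT / "agreement.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")

    corr = correlations_to_frame(stratified_correlations(prof_ffq, prof_sdq, th))
    corr.to_csv(OUT / "correlations.csv", index=False)

    props = proportion_meeting(prof_ffq, criteria)
    pd.DataFrame({"food_group": [g.value for g in props],
                  "pct_meeting": list(props.values())}).to_csv(
        OUT / "proportions.csv", index=False)

    bland_altman_plot(pairs["ffq_total"], pairs["sdq_total"], res, OUT / "bland_altman.png")

    print(f"n={res.n_pairs} paired respondents")
    print(f"  mean difference (FFQ−SDQ): {res.mean_diff:.2f} points "
          f"(SD {res.sd_diff:.2f}); LOA ({res.loa_lower:.2f}, {res.loa_upper:.2f})")
    print(f"  bias regression: slope {res.slope:.3f} "
          f"(95% CI {res.slope_ci_low:.3f}, {res.slope_ci_high:.3f}; p={res.slope_p:.2f})")
    print(f"  total-score correlation r={r_total:.2f} (p={p_total:.2g})")
    negligible = corr[(corr.stratum != "all") & corr.negligible]
    strat = corr[corr.stratum != "all"]
    print(f"  {len(negligible)}/{len(strat)} stratified group correlations "
          f"negligible (r<{th.negligible_r})")
    print(f"wrote agreement.json, correlations.csv, proportions.csv, "
          f"bland_altman.png under {OUT}")


if __name__ == "__main__":
    main()
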