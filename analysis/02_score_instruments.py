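"""Harmonize both instruments onto serves/day and apply the 30-point score.

Reads the response tables written by 01_simulate_cohort.py, converts each
instrument to a per-respondent serves/day profile (FFQ: frequency label →
grams → serves; SDQ: unit-specific daily conversion), scores both against
the default criteria, and writes profiles and scores under results/cohort/.
"""

import argparse
from pathlib import Path

import numpy as np

from dietscreen import (
    default_composition,
    default_criteria,
    default_ffq_schema,
    default_sdq_schema,
    ffq_to_profiles,
    profiles_to_frame,
    read_responses,
    score_profiles,
    scores_to_frame,
    sdq_to_profiles,
)

RESULTS = Path(__file__).resolve().parents[1] / "results" / "cohort"


def main() -> None:
    argparse.ArgumentParser(description=__doc__).parse_args()

    ffq_schema, sdq_schema = default_ffq_schema(), default_sdq_schema()
    criteria = default_criteria()
    composition = default_composition()

    ffq_resp = read_responses(RESULTS / "ffq_responses.csv", ffq_schema)
    sdq_resp = read_responses(RESULTS / "sdq_responses.csv", sdq_schema)

    prof_ffq = ffq_to_profiles(ffq_resp, ffq_schema, composition)
    prof_sdq = sdq_to_profiles(sdq_resp, sdq_schema)
    scores_ffq = score_profiles(prof_ffq, criteria)
    scores_sdq = score_profiles(prof_sdq, criteria)

    profiles_to_frame(prof_ffq).to_csv(RESULTS / "profiles_ffq.csv", index=False,
                                       float_format="%.6f")
    profiles_to_frame(prof_sdq).to_csv(RESULTS / "profiles_sdq.csv", index=False,
                                       float_format="%.6f")
    scores_to_frame(scores_ffq).to_csv(RESULTS / "scores_ffq.csv", index=False)
    scores_to_frame(scores_sdq).to_csv(RESULTS / "scores_sdq.csv", index=False)

    for name, scores in (("FFQ", scores_ffq), ("SDQ", scores_sdq)):
        totals = np.array([s.total for s in scores])
        print(f"{name}: n={len(totals)}, total score mean {totals.mean():.1f} "
              f"(SD {totals.std(ddof=1):.1f}) out of {criteria.max_total}")
    print(f"wrote profiles_*.csv and scores_*.csv under {RESULTS}")


if __name__ == "__main__":
    main()
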