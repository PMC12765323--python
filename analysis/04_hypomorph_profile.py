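#!/usr/bin/env python
"""Profile the ABCA4 hypomorph reference set and test a candidate against it.

Classifies the nine well-characterized ABCA4 hypomorphic variants with the
default score thresholds (the predictor calls only one of them pathogenic),
builds the min/median/max population-metric envelope — over all nine and
over the eight the predictor misses — and checks whether the long-read
candidate Pro1948Leu falls inside the nine-variant envelope. Writes
results/hypomorph_profile.json.
"""

import json
from pathlib import Path

from vpbench.classification import classify_score
from vpbench.flagger import build_profile, compare_to_profile
from vpbench.reference import (
    ABCA4_HYPOMORPHS,
    PRO1948LEU,
    hypomorph_population_records,
    pro1948leu_record,
)

ROOT = Path(__file__).resolve().parents[1]


def env_json(profile) -> dict:
    return {
        name: {"min": e.minimum, "median": e.median, "max": e.maximum}
        for name in ("allele_frequency", "homozygote_count", "cadd_phred")
        for e in [getattr(profile, name)]
    }


def main() -> None:
    calls = {change: classify_score(score).value
             for change, score, *_ in ABCA4_HYPOMORPHS}
    n_pathogenic = sum(1 for c in calls.values() if c == "pathogenic")
    print(f"predictor calls on the 9 reference hypomorphs: "
          f"{n_pathogenic} pathogenic, "
          f"{sum(1 for c in calls.values() if c == 'ambiguous')} ambiguous, "
          f"{sum(1 for c in calls.values() if c == 'benign')} benign")

    profile9 = build_profile(hypomorph_population_records())
    profile8 = build_profile(hypomorph_population_records(exclude="Gly1961Glu"))
    print(f"8-variant medians (excluding the one correct call): "
          f"AF {profile8.allele_frequency.median:.3g}, "
          f"homozygotes {profile8.homozygote_count.median:g}, "
          f"CADD {profile8.cadd_phred.median:g}")

    query = pro1948leu_record()
    cmp = compare_to_profile(query, profile9)
    verdict = "inside" if cmp.overall_within else "outside"
    print(f"candidate {PRO1948LEU[0]} (AF {PRO1948LEU[1]:g}, "
          f"{PRO1948LEU[2]} homozygotes, CADD {PRO1948LEU[3]}) is {verdict} "
          f"the 9-variant envelope")

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    (results / "hypomorph_profile.json").write_text(json.dumps({
        "predicted_classes": calls,
        "profile_all9": env_json(profile9),
        "profile_without_Gly1961Glu": env_json(profile8),
        "candidate": {
            "variant": PRO1948LEU[0],
            "per_metric_within": dict(cmp.per_metric),
            "overall_within": cmp.overall_within,
        },
    }, indent=2) + "\n")
    print(f"-> {results / 'hypomorph_profile.json'}")


if __name__ == "__main__":
    main()
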