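"""Group-level inference on prediction accuracy: one-sample t-tests per
group/area/condition, childhood-vs-post-childhood contrasts, the
speech-minus-music voice effect, and per-child pSTC permutation tests.

The drivers use 499 permutations per participant (the analysis default
is 5000); the permutation p floor is therefore 1/500.

Output (results/): group_stats.json
"""

import json

from common import RESULTS, build_cohort, get_config

from emoenc.encoding import RidgeSpec
from emoenc.io import write_json
from emoenc.pipeline import (
    fit_cohort_encoding,
    group_statistics,
    pstc_permutation_pvalues,
)


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    cfg = get_config()
    cohort = build_cohort(cfg)
    spec = RidgeSpec(lambda_grid=cfg.lambda_grid, k_folds=cfg.k_folds)
    results, lam = fit_cohort_encoding(cohort, spec)

    stats = group_statistics(results, cohort)
    child_pstc = [p.id for p in cohort.participants
                  if p.group == "childhood" and "pSTC" in p.binned]
    stats["childhood_pstc_permutation"] = pstc_permutation_pvalues(
        cohort, lam, n_perm=cfg.n_perm, seed=cfg.seed,
        k_folds=cfg.k_folds, participants=child_pstc,
    )
    stats["global_lambda"] = lam
    write_json(stats, RESULTS / "group_stats.json")

    print("one-sample t on mean r (group/area/condition):")
    for key, v in stats["one_sample"].items():
        print(f"  {key:35s} mean_r={v['mean_r']:+.3f} "
              f"t({v['df']})={v['t']:+.2f} p={v['p']:.4f}")
    print("childhood vs post-childhood (unpaired t):")
    for key, v in stats["between_groups"].items():
        print(f"  {key:35s} t({v['df']})={v['t']:+.2f} p={v['p']:.4f}")
    print("children's pSTC permutation p (speech, 499 shuffles):")
    print("  " + json.dumps(stats["childhood_pstc_permutation"]))
    print(f"wrote {RESULTS / 'group_stats.json'}")


if __name__ == "__main__":
    main()
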