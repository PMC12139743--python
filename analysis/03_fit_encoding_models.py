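"""Fit the lagged ridge encoding models for every participant, area and
condition, with one global regularisation strength shared by all.

Output (results/): encoding_results.tsv — one row per (participant,
area, condition) with the 5-fold prediction accuracies and their mean.
"""

import pandas as pd
from common import RESULTS, build_cohort, get_config

from emoenc.encoding import RidgeSpec
from emoenc.io import read_encoding_results_tsv, write_encoding_results_tsv
from emoenc.pipeline import fit_cohort_encoding


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    cfg = get_config()
    cohort = build_cohort(cfg)
    spec = RidgeSpec(lambda_grid=cfg.lambda_grid, k_folds=cfg.k_folds)
    results, lam = fit_cohort_encoding(cohort, spec)
    write_encoding_results_tsv(results, RESULTS / "encoding_results.tsv")

    df = read_encoding_results_tsv(RESULTS / "encoding_results.tsv")
    meta = {p.id: p.group for p in cohort.participants}
    df["group"] = df["participant"].map(meta)
    print(f"fitted {len(df)} datasets; global lambda = {lam:.1f}")
    summary = (
        df.groupby(["group", "area", "condition"])["mean_r"]
        .agg(["mean", "count"])
        .round(4)
    )
    print(summary.to_string())
    print(f"wrote {RESULTS / 'encoding_results.tsv'}")


if __name__ == "__main__":
    main()
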