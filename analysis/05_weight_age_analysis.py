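"""Weight-versus-age analysis in pSTC (speech condition): pool absolute
ridge weights over folds and lags, keep participants whose encoding is
individually significant under the temporal-shuffle permutation test,
correlate each feature's pooled weight with age, and rank.

Outputs (results/): weight_age.tsv (ranked per-feature table) and
weight_age.json (complex/basic aggregate correlations).
"""

from common import RESULTS, build_cohort, get_config

from emoenc.encoding import RidgeSpec
from emoenc.io import write_json
from emoenc.pipeline import (
    fit_cohort_encoding,
    pstc_permutation_pvalues,
    weight_age_analysis,
)


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    cfg = get_config()
    cohort = build_cohort(cfg)
    spec = RidgeSpec(lambda_grid=cfg.lambda_grid, k_folds=cfg.k_folds)
    results, lam = fit_cohort_encoding(cohort, spec)
    pvals = pstc_permutation_pvalues(cohort, lam, n_perm=cfg.n_perm_inclusion,
                                     seed=cfg.seed + 1, k_folds=cfg.k_folds)
    wa, kept = weight_age_analysis(cohort, results, pvals, alpha=cfg.alpha)

    wa.table.to_csv(RESULTS / "weight_age.tsv", sep="\t", index=False)
    write_json(
        {"complex_r": wa.complex_r, "complex_p": wa.complex_p,
         "basic_r": wa.basic_r, "basic_p": wa.basic_p,
         "n_included": len(kept),
         "included": [p.participant for p in kept]},
        RESULTS / "weight_age.json",
    )
    print(f"{len(kept)} of {sum(1 for p in cohort.participants if 'pSTC' in p.binned)} "
          f"pSTC participants pass the inclusion filter (permutation p < "
          f"{cfg.alpha})")
    print(f"complex-aggregate weight-age r = {wa.complex_r:+.4f} "
          f"(p = {wa.complex_p:.4f})")
    print(f"basic-aggregate   weight-age r = {wa.basic_r:+.4f} "
          f"(p = {wa.basic_p:.4f})")
    print("top 8 features by weight-age correlation:")
    print(wa.table.head(8).to_string(index=False))
    print(f"wrote {RESULTS / 'weight_age.tsv'}, weight_age.json")


if __name__ == "__main__":
    main()
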