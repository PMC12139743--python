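"""End-to-end orchestration: simulate -> design -> encode -> stats ->
weights.

The stages are thin compositions of the library modules; every run
writes its result tables plus a manifest (config hash, seed, package
version, stages completed) and is bit-reproducible given an identical
configuration and seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .data import BinnedHFB, FeatureTimecourses
from .design import build_lagged_design, concatenate_contacts
from .encoding import EncodingResult, RidgeSpec, cv_evaluate, select_global_lambda
from .errors import DegenerateDataError
from .features import default_feature_set
from .io import write_encoding_results_tsv, write_events_tsv, write_json
from .simulate import (
    Cohort,
    GroundTruth,
    default_cohort_spec,
    generate_cohort,
    sample_ground_truth_weights,
)
from .stats import one_sample_t, paired_t, permutation_test, unpaired_t, voice_effect
from .weights import (
    WeightProfile,
    filter_significant,
    pool_fold_weights,
    weight_age_correlation,
)

__all__ = [
    "cohort_datasets",
    "fit_cohort_encoding",
    "group_statistics",
    "pstc_permutation_pvalues",
    "weight_age_analysis",
    "run_pipeline",
]


@dataclass(frozen=True)
class DatasetKey:
    participant: str
    area: str
    condition: str


def cohort_datasets(
    cohort: Cohort,
) -> list[tuple[DatasetKey, np.ndarray, np.ndarray, np.ndarray]]:
    """Flatten a cohort into (key, X, y, blocks) regression datasets,
    one per participant x covered area x condition."""
    out = []
    for p in cohort.participants:
        for area, binned in sorted(p.binned.items()):
            for cond in ("speech", "music"):
                blocks = [
                    int(b) for b in cohort.schedule.blocks_for(cond)
                    if int(b) in cohort.features.blocks
                ]
                if not blocks:
                    continue
                design = build_lagged_design(
                    cohort.features.subset(blocks), cohort.lags
                )
                X, y, row_blocks, _ = concatenate_contacts(
                    binned.subset(blocks), design
                )
                out.append((DatasetKey(p.id, area, cond), X, y, row_blocks))
    return out


def fit_cohort_encoding(
    cohort: Cohort, spec: RidgeSpec | None = None
) -> tuple[list[EncodingResult], float]:
    """Select one global regularisation strength over every dataset of
    the cohort, then CV-evaluate each dataset at that value."""
    spec = spec or RidgeSpec()
    datasets = cohort_datasets(cohort)
    lam = select_global_lambda([(X, y, b) for _, X, y, b in datasets], spec)
    results = [
        cv_evaluate(
            X, y, b, lam, spec.k_folds,
            participant=k.participant, area=k.area, condition=k.condition,
        )
        for k, X, y, b in datasets
    ]
    return results, lam


def _accuracy_frame(results: list[EncodingResult], cohort: Cohort) -> pd.DataFrame:
    meta = {p.id: p for p in cohort.participants}
    return pd.DataFrame(
        {
            "participant": r.participant,
            "area": r.area,
            "condition": r.condition,
            "group": meta[r.participant].group,
            "age": meta[r.participant].age,
            "mean_r": r.mean_r,
        }
        for r in results
    )


def group_statistics(results: list[EncodingResult], cohort: Cohort) -> dict:
    """Parametric group-level tests on prediction accuracy.

    Per (group, area, condition): one-sample t of mean r against 0.
    Per (area, condition): childhood vs post-childhood unpaired t.
    Per (group, area): speech vs music paired t, and the between-group
    contrast of the per-participant speech-minus-music voice effect.
    """
    df = _accuracy_frame(results, cohort)
    out: dict = {"one_sample": {}, "between_groups": {}, "paired_speech_music": {},
                 "voice_effect": {}}
    for (group, area, cond), sub in df.groupby(["group", "area", "condition"]):
        if len(sub) < 2:
            continue
        try:
            t = one_sample_t(sub["mean_r"])
        except DegenerateDataError:
            continue
        out["one_sample"][f"{group}/{area}/{cond}"] = {
            "t": t.t, "df": t.df, "p": t.p,
            "mean_r": float(sub["mean_r"].mean()), "n": len(sub),
        }
    for (area, cond), sub in df.groupby(["area", "condition"]):
        a = sub.loc[sub["group"] == "childhood", "mean_r"]
        b = sub.loc[sub["group"] == "post_childhood", "mean_r"]
        if len(a) >= 2 and len(b) >= 2:
            t = unpaired_t(a, b)
            out["between_groups"][f"{area}/{cond}"] = {
                "t": t.t, "df": t.df, "p": t.p, "n_child": len(a), "n_post": len(b),
            }
    wide = df.pivot_table(
        index=["participant", "group", "area"], columns="condition",
        values="mean_r",
    ).reset_index()
    if {"speech", "music"} <= set(wide.columns):
        for (group, area), sub in wide.groupby(["group", "area"]):
            sub = sub.dropna(subset=["speech", "music"])
            if len(sub) >= 2:
                try:
                    t = paired_t(sub["speech"], sub["music"])
                except DegenerateDataError:
                    continue
                out["paired_speech_music"][f"{group}/{area}"] = {
                    "t": t.t, "df": t.df, "p": t.p, "n": len(sub),
                }
        for area, sub in wide.dropna(subset=["speech", "music"]).groupby("area"):
            if sub["group"].nunique() == 2 and len(sub) >= 4:
                _, contrast = voice_effect(
                    sub["speech"], sub["music"], groups=sub["group"]
                )
                if contrast is not None:
                    out["voice_effect"][area] = {
                        "t": contrast.t, "df": contrast.df, "p": contrast.p,
                    }
    return out


def pstc_permutation_pvalues(
    cohort: Cohort,
    lam: float,
    condition: str = "speech",
    area: str = "pSTC",
    n_perm: int = 199,
    seed: int = 0,
    k_folds: int = 5,
    participants: list[str] | None = None,
) -> dict[str, float]:
    """Per-participant temporal-shuffle permutation p on one area and
    condition (used for children's pSTC inference and for the weight
    stage's inclusion filter)."""
    blocks = [
        int(b) for b in cohort.schedule.blocks_for(condition)
        if int(b) in cohort.features.blocks
    ]
    feats = cohort.features.subset(blocks)
    ss = np.random.SeedSequence(seed)
    out: dict[str, float] = {}
    targets = [
        p for p in cohort.participants
        if area in p.binned and (participants is None or p.id in participants)
    ]
    for p, sub_ss in zip(targets, ss.spawn(len(targets))):
        res = permutation_test(
            feats, p.binned[area].subset(blocks), lam,
            lags=cohort.lags, k_folds=k_folds, n_perm=n_perm,
            seed=int(sub_ss.generate_state(1)[0] % (2**31)),
        )
        out[p.id] = res.p_two_tailed
    return out


def weight_age_analysis(
    cohort: Cohort,
    results: list[EncodingResult],
    p_values: dict[str, float],
    area: str = "pSTC",
    condition: str = "speech",
    alpha: float = 0.05,
):
    """Fold-pooled |weight| profiles for individually significant
    participants, correlated with age and ranked."""
    ages = {p.id: p.age for p in cohort.participants}
    profiles = []
    for r in results:
        if r.area != area or r.condition != condition:
            continue
        if r.participant not in p_values:
            continue
        profiles.append(
            WeightProfile(
                participant=r.participant,
                age=ages[r.participant],
                weights_abs=pool_fold_weights(
                    r, cohort.feature_set.names, len(cohort.lags)
                ),
            )
        )
    kept = filter_significant(profiles, p_values, alpha)
    if len(kept) < 3:
        raise ValueError(
            f"only {len(kept)} significant participants in {area}/{condition}; "
            "need at least 3 for the age correlation"
        )
    return weight_age_correlation(kept, cohort.feature_set), kept


def run_pipeline(
    config: PipelineConfig, out_dir, cohort_spec=None
) -> dict:
    """Run the five stages on a synthetic cohort and write results.

    Writes events.tsv, participants.tsv, encoding_results.tsv,
    group_stats.json, weight_age.tsv/json and manifest.json under
    ``out_dir``; returns the manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: list[str] = []
    fset = default_feature_set(config.five_complex)
    rng = np.random.default_rng(config.seed)

    # 1. simulate
    spec = cohort_spec or default_cohort_spec(
        seed=config.seed,
        complex_age_slope=config.complex_age_slope,
        voice_gain=config.voice_gain,
    )
    base = GroundTruth(
        weights=sample_ground_truth_weights(
            rng, fset.n_features, len(config.lags), scale=config.weight_scale
        ),
        noise_sd=config.noise_sd,
        seed=config.seed,
    )
    cohort = generate_cohort(
        spec, base, seed=config.seed, feature_set=fset, lags=config.lags,
        n_blocks=config.n_blocks, block_dur=config.block_dur,
    )
    write_events_tsv(cohort.schedule, out / "events.tsv")
    cohort.metadata().to_csv(out / "participants.tsv", sep="\t", index=False)
    stages.append("simulate")

    # 2. design (materialised inside cohort_datasets; recorded as a stage
    # for the manifest's accounting of the standard chain)
    ridge = RidgeSpec(lambda_grid=config.lambda_grid, k_folds=config.k_folds)
    datasets = cohort_datasets(cohort)
    if not datasets:
        raise ValueError("cohort produced no regression datasets")
    stages.append("design")

    # 3. encode
    lam = select_global_lambda([(X, y, b) for _, X, y, b in datasets], ridge)
    results = [
        cv_evaluate(X, y, b, lam, ridge.k_folds,
                    participant=k.participant, area=k.area, condition=k.condition)
        for k, X, y, b in datasets
    ]
    write_encoding_results_tsv(results, out / "encoding_results.tsv")
    stages.append("encode")

    # 4. stats
    gstats = group_statistics(results, cohort)
    child_pstc = [
        p.id for p in cohort.participants
        if p.group == "childhood" and "pSTC" in p.binned
    ]
    if child_pstc:
        gstats["childhood_pstc_permutation"] = pstc_permutation_pvalues(
            cohort, lam, n_perm=config.n_perm, seed=config.seed,
            k_folds=config.k_folds, participants=child_pstc,
        )
    gstats["global_lambda"] = lam
    write_json(gstats, out / "group_stats.json")
    stages.append("stats")

    # 5. weights
    pvals = pstc_permutation_pvalues(
        cohort, lam, n_perm=config.n_perm_inclusion, seed=config.seed + 1,
        k_folds=config.k_folds,
    )
    try:
        wa, kept = weight_age_analysis(
            cohort, results, pvals, alpha=config.alpha
        )
        wa.table.to_csv(out / "weight_age.tsv", sep="\t", index=False)
        write_json(
            {
                "complex_r": wa.complex_r, "complex_p": wa.complex_p,
                "basic_r": wa.basic_r, "basic_p": wa.basic_p,
                "n_included": len(kept),
                "included": [p.participant for p in kept],
            },
            out / "weight_age.json",
        )
    except ValueError as exc:
        warnings.warn(f"weight stage skipped: {exc}", RuntimeWarning)
    stages.append("weights")

    manifest = {
        "package": "emoenc",
        "version": __version__,
        "config_digest": config.digest(),
        "seed": config.seed,
        "stages": stages,
        "n_participants": len(cohort.participants),
        "global_lambda": lam,
    }
    write_json(manifest, out / "manifest.json")
    return manifest
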