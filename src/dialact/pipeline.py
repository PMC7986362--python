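"""End-to-end cohort pipeline: simulate -> QC -> impute -> classify -> summarise.

Runs the whole analysis on the synthetic cohort: generate participants
and their epoch-tier accelerometer records, train the balanced forest +
HMM on the labelled "camera subset", detect non-wear, build and impute
minute grids, predict functional behaviours for everyone, and compute
the per-participant and cohort summaries the study tables report.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .behavior import (
    STATES,
    BehaviourModel,
    evaluate_model,
    train_balanced_rf,
    viterbi_smooth_batch,
)
from .cohort_stats import (
    ActivitySummary,
    group_mean_se,
    paired_daytype_test,
    summaries_to_frame,
    summarize_participant,
)
from .questionnaires import score_kccq
from .raw_io import EpochSeries
from .synthetic import (
    GeneratorConfig,
    generate_cohort,
    generate_control_pool,
    generate_participant_epochs,
    generate_questionnaires,
)
from .wear_qc import assess_wear, build_minute_grid, detect_nonwear, impute_minute_grid

__all__ = [
    "run_cohort_pipeline",
    "run_control_pipeline",
    "cohort_statistics",
    "replicate_seeds",
    "AGE_TERTILE_BOUNDS",
    "age_third",
]

# cohort age-third boundaries (years); thirds are <=62, 62-74, >74
AGE_TERTILE_BOUNDS = (62.0, 74.0)


def age_third(age: float) -> str:
    if age <= AGE_TERTILE_BOUNDS[0]:
        return "young"
    if age <= AGE_TERTILE_BOUNDS[1]:
        return "middle"
    return "old"


def replicate_seeds(base_seed: int, n: int = 3) -> list[int]:
    """The documented seed set: ``n`` replicate-cohort seeds derived from one.

    Cohort-level recovery statistics average over replicate synthetic
    cohorts, since a single n=73 draw leaves subgroup means dominated by
    sampling noise. Seeds stay below 2**31.
    """
    return [(base_seed + k * 1_000_003) % 2**31 for k in range(n)]


def cohort_statistics(df: pd.DataFrame) -> dict[str, tuple[float, int]]:
    """Headline (value, n) statistics of one cohort summary frame."""
    young = df[df.age_third == "young"]
    old = df[df.age_third == "old"]
    weak = df[df.leg_weakness]
    return {
        "vm_overall": (float(df["vm_overall"].mean()), len(df)),
        "vm_dialysis": (float(df["vm_dialysis"].mean()), len(df)),
        "vm_non-dialysis": (float(df["vm_non-dialysis"].mean()), len(df)),
        "hours_walking": (float(df["hours_walking_overall"].mean()), len(df)),
        "hours_sedentary": (float(df["hours_sedentary_overall"].mean()), len(df)),
        "hours_sleep": (float(df["hours_sleep_overall"].mean()), len(df)),
        "vm_young_third": (float(young["vm_overall"].mean()), len(young)),
        "vm_old_third": (float(old["vm_overall"].mean()), len(old)),
        "vm_leg_weakness": (float(weak["vm_overall"].mean()), len(weak)),
    }


def _full_day_slices(epochs: EpochSeries) -> tuple[list[slice], list[slice]]:
    """Split an epoch record into per-calendar-day slices (full vs partial)."""
    idx = pd.DatetimeIndex(epochs.start)
    dates = idx.normalize()
    full, partial = [], []
    per_day = 2880
    start = 0
    for _, count in dates.value_counts().sort_index().items():
        sl = slice(start, start + count)
        (full if count == per_day else partial).append(sl)
        start += count
    return full, partial


def _predict_states(
    all_epochs: list[EpochSeries], model: BehaviourModel, batch: int = 500_000
) -> list[np.ndarray]:
    """Forest argmax labels for every epoch, HMM-smoothed day by day."""
    sizes = [len(ep) for ep in all_epochs]
    X = np.concatenate([ep.features for ep in all_epochs])
    pred = np.empty(len(X), dtype=np.int8)
    for lo in range(0, len(X), batch):
        sl = slice(lo, min(lo + batch, len(X)))
        pred[sl] = model.forest.predict(X[sl]).astype(np.int8)

    offsets = np.concatenate([[0], np.cumsum(sizes)])
    day_windows = []
    for i, ep in enumerate(all_epochs):
        full, _ = _full_day_slices(ep)
        day_windows += [
            (offsets[i] + sl.start, offsets[i] + sl.stop) for sl in full
        ]
    if day_windows:
        obs = np.stack([pred[a:b] for a, b in day_windows]).astype(int)
        smoothed = viterbi_smooth_batch(obs, model)
        for (a, b), row in zip(day_windows, smoothed):
            pred[a:b] = row
    out, names = [], np.asarray(model.states, dtype=object)
    for i in range(len(all_epochs)):
        out.append(names[pred[offsets[i] : offsets[i + 1]]])
    return out


def _camera_training_data(
    all_epochs: list[EpochSeries], camera_ids: list[int], camera_days: int
) -> tuple[np.ndarray, np.ndarray, list[np.ndarray]]:
    """Labelled worn epochs from the camera subset's first full wear days."""
    X_parts, y_parts, sequences = [], [], []
    for i in camera_ids:
        ep = all_epochs[i]
        full, _ = _full_day_slices(ep)
        for sl in full[:camera_days]:
            worn = ep.wear[sl]
            X_parts.append(ep.features[sl][worn])
            y_parts.append(ep.label[sl][worn])
            sequences.append(ep.label[sl][worn])
    return np.concatenate(X_parts), np.concatenate(y_parts), sequences


def run_cohort_pipeline(
    config: GeneratorConfig | None = None,
    seed: int | None = None,
    with_questionnaires: bool = True,
) -> dict:
    """Run the full dialysis-cohort analysis on synthetic data.

    Returns a dict with the participant records, truth table, trained
    model, classification metrics, per-participant summary frame (merged
    with demographics), cohort mean (SE) tables and the paired day-type
    tests. Deterministic given ``config.seed`` / ``seed``.
    """
    if config is None:
        config = GeneratorConfig()
    if seed is not None:
        config = config.replace(seed=seed)

    records, truth = generate_cohort(config)
    all_epochs = [
        generate_participant_epochs(rec, truth.iloc[i], config)
        for i, rec in enumerate(records)
    ]

    rng = np.random.default_rng([config.seed, 555])
    camera_ids = sorted(
        rng.choice(len(records), size=min(config.camera_subset_size, len(records)), replace=False)
    )
    X_cam, y_cam, seqs = _camera_training_data(all_epochs, camera_ids, config.camera_days)
    model = train_balanced_rf(
        X_cam, y_cam, sequences=seqs, n_trees=100, seed=int(rng.integers(2**31 - 1))
    )

    predicted = _predict_states(all_epochs, model)
    truth_labels = np.concatenate([ep.label[ep.wear] for ep in all_epochs])
    pred_labels = np.concatenate([p[ep.wear] for p, ep in zip(predicted, all_epochs)])
    metrics = evaluate_model(pred_labels, truth_labels)

    summaries: list[ActivitySummary] = []
    wear_reports, grids, included = [], [], []
    for rec, ep, pred in zip(records, all_epochs, predicted):
        ep_pred = EpochSeries(
            epoch_length_s=ep.epoch_length_s,
            start=ep.start,
            vm_mg=ep.vm_mg,
            wear=ep.wear,
            stationary=ep.stationary,
            label=pred,
            features=None,
        )
        ep_pred = detect_nonwear(ep_pred)
        grid = build_minute_grid(ep_pred, rec)
        report = assess_wear(grid)
        wear_reports.append(report)
        if not report.excellent_both_daytypes:
            continue
        grid = impute_minute_grid(grid)
        grids.append(grid)
        included.append(rec)
        summaries.append(summarize_participant(grid))

    df = summaries_to_frame(summaries)
    demo = pd.DataFrame(
        {
            "id": [r.id for r in included],
            "age": [r.age for r in included],
            "sex": [r.sex for r in included],
            "leg_weakness": [r.leg_weakness for r in included],
            "slot": [r.slot for r in included],
            "age_third": [age_third(r.age) for r in included],
        }
    )
    df = demo.merge(df, on="id")

    if with_questionnaires:
        truth_by_id = truth.set_index("id")
        qrows = []
        for rec in included:
            kccq, eq5d = generate_questionnaires(
                rec,
                float(truth_by_id.loc[rec.id, "vm_overall"]),
                config,
                rng=np.random.default_rng([config.seed, 777, int(rec.id[1:])]),
            )
            scores = score_kccq(kccq).as_dict()
            scores["id"] = rec.id
            scores["eq5d_vas"] = eq5d.vas
            qrows.append(scores)
        df = df.merge(pd.DataFrame(qrows), on="id")

    outcome_cols = [
        c
        for c in df.columns
        if c.startswith("vm_") or c.startswith("hours_")
    ]
    tables = {
        "all": df[outcome_cols].agg(["mean", "sem", "count"]).T,
        "by_age_third": group_mean_se(df, "age_third", outcome_cols),
        "by_sex": group_mean_se(df, "sex", outcome_cols),
        "by_leg_weakness": group_mean_se(df, "leg_weakness", outcome_cols),
    }
    paired = {
        out: paired_daytype_test(df, out)
        for out in ("vm", "hours_walking", "hours_sedentary", "hours_sleep")
    }

    return {
        "config": config,
        "records": records,
        "included": included,
        "truth": truth,
        "model": model,
        "metrics": metrics,
        "summaries": df,
        "tables": tables,
        "paired_tests": paired,
        "wear_reports": wear_reports,
        "grids": grids,
    }


def run_control_pipeline(
    scenario: str,
    n: int | None = None,
    config: GeneratorConfig | None = None,
    seed: int | None = None,
    wear_days: int = 7,
) -> dict:
    """Summarise a control pool: generate, QC, impute, average (no classifier).

    Controls have no dialysis days, so no day-type stratification
    applies; the pool mean vector magnitude is the quantity compared
    against the dialysis cohort.
    """
    if config is None:
        config = GeneratorConfig()
    if seed is not None:
        config = config.replace(seed=seed)
    config = config.replace(wear_days=wear_days)
    records, truth = generate_control_pool(scenario, n=n, config=config, seed=config.seed)

    summaries = []
    for i, rec in enumerate(records):
        ep = generate_participant_epochs(
            rec, truth.iloc[i], config, with_features=False
        )
        ep = detect_nonwear(ep)
        grid = build_minute_grid(ep, rec)
        if not assess_wear(grid).excellent_both_daytypes:
            continue
        grid = impute_minute_grid(grid)
        summaries.append(summarize_participant(grid))
    df = summaries_to_frame(summaries)
    return {
        "config": config,
        "records": records,
        "truth": truth,
        "summaries": df,
        "mean_vm": float(df["vm_overall"].mean()),
        "se_vm": float(df["vm_overall"].sem()),
    }
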