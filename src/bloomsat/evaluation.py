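"""Self-contained evaluation studies of the pipeline's statistical behavior.

Each function generates its own synthetic inputs from an explicit seed,
runs the relevant stage(s) and returns the measured quantities: harmonic-fit
exactness, peak-day recovery under monthly binomial observation noise,
two-peak event counts, planted-population clustering agreement, bootstrap
null calibration and detector accuracy.  The studies double as acceptance
checks and as worked examples of the package's expected performance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import clustering, detector, phenology, synthetic
from . import association as assoc
from .radiometry import (BORDER_PIXELS, CORE_PIXELS, NIR_SCALE, grid_shape)

__all__ = [
    "arithmetic_summaries", "harmonic_exactness", "peak_recovery_study",
    "two_peak_study", "clustering_recovery", "bootstrap_calibration",
    "detector_study",
]

#: study conditions of the synthetic recovery experiments: monodominant
#: stands in full synchronized bloom for several weeks, detected almost
#: surely when fully visible
RECOVERY_DURATION = (55.0, 75.0)
RECOVERY_AMPLITUDE = (0.9, 1.0)
RECOVERY_P_DETECT = 0.95


def arithmetic_summaries() -> dict[str, float]:
    """Bookkeeping quantities of the full-scale study, recomputed."""
    rows, cols = grid_shape(10_240, 10_240)
    n_bloom, n_background = 35_541, 123_071
    n_total = n_bloom + n_background
    n_train = int(round(0.8 * n_total))
    n_scenes = 33_798
    patches_per_scene = rows * cols
    total_predictions = n_scenes * patches_per_scene
    return {
        "patch_grid_side": float(rows),
        "patch_side_pixels": float(CORE_PIXELS + 2 * BORDER_PIXELS),
        "nir_scale_constant": round(10_000 / 2_540, 3),
        "nir_scale_used": NIR_SCALE,
        "n_training_images": float(n_total),
        "n_train_split": float(n_train),
        "class_weight_ratio": round(
            detector.class_weight_ratio(n_background, n_bloom), 1),
        "total_patch_predictions": float(total_predictions),
        "prediction_years_at_1s": round(
            total_predictions / (365 * 24 * 3600), 2),
    }


def harmonic_exactness(seed: int = 0) -> dict[str, float]:
    """Fit a noiseless series of the three-harmonic family and measure the
    worst parameter error, the weighted R^2 and the agreement between the
    amplitude/phase parameterization and the exact linear solution."""
    rng = np.random.default_rng(seed)
    truth = dict(bloom0=0.8, pow0=2.0, p4=0.15, p6=0.25, p12=0.6,
                 rho4=0.7, rho6=-0.4, rho12=1.1)
    t = np.arange(1, 37, dtype=float)
    y = truth["bloom0"] + truth["pow0"] * sum(
        truth[f"p{p}"] * np.sin(2 * np.pi * t / p + truth[f"rho{p}"])
        for p in (4, 6, 12))
    w = rng.uniform(0.5, 2.0, 36)
    fit = phenology.fit_bloom_model(phenology.CleanedSeries(y, w, 0.0))
    param_err = max(abs(getattr(fit, k) - v) for k, v in truth.items())
    # independent linear solve in the harmonic basis
    X = np.column_stack(
        [np.ones(36)] + [f(2 * np.pi * t / p) for p in (4, 6, 12)
                         for f in (np.sin, np.cos)])
    sw = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    linear_diff = float(np.max(np.abs(fit.predict(t) - X @ beta)))
    return {
        "max_param_error": float(param_err),
        "weighted_r2": float(fit.weighted_r2),
        "linear_agreement_max_diff": linear_diff,
    }


def _single_pixel_world(peak, duration, amplitude, seed):
    cfg = synthetic.WorldConfig(
        grid_rows=1, grid_cols=1, patch_pixels=8,
        populations=(synthetic.PopulationConfig(
            peak, duration, amplitude, 0.0, 0.0, 1.0),),
        background_fraction=1.0, peak_jitter_days=0.0, seed=seed)
    return synthetic.generate_world(cfg)


def peak_recovery_study(seed: int = 0, n_pixels: int = 200
                        ) -> dict[str, float]:
    """Daily observations for one year (30 per month) with binomial
    detection noise; measures how often the recovered peak day lands within
    5 days of the truth."""
    rng = np.random.default_rng(seed)
    errors = []
    for i in range(n_pixels):
        peak = int(rng.integers(1, 366))
        dur = float(rng.uniform(*RECOVERY_DURATION))
        amp = float(rng.uniform(*RECOVERY_AMPLITUDE))
        world = _single_pixel_world(peak, dur, amp,
                                    int(rng.integers(2 ** 31)))
        obs = synthetic.simulate_observations(
            world, list(range(1, 366)), p_detect=RECOVERY_P_DETECT,
            cloud_prob=0.0, seed=int(rng.integers(2 ** 31)))
        result = phenology.analyze_pixel(
            phenology.monthly_series(obs.dates, obs.pixel(0, 0)))
        if result is None or not result[2]:
            errors.append(365.0)
            continue
        _, _, events = result
        truth_peak = world.phenology["peak_day"].iloc[0]
        main = max(events, key=lambda e: e.peak_value)
        errors.append(abs((main.peak_day - truth_peak + 182.5) % 365
                          - 182.5))
    errors = np.asarray(errors)
    return {
        "pct_within_5_days": float(100.0 * (errors <= 5).mean()),
        "median_error_days": float(np.median(errors)),
        "n": n_pixels,
    }


def two_peak_study(seed: int = 0, n_pixels: int = 200) -> dict[str, float]:
    """Pixels belonging to two populations with peaks at least 90 days
    apart; measures how often exactly two bloom events are recovered."""
    rng = np.random.default_rng(seed)
    n_events = []
    for i in range(n_pixels):
        p1 = int(rng.integers(1, 366))
        gap = int(rng.integers(90, 183))
        p2 = (p1 + gap - 1) % 365 + 1
        pops = tuple(
            synthetic.PopulationConfig(
                p, float(rng.uniform(*RECOVERY_DURATION)),
                float(rng.uniform(*RECOVERY_AMPLITUDE)), 0.0, 0.0, 1.0)
            for p in (p1, p2))
        cfg = synthetic.WorldConfig(
            grid_rows=1, grid_cols=1, patch_pixels=8, populations=pops,
            background_fraction=1.0, two_peak_fraction=1.0,
            peak_jitter_days=0.0, seed=int(rng.integers(2 ** 31)))
        world = synthetic.generate_world(cfg)
        if len(world.phenology) != 2:
            continue
        obs = synthetic.simulate_observations(
            world, list(range(1, 366)), p_detect=RECOVERY_P_DETECT,
            cloud_prob=0.0, seed=int(rng.integers(2 ** 31)))
        result = phenology.analyze_pixel(
            phenology.monthly_series(obs.dates, obs.pixel(0, 0)))
        n_events.append(0 if result is None else len(result[2]))
    n_events = np.asarray(n_events)
    return {
        "pct_exactly_two_events": float(100.0 * (n_events == 2).mean()),
        "n": int(n_events.size),
    }


def clustering_recovery(seed: int = 0, n_seeds: int = 20
                        ) -> dict[str, float]:
    """Three planted populations (peaks 50/170/330, disjoint centers);
    measures the adjusted Rand agreement of seeded K-means with the truth."""
    from sklearn.metrics import adjusted_rand_score

    scores = []
    for s in range(n_seeds):
        rng = np.random.default_rng(seed * 1000 + s)
        rows = []
        for label, (peak, cx, cy) in enumerate(
                [(50, 3.0e5, 7.4e6), (170, 9.0e5, 7.9e6),
                 (330, 3.0e5, 7.9e6)]):
            n = 40
            rows.append(pd.DataFrame({
                "pixel_id": np.arange(n) + 100 * label,
                "start_day": peak - 30 + rng.normal(0, 3, n),
                "peak_day": peak + rng.normal(0, 3, n),
                "end_day": peak + 30 + rng.normal(0, 3, n),
                "start_value": np.zeros(n),
                "peak_value": rng.uniform(4, 8, n),
                "end_value": np.zeros(n),
                "x_m": cx + rng.uniform(-5e4, 5e4, n),
                "y_m": cy + rng.uniform(-5e4, 5e4, n),
                "truth": label,
            }))
        events = pd.concat(rows, ignore_index=True)
        table = clustering.build_feature_table(
            events.drop(columns="truth"),
            events[["pixel_id", "x_m", "y_m"]])
        model = clustering.cluster_populations(table, k=3, seed=s)
        scores.append(adjusted_rand_score(events["truth"],
                                          model.assignments))
    return {"mean_adjusted_rand": float(np.mean(scores)),
            "n_seeds": n_seeds}


def bootstrap_calibration(seed: int = 0, n_trials: int = 100,
                          n_presence: int = 500, n_boot: int = 100
                          ) -> dict[str, float]:
    """Null calibration: presence drawn uniformly at random, so each decile
    class should be flagged significant about 5% of the time."""
    rng = np.random.default_rng(seed)
    cov = rng.uniform(0, 1, 10_000)
    classes = assoc.quantile_classes(cov.reshape(100, 100), 10)
    domain = classes.labels.ravel()
    rejections, total = 0, 0
    for trial in range(n_trials):
        labels = domain[rng.integers(0, domain.size, n_presence)]
        res = assoc.bootstrap_association(
            labels, classes, n_boot=n_boot,
            seed=int(rng.integers(2 ** 31)))
        rejections += int(res["significant"].sum())
        total += len(res)
    return {
        "rejection_pct": float(100.0 * rejections / total),
        "n_tests": total,
    }


def detector_study(seed: int = 0, n_patches: int = 500,
                   epochs: int = 30) -> dict[str, float]:
    """Train the tiny encoder on separable synthetic patches and measure
    the weighted validation accuracy and the agreement with the
    deterministic color-rule oracle on a fresh unambiguous set."""
    X, y = synthetic.make_patch_dataset(n_patches, side=32, seed=seed)
    config = detector.DetectorConfig(
        n_blocks=2, filters_per_block=(8, 16), dense_units=32,
        dropout_rate=0.2, learning_rate=1e-3, batch_size=32,
        epochs=epochs, input_side=32, seed=seed)
    model = detector.build_detector(config)
    model, history = detector.train_detector(model, X, y, config)
    X_new, _ = synthetic.make_patch_dataset(200, side=32, seed=seed + 1)
    oracle = np.array([detector.reference_color_detector(p)
                       for p in X_new])
    preds = detector.predict_patches(model, X_new)
    return {
        "validation_accuracy_pct":
            float(100.0 * history.best_weighted_accuracy),
        "best_epoch": float(history.best_epoch),
        "oracle_agreement_pct": float(100.0 * (preds == oracle).mean()),
        "n": n_patches,
    }
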