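"""K-means grouping of flowering events into phenological populations.

One feature row per bloom event (a two-peak pixel contributes two rows):
start/peak/end day-of-year, the bloom values at those days, and the pixel's
metric xy coordinates divided by 100,000 and rounded to the nearest unit.
The coordinate down-scaling keeps location from dominating the variance so
clusters reflect flowering timing rather than mere pixel distance.  All
features are centered and scaled before K-means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.preprocessing import StandardScaler

__all__ = ["FEATURE_COLUMNS", "ClusterModel", "build_feature_table",
           "cluster_populations"]

FEATURE_COLUMNS = [
    "start_day", "peak_day", "end_day",
    "start_value", "peak_value", "end_value",
    "x_scaled", "y_scaled",
]

COORD_DIVISOR = 100_000.0


@dataclass
class ClusterModel:
    """Fitted K-means populations with the within-SS curve used to pick k."""

    k: int
    centroids: np.ndarray          # in standardized feature space
    assignments: np.ndarray        # cluster label per feature row
    within_ss_curve: np.ndarray    # total within-cluster SS for k = 1..k_max
    seed: int
    rows: pd.DataFrame

    def summary(self) -> pd.DataFrame:
        """Per-cluster size, share (%) and mean/modal member peak date."""
        out = []
        n = len(self.assignments)
        for c in range(self.k):
            sel = self.assignments == c
            peaks = self.rows.loc[sel, "peak_day"]
            out.append({
                "cluster": c,
                "n": int(sel.sum()),
                "pct": 100.0 * sel.sum() / n,
                "mean_peak_day": float(peaks.mean()),
                "modal_peak_day": float(peaks.round().mode().iloc[0])
                if sel.any() else float("nan"),
            })
        return pd.DataFrame(out)


def build_feature_table(
    events: pd.DataFrame, coordinates_m: pd.DataFrame
) -> pd.DataFrame:
    """Join events with pixel coordinates and add the down-scaled xy columns.

    ``events`` needs columns pixel_id, start_day, peak_day, end_day,
    start_value, peak_value, end_value (one row per event);
    ``coordinates_m`` needs pixel_id, x_m, y_m in metres.
    """
    required = {"pixel_id", "start_day", "peak_day", "end_day",
                "start_value", "peak_value", "end_value"}
    missing = required - set(events.columns)
    if missing:
        raise ValueError(f"events table missing columns: {sorted(missing)}")
    if events.empty:
        return events.assign(x_scaled=pd.Series(dtype=float),
                             y_scaled=pd.Series(dtype=float))
    events = events.drop(
        columns=[c for c in ("x_m", "y_m", "x_scaled", "y_scaled")
                 if c in events.columns])
    merged = events.merge(coordinates_m[["pixel_id", "x_m", "y_m"]],
                          on="pixel_id", how="left", validate="many_to_one")
    if merged[["x_m", "y_m"]].isna().any().any():
        bad = merged.loc[merged["x_m"].isna(), "pixel_id"].unique()
        raise ValueError(f"events without coordinates: pixels {bad[:5]}")
    merged["x_scaled"] = np.round(merged["x_m"] / COORD_DIVISOR)
    merged["y_scaled"] = np.round(merged["y_m"] / COORD_DIVISOR)
    return merged


def _elbow_k(within_ss: np.ndarray, threshold: float) -> int:
    """Largest k whose relative within-SS decrease over k-1 exceeds the
    threshold (defaults to 2%); k=1 when no step qualifies."""
    k = 1
    for i in range(1, within_ss.size):
        prev = within_ss[i - 1]
        if prev <= 0:
            break
        if (prev - within_ss[i]) / prev > threshold:
            k = i + 1
    return k


def cluster_populations(
    rows: pd.DataFrame,
    k: int | None = None,
    k_max: int = 15,
    seed: int = 0,
    elbow_threshold: float = 0.02,
    n_init: int = 10,
    max_iter: int = 300,
) -> ClusterModel:
    """Standardize the feature table and run seeded K-means.

    When ``k`` is None the within-SS curve for k = 1..k_max is computed and
    k is the largest cluster count still giving a relative within-SS
    improvement above ``elbow_threshold`` (favouring the maximum number of
    clusters the curve supports).
    """
    X = rows[FEATURE_COLUMNS].to_numpy(float)
    if X.shape[0] == 0:
        raise ValueError("no feature rows to cluster")
    scaler = StandardScaler()
    sd = X.std(axis=0)
    Xs = np.where(sd > 0, scaler.fit_transform(X), 0.0)
    k_max = min(k_max, X.shape[0])
    if k is not None and k > X.shape[0]:
        raise ValueError(f"k={k} exceeds the {X.shape[0]} rows")
    curve = np.empty(k_max)
    models = {}
    for kk in range(1, k_max + 1):
        km = KMeans(n_clusters=kk, n_init=n_init, max_iter=max_iter,
                    random_state=seed).fit(Xs)
        curve[kk - 1] = km.inertia_
        models[kk] = km
    if k is None:
        k = _elbow_k(curve, elbow_threshold)
    if k in models:
        km = models[k]
    else:
        km = KMeans(n_clusters=k, n_init=n_init, max_iter=max_iter,
                    random_state=seed).fit(Xs)
    return ClusterModel(
        k=k, centroids=km.cluster_centers_, assignments=km.labels_,
        within_ss_curve=curve, seed=seed, rows=rows.reset_index(drop=True),
    )
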