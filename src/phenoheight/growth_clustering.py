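"""Cluster accessions by their height trajectories and choose the count.

K-means (Lloyd's algorithm with k-means++ starts, via scikit-learn) on the
raw plots x time-points height matrix, with two cluster-count criteria: the
within-cluster-sum-of-squares elbow and Tibshirani's gap statistic with
uniform-box reference sets. Trajectories are clustered in absolute metres —
what separates accessions here is exactly the scale of their growth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans


@dataclass
class ClusterResult:
    assignments: np.ndarray  # per-accession cluster id, 0..k-1
    centers: np.ndarray  # k x n_times
    wcss: float  # within-cluster sum of squares (inertia)
    k: int
    seed: int


@dataclass
class GapResult:
    k_values: np.ndarray
    gap: np.ndarray
    sk: np.ndarray  # reference-set standard error per k
    log_wk: np.ndarray
    chosen_k: int  # one-standard-error rule (first k where the gap levels off)
    argmax_k: int  # raw argmax of the gap curve


def impute_series(series: np.ndarray) -> np.ndarray:
    """Mean-impute undefined trajectory cells per time point."""
    out = np.array(series, dtype=float)
    col_mean = np.nanmean(out, axis=0)
    idx = np.where(np.isnan(out))
    out[idx] = col_mean[idx[1]]
    return out


def kmeans(
    series: np.ndarray, k: int, seed: int = 0, n_init: int = 10
) -> ClusterResult:
    """Best-of-``n_init`` k-means++ runs by within-cluster sum of squares."""
    series = np.asarray(series, dtype=float)
    if k < 1:
        raise ValueError("k must be at least 1")
    if k > series.shape[0]:
        raise ValueError("more clusters than accessions")
    if np.isnan(series).any():
        raise ValueError("undefined cells present: impute or drop first")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, random_state=seed)
    labels = km.fit_predict(series)
    return ClusterResult(labels, km.cluster_centers_, float(km.inertia_), k, seed)


def elbow_curve(
    series: np.ndarray, k_range: list[int], seed: int = 0, n_init: int = 10
) -> tuple[pd.DataFrame, int | None]:
    """WCSS per k plus a largest-second-difference elbow suggestion.

    The suggestion needs at least three consecutive k values; with fewer,
    None is returned.
    """
    k_range = sorted(k_range)
    if not k_range:
        raise ValueError("k_range is empty")
    wcss = [kmeans(series, k, seed=seed, n_init=n_init).wcss for k in k_range]
    df = pd.DataFrame({"k": k_range, "wcss": wcss})
    if len(k_range) < 3:
        return df, None
    second_diff = np.diff(wcss, 2)  # convexity: big value = sharp bend at k[i+1]
    return df, int(k_range[int(np.argmax(second_diff)) + 1])


def _dispersion(X: np.ndarray, labels: np.ndarray, power: int) -> float:
    """Pooled within-cluster dispersion W_k = sum_r D_r / (2 n_r), with D_r
    the summed (plain or squared) pairwise distances inside cluster r.
    ``power`` = 2 recovers the within-cluster sum of squares."""
    from scipy.spatial.distance import pdist

    total = 0.0
    for c in np.unique(labels):
        member = X[labels == c]
        if len(member) > 1:
            total += (pdist(member) ** power).sum() / len(member)
    return 0.5 * total


def gap_statistic(
    series: np.ndarray,
    k_range: list[int],
    B: int = 50,
    seed: int = 0,
    n_init: int = 10,
    d_power: int = 1,
) -> GapResult:
    """Tibshirani gap statistic with uniform reference sets.

    gap(k) = E*[log Wk] - log Wk, with Wk the pooled within-cluster
    dispersion of the k-means partition and the expectation estimated from
    ``B`` datasets drawn uniformly over the box spanned by the data in its
    principal-component basis (the reference recommended for elongated
    clouds, which growth trajectories are). ``d_power`` = 1 — plain rather
    than squared pairwise distances, the default of the reference R
    implementation — keeps the gap from creeping upward when k-means splits
    an elongated cluster. The reported optimum is where the gap curve
    reaches its ceiling: the smallest k with gap(k) >= gap(k+1) - s(k+1)
    (the one-standard-error rule). The raw argmax is also reported.
    """
    series = np.asarray(series, dtype=float)
    if B < 1:
        raise ValueError("need at least one reference set")
    k_range = sorted(k_range)
    if not k_range:
        raise ValueError("k_range is empty")
    rng = np.random.default_rng(seed)
    n, d = series.shape
    mu = series.mean(axis=0)
    _, _, Vt = np.linalg.svd(series - mu, full_matrices=False)
    rotated = (series - mu) @ Vt.T
    lo = rotated.min(axis=0)
    hi = rotated.max(axis=0)

    def log_disp(X: np.ndarray, k: int, km_seed: int) -> float:
        labels = kmeans(X, k, seed=km_seed, n_init=n_init).assignments
        return float(np.log(_dispersion(X, labels, d_power)))

    log_wk = np.array([log_disp(series, k, seed) for k in k_range])
    ref_log = np.empty((B, len(k_range)))
    for b in range(B):
        ref = rng.uniform(lo, hi, size=(n, d)) @ Vt + mu
        ref_seed = int(rng.integers(0, 2**31 - 1))
        for j, k in enumerate(k_range):
            ref_log[b, j] = log_disp(ref, k, ref_seed)
    gap = ref_log.mean(axis=0) - log_wk
    sk = ref_log.std(axis=0) * np.sqrt(1.0 + 1.0 / B)
    argmax_k = int(k_range[int(np.argmax(gap))])
    chosen = argmax_k
    for j in range(len(k_range) - 1):
        if gap[j] >= gap[j + 1] - sk[j + 1]:
            chosen = int(k_range[j])
            break
    return GapResult(np.array(k_range), gap, sk, log_wk, chosen, argmax_k)


def cluster_dynamics(result: ClusterResult, series: np.ndarray) -> pd.DataFrame:
    """Per-cluster mean trajectory, size, peak height, and growth rate.

    Clusters are reported sorted by mean growth rate (mean height gain per
    time step), the ordering used to name slow-to-fast growth groups.
    """
    series = np.asarray(series, dtype=float)
    rows = []
    for c in range(result.k):
        members = result.assignments == c
        if not members.any():
            raise ValueError(f"cluster {c} is empty")
        curve = series[members].mean(axis=0)
        rate = float(np.diff(curve).mean())
        rows.append(
            {
                "cluster": c,
                "n": int(members.sum()),
                "mean_curve": curve,
                "max_height": float(curve.max()),
                "time_of_max": int(np.argmax(curve)),
                "growth_rate": rate,
            }
        )
    df = pd.DataFrame(rows).sort_values("growth_rate").reset_index(drop=True)
    df["rate_rank"] = np.arange(1, len(df) + 1)
    return df
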