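"""Dynamic FNC state analysis.

Windowed connectivity samples (or their latent features) are clustered with
k-means into recurring brain states; the number of states is picked by an
elbow criterion on the mean sample-to-centroid L2 distance over k = 2..9.
Per group the analysis yields element-wise median state matrices, dwell
times (windows in a state per subject visiting it), and transition
probability matrices over consecutive windows with self-transitions
excluded, plus the group-difference statistics on each.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests


@dataclass
class StateModel:
    """k-means result over windowed samples.

    ``assignments`` carries one row per (subject, window) with the 1-based
    state label; ``inertia_curve`` maps k -> mean L2 distance when the model
    came from an elbow search.
    """

    k: int
    centroids: np.ndarray
    assignments: pd.DataFrame  # columns: subject_id, window_index, group, state
    mean_l2: float
    inertia_curve: dict[int, float] = field(default_factory=dict)
    elbow_warning: bool = False


def _mean_l2(X: np.ndarray, labels: np.ndarray, centroids: np.ndarray) -> float:
    return float(np.mean(np.linalg.norm(X - centroids[labels], axis=1)))


def cluster_latent(Z: np.ndarray, k: int, seed: int = 0,
                   subject_ids=None, window_indices=None, groups=None,
                   n_init: int = 50) -> StateModel:
    """k-means (k-means++ init, ``n_init`` restarts, fixed seed) on pooled
    windowed features of all groups."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    n = Z.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"need at least k={k} samples, got {n}")
    km = KMeans(n_clusters=k, random_state=seed, n_init=n_init)
    labels = km.fit_predict(Z)
    df = pd.DataFrame({
        "subject_id": subject_ids if subject_ids is not None else np.arange(n),
        "window_index": window_indices if window_indices is not None else np.zeros(n, int),
        "group": groups if groups is not None else ["all"] * n,
        "state": labels + 1,
    })
    return StateModel(k=k, centroids=km.cluster_centers_, assignments=df,
                      mean_l2=_mean_l2(Z, labels, km.cluster_centers_))


def select_k_elbow(Z: np.ndarray, k_range=range(2, 10), seed: int = 0,
                   n_init: int = 50, **assign_kwargs) -> StateModel:
    """Fit every k in ``k_range`` and keep the elbow of the mean-L2 curve.

    The elbow is operationalized as the k maximizing the discrete second
    difference of the curve (the sharpest bend); the endpoints of the range
    cannot host a second difference and are only selected when the curve is
    monotone-flat, in which case the smallest k is returned with
    ``elbow_warning=True``.
    """
    ks = sorted(k_range)
    if len(ks) < 3:
        raise ValueError("k_range must contain at least three values")
    models = {k: cluster_latent(Z, k, seed=seed, n_init=n_init, **assign_kwargs)
              for k in ks}
    curve = {k: models[k].mean_l2 for k in ks}
    k_star, warning = elbow_point(curve)
    if warning:
        warnings.warn("inertia curve has no clear elbow; returning smallest k")
    best = models[k_star]
    best.inertia_curve = curve
    best.elbow_warning = warning
    return best


def elbow_point(curve: dict[int, float], flat_ratio: float = 0.2
                ) -> tuple[int, bool]:
    """Sharpest-bend k of an inertia curve: argmax of the discrete second
    difference.

    The warning flag marks curves without a real elbow: either no positive
    curvature anywhere, or the curve keeps decreasing after the bend — the
    mean post-bend slope exceeding ``flat_ratio`` of the mean pre-bend slope
    (a single Gaussian yields ratios around 0.3; well-separated planted
    clusters around 0.05).
    """
    ks = sorted(curve)
    d2 = {k: curve[km1] - 2 * curve[k] + curve[kp1]
          for km1, k, kp1 in zip(ks[:-2], ks[1:-1], ks[2:])}
    if not d2 or max(d2.values()) <= 0:
        return ks[0], True
    k_star = max(d2, key=lambda k: (d2[k], -k))
    pre = (curve[ks[0]] - curve[k_star]) / (k_star - ks[0])
    post = (curve[k_star] - curve[ks[-1]]) / (ks[-1] - k_star)
    warning = pre <= 0 or (post / pre) > flat_ratio
    return k_star, warning


def posterior_sample_decode(model, X: np.ndarray, seed: int = 0) -> np.ndarray:
    """One decoded posterior draw z ~ q(z|x) per sample (delegates to the
    trained VAE; kept here as the dFNC-generation entry point)."""
    return model.posterior_sample_decode(X, seed=seed)


def state_medians(vectors: np.ndarray, assignments: pd.DataFrame
                  ) -> dict[tuple[str, int], np.ndarray]:
    """Element-wise median vector per (group, state) cell.

    Cells with no members are simply absent from the result (callers can
    compare key sets to detect them).
    """
    vectors = np.atleast_2d(np.asarray(vectors, dtype=float))
    assignments = assignments.reset_index(drop=True)
    out = {}
    for (group, state), idx in assignments.groupby(
            ["group", "state"], sort=True).groups.items():
        out[(group, int(state))] = np.median(vectors[np.asarray(idx)], axis=0)
    return out


def order_and_match_states(
    original: StateModel,
    generated_medians: dict[tuple[str, int], np.ndarray],
    original_medians: dict[tuple[str, int], np.ndarray],
    control_group: str = "control",
) -> tuple[dict[int, int], dict[int, int]]:
    """Canonical state ordering and generated-to-original matching.

    Original states are relabeled 1..k in increasing fraction of
    control-group windows (ties broken by state size, then index).
    Generated states are matched one-to-one to the relabeled originals by
    maximizing the summed Pearson similarity between pooled-group median
    vectors (optimal assignment).  Returns (original_relabel, generated_match),
    both old-label -> new-label maps.
    """
    df = original.assignments
    k = original.k
    frac, size = {}, {}
    for s in range(1, k + 1):
        members = df[df["state"] == s]
        size[s] = len(members)
        frac[s] = (members["group"] == control_group).mean() if len(members) else 0.0
    order = sorted(range(1, k + 1), key=lambda s: (frac[s], size[s], s))
    original_relabel = {old: new + 1 for new, old in enumerate(order)}

    def pooled(medians, state):
        vs = [v for (g, s), v in medians.items() if s == state]
        return np.mean(vs, axis=0)

    gen_states = sorted({s for _, s in generated_medians})
    orig_states = sorted({s for _, s in original_medians})
    if len(gen_states) != len(orig_states):
        raise ValueError("generated and original state sets must have equal k")
    sim = np.empty((len(gen_states), len(orig_states)))
    for i, gs in enumerate(gen_states):
        gv = pooled(generated_medians, gs)
        for j, os_ in enumerate(orig_states):
            ov = pooled(original_medians, os_)
            sim[i, j] = np.corrcoef(gv, ov)[0, 1]
    rows, cols = linear_sum_assignment(-sim)
    generated_match = {
        gen_states[i]: original_relabel.get(orig_states[j], orig_states[j])
        for i, j in zip(rows, cols)
    }
    return original_relabel, generated_match


# ---------------------------------------------------------------------------
# dwell time and transitions
# ---------------------------------------------------------------------------

@dataclass
class DynamicsSummary:
    """Group-wise dwell times and transition statistics."""

    dwell: pd.DataFrame          # group, state, n_fnc, n_subj, dwell_time
    per_subject: pd.DataFrame    # group, subject_id, state, n_windows
    counts: dict[str, np.ndarray] | None = None   # group -> k x k N_{a->b}
    P: dict[str, np.ndarray] | None = None        # group -> k x k, diag 0
    flagged_rows: dict[str, list[int]] | None = None


def dwell_time(assignments: pd.DataFrame, k: int | None = None) -> DynamicsSummary:
    """Dwell time per (group, state): windows assigned to the state divided
    by the number of subjects with at least one window there.

    States never visited by a group appear with n_subj = 0 and missing
    dwell time.  Per-subject window counts (zeros included) are retained
    for the group-difference tests.
    """
    k = int(assignments["state"].max()) if k is None else k
    per_subj = []
    for (group, sid), sub in assignments.groupby(["group", "subject_id"], sort=True):
        counts = sub["state"].value_counts()
        for state in range(1, k + 1):
            per_subj.append({"group": group, "subject_id": sid, "state": state,
                             "n_windows": int(counts.get(state, 0))})
    per_subject = pd.DataFrame(per_subj)
    rows = []
    for (group, state), sub in per_subject.groupby(["group", "state"], sort=True):
        visitors = sub[sub["n_windows"] > 0]
        n_fnc = int(sub["n_windows"].sum())
        n_subj = len(visitors)
        rows.append({
            "group": group, "state": state, "n_fnc": n_fnc, "n_subj": n_subj,
            "dwell_time": n_fnc / n_subj if n_subj else np.nan,
        })
    return DynamicsSummary(dwell=pd.DataFrame(rows), per_subject=per_subject)


def transition_counts(assignments: pd.DataFrame, k: int | None = None
                      ) -> dict[str, np.ndarray]:
    """Group-wise transition mass N_{a->b}: per subject the fraction of its
    T-1 consecutive-window moves (self-moves included), averaged over the
    group's subjects; each group's matrix sums to 1."""
    k = int(assignments["state"].max()) if k is None else k
    out = {}
    for group, sub in assignments.groupby("group", sort=True):
        mats = []
        for _, subj in sub.groupby("subject_id", sort=True):
            seq = subj.sort_values("window_index")["state"].to_numpy()
            m = np.zeros((k, k))
            if seq.size >= 2:
                np.add.at(m, (seq[:-1] - 1, seq[1:] - 1), 1.0)
                m /= seq.size - 1
            mats.append(m)
        out[group] = np.mean(mats, axis=0)
    return out


def transition_matrix(counts: np.ndarray) -> tuple[np.ndarray, list[int]]:
    """Conditional cross-state transition probabilities.

    Off-diagonal P(a, b) = N_{a->b} / sum_{c != a} N_{a->c}; the diagonal is
    0 by convention (self-transitions excluded), so every defined row sums
    to 1.  Rows with no outgoing cross-state mass are NaN and their indices
    returned as flagged.
    """
    counts = np.asarray(counts, dtype=float)
    k = counts.shape[0]
    P = np.zeros((k, k))
    flagged = []
    off = counts - np.diag(np.diag(counts))
    for a in range(k):
        total = off[a].sum()
        if total <= 0:
            P[a] = np.nan
            flagged.append(a)
        else:
            P[a] = off[a] / total
            P[a, a] = 0.0
    return P, flagged


def dynamics_summary(assignments: pd.DataFrame, k: int | None = None
                     ) -> DynamicsSummary:
    """Dwell times plus transition counts and probability matrices."""
    k = int(assignments["state"].max()) if k is None else k
    summ = dwell_time(assignments, k)
    summ.counts = transition_counts(assignments, k)
    summ.P, summ.flagged_rows = {}, {}
    for g, c in summ.counts.items():
        summ.P[g], summ.flagged_rows[g] = transition_matrix(c)
    return summ


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------

def state_group_difference(vectors: np.ndarray, assignments: pd.DataFrame,
                           state: int, groups: tuple[str, str] = ("patient", "control"),
                           alpha: float = 0.05,
                           level: str = "window") -> dict:
    """Patient-minus-control difference map for one state with a per-edge
    two-sample t-test, Bonferroni-corrected over the V edges.

    ``level`` "window" pools member windows (default); "subject" first
    averages each subject's windows in the state, avoiding pseudo-replication.
    Returns the median difference vector, t/p arrays and the significance
    mask; if either group is absent from the state, ``skipped`` is True.
    """
    vectors = np.atleast_2d(np.asarray(vectors, dtype=float))
    assignments = assignments.reset_index(drop=True)
    sel = assignments["state"] == state
    out = {"state": state, "skipped": False}
    sides = []
    for g in groups:
        mask = sel & (assignments["group"] == g)
        rows = np.flatnonzero(mask.to_numpy())
        if rows.size == 0:
            return {"state": state, "skipped": True, "missing_group": g}
        if level == "subject":
            sub = assignments.loc[mask]
            mats = [vectors[np.asarray(i)].mean(axis=0)
                    for _, i in sub.groupby("subject_id").groups.items()]
            sides.append(np.vstack(mats))
        else:
            sides.append(vectors[rows])
    a, b = sides  # patient, control
    V = a.shape[1]
    t, p = stats.ttest_ind(a, b, axis=0)
    p_adj = np.minimum(1.0, p * V)
    out.update({
        "difference": np.median(a, axis=0) - np.median(b, axis=0),
        "t": t, "p_raw": p, "p_adjusted": p_adj,
        "significant": p_adj < alpha,
        "n_patient": a.shape[0], "n_control": b.shape[0],
    })
    return out


_STAR_LEVELS = (0.05, 0.01, 0.001, 0.0001)


def dwell_time_tests(per_subject: pd.DataFrame,
                     groups: tuple[str, str] = ("patient", "control"),
                     min_n: int = 2, visitors_only: bool = True) -> pd.DataFrame:
    """Per-state two-sample t-test on per-subject dwell, FDR-corrected
    (Benjamini-Hochberg) over the k states.

    ``visitors_only`` drops subjects that never enter the state, matching
    the dwell-time denominator; states with fewer than ``min_n`` subjects in
    either group are skipped with a flag.  Stars count the significance
    levels 0.05, 0.01, 0.001, 0.0001 passed by the adjusted p.
    """
    rows = []
    for state, sub in per_subject.groupby("state", sort=True):
        sides = []
        for g in groups:
            v = sub.loc[sub["group"] == g, "n_windows"].to_numpy(dtype=float)
            if visitors_only:
                v = v[v > 0]
            sides.append(v)
        a, b = sides
        if len(a) < min_n or len(b) < min_n:
            rows.append({"state": state, "skipped": True, "t": np.nan,
                         "p_raw": np.nan, "n_a": len(a), "n_b": len(b),
                         "mean_a": np.nan, "mean_b": np.nan})
            continue
        t, p = stats.ttest_ind(a, b)
        rows.append({"state": state, "skipped": False, "t": float(t),
                     "p_raw": float(p), "n_a": len(a), "n_b": len(b),
                     "mean_a": float(a.mean()), "mean_b": float(b.mean())})
    df = pd.DataFrame(rows)
    tested = ~df["skipped"]
    df["p_adjusted"] = np.nan
    if tested.any():
        df.loc[tested, "p_adjusted"] = multipletests(
            df.loc[tested, "p_raw"], method="fdr_bh")[1]
    df["stars"] = [
        sum(p < lev for lev in _STAR_LEVELS) if np.isfinite(p) else 0
        for p in df["p_adjusted"]
    ]
    return df


def state_midpoint_interpolation(model, centroid_a: np.ndarray,
                                 centroid_b: np.ndarray, draw_count: int = 50,
                                 noise_scale: float = 0.0, seed: int = 0,
                                 alpha: float = 1e-4) -> dict:
    """Generated matrices at two state centroids and their midpoint, plus
    edge-wise signed-rank a-vs-b tests (Bonferroni over V edges)."""
    from .static_interp import TrajectorySpec, interpolate_trajectory, \
        trajectory_edge_tests

    spec = TrajectorySpec(start=np.asarray(centroid_a, float),
                          end=np.asarray(centroid_b, float),
                          n_points=3, draw_count=draw_count,
                          noise_scale=noise_scale)
    draws_a, draws_mid, draws_b = interpolate_trajectory(model, spec, seed=seed)
    return {
        "points": spec.points,
        "draws": {"a": draws_a, "midpoint": draws_mid, "b": draws_b},
        "edge_tests": trajectory_edge_tests(draws_a, draws_b, alpha=alpha),
    }
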