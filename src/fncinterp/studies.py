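"""Reproducible evaluation studies on synthetic ground-truth data.

Each study generates its own data from a seed, runs the relevant part of
the stack, and returns plain numbers: optimal-assignment and PPCA oracle
checks, planted-structure recovery (elbow k, state labels, transition
matrices, dwell-time contrasts), the nonlinear-vs-linear model comparison,
and null calibration of the significance machinery.  The acceptance script
and the test suite both run these.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy.linalg import subspace_angles
from scipy.stats import spearmanr, wilcoxon
from sklearn.metrics import adjusted_rand_score

from .dynamic_states import (cluster_latent, dwell_time, dwell_time_tests,
                             select_k_elbow, state_group_difference,
                             transition_counts, transition_matrix)
from .metrics import reconstruction_metrics
from .ppca import ppca_fit_em, ppca_reconstruct
from .static_interp import assign_to_grid, assignment_cost, make_grid
from .synthetic import (DynamicsSpec, default_state_prototypes,
                        default_transition_truth, nonlinear_continuum_spec,
                        simulate_dfnc, simulate_sfnc)
from .vae import VAE, TrainConfig


def subseed(seed: int, salt: int) -> int:
    """Deterministic independent stream seed below 2^31."""
    return int(np.random.default_rng((seed, salt)).integers(0, 2**31 - 1))


def jv_oracle_study(seed: int, trials: int = 1000) -> dict:
    """Fraction of small assignment instances (N <= 6 on a 3x3 grid) where
    the linear-sum-assignment cost equals the brute-force optimum."""
    rng = np.random.default_rng(subseed(seed, 1))
    grid = make_grid(1.0, side=3)
    agree = 0
    for _ in range(trials):
        n = int(rng.integers(2, 7))
        latents = rng.uniform(-1.3, 1.3, size=(n, 2))
        a = assign_to_grid(latents, grid)
        cost = assignment_cost(latents, grid, a)
        d = np.linalg.norm(latents[:, None, :] - grid.coords[None, :, :], axis=2)
        best = min(sum(d[i, c] for i, c in enumerate(p))
                   for p in itertools.permutations(range(9), n))
        agree += int(abs(cost - best) < 1e-9)
    return {"agreement_fraction": agree / trials, "trials": trials}


def ppca_oracle_study(seed: int, n: int = 2000, v: int = 50, q: int = 2,
                      noise: float = 0.5) -> dict:
    """EM fit on planted linear data vs the eigendecomposition closed form:
    largest principal angle to the true subspace (degrees) and the gap
    between sigma^2 and the mean trailing eigenvalue of the ML covariance."""
    rng = np.random.default_rng(subseed(seed, 2))
    W_true = rng.normal(size=(v, q)) * np.linspace(2.0, 1.2, q)
    X = rng.normal(size=(n, q)) @ W_true.T + rng.normal(scale=noise, size=(n, v))
    model = ppca_fit_em(X, q=q, seed=subseed(seed, 3), tol=1e-10, max_iter=5000)
    X0 = X - X.mean(axis=0)
    ev = np.linalg.eigvalsh(X0.T @ X0 / n)
    return {
        "principal_angle_deg": float(np.degrees(subspace_angles(model.W, W_true)).max()),
        "sigma2_gap": float(abs(model.sigma2 - ev[:-q].mean())),
        "n": n,
    }


def _planted_centers(k: int = 5, radius: float = 6.0) -> np.ndarray:
    ang = np.linspace(0, 2 * np.pi, k + 1)[:k]
    return np.column_stack([np.cos(ang), np.sin(ang)]) * radius


def elbow_recovery_study(seed: int, n_repeats: int = 10, n: int = 1500) -> dict:
    """How often the elbow criterion recovers planted k = 5 (separation ~6
    sigma) over independent draws."""
    centers = _planted_centers(5)
    hits = 0
    for i in range(n_repeats):
        rng = np.random.default_rng(subseed(seed, 10 + i))
        labels = rng.integers(0, 5, size=n)
        Z = centers[labels] + rng.normal(scale=1.0, size=(n, 2))
        sm = select_k_elbow(Z, k_range=range(2, 10), seed=subseed(seed, 30 + i),
                            n_init=10)
        hits += int(sm.k == 5)
    return {"hits": hits, "repeats": n_repeats, "n": n}


def state_ari_study(seed: int, n: int = 1000) -> dict:
    """Adjusted Rand index of k-means labels vs planted well-separated states."""
    centers = _planted_centers(5)
    rng = np.random.default_rng(subseed(seed, 40))
    labels = rng.integers(0, 5, size=n)
    Z = centers[labels] + rng.normal(scale=0.6, size=(n, 2))
    sm = cluster_latent(Z, k=5, seed=subseed(seed, 41), n_init=10)
    return {"ari": float(adjusted_rand_score(labels, sm.assignments["state"])),
            "n": n}


def transition_recovery_study(seed: int, n_subjects: int = 50, T: int = 150,
                              stay: float = 0.6) -> dict:
    """Max absolute error of the estimated cross-state transition matrix vs
    the planted truth at n_subjects x T windows.

    All subjects follow one chain so every off-diagonal estimate rests on
    hundreds of cross-state transitions; the conditional probabilities are
    the noisiest quantity here and splitting the cohort would halve their
    effective counts.
    """
    truth = default_transition_truth(3, stay=stay, patient_state1_stay=stay)
    spec = DynamicsSpec(k_true=3, state_prototypes=default_state_prototypes(3),
                        transition_truth=truth, T=T, window_noise_sd=0.0)
    groups = {f"c{i:02d}": "control" for i in range(n_subjects)}
    _, truth_df = simulate_dfnc(spec, groups, seed=subseed(seed, 50),
                                return_samples=False)
    P_hat, _ = transition_matrix(transition_counts(truth_df, k=3)["control"])
    P_true, _ = transition_matrix(truth["control"])
    err = float(np.nanmax(np.abs(P_hat - P_true)))
    return {"max_abs_err": err, "n": n_subjects * T}


def dwell_flag_study(seed: int, n_repeats: int = 10, n_per_group: int = 20,
                     T: int = 100) -> dict:
    """How often the FDR dwell-time test flags the planted patient-dwells-
    longer-in-state-1 contrast with the correct direction."""
    flags = 0
    for i in range(n_repeats):
        spec = DynamicsSpec(
            k_true=3, state_prototypes=default_state_prototypes(3),
            transition_truth=default_transition_truth(
                3, stay=0.80, patient_state1_stay=0.93),
            T=T, window_noise_sd=0.0)
        groups = {f"c{j:02d}": "control" for j in range(n_per_group)}
        groups |= {f"p{j:02d}": "patient" for j in range(n_per_group)}
        _, tdf = simulate_dfnc(spec, groups, seed=subseed(seed, 60 + i),
                               return_samples=False)
        tests = dwell_time_tests(dwell_time(tdf, k=3).per_subject
                                 ).set_index("state")
        flags += int(tests.loc[1, "p_adjusted"] < 0.05
                     and tests.loc[1, "mean_a"] > tests.loc[1, "mean_b"])
    return {"flags": flags, "repeats": n_repeats, "n": n_per_group * T}


def model_comparison_study(seed: int, n_seeds: int = 10, n_per_group: int = 120,
                           edge_noise_sd: float = 0.02) -> dict:
    """Nonlinear VAE vs linear PPCA (q = 2) on the curved two-group
    continuum: per-seed mean test reconstruction correlation, paired
    one-sided Wilcoxon."""
    spec = nonlinear_continuum_spec(n_per_group=n_per_group,
                                    edge_noise_sd=edge_noise_sd)
    samples, _ = simulate_sfnc(spec, seed=subseed(seed, 70))
    X = np.vstack([s.vector for s in samples])
    rng = np.random.default_rng(subseed(seed, 71))
    idx = rng.permutation(len(X))
    ntr = int(round(0.85 * len(X)))
    tr, te = idx[:ntr], idx[ntr:]
    V = X.shape[1]
    cfg = TrainConfig(max_epochs=250, batch_size=16, kl_weight=0.2 / V)
    vae_r, ppca_r = [], []
    for i in range(n_seeds):
        vm = VAE(V, hidden=(256, 64), seed=subseed(seed, 80 + i))
        vm.fit(X[tr], cfg)
        vae_r.append(float(reconstruction_metrics(
            vm.reconstruct(X[te]), X[te])["pearson_r"].mean()))
        pm = ppca_fit_em(X[tr], 2, seed=subseed(seed, 90 + i))
        ppca_r.append(float(reconstruction_metrics(
            ppca_reconstruct(pm, X[te]), X[te])["pearson_r"].mean()))
    return {
        "vae_r": vae_r,
        "ppca_r": ppca_r,
        "wilcoxon_p": float(wilcoxon(vae_r, ppca_r, alternative="greater").pvalue),
        "wins": int(sum(v > p for v, p in zip(vae_r, ppca_r))),
        "n": 2 * n_per_group,
    }


def latent_alignment_study(seed: int, n_seeds: int = 10, n_per_group: int = 100
                           ) -> dict:
    """Spearman alignment between the planted 1-D severity factor and the
    best-aligned VAE latent coordinate, over model seeds."""
    spec = nonlinear_continuum_spec(n_per_group=n_per_group,
                                    edge_noise_sd=0.02, secondary_sd=0.0)
    samples, meta = simulate_sfnc(spec, seed=subseed(seed, 100))
    X = np.vstack([s.vector for s in samples])
    sev = meta["severity"].to_numpy()
    V = X.shape[1]
    cfg = TrainConfig(max_epochs=200, batch_size=16, kl_weight=0.2 / V)
    rhos = []
    for i in range(n_seeds):
        vm = VAE(V, hidden=(128, 32), seed=subseed(seed, 110 + i))
        vm.fit(X, cfg)
        mu, _ = vm.encode(X)
        rhos.append(max(abs(float(spearmanr(sev, mu[:, 0]).statistic)),
                        abs(float(spearmanr(sev, mu[:, 1]).statistic))))
    return {"rhos": rhos, "median_rho": float(np.median(rhos)),
            "n": 2 * n_per_group}


def null_edge_study(seed: int, n_sims: int = 100, v: int = 45,
                    n_per_group: int = 40, alpha: float = 0.05) -> dict:
    """Family-wise false-positive rate of the Bonferroni edge-wise state
    test when both groups share one distribution."""
    false_pos = 0
    for i in range(n_sims):
        rng = np.random.default_rng(subseed(seed, 200 + i))
        Xn = rng.normal(scale=0.1, size=(2 * n_per_group, v))
        df = pd.DataFrame({
            "subject_id": [f"s{j}" for j in range(2 * n_per_group)],
            "window_index": 0,
            "group": ["patient"] * n_per_group + ["control"] * n_per_group,
            "state": 1})
        res = state_group_difference(Xn, df, state=1, alpha=alpha)
        false_pos += int(res["significant"].any())
    return {"family_fpr": false_pos / n_sims, "sims": n_sims}


def null_dwell_study(seed: int, n_sims: int = 100, n_per_group: int = 15,
                     T: int = 60, alpha: float = 0.05) -> dict:
    """Rate at which any state is flagged by the FDR dwell-time test when
    the two groups follow identical dynamics."""
    truth = default_transition_truth(3, stay=0.8, patient_state1_stay=0.8)
    sig = 0
    for i in range(n_sims):
        spec = DynamicsSpec(k_true=3,
                            state_prototypes=default_state_prototypes(3),
                            transition_truth=truth, T=T, window_noise_sd=0.0)
        groups = {f"c{j:02d}": "control" for j in range(n_per_group)}
        groups |= {f"p{j:02d}": "patient" for j in range(n_per_group)}
        _, tdf = simulate_dfnc(spec, groups, seed=subseed(seed, 400 + i),
                               return_samples=False)
        tests = dwell_time_tests(dwell_time(tdf, k=3).per_subject)
        sig += int((tests["p_adjusted"].dropna() < alpha).any())
    return {"any_state_fpr": sig / n_sims, "sims": n_sims}
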