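"""Synthetic FNC data with known ground truth.

Emulates the statistical structure the interpolation framework assumes:
53-component connectivity matrices organized in 7 functional domains, two
diagnostic groups joined by a continuous severity factor that modulates
block connectivity, and first-order Markov switching among k latent dynamic
states.  Every emitted matrix is an exactly valid correlation matrix —
noise is introduced by drawing a finite Gaussian series with the target
correlation and taking its empirical correlation, so symmetry, unit
diagonal, bounded entries and positive semidefiniteness hold by
construction.

The shipped group prototypes are synthetic fixtures built from the
qualitative contrast the framework targets (patients show reduced positive
connectivity within the auditory, sensorimotor and visual domains and
between the subcortical and cerebellar domains); they are not estimates
from any clinical dataset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable

import numpy as np
import pandas as pd
from statsmodels.stats.correlation_tools import corr_nearest

from .fnc_data import DOMAINS, FNCSample, TimeCourseSet

#: Component counts per functional domain (sums to 53).
DOMAIN_SIZES = {"SC": 5, "AU": 2, "SM": 9, "VI": 9, "CC": 17, "DM": 7, "CB": 4}


def domain_blocks(sizes: dict[str, int] | None = None) -> dict[str, np.ndarray]:
    """Component-index slices per functional domain, in canonical order."""
    sizes = sizes or DOMAIN_SIZES
    blocks, start = {}, 0
    for d in DOMAINS:
        if d not in sizes:
            continue
        blocks[d] = np.arange(start, start + sizes[d])
        start += sizes[d]
    return blocks


def domain_labels(sizes: dict[str, int] | None = None) -> dict[int, str]:
    """Component index -> domain label map matching :func:`domain_blocks`."""
    return {int(i): d for d, idx in domain_blocks(sizes).items() for i in idx}


def _psd_floor(m: np.ndarray, floor: float = 1e-7) -> np.ndarray:
    """Clip eigenvalues at ``floor`` and rescale back to unit diagonal."""
    vals, vecs = np.linalg.eigh((m + m.T) / 2.0)
    if vals.min() >= floor:
        return (m + m.T) / 2.0
    vals = np.clip(vals, floor, None)
    m = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(m))
    m = m / np.outer(d, d)
    np.fill_diagonal(m, 1.0)
    return m


def project_to_correlation(m: np.ndarray, shrink: float = 0.0) -> np.ndarray:
    """Nearest valid correlation matrix (alternating projections), with an
    optional shrink toward the identity to leave an eigenvalue margin."""
    m = (np.asarray(m, float) + np.asarray(m, float).T) / 2.0
    np.fill_diagonal(m, 1.0)
    m = np.clip(m, -0.999, 0.999)
    np.fill_diagonal(m, 1.0)
    with warnings.catch_warnings():
        # the subsequent eigenvalue floor guarantees validity even when the
        # alternating projections stop at their iteration cap
        warnings.simplefilter("ignore")
        out = np.asarray(corr_nearest(m, threshold=1e-8, n_fact=200))
    if shrink > 0:
        out = (1 - shrink) * out + shrink * np.eye(m.shape[0])
    np.fill_diagonal(out, 1.0)
    return _psd_floor(out)


def build_block_prototype(kind: str, sizes: dict[str, int] | None = None) -> np.ndarray:
    """Construct the control or patient group prototype (valid correlation).

    ``kind`` is ``"control"`` or ``"patient"``.  Controls carry strong
    within-domain blocks, positive coupling among the sensory domains
    (AU, SM, VI) and between SC and CB, and negative SC/CB-to-sensory
    coupling; the patient prototype attenuates the within-sensory blocks
    and the SC-CB coupling.
    """
    if kind not in ("control", "patient"):
        raise ValueError("kind must be 'control' or 'patient'")
    blocks = domain_blocks(sizes)
    C = sum(len(v) for v in blocks.values())
    m = np.zeros((C, C))

    within = {d: 0.50 for d in blocks}
    between: dict[tuple[str, str], float] = {}
    for a in ("AU", "SM", "VI"):
        for b in ("AU", "SM", "VI"):
            if a < b:
                between[(a, b)] = 0.30
    between[("SC", "CB")] = 0.30
    for s in ("AU", "SM", "VI"):
        between[("SC", s)] = -0.20
        between[(s, "CB")] = -0.20
    between[("CC", "DM")] = -0.15
    between[("SM", "CC")] = 0.10

    if kind == "patient":
        for d in ("AU", "SM", "VI"):
            within[d] = 0.20                      # reduced within-sensory
        between[("SC", "CB")] = 0.05              # reduced SC-CB
        for s in ("AU", "SM", "VI"):
            between[("SC", s)] = -0.08
            between[(s, "CB")] = -0.08
        between[("CC", "DM")] = -0.25

    for d, idx in blocks.items():
        m[np.ix_(idx, idx)] = within[d]
    for (a, b), v in between.items():
        if a in blocks and b in blocks:
            m[np.ix_(blocks[a], blocks[b])] = v
            m[np.ix_(blocks[b], blocks[a])] = v
    np.fill_diagonal(m, 1.0)
    return project_to_correlation(m, shrink=0.05)


def default_prototypes() -> tuple[np.ndarray, np.ndarray]:
    """Load the shipped synthetic (control, patient) prototype matrices."""
    out = []
    for name in ("synthetic_control_prototype.csv", "synthetic_patient_prototype.csv"):
        with resources.files("fncinterp.data").joinpath(name).open() as fh:
            out.append(np.loadtxt(fh, delimiter=","))
    return out[0], out[1]


def _noisy_correlation(target: np.ndarray, noise_sd: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Empirical correlation of a finite Gaussian series with the target
    correlation; sampling length L ~ 1/noise_sd^2 sets the edge noise level."""
    C = target.shape[0]
    if noise_sd <= 0:
        return target.copy()
    L = max(C + 2, int(round(1.0 / noise_sd**2)))
    chol = np.linalg.cholesky(_psd_floor(target))
    series = rng.standard_normal((L, C)) @ chol.T
    emp = np.corrcoef(series, rowvar=False)
    np.fill_diagonal(emp, 1.0)
    return emp


# ---------------------------------------------------------------------------
# static continuum
# ---------------------------------------------------------------------------

@dataclass
class ContinuumSpec:
    """Two-group static FNC continuum.

    Per subject a severity s in [0, 1] is drawn (controls ~ Beta(2, 8),
    patients ~ Beta(8, 2): overlapping tails, emulating a continuum rather
    than a dichotomy) and the sample is built from the blend
    ``(1 - s) * control + s * patient`` plus an optional secondary latent
    factor, passed through an optional element-wise monotone
    ``nonlinearity``, validity-projected, and perturbed by edge noise.
    """

    n_per_group: int = 100
    base_fnc_control: np.ndarray | None = None
    base_fnc_patient: np.ndarray | None = None
    edge_noise_sd: float = 0.05
    nonlinearity: Callable[[np.ndarray], np.ndarray] | None = None
    severity_beta_control: tuple[float, float] = (2.0, 8.0)
    severity_beta_patient: tuple[float, float] = (8.0, 2.0)
    secondary_matrix: np.ndarray | None = None
    secondary_sd: float = 0.0
    interaction_matrix: np.ndarray | None = None
    #: Additional manifold terms: (coefficient(severity, secondary), contrast
    #: matrix) pairs added to the blend before the nonlinearity.  Nonlinear
    #: coefficient functions (quadratic, interaction, ...) bend the
    #: two-factor manifold so that it spans more linear dimensions than any
    #: two-component linear model can capture.
    extra_terms: list[tuple[Callable[[float, float], float], np.ndarray]] = field(
        default_factory=list)

    def __post_init__(self):
        if self.base_fnc_control is None or self.base_fnc_patient is None:
            c, p = default_prototypes()
            self.base_fnc_control = c if self.base_fnc_control is None else self.base_fnc_control
            self.base_fnc_patient = p if self.base_fnc_patient is None else self.base_fnc_patient
        self.base_fnc_control = np.asarray(self.base_fnc_control, float)
        self.base_fnc_patient = np.asarray(self.base_fnc_patient, float)
        if self.base_fnc_control.shape != self.base_fnc_patient.shape:
            raise ValueError("prototypes must share a shape")

    @property
    def n_components(self) -> int:
        return self.base_fnc_control.shape[0]


def continuum_matrix(spec: ContinuumSpec, severity: float,
                     secondary: float = 0.0) -> np.ndarray:
    """Noiseless continuum matrix at a given severity (and secondary factor).

    Severity 0 with identity nonlinearity reproduces the control prototype;
    severity 1 the patient prototype; 0.5 their element-wise mean (up to the
    validity projection).
    """
    m = spec.base_fnc_control + severity * (spec.base_fnc_patient - spec.base_fnc_control)
    if spec.secondary_matrix is not None and secondary != 0.0:
        m = m + secondary * spec.secondary_matrix
    if spec.interaction_matrix is not None and secondary != 0.0:
        m = m + (severity * secondary) * spec.interaction_matrix
    for coef_fn, contrast in spec.extra_terms:
        m = m + coef_fn(severity, secondary) * contrast
    if spec.nonlinearity is not None:
        m = np.asarray(spec.nonlinearity(m), float)
    m = np.clip((m + m.T) / 2.0, -0.999, 0.999)
    np.fill_diagonal(m, 1.0)
    return _psd_floor(m)


def simulate_sfnc(spec: ContinuumSpec, seed: int = 0
                  ) -> tuple[list[FNCSample], pd.DataFrame]:
    """Draw per-subject static FNC samples and their ground-truth metadata.

    Returns the samples plus a frame with columns
    ``subject_id, group, severity, secondary``.
    """
    rng = np.random.default_rng(seed)
    samples, meta = [], []
    for group, ab in (("control", spec.severity_beta_control),
                      ("patient", spec.severity_beta_patient)):
        for i in range(spec.n_per_group):
            s = float(rng.beta(*ab))
            w = float(rng.normal(0.0, spec.secondary_sd)) if spec.secondary_sd > 0 else 0.0
            m = _noisy_correlation(continuum_matrix(spec, s, w),
                                   spec.edge_noise_sd, rng)
            sid = f"{group[:3]}_{i:04d}"
            samples.append(FNCSample(subject_id=sid, matrix=m, group_label=group))
            meta.append({"subject_id": sid, "group": group,
                         "severity": s, "secondary": w})
    return samples, pd.DataFrame(meta)


def tanh_warp(gain: float = 2.5) -> Callable[[np.ndarray], np.ndarray]:
    """Element-wise monotone warp tanh(gain * v) / gain.

    Applied to the severity blend it bends the one-dimensional continuum
    into a curve that no 2D linear subspace contains, which is what makes
    the nonlinear-manifold datasets genuinely nonlinear.
    """
    def f(v: np.ndarray) -> np.ndarray:
        return np.tanh(gain * v) / gain
    return f


def _block_contrast(blocks: dict[str, np.ndarray], C: int,
                    entries: dict[tuple[str, str], float]) -> np.ndarray:
    m = np.zeros((C, C))
    for (a, b), v in entries.items():
        if a in blocks and b in blocks:
            m[np.ix_(blocks[a], blocks[b])] = v
            m[np.ix_(blocks[b], blocks[a])] = v
    np.fill_diagonal(m, 0.0)
    return m


def nonlinear_continuum_spec(n_per_group: int = 120, edge_noise_sd: float = 0.05,
                             gain: float = 3.0, secondary_sd: float = 0.5,
                             sizes: dict[str, int] | None = None) -> ContinuumSpec:
    """Preset two-group continuum on a genuinely curved 2-factor manifold.

    The severity blend is augmented with a secondary latent factor, a
    severity-by-secondary interaction, a quadratic-in-severity contrast, and
    a tanh warp.  The resulting manifold is intrinsically two-dimensional
    but spans well over two linear dimensions, so a two-component linear
    model has an irreducible reconstruction deficit while a 2D nonlinear
    decoder does not.  This is the dataset for the nonlinear-vs-linear model
    comparison; a plain monotone blend of two prototypes would lie on a
    straight segment that PPCA captures exactly.
    """
    if sizes:
        Pc = build_block_prototype("control", sizes)
        Pp = build_block_prototype("patient", sizes)
    else:
        Pc, Pp = default_prototypes()
    blocks = domain_blocks(sizes)
    C = Pc.shape[0]
    # secondary factor: default-mode / cognitive-control modulation
    Q = _block_contrast(blocks, C, {("DM", "CC"): 0.25, ("DM", "DM"): 0.15})
    # severity x secondary interaction: sensory-to-control coupling
    R = _block_contrast(blocks, C, {("SM", "CC"): 0.30, ("CC", "VI"): -0.20})
    # quadratic severity response: mid-continuum visual/cerebellar excursion
    B2 = _block_contrast(blocks, C, {("VI", "CB"): 0.35, ("VI", "VI"): -0.20,
                                     ("AU", "DM"): 0.25})
    return ContinuumSpec(
        n_per_group=n_per_group,
        base_fnc_control=Pc, base_fnc_patient=Pp,
        edge_noise_sd=edge_noise_sd,
        nonlinearity=tanh_warp(gain),
        secondary_sd=secondary_sd,
        secondary_matrix=Q,
        interaction_matrix=R,
        extra_terms=[(lambda s, w: 4.0 * s * (1.0 - s), B2)],
    )


# ---------------------------------------------------------------------------
# dynamic states
# ---------------------------------------------------------------------------

@dataclass
class DynamicsSpec:
    """Markov-switching windowed FNC.

    Each subject follows a first-order Markov chain over ``k_true`` states;
    each window's matrix is a noisy realization of that state's prototype.
    Group-specific transition matrices let patients dwell longer in the
    sparsely connected states, the contrast the state statistics are meant
    to recover.
    """

    k_true: int = 5
    state_prototypes: list[np.ndarray] = field(default_factory=list)
    transition_truth: dict[str, np.ndarray] = field(default_factory=dict)
    T: int = 137
    window_noise_sd: float = 0.05
    initial_distribution: np.ndarray | None = None

    def __post_init__(self):
        if not self.state_prototypes:
            self.state_prototypes = default_state_prototypes(self.k_true)
        self.k_true = len(self.state_prototypes)
        if not self.transition_truth:
            self.transition_truth = default_transition_truth(self.k_true)
        for g, P in self.transition_truth.items():
            P = np.asarray(P, float)
            if P.shape != (self.k_true, self.k_true):
                raise ValueError(f"transition matrix for {g} must be k x k")
            if not np.allclose(P.sum(axis=1), 1.0, atol=1e-10):
                raise ValueError(f"transition rows for {g} must sum to 1")
            self.transition_truth[g] = P


def default_state_prototypes(k: int = 5, sizes: dict[str, int] | None = None
                             ) -> list[np.ndarray]:
    """k distinct state prototypes spanning sparse-to-dense connectivity.

    State 1 is sparsely connected (overall coupling scaled down), the last
    state densely connected; intermediate states interpolate and mix in the
    patient-contrast pattern so states differ in pattern, not just scale.
    """
    Pc = build_block_prototype("control", sizes)
    Pp = build_block_prototype("patient", sizes)
    protos = []
    for j in range(k):
        frac = j / max(k - 1, 1)
        scale = 0.25 + 0.75 * frac        # sparse -> dense
        mix = 1.0 - frac                   # patient-like -> control-like
        base = mix * Pp + (1 - mix) * Pc
        off = base - np.diag(np.diag(base))
        m = np.eye(base.shape[0]) + scale * off
        protos.append(_psd_floor(m))
    return protos


def default_transition_truth(k: int = 5, stay: float = 0.85,
                             patient_state1_stay: float = 0.95) -> dict[str, np.ndarray]:
    """Sticky group-specific Markov transition matrices.

    Both groups are sticky; patients are stickier in state 1 (the sparsely
    connected state), producing the planted dwell-time group difference.
    """
    def sticky(stay_vec):
        P = np.zeros((k, k))
        for a in range(k):
            P[a] = (1 - stay_vec[a]) / (k - 1)
            P[a, a] = stay_vec[a]
        return P

    ctrl = sticky([stay] * k)
    pat_stays = [stay] * k
    pat_stays[0] = patient_state1_stay
    pat = sticky(pat_stays)
    return {"control": ctrl, "patient": pat}


def simulate_dfnc(spec: DynamicsSpec, group_assignments: dict[str, str],
                  seed: int = 0, return_samples: bool = True
                  ) -> tuple[list[FNCSample], pd.DataFrame]:
    """Simulate windowed FNC per subject with known state sequences.

    ``group_assignments`` maps subject_id -> group name (a key of
    ``spec.transition_truth``).  Returns windowed samples plus a truth frame
    with columns ``subject_id, group, window_index, state`` (1-based states).
    ``return_samples=False`` skips the window matrices (empty sample list)
    for studies that only use the sequences.
    """
    rng = np.random.default_rng(seed)
    k = spec.k_true
    init = (np.full(k, 1.0 / k) if spec.initial_distribution is None
            else np.asarray(spec.initial_distribution, float))
    cum_init = np.cumsum(init)
    cum_P = {g: np.cumsum(P, axis=1) for g, P in spec.transition_truth.items()}
    samples, truth = [], []
    for sid in sorted(group_assignments):
        group = group_assignments[sid]
        cp = cum_P[group]
        u = rng.random(spec.T)
        states = np.empty(spec.T, dtype=int)
        states[0] = int(np.searchsorted(cum_init, u[0]))
        for t in range(1, spec.T):
            states[t] = int(np.searchsorted(cp[states[t - 1]], u[t]))
        for t in range(spec.T):
            if return_samples:
                m = _noisy_correlation(spec.state_prototypes[states[t]],
                                       spec.window_noise_sd, rng)
                samples.append(FNCSample(subject_id=sid, matrix=m,
                                         window_index=t, group_label=group))
            truth.append({"subject_id": sid, "group": group,
                          "window_index": t, "state": int(states[t]) + 1})
    return samples, pd.DataFrame(truth)


def simulate_timecourses(target_fnc: np.ndarray, T: int, seed: int = 0,
                         tr_seconds: float = 2.0,
                         subject_id: str = "sim") -> TimeCourseSet:
    """T draws from a zero-mean Gaussian whose correlation is ``target_fnc``.

    The empirical correlation of the returned time courses converges to the
    target as T grows, letting the FNC-construction path be tested
    end-to-end.
    """
    target = _psd_floor(np.asarray(target_fnc, float))
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(target)
    tc = rng.standard_normal((T, target.shape[0])) @ chol.T
    return TimeCourseSet(subject_id=subject_id, tc=tc, tr_seconds=tr_seconds,
                         component_domains=domain_labels()
                         if target.shape[0] == 53 else {})
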