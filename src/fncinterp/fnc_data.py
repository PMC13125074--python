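"""Construction of static and dynamic functional network connectivity (FNC).

Static FNC (sFNC) is the pairwise Pearson correlation between component time
courses over the full scan; dynamic FNC (dFNC) is estimated per sliding
window with a tapered weight profile (a rectangle convolved with a Gaussian)
so that window edges contribute less than the centre.  Matrices are C x C
symmetric with unit diagonal; the model-facing representation is the
vectorized strict upper triangle of length V = C(C-1)/2 (1378 for C = 53).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as _signal


#: The seven canonical functional domains for the 53-component decomposition:
#: subcortical, auditory, sensorimotor, visual, cognitive control,
#: default mode, cerebellar.
DOMAINS = ("SC", "AU", "SM", "VI", "CC", "DM", "CB")

_SYM_TOL = 1e-8


class DimensionError(ValueError):
    """Shape of an input is inconsistent with what the operation requires."""


class ValidationError(ValueError):
    """Input values violate an invariant (asymmetry, zero variance, ...)."""


class InsufficientDataError(ValueError):
    """Too few timepoints for the requested windowing."""


@dataclass
class TimeCourseSet:
    """Per-subject component time courses.

    Parameters
    ----------
    subject_id
        Identifier carried through to every derived FNC sample.
    tc
        T x C array, one column per component, arbitrary units.
    tr_seconds
        Repetition time (sampling interval) in seconds.
    component_domains
        Map component index (0-based) -> domain label covering all C columns.
    """

    subject_id: str
    tc: np.ndarray
    tr_seconds: float
    component_domains: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.tc = np.asarray(self.tc, dtype=float)
        if self.tc.ndim != 2 or self.tc.shape[0] < 2 or self.tc.shape[1] < 2:
            raise DimensionError(
                f"time courses must be T x C with T >= 2, C >= 2; got {self.tc.shape}"
            )
        if not np.all(np.isfinite(self.tc)):
            raise ValidationError("time courses contain non-finite values")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.component_domains:
            missing = set(range(self.n_components)) - set(self.component_domains)
            if missing:
                raise ValidationError(
                    f"domain map missing components {sorted(missing)}"
                )

    @property
    def n_timepoints(self) -> int:
        return self.tc.shape[0]

    @property
    def n_components(self) -> int:
        return self.tc.shape[1]


@dataclass
class FNCSample:
    """One connectivity observation: a symmetric matrix and its vector form.

    ``window_index`` is ``None`` for static FNC and the window ordinal for
    dynamic FNC.
    """

    subject_id: str
    matrix: np.ndarray
    window_index: int | None = None
    group_label: str | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        _check_symmetric(self.matrix)

    @property
    def n_components(self) -> int:
        return self.matrix.shape[0]

    @property
    def vector(self) -> np.ndarray:
        """Strict upper triangle, row-major, length C(C-1)/2."""
        return vectorize_upper(self.matrix)


@dataclass
class TaperSpec:
    """Sliding-window weight profile: rectangle convolved with a Gaussian."""

    width_tr: int
    gaussian_sigma_tr: float
    step_tr: int = 1
    weights: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.width_tr < 1:
            raise ValueError("width_tr must be >= 1")
        if self.gaussian_sigma_tr <= 0:
            raise ValueError("gaussian_sigma_tr must be > 0")
        if self.step_tr < 1:
            raise ValueError("step_tr must be >= 1")
        if self.weights is None:
            self.weights = _taper_weights(self.width_tr, self.gaussian_sigma_tr)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (self.width_tr,):
            raise DimensionError("weights length must equal width_tr")
        if np.any(self.weights <= 0):
            raise ValidationError("taper weights must be strictly positive")


def _check_symmetric(m: np.ndarray, tol: float = _SYM_TOL) -> None:
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise DimensionError(f"matrix must be square, got shape {m.shape}")
    if m.shape[0] < 2:
        raise DimensionError("matrix must be at least 2 x 2")
    asym = np.max(np.abs(m - m.T))
    if asym > tol:
        raise ValidationError(f"matrix asymmetric beyond tolerance: {asym:.3g}")


def vectorize_upper(matrix: np.ndarray) -> np.ndarray:
    """Vectorize the strict upper triangle of a symmetric matrix.

    Row-major traversal, diagonal excluded; the result has length
    V = C(C-1)/2 (1378 for C = 53).
    """
    matrix = np.asarray(matrix, dtype=float)
    _check_symmetric(matrix)
    iu = np.triu_indices(matrix.shape[0], k=1)
    return matrix[iu].copy()


def devectorize(vector: np.ndarray, n_components: int, diag_value: float = 1.0) -> np.ndarray:
    """Inverse of :func:`vectorize_upper`: rebuild the symmetric matrix.

    The diagonal is filled with ``diag_value`` (1 by correlation convention).
    """
    vector = np.asarray(vector, dtype=float).ravel()
    expected = n_components * (n_components - 1) // 2
    if vector.size != expected:
        raise DimensionError(
            f"vector length {vector.size} inconsistent with C={n_components} "
            f"(expected {expected})"
        )
    m = np.full((n_components, n_components), 0.0)
    iu = np.triu_indices(n_components, k=1)
    m[iu] = vector
    m = m + m.T
    np.fill_diagonal(m, diag_value)
    return m


def n_pairs(n_components: int) -> int:
    """Number of distinct component pairs, V = C(C-1)/2."""
    return n_components * (n_components - 1) // 2


def postprocess_tc(
    tcs: TimeCourseSet,
    motion_regressors: np.ndarray | None = None,
    lowpass_hz: float = 0.15,
    despike_mad: float = 4.0,
) -> TimeCourseSet:
    """Standard time-course cleanup before FNC estimation.

    Per component: linear detrend; OLS residualization on the motion
    regressors if provided; despiking by clipping samples further than
    ``despike_mad`` median absolute deviations from the per-component median;
    zero-phase Butterworth low-pass at ``lowpass_hz``.
    """
    nyquist = 1.0 / (2.0 * tcs.tr_seconds)
    if lowpass_hz >= nyquist:
        raise ValueError(
            f"lowpass_hz={lowpass_hz} must be below the Nyquist frequency {nyquist}"
        )
    x = _signal.detrend(tcs.tc, axis=0, type="linear")

    if motion_regressors is not None:
        reg = np.asarray(motion_regressors, dtype=float)
        if reg.ndim == 1:
            reg = reg[:, None]
        if reg.shape[0] != x.shape[0]:
            raise DimensionError("motion regressors must have T rows")
        reg = _signal.detrend(reg, axis=0, type="linear")  # match the data
        design = np.column_stack([np.ones(reg.shape[0]), reg])
        beta, *_ = np.linalg.lstsq(design, x, rcond=None)
        x = x - design @ beta

    med = np.median(x, axis=0)
    mad = np.median(np.abs(x - med), axis=0)
    mad = np.where(mad > 0, mad, np.inf)  # flat component: nothing to clip
    lo, hi = med - despike_mad * mad, med + despike_mad * mad
    x = np.clip(x, lo, hi)

    b, a = _signal.butter(5, lowpass_hz / nyquist, btype="low")
    x = _signal.filtfilt(b, a, x, axis=0)
    return replace(tcs, tc=x)


def compute_sfnc(tcs: TimeCourseSet, group_label: str | None = None) -> FNCSample:
    """Static FNC: pairwise Pearson correlation over the full time course."""
    x = tcs.tc
    if x.shape[0] < 3:
        raise InsufficientDataError("need at least 3 timepoints for correlation")
    sd = x.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValidationError(f"zero-variance component(s): {dead.tolist()}")
    m = np.corrcoef(x, rowvar=False)
    np.fill_diagonal(m, 1.0)
    return FNCSample(subject_id=tcs.subject_id, matrix=m, group_label=group_label)


def _taper_weights(width_tr: int, sigma_tr: float) -> np.ndarray:
    # Full discrete convolution of a unit rectangle with a Gaussian kernel
    # truncated at +/-3 sigma; the central `width_tr` samples are retained and
    # normalized to sum to 1.
    half = max(1, int(np.ceil(3.0 * sigma_tr)))
    t = np.arange(-half, half + 1, dtype=float)
    kernel = np.exp(-0.5 * (t / sigma_tr) ** 2)
    kernel /= kernel.sum()
    rect = np.ones(width_tr)
    full = np.convolve(rect, kernel, mode="full")
    start = (full.size - width_tr) // 2
    w = full[start : start + width_tr]
    return w / w.sum()


def make_taper(width_tr: int, sigma_tr: float, step_tr: int = 1) -> TaperSpec:
    """Build the tapered window: rectangle of ``width_tr`` TRs convolved with
    a Gaussian of ``sigma_tr`` TRs (the 20-TR / sigma 3 profile by default
    usage), normalized to sum to 1."""
    return TaperSpec(width_tr=width_tr, gaussian_sigma_tr=sigma_tr, step_tr=step_tr)


def count_windows(n_timepoints: int, width_tr: int, step_tr: int = 1) -> int:
    """Number of sliding windows: floor((T - width) / step).

    With 157 timepoints, width 20 and step 1 this yields 137 windows.
    """
    if n_timepoints <= width_tr:
        raise InsufficientDataError(
            f"T={n_timepoints} must exceed window width {width_tr}"
        )
    return (n_timepoints - width_tr) // step_tr


def _weighted_corr(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    w = w / w.sum()
    mu = w @ x
    xc = x - mu
    cov = (xc * w[:, None]).T @ xc
    d = np.sqrt(np.clip(np.diag(cov), 1e-300, None))
    corr = cov / np.outer(d, d)
    np.fill_diagonal(corr, 1.0)
    return np.clip(corr, -1.0, 1.0)


def compute_dfnc(
    tcs: TimeCourseSet,
    taper: TaperSpec,
    estimator: str = "weighted_pearson",
    glasso_penalty: float = 0.01,
    group_label: str | None = None,
) -> list[FNCSample]:
    """Dynamic FNC: one tapered-window correlation matrix per window.

    ``estimator`` is ``"weighted_pearson"`` (taper-weighted correlation,
    the default) or ``"graphical_lasso"`` (L1-penalized covariance estimate
    at ``glasso_penalty``, rescaled to a correlation matrix; a penalty of 0
    is the unpenalized MLE, i.e. the weighted sample correlation itself).
    """
    if estimator not in ("weighted_pearson", "graphical_lasso"):
        raise ValueError(f"unknown estimator {estimator!r}")
    T = tcs.n_timepoints
    w, step = taper.width_tr, taper.step_tr
    n_win = count_windows(T, w, step)
    out: list[FNCSample] = []
    for wi in range(n_win):
        start = wi * step
        seg = tcs.tc[start : start + w]
        corr = _weighted_corr(seg, taper.weights)
        if estimator == "graphical_lasso" and glasso_penalty > 0:
            from sklearn.covariance import graphical_lasso as _glasso

            try:
                cov_est, _ = _glasso(corr, alpha=glasso_penalty, max_iter=200)
            except FloatingPointError as exc:  # pragma: no cover - degenerate
                raise ValidationError(
                    f"graphical lasso failed at window {wi}: {exc}"
                ) from exc
            d = np.sqrt(np.diag(cov_est))
            corr = cov_est / np.outer(d, d)
            np.fill_diagonal(corr, 1.0)
        corr = (corr + corr.T) / 2.0
        out.append(
            FNCSample(
                subject_id=tcs.subject_id,
                matrix=corr,
                window_index=wi,
                group_label=group_label,
            )
        )
    return out


def samples_to_matrix(samples: list[FNCSample]) -> np.ndarray:
    """Stack sample vectors into an N x V design matrix."""
    return np.vstack([s.vector for s in samples])
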