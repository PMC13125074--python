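"""Variational autoencoder for vectorized FNC matrices.

The model learns a low-dimensional (default 2D) latent representation z of
connectivity vectors x in R^V.  The approximate posterior is a diagonal
Gaussian q(z|x) = N(mu(x), diag(sigma^2(x))) produced by an MLP encoder; an
MLP decoder parameterizes the likelihood mean.  Training minimizes the
per-sample objective

    L = (1/V) sum_i (x_i - xhat_i)^2  - 1/2 sum_j (1 + log s_j^2 - mu_j^2 - s_j^2)

(mean squared reconstruction error plus the closed-form KL divergence from
the posterior to the standard-normal prior), averaged over a batch, using
the reparameterization z = mu + sigma * eps with eps ~ N(0, I).

Everything is plain NumPy with hand-written backpropagation and Adam, which
keeps runs bitwise reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_LOGVAR_CLIP = 15.0  # numerical guard on the encoder's log-variance head


# ---------------------------------------------------------------------------
# objective pieces (pure functions, used by the trainer and directly testable)
# ---------------------------------------------------------------------------

def kl_term(mu: np.ndarray, log_var: np.ndarray) -> float:
    """KL( N(mu, diag exp(log_var)) || N(0, I) ), closed form; always >= 0."""
    mu = np.asarray(mu, dtype=float)
    log_var = np.asarray(log_var, dtype=float)
    if not (np.all(np.isfinite(mu)) and np.all(np.isfinite(log_var))):
        raise FloatingPointError("non-finite posterior parameters")
    return float(-0.5 * np.sum(1.0 + log_var - mu**2 - np.exp(log_var)))


def vae_loss(x: np.ndarray, x_hat: np.ndarray, mu: np.ndarray, log_var: np.ndarray) -> float:
    """Per-sample objective: mean squared error over V plus the KL term."""
    x = np.asarray(x, dtype=float)
    x_hat = np.asarray(x_hat, dtype=float)
    if x.shape != x_hat.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {x_hat.shape}")
    return float(np.mean((x - x_hat) ** 2)) + kl_term(mu, log_var)


def reparameterize(mu: np.ndarray, log_var: np.ndarray, epsilon: np.ndarray) -> np.ndarray:
    """z = mu + sigma * eps, deterministic given eps."""
    mu = np.asarray(mu, dtype=float)
    log_var = np.asarray(log_var, dtype=float)
    epsilon = np.asarray(epsilon, dtype=float)
    if not (mu.shape == log_var.shape == epsilon.shape):
        raise ValueError("mu, log_var and epsilon must share a shape")
    return mu + np.exp(0.5 * log_var) * epsilon


def gaussian_kl(mu, log_var, prior_mu, prior_log_var) -> float:
    """KL between two diagonal Gaussians (posterior vs a conditional prior)."""
    mu, lv = np.asarray(mu, float), np.asarray(log_var, float)
    pm, plv = np.asarray(prior_mu, float), np.asarray(prior_log_var, float)
    return float(
        0.5 * np.sum(plv - lv + (np.exp(lv) + (mu - pm) ** 2) / np.exp(plv) - 1.0)
    )


def ivae_loss(x, x_hat, mu, log_var, prior_mu, prior_log_var) -> float:
    """iVAE objective: reconstruction term plus KL to the label-conditional prior.

    With a standard-normal prior for every label this reduces exactly to
    :func:`vae_loss`.
    """
    x = np.asarray(x, dtype=float)
    x_hat = np.asarray(x_hat, dtype=float)
    if x.shape != x_hat.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {x_hat.shape}")
    return float(np.mean((x - x_hat) ** 2)) + gaussian_kl(mu, log_var, prior_mu, prior_log_var)


# ---------------------------------------------------------------------------
# minimal MLP machinery
# ---------------------------------------------------------------------------

class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        # He-style init for ReLU nets
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.gW += self._x.T @ grad
        self.gb += grad.sum(axis=0)
        return grad @ self.W.T

    def params(self):
        return [(self.W, self.gW), (self.b, self.gb)]

    def zero_grad(self):
        self.gW[:] = 0.0
        self.gb[:] = 0.0


class _MLP:
    """Stack of dense layers with ReLU on hidden layers, linear output."""

    def __init__(self, sizes: list[int], rng: np.random.Generator):
        self.layers = [_Dense(a, b, rng) for a, b in zip(sizes[:-1], sizes[1:])]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._masks = []
        for i, layer in enumerate(self.layers):
            x = layer.forward(x)
            if i < len(self.layers) - 1:
                mask = x > 0
                self._masks.append(mask)
                x = x * mask
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for i in range(len(self.layers) - 1, -1, -1):
            if i < len(self.layers) - 1:
                grad = grad * self._masks[i]
            grad = self.layers[i].backward(grad)
        return grad

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def zero_grad(self):
        for layer in self.layers:
            layer.zero_grad()


class _Adam:
    def __init__(self, params, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (p, g) in enumerate(self.params):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Training protocol: Adam at 0.001 with a reduce-on-plateau scheduler
    (factor 0.1, patience 10 epochs), early stopping after 20 epochs without
    improvement, at most 1000 epochs.  Batch size 16 suits per-subject static
    FNC; 512 suits the much larger windowed dynamic sets."""

    lr: float = 1e-3
    scheduler_factor: float = 0.1
    scheduler_patience: int = 10
    early_stop_patience: int = 20
    max_epochs: int = 1000
    batch_size: int = 16
    n_seeds: int = 10
    seeds: tuple[int, ...] = tuple(range(10))
    #: Weight on the KL term during optimization.  ``None`` means 1/V, which
    #: together with the per-edge mean reconstruction error reproduces the
    #: classic summed-ELBO balance (sum of squared errors + KL) for a
    #: fixed-variance Gaussian likelihood.  A full-weight KL against a
    #: per-edge-averaged reconstruction term overwhelms it by a factor of V
    #: and collapses the posterior to the prior on data at correlation scale.
    kl_weight: float | None = None

    def __post_init__(self):
        if min(self.lr, self.scheduler_factor) <= 0 or min(
            self.scheduler_patience, self.early_stop_patience, self.max_epochs,
            self.batch_size,
        ) <= 0:
            raise ValueError("all TrainConfig fields must be positive")


# ---------------------------------------------------------------------------
# the VAE
# ---------------------------------------------------------------------------

class VAE:
    """MLP encoder/decoder VAE over length-V connectivity vectors.

    Parameters
    ----------
    input_dim
        V, the length of the vectorized upper triangle.
    latent_dim
        D, the latent dimensionality (2 by default so the manifold can be
        laid out on a planar grid).
    hidden
        Hidden layer widths of the encoder; the decoder mirrors them.
    seed
        Controls weight initialization (and, during :meth:`fit`, shuffling
        and the eps draws).
    """

    def __init__(self, input_dim: int, latent_dim: int = 2,
                 hidden: tuple[int, ...] = (256, 64), seed: int = 0):
        if latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        self.input_dim = int(input_dim)
        self.latent_dim = int(latent_dim)
        self.hidden = tuple(int(h) for h in hidden)
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        enc_sizes = [self.input_dim, *self.hidden]
        self.enc_trunk = _MLP(enc_sizes, rng) if self.hidden else None
        trunk_out = self.hidden[-1] if self.hidden else self.input_dim
        self.head_mu = _Dense(trunk_out, self.latent_dim, rng)
        self.head_lv = _Dense(trunk_out, self.latent_dim, rng)
        # start the posterior scale small (sigma ~ 0.1) so early epochs are
        # not dominated by reparameterization noise
        self.head_lv.b[:] = -4.0
        self.decoder = _MLP([self.latent_dim, *self.hidden[::-1], self.input_dim], rng)
        self.loss_history: list[float] = []

    # -- inference ---------------------------------------------------------
    def encode(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Posterior parameters (mu, log_var) for each row of X."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        h = self._trunk_forward(X)
        mu = self.head_mu.forward(h)
        lv = np.clip(self.head_lv.forward(h), -_LOGVAR_CLIP, _LOGVAR_CLIP)
        return mu, lv

    def decode(self, Z: np.ndarray) -> np.ndarray:
        """Deterministic decoder mean for each latent point."""
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        return self.decoder.forward(Z)

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        """Decode the posterior mean (no sampling)."""
        mu, _ = self.encode(X)
        return self.decode(mu)

    def posterior_sample_decode(self, X: np.ndarray, seed: int = 0) -> np.ndarray:
        """Decode one posterior draw z ~ q(z|x) per sample."""
        mu, lv = self.encode(X)
        rng = np.random.default_rng(seed)
        eps = rng.standard_normal(mu.shape)
        return self.decode(reparameterize(mu, lv, eps))

    # -- training ----------------------------------------------------------
    def _trunk_forward(self, X: np.ndarray) -> np.ndarray:
        if self.enc_trunk is None:
            return X
        h = X
        self._trunk_masks = []
        for layer in self.enc_trunk.layers:
            h = layer.forward(h)
            mask = h > 0
            self._trunk_masks.append(mask)
            h = h * mask
        return h

    def _trunk_backward(self, grad: np.ndarray) -> None:
        if self.enc_trunk is None:
            return
        for i in range(len(self.enc_trunk.layers) - 1, -1, -1):
            grad = grad * self._trunk_masks[i]
            grad = self.enc_trunk.layers[i].backward(grad)

    def _params(self):
        ps = []
        if self.enc_trunk is not None:
            ps += self.enc_trunk.params()
        ps += self.head_mu.params() + self.head_lv.params() + self.decoder.params()
        return ps

    def _zero_grad(self):
        if self.enc_trunk is not None:
            self.enc_trunk.zero_grad()
        self.head_mu.zero_grad()
        self.head_lv.zero_grad()
        self.decoder.zero_grad()

    def _batch_step(self, xb: np.ndarray, eps: np.ndarray, opt: _Adam,
                    extra=None, kl_weight: float = 1.0) -> float:
        """One forward/backward/update on a batch; returns the batch loss."""
        B, V = xb.shape
        self._zero_grad()
        h = self._trunk_forward(xb)
        mu = self.head_mu.forward(h)
        lv_raw = self.head_lv.forward(h)
        lv = np.clip(lv_raw, -_LOGVAR_CLIP, _LOGVAR_CLIP)
        sig = np.exp(0.5 * lv)
        z = mu + sig * eps
        xhat = self.decoder.forward(z)

        recon = np.mean((xb - xhat) ** 2, axis=1)
        if extra is None:
            klv = -0.5 * np.sum(1.0 + lv - mu**2 - np.exp(lv), axis=1)
            dmu_kl = mu / B
            dlv_kl = 0.5 * (np.exp(lv) - 1.0) / B
        else:
            pm, plv, scatter = extra
            klv = 0.5 * np.sum(
                plv - lv + (np.exp(lv) + (mu - pm) ** 2) / np.exp(plv) - 1.0, axis=1
            )
            inv_pv = np.exp(-plv)
            dmu_kl = (mu - pm) * inv_pv / B
            dlv_kl = 0.5 * (np.exp(lv) * inv_pv - 1.0) / B
            dpm = -kl_weight * (mu - pm) * inv_pv / B
            dplv = kl_weight * 0.5 * (1.0 - (np.exp(lv) + (mu - pm) ** 2) * inv_pv) / B
            scatter(dpm, dplv)
        loss = float(np.mean(recon + kl_weight * klv))
        if not np.isfinite(loss):
            raise FloatingPointError("non-finite loss")

        dxhat = 2.0 * (xhat - xb) / (V * B)
        dz = self.decoder.backward(dxhat)
        dmu = dz + kl_weight * dmu_kl
        dlv = dz * 0.5 * sig * eps + kl_weight * dlv_kl
        dlv = dlv * ((lv_raw > -_LOGVAR_CLIP) & (lv_raw < _LOGVAR_CLIP))
        dh = self.head_mu.backward(dmu) + self.head_lv.backward(dlv)
        self._trunk_backward(dh)
        opt.step()
        return loss

    def fit(self, X: np.ndarray, cfg: TrainConfig | None = None,
            _extra_hook=None, _extra_params=()) -> list[float]:
        """Train on rows of X; returns the per-epoch mean loss history.

        Deterministic for a fixed construction seed: shuffling and eps draws
        come from a generator seeded from ``self.seed``.
        """
        cfg = cfg or TrainConfig()
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("need an N x V matrix with N >= 2")
        if X.shape[1] != self.input_dim:
            raise ValueError(f"expected V={self.input_dim}, got {X.shape[1]}")
        rng = np.random.default_rng((self.seed, 0xF17))
        opt = _Adam(list(self._params()) + list(_extra_params), lr=cfg.lr)
        kl_weight = (1.0 / self.input_dim) if cfg.kl_weight is None else float(cfg.kl_weight)
        N = X.shape[0]
        best = np.inf
        stale = 0
        self.loss_history = []
        for epoch in range(cfg.max_epochs):
            order = rng.permutation(N)
            losses = []
            for s in range(0, N, cfg.batch_size):
                idx = order[s : s + cfg.batch_size]
                xb = X[idx]
                eps = rng.standard_normal((xb.shape[0], self.latent_dim))
                extra = _extra_hook(idx) if _extra_hook is not None else None
                try:
                    losses.append(
                        self._batch_step(xb, eps, opt, extra=extra,
                                         kl_weight=kl_weight))
                except FloatingPointError as exc:
                    raise FloatingPointError(
                        f"training diverged at epoch {epoch}, batch {s // cfg.batch_size}"
                    ) from exc
            epoch_loss = float(np.mean(losses))
            self.loss_history.append(epoch_loss)
            if epoch_loss < best - 1e-12:
                best = epoch_loss
                stale = 0
            else:
                stale += 1
                if stale % cfg.scheduler_patience == 0:
                    opt.lr *= cfg.scheduler_factor
                if stale >= cfg.early_stop_patience:
                    break
        return self.loss_history


def _collect_weights(model: "VAE") -> dict[str, np.ndarray]:
    out = {}
    if model.enc_trunk is not None:
        for i, layer in enumerate(model.enc_trunk.layers):
            out[f"enc{i}_W"], out[f"enc{i}_b"] = layer.W, layer.b
    out["mu_W"], out["mu_b"] = model.head_mu.W, model.head_mu.b
    out["lv_W"], out["lv_b"] = model.head_lv.W, model.head_lv.b
    for i, layer in enumerate(model.decoder.layers):
        out[f"dec{i}_W"], out[f"dec{i}_b"] = layer.W, layer.b
    return out


def save_model(model: "VAE", bundle_dir) -> None:
    """Persist a model bundle: weights (npz), architecture echo (YAML),
    loss history (CSV)."""
    import csv
    from pathlib import Path

    import yaml

    d = Path(bundle_dir)
    d.mkdir(parents=True, exist_ok=True)
    arch = {"class": type(model).__name__, "input_dim": model.input_dim,
            "latent_dim": model.latent_dim, "hidden": list(model.hidden),
            "seed": model.seed}
    weights = _collect_weights(model)
    if isinstance(model, IVAE):
        arch["labels"] = [str(lab) for lab in
                          sorted(model.label_index, key=model.label_index.get)]
        weights["prior_mu"] = model.prior_mu
        weights["prior_log_var"] = model.prior_log_var
    np.savez(d / "weights.npz", **weights)
    with open(d / "architecture.yaml", "w") as fh:
        yaml.safe_dump(arch, fh, sort_keys=True)
    with open(d / "loss_history.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["epoch", "loss"])
        w.writerows(enumerate(model.loss_history))


def load_model(bundle_dir) -> "VAE":
    """Rebuild a model from :func:`save_model` output; decoding is
    bit-identical to the saved model."""
    from pathlib import Path

    import yaml

    d = Path(bundle_dir)
    with open(d / "architecture.yaml") as fh:
        arch = yaml.safe_load(fh)
    weights = np.load(d / "weights.npz")
    if arch["class"] == "IVAE":
        model: VAE = IVAE(arch["input_dim"], labels=arch["labels"],
                          latent_dim=arch["latent_dim"],
                          hidden=tuple(arch["hidden"]), seed=arch["seed"])
        model.prior_mu = weights["prior_mu"].copy()
        model.prior_log_var = weights["prior_log_var"].copy()
    else:
        model = VAE(arch["input_dim"], latent_dim=arch["latent_dim"],
                    hidden=tuple(arch["hidden"]), seed=arch["seed"])
    if model.enc_trunk is not None:
        for i, layer in enumerate(model.enc_trunk.layers):
            layer.W, layer.b = weights[f"enc{i}_W"].copy(), weights[f"enc{i}_b"].copy()
    model.head_mu.W, model.head_mu.b = weights["mu_W"].copy(), weights["mu_b"].copy()
    model.head_lv.W, model.head_lv.b = weights["lv_W"].copy(), weights["lv_b"].copy()
    for i, layer in enumerate(model.decoder.layers):
        layer.W, layer.b = weights[f"dec{i}_W"].copy(), weights[f"dec{i}_b"].copy()
    return model


class IVAE(VAE):
    """Identifiable VAE: the latent prior is conditioned on an auxiliary
    one-hot variable (here the diagnostic label), N(z | m_u, diag exp(v_u)).

    The prior network over a one-hot input is exactly a per-label lookup
    table of (mean, log-variance) pairs, learned jointly with the encoder
    and decoder.  With the tables frozen at (0, 0) the objective coincides
    with the plain VAE.
    """

    def __init__(self, input_dim: int, labels: list[str], latent_dim: int = 2,
                 hidden: tuple[int, ...] = (256, 64), seed: int = 0):
        super().__init__(input_dim, latent_dim=latent_dim, hidden=hidden, seed=seed)
        self.label_index = {lab: i for i, lab in enumerate(dict.fromkeys(labels))}
        L = len(self.label_index)
        self.prior_mu = np.zeros((L, latent_dim))
        self.prior_log_var = np.zeros((L, latent_dim))
        self._g_prior_mu = np.zeros_like(self.prior_mu)
        self._g_prior_lv = np.zeros_like(self.prior_log_var)

    def prior_params(self, label: str) -> tuple[np.ndarray, np.ndarray]:
        if label not in self.label_index:
            raise KeyError(
                f"unseen label {label!r}; known labels: {sorted(self.label_index)}"
            )
        i = self.label_index[label]
        return self.prior_mu[i].copy(), self.prior_log_var[i].copy()

    def fit_labeled(self, X: np.ndarray, labels: np.ndarray,
                    cfg: TrainConfig | None = None) -> list[float]:
        labels = np.asarray(labels)
        if labels.shape[0] != X.shape[0]:
            raise ValueError("one label per sample required")
        lab_idx = np.array([self.label_index[l] for l in labels])

        def hook(idx):
            li = lab_idx[idx]
            self._g_prior_mu[:] = 0.0
            self._g_prior_lv[:] = 0.0

            def scatter(dpm, dplv):
                # gathered rows are copies; route their gradients back to
                # the per-label tables before the optimizer step
                np.add.at(self._g_prior_mu, li, dpm)
                np.add.at(self._g_prior_lv, li, dplv)

            return self.prior_mu[li], self.prior_log_var[li], scatter

        return self.fit(
            X, cfg, _extra_hook=hook,
            _extra_params=[(self.prior_mu, self._g_prior_mu),
                           (self.prior_log_var, self._g_prior_lv)],
        )
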