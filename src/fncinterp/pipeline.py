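"""End-to-end workflow orchestration.

A run is configured by a YAML/dict ``RunConfig`` and produces a run
directory containing every artifact as delimited text plus a JSON manifest
(config echo, package version, seeds, per-stage status) from which the run
is reproducible.  Pathways: train a generative model on vectorized FNC,
then either decode a latent grid and assign the originals to it (static
analysis) or cluster latent features into states and summarize their
dynamics (dynamic analysis), alongside the baseline k-means on the original
matrices.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dynamic_states import (dynamics_summary, select_k_elbow, state_medians)
from .fnc_data import samples_to_matrix
from .metrics import reconstruction_metrics
from .ppca import ppca_fit_em, ppca_reconstruct, ppca_transform
from .static_interp import (assign_to_grid, choose_grid_side, decode_grid,
                            grid_correspondence, grid_range, make_grid)
from .synthetic import (ContinuumSpec, DynamicsSpec, nonlinear_continuum_spec,
                        simulate_dfnc, simulate_sfnc)
from .vae import IVAE, VAE, TrainConfig, save_model

log = logging.getLogger("fncinterp")


@dataclass
class RunConfig:
    """Pipeline configuration; every field is echoed into the run manifest."""

    out_dir: str
    data_type: str = "sfnc"               # sfnc | dfnc
    model: str = "vae"                    # vae | ppca | ivae
    seed: int = 0
    simulate: dict = field(default_factory=dict)
    data: dict = field(default_factory=dict)
    train: dict = field(default_factory=dict)
    train_fraction: float = 0.85
    grid_side: int | None = None
    grid_percentile: float = 80.0
    k_range: tuple[int, int] = (2, 9)
    alpha: float = 0.05

    def __post_init__(self):
        if self.data_type not in ("sfnc", "dfnc"):
            raise ValueError("data_type must be 'sfnc' or 'dfnc'")
        if self.model not in ("vae", "ppca", "ivae"):
            raise ValueError("model must be 'vae', 'ppca' or 'ivae'")
        for key in ("vector_table", "metadata"):
            if key in self.data and not Path(self.data[key]).exists():
                raise FileNotFoundError(
                    f"configured path does not exist: {self.data[key]}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


class _PPCAFrontend:
    """Gives the linear PPCA baseline the encode/decode surface the grid
    and state operations expect."""

    latent_dim = 2

    def __init__(self, model):
        self.model = model
        self.latent_dim = model.q

    def encode(self, X):
        Z = ppca_transform(self.model, X)
        return Z, np.full_like(Z, -np.inf)  # point posterior: log-variance -> -inf

    def decode(self, Z):
        Z = np.atleast_2d(np.asarray(Z, float))
        return Z @ self.model.W.T + self.model.mean

    def reconstruct(self, X):
        return ppca_reconstruct(self.model, X)

    def posterior_sample_decode(self, X, seed=0):
        return self.reconstruct(X)


def _simulate(cfg: RunConfig):
    sim = dict(cfg.simulate)
    kind = sim.pop("kind", "nonlinear_continuum")
    if cfg.data_type == "sfnc":
        if kind == "nonlinear_continuum":
            spec = nonlinear_continuum_spec(**sim)
        else:
            spec = ContinuumSpec(**sim)
        samples, meta = simulate_sfnc(spec, seed=cfg.seed)
    else:
        n_per_group = sim.pop("n_per_group", 25)
        spec = DynamicsSpec(**sim)
        groups = {f"con_{i:03d}": "control" for i in range(n_per_group)}
        groups |= {f"pat_{i:03d}": "patient" for i in range(n_per_group)}
        samples, meta = simulate_dfnc(spec, groups, seed=cfg.seed)
    return samples, meta


def _load(cfg: RunConfig):
    from .io import load_vector_table

    table = cfg.data.get("vector_table")
    if table is None:
        raise ValueError("config must provide either simulate or data.vector_table")
    n_components = int(cfg.data["n_components"])
    samples = load_vector_table(table, n_components)
    meta_path = cfg.data.get("metadata")
    meta = (pd.read_csv(meta_path) if meta_path else pd.DataFrame({
        "subject_id": [s.subject_id for s in samples],
        "group": [s.group_label or "all" for s in samples],
    }))
    return samples, meta


def _split(n: int, labels: np.ndarray, fraction: float, seed: int):
    """Stratified train/test split with per-group rounding."""
    rng = np.random.default_rng((seed, 0x5B117))
    train_idx, test_idx = [], []
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        rng.shuffle(idx)
        ntr = int(round(fraction * idx.size))
        train_idx.extend(idx[:ntr])
        test_idx.extend(idx[ntr:])
    return np.sort(train_idx), np.sort(test_idx)


def _train_model(cfg: RunConfig, X_train: np.ndarray, labels_train):
    train_kwargs = dict(cfg.train)
    hidden = tuple(train_kwargs.pop("hidden", (256, 64)))
    latent_dim = int(train_kwargs.pop("latent_dim", 2))
    if cfg.model == "ppca":
        model = ppca_fit_em(X_train, latent_dim, seed=cfg.seed)
        return _PPCAFrontend(model), [float(v) for v in model.loglik_history]
    tc = TrainConfig(**train_kwargs) if train_kwargs else TrainConfig()
    if cfg.model == "ivae":
        model = IVAE(X_train.shape[1], labels=list(labels_train),
                     latent_dim=latent_dim, hidden=hidden, seed=cfg.seed)
        history = model.fit_labeled(X_train, np.asarray(labels_train), tc)
    else:
        model = VAE(X_train.shape[1], latent_dim=latent_dim, hidden=hidden,
                    seed=cfg.seed)
        history = model.fit(X_train, tc)
    return model, history


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the configured workflow; returns the run directory.

    Stage failures abort the run but leave completed artifacts in place,
    with the manifest marking the failed stage.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "seed": cfg.seed,
                "config": asdict(cfg), "stages": {}}

    def done(stage, **extra):
        manifest["stages"][stage] = {"status": "ok", **extra}
        log.info("stage %s ok %s", stage, extra or "")
        _write_manifest(out, manifest)

    try:
        with open(out / "config_echo.yaml", "w") as fh:
            yaml.safe_dump(asdict(cfg), fh, sort_keys=True)

        samples, meta = _simulate(cfg) if cfg.simulate else _load(cfg)
        X = samples_to_matrix(samples)
        subject_ids = np.array([s.subject_id for s in samples])
        groups = np.array([s.group_label or "all" for s in samples])
        meta.to_csv(out / "metadata.csv", index=False)
        done("data", n_samples=len(samples), n_features=int(X.shape[1]))

        if cfg.data_type == "sfnc":
            tr, te = _split(len(X), groups, cfg.train_fraction, cfg.seed)
        else:  # split whole subjects, windows stay together
            subj = np.unique(subject_ids)
            subj_groups = np.array(
                [groups[subject_ids == s][0] for s in subj])
            str_, ste = _split(len(subj), subj_groups, cfg.train_fraction, cfg.seed)
            tr = np.flatnonzero(np.isin(subject_ids, subj[str_]))
            te = np.flatnonzero(np.isin(subject_ids, subj[ste]))
        np.savetxt(out / "split_train_indices.csv", tr, fmt="%d")
        done("split", n_train=int(tr.size), n_test=int(te.size))

        model, history = _train_model(cfg, X[tr], groups[tr])
        pd.DataFrame({"epoch": range(len(history)), "loss": history}).to_csv(
            out / "loss_history.csv", index=False)
        if cfg.model in ("vae", "ivae"):
            save_model(model, out / "model")
        done("train", epochs=len(history))

        mu_all, _ = model.encode(X)
        lat = {"subject_id": subject_ids, "group": groups}
        lat |= {f"z{j + 1}": mu_all[:, j] for j in range(mu_all.shape[1])}
        lat["split"] = np.where(np.isin(np.arange(len(X)), tr), "train", "test")
        pd.DataFrame(lat).to_csv(out / "latents.csv", index=False)
        rec = model.reconstruct(X[te])
        mdf = reconstruction_metrics(rec, X[te], groups=groups[te],
                                     sample_ids=subject_ids[te])
        mdf.insert(0, "method", cfg.model)
        mdf.insert(1, "seed", cfg.seed)
        mdf.to_csv(out / "test_metrics.csv", index=False)
        done("reconstruction",
             mean_r=float(mdf["pearson_r"].mean()),
             median_r=float(mdf["pearson_r"].median()))

        if cfg.data_type == "sfnc":
            _static_stage(cfg, out, model, X, mu_all, tr, subject_ids, groups,
                          done)
        else:
            _dynamic_stage(cfg, out, model, X, mu_all, samples, done)
    except Exception as exc:
        stage = f"failed:{type(exc).__name__}"
        manifest["stages"][stage] = {"status": "error", "message": str(exc)}
        _write_manifest(out, manifest)
        raise
    return out


def _static_stage(cfg, out, model, X, mu_all, tr, subject_ids, groups, done):
    side = cfg.grid_side or choose_grid_side(tr.size)
    r = grid_range(mu_all[tr], cfg.grid_percentile)
    grid = make_grid(r, side=side)
    decoded = decode_grid(model, grid)
    order = np.argsort(subject_ids[tr])
    assignment = assign_to_grid(mu_all[tr], grid, order=order)
    corr = grid_correspondence(decoded, X[tr], assignment,
                               groups=groups[tr], sample_ids=subject_ids[tr])
    corr["metrics"].to_csv(out / "grid_correspondence.csv", index=False)
    rows = []
    for i in range(grid.n_nodes):
        row, col = grid.node_rowcol(i)
        rows.append({"node_row": row, "node_col": col,
                     "z1": grid.coords[i, 0], "z2": grid.coords[i, 1],
                     "assigned_subject_id": ""})
    gdf = pd.DataFrame(rows)
    for latent_i, node in assignment.items():
        gdf.loc[node, "assigned_subject_id"] = subject_ids[tr][latent_i]
    gdf.to_csv(out / "grid_layout.csv", index=False)
    done("grid", side=side, radius=float(r),
         fractions={str(k): v for k, v in corr["fractions"].items()})


def _dynamic_stage(cfg, out, model, X, mu_all, samples, done):
    ids = [s.subject_id for s in samples]
    wins = [s.window_index for s in samples]
    grp = [s.group_label or "all" for s in samples]
    sm = select_k_elbow(mu_all, k_range=range(cfg.k_range[0], cfg.k_range[1] + 1),
                        seed=cfg.seed, subject_ids=ids, window_indices=wins,
                        groups=grp)
    sm.assignments.to_csv(out / "state_assignments.csv", index=False)
    pd.DataFrame({"k": list(sm.inertia_curve),
                  "mean_l2": list(sm.inertia_curve.values())}).to_csv(
        out / "inertia_curve.csv", index=False)

    gen = model.posterior_sample_decode(X, seed=cfg.seed)
    med = state_medians(gen, sm.assignments)
    for (g, s), v in med.items():
        np.savetxt(out / f"state_{g}_{s}_generated.csv", v, delimiter=",")
    med_orig = state_medians(X, sm.assignments)
    for (g, s), v in med_orig.items():
        np.savetxt(out / f"state_{g}_{s}_original.csv", v, delimiter=",")

    summ = dynamics_summary(sm.assignments, sm.k)
    summ.dwell.to_csv(out / "dwell_times.csv", index=False)
    for g, P in (summ.P or {}).items():
        np.savetxt(out / f"transition_matrix_{g}.csv", P, delimiter=",")
    done("states", k_star=int(sm.k), elbow_warning=bool(sm.elbow_warning))


def _write_manifest(out: Path, manifest: dict) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)


def report(run_dirs: list[str | Path], out_path: str | Path | None = None
           ) -> pd.DataFrame:
    """Aggregate per-run test metrics into one summary table.

    One row per (run, method, seed, group) with mean/median r and MSE;
    raises if no run directory contains metrics.
    """
    frames = []
    for d in run_dirs:
        p = Path(d) / "test_metrics.csv"
        if p.exists():
            df = pd.read_csv(p)
            df.insert(0, "run", str(d))
            frames.append(df)
    if not frames:
        raise FileNotFoundError("no runs found: no test_metrics.csv under the "
                                "given directories")
    allm = pd.concat(frames, ignore_index=True)
    summary = (allm.groupby(["run", "method", "seed", "group"])
               .agg(n=("sample_id", "size"), mean_r=("pearson_r", "mean"),
                    median_r=("pearson_r", "median"), mean_mse=("mse", "mean"))
               .reset_index())
    if out_path is not None:
        summary.to_csv(out_path, index=False)
    return summary
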