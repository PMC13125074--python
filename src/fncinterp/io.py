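"""Delimited-text input/output for time courses, FNC matrices and metadata.

Formats are deliberately plain: per-subject T x C time-course text files
with a manifest CSV (subject_id, path, label, tr_seconds), per-sample C x C
matrix files, a long-format vector table (one row per sample, V edge
columns), and a two-column component -> domain map with 1-based component
indices.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .fnc_data import FNCSample, TimeCourseSet, devectorize, n_pairs


def save_matrix(sample: FNCSample, path: str | Path) -> None:
    np.savetxt(path, sample.matrix, delimiter=",", fmt="%.8f")


def load_matrix(path: str | Path, subject_id: str | None = None,
                window_index: int | None = None,
                group_label: str | None = None) -> FNCSample:
    m = np.loadtxt(path, delimiter=",")
    return FNCSample(subject_id=subject_id or Path(path).stem, matrix=m,
                     window_index=window_index, group_label=group_label)


def save_vector_table(samples: list[FNCSample], path: str | Path) -> None:
    """Long-format table: subject_id, window_index, group, e0001..eV."""
    V = n_pairs(samples[0].n_components)
    cols = [f"e{i + 1:04d}" for i in range(V)]
    rows = []
    for s in samples:
        row = {"subject_id": s.subject_id,
               "window_index": -1 if s.window_index is None else s.window_index,
               "group": s.group_label or ""}
        row.update(dict(zip(cols, s.vector)))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.8f")


def load_vector_table(path: str | Path, n_components: int) -> list[FNCSample]:
    df = pd.read_csv(path)
    V = n_pairs(n_components)
    cols = [f"e{i + 1:04d}" for i in range(V)]
    out = []
    for _, row in df.iterrows():
        wi = int(row["window_index"])
        group = row["group"]
        out.append(FNCSample(
            subject_id=str(row["subject_id"]),
            matrix=devectorize(row[cols].to_numpy(dtype=float), n_components),
            window_index=None if wi < 0 else wi,
            group_label=None if pd.isna(group) or group == "" else str(group),
        ))
    return out


def save_timecourses(tcs: TimeCourseSet, path: str | Path) -> None:
    np.savetxt(path, tcs.tc, delimiter=",", fmt="%.8f")


def load_timecourses_manifest(manifest_path: str | Path,
                              domain_map: dict[int, str] | None = None
                              ) -> list[tuple[TimeCourseSet, str]]:
    """Load (TimeCourseSet, label) pairs from a manifest CSV with columns
    subject_id, path, label, tr_seconds; paths are relative to the manifest."""
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    required = {"subject_id", "path", "label", "tr_seconds"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        p = Path(row["path"])
        if not p.is_absolute():
            p = manifest_path.parent / p
        tc = np.loadtxt(p, delimiter=",")
        out.append((
            TimeCourseSet(subject_id=str(row["subject_id"]), tc=tc,
                          tr_seconds=float(row["tr_seconds"]),
                          component_domains=domain_map or {}),
            str(row["label"]),
        ))
    return out


def load_domain_map(path: str | Path) -> dict[int, str]:
    """Two-column CSV (component_index, domain) with 1-based indices on
    disk, returned 0-based."""
    df = pd.read_csv(path)
    cols = list(df.columns)
    return {int(r[cols[0]]) - 1: str(r[cols[1]]) for _, r in df.iterrows()}


def save_domain_map(domain_map: dict[int, str], path: str | Path) -> None:
    pd.DataFrame(
        {"component_index": [i + 1 for i in sorted(domain_map)],
         "domain": [domain_map[i] for i in sorted(domain_map)]}
    ).to_csv(path, index=False)
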