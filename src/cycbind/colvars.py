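"""Colvar time-series files and umbrella-window manifests.

The time-series dialect: comment lines start with '#', the first column is
an integer step, and each further column is one coordinate value. The
reader also accepts the multi-space-separated layout common colvars
modules emit.
"""

from __future__ import annotations

from pathlib import Path
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd

from cycbind.synth.sampling import WindowSample, WindowSpec


def write_colvar_series(path, steps: Sequence[int], columns: Sequence[np.ndarray],
                        names: Sequence[str] = ()) -> None:
    steps = np.asarray(steps, dtype=int)
    cols = [np.asarray(c, dtype=float) for c in columns]
    for c in cols:
        if c.shape != steps.shape:
            raise ValueError("every column must match the step column length")
    header = "# step " + " ".join(names or [f"cv{i}" for i in range(len(cols))])
    lines = [header]
    for i, s in enumerate(steps):
        lines.append(" ".join([str(int(s))] + [f"{c[i]:.10g}" for c in cols]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_colvar_series(path) -> Tuple[np.ndarray, np.ndarray]:
    """Returns (steps, values[n_rows, n_cols]); tolerant of repeated spaces."""
    data = np.loadtxt(path, comments="#", ndmin=2)
    if data.shape[1] < 2:
        raise ValueError("colvar file needs a step column plus >= 1 coordinate column")
    return data[:, 0].astype(int), data[:, 1:]


def write_windows_manifest(path, windows: Sequence[WindowSpec]) -> None:
    df = pd.DataFrame(
        [{"index": w.index, "center": w.center, "force_constant": w.force_constant}
         for w in windows]
    )
    df.to_csv(path, sep="\t", index=False)


def read_windows_manifest(path) -> List[WindowSpec]:
    df = pd.read_csv(path, sep="\t")
    for col in ("index", "center", "force_constant"):
        if col not in df.columns:
            raise ValueError(f"windows manifest missing column {col!r}")
    return [
        WindowSpec(center=float(r.center), force_constant=float(r.force_constant),
                   index=int(r.index))
        for r in df.itertuples(index=False)
    ]


def load_window_samples(manifest_path, series_paths: Sequence) -> List[WindowSample]:
    """Pair a windows manifest with one colvar series file per window."""
    windows = read_windows_manifest(manifest_path)
    if len(windows) != len(series_paths):
        raise ValueError(
            f"manifest lists {len(windows)} windows but {len(series_paths)} "
            "series files were given"
        )
    samples = []
    for w, p in zip(windows, series_paths):
        _, values = read_colvar_series(p)
        samples.append(WindowSample(window=w, values=values[:, 0]))
    return samples
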