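"""On-disk formats: wide-CSV cohorts, manifests, flat config files and
model JSON.

The wide CSV has one row per sample with columns ``sample_id, group,
run_index, t0001 ... tNNNN`` (zero-padded so the trace columns sort
lexically); the manifest repeats the three metadata columns only.  Config
files are flat ``key = value`` lines with dotted namespaces.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import GROUPS, Chromatogram, Cohort
from .config import SimulationConfig


class FormatError(ValueError):
    """Malformed cohort file; the message names the row or column."""


def _trace_columns(grid_length: int) -> list[str]:
    width = max(4, len(str(grid_length)))
    return [f"t{i:0{width}d}" for i in range(1, grid_length + 1)]


def write_cohort(cohort: Cohort, path: str | Path,
                 manifest_path: str | Path | None = None) -> None:
    """Write a cohort as wide CSV (and optionally a manifest CSV)."""
    cols = _trace_columns(cohort.grid_length)
    meta = pd.DataFrame({
        "sample_id": cohort.sample_ids,
        "group": cohort.labels,
        "run_index": [s.run_index for s in cohort],
    })
    traces = pd.DataFrame(cohort.resistance_matrix(), columns=cols)
    pd.concat([meta, traces], axis=1).to_csv(path, index=False)
    if manifest_path is not None:
        meta.to_csv(manifest_path, index=False)


def read_cohort(path: str | Path) -> Cohort:
    """Read a wide-CSV cohort, enforcing the container invariants."""
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise FormatError(f"ragged or unparseable CSV: {exc}") from exc
    for col in ("sample_id", "group", "run_index"):
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r}")
    trace_cols = [c for c in df.columns
                  if c not in ("sample_id", "group", "run_index")]
    expected = _trace_columns(len(trace_cols))
    if trace_cols != expected:
        missing = sorted(set(expected) - set(trace_cols))
        extra = sorted(set(trace_cols) - set(expected))
        detail = (f"missing trace column(s) {missing[:3]}" if missing
                  else f"unexpected column(s) {extra[:3]}")
        raise FormatError(f"trace columns do not form t0001..t{len(trace_cols)}: "
                          f"{detail}")
    bad_groups = set(df["group"]) - set(GROUPS)
    if bad_groups:
        row = int(df.index[df["group"].isin(bad_groups)][0])
        raise FormatError(f"unknown group label {sorted(bad_groups)[0]!r} "
                          f"at row {row}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise FormatError(f"duplicated sample_id {dup!r}")
    traces = df[trace_cols].to_numpy()
    if not np.issubdtype(traces.dtype, np.number):
        bad = next(c for c in trace_cols
                   if not pd.api.types.is_numeric_dtype(df[c]))
        raise FormatError(f"non-numeric trace values in column {bad!r}")
    samples = [
        Chromatogram(sample_id=str(row.sample_id), group=str(row.group),
                     resistance=traces[i], run_index=int(row.run_index))
        for i, row in enumerate(df.itertuples(index=False))
    ]
    return Cohort(samples)


# ---------------------------------------------------------------------------
# Config files
# ---------------------------------------------------------------------------

def write_config(config: SimulationConfig, path: str | Path) -> None:
    """Write a config as flat ``key = value`` lines with dotted namespaces."""
    lines = [f"{k} = {v}" for k, v in sorted(config.to_flat_dict().items())]
    Path(path).write_text("\n".join(lines) + "\n")


def read_config(path: str | Path,
                overrides: dict[str, str] | None = None) -> SimulationConfig:
    flat: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise FormatError(f"line {lineno}: expected 'key = value'")
        key, _, value = line.partition("=")
        flat[key.strip()] = value.strip()
    if overrides:
        flat.update(overrides)
    return SimulationConfig.from_flat_dict(flat)


# ---------------------------------------------------------------------------
# Model persistence
# ---------------------------------------------------------------------------

def write_lda_model(model, path: str | Path, extra: dict | None = None) -> None:
    """Persist a fitted stepwise-LDA model as JSON."""
    payload = {
        "model": "stepwise_lda",
        "feature_indices_1based": [int(j) + 1 for j in model.support_],
        "coefficients": [float(c) for c in model.coef_],
        "threshold": float(model.threshold_),
        "priors": [float(p) for p in model.estimator_.priors_],
    }
    if model.selection_ is not None:
        payload["entry_statistics"] = model.selection_.entry_statistics
        payload["tolerances"] = model.selection_.tolerances
        payload["wilks_path"] = model.selection_.wilks_path
    payload.update(extra or {})
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def write_plsda_model(model, path: str | Path, extra: dict | None = None) -> None:
    """Persist a fitted PLS-DA model as JSON."""
    payload = {
        "model": "plsda",
        "n_factors": int(model.n_components),
        "decision_threshold": float(model.decision_threshold),
        "y_mean": float(model.y_mean_),
        "y_loadings": [float(v) for v in model.y_loadings_],
        "coefficients": [float(v) for v in model.coef_],
        "x_mean": [float(v) for v in model.x_mean_],
    }
    payload.update(extra or {})
    Path(path).write_text(json.dumps(payload) + "\n")
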