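"""Reading and writing datasets, feature sets and run reports.

Datasets travel as plain CSV: first column the time axis, header row the
wavelengths, cells the signal.  Ground truth and results are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import KineticDataset
from .discretize import Feature, FeatureSet
from .workflows import PipelineResult

__all__ = [
    "read_dataset",
    "write_dataset",
    "feature_set_to_dict",
    "feature_set_from_dict",
    "write_report",
]

REPORT_SCHEMA = "kinenet-report/1"


class DatasetParseError(ValueError):
    pass


def read_dataset(path: str | Path) -> KineticDataset:
    """Parse a dataset CSV (time column, wavelength header, signal cells)."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise DatasetParseError(f"{path}: {exc}") from exc
    if df.shape[1] < 2:
        raise DatasetParseError(f"{path}: need a time column and >= 1 wavelength")
    try:
        wavelengths = np.array([float(c) for c in df.columns[1:]])
    except ValueError as exc:
        raise DatasetParseError(f"{path}: non-numeric wavelength header") from exc
    try:
        values = df.to_numpy(dtype=float, na_value=np.nan)
    except (ValueError, TypeError) as exc:
        raise DatasetParseError(f"{path}: non-numeric cell ({exc})") from exc
    if not np.all(np.isfinite(values)):
        bad = int(np.argwhere(~np.isfinite(values))[0, 0]) + 2  # header is line 1
        raise DatasetParseError(f"{path}: non-numeric or missing cell at line {bad}")
    times = values[:, 0]
    if not np.all(np.diff(times) > 0):
        bad = int(np.flatnonzero(np.diff(times) <= 0)[0]) + 3
        raise DatasetParseError(f"{path}: time not strictly increasing at line {bad}")
    try:
        return KineticDataset(times, wavelengths, values[:, 1:])
    except ValueError as exc:
        raise DatasetParseError(f"{path}: {exc}") from exc


def write_dataset(dataset: KineticDataset, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(
        dataset.signal,
        columns=[f"{w:.10g}" for w in dataset.wavelengths],
    )
    df.insert(0, "time", dataset.times)
    df.to_csv(path, index=False, float_format="%.17g")


def feature_set_to_dict(fs: FeatureSet) -> list[dict]:
    out = []
    for f in fs:
        out.append(
            {
                "tau": None if np.isinf(f.tau) else float(f.tau),
                "dads": [float(a) for a in np.atleast_1d(f.dads)],
                "per_wavelength_tau": (
                    None
                    if f.per_wavelength_tau is None
                    else [
                        None if not np.isfinite(t) else float(t)
                        for t in f.per_wavelength_tau
                    ]
                ),
                "flags": list(f.flags),
            }
        )
    return out


def feature_set_from_dict(items: list[dict]) -> FeatureSet:
    feats = []
    for d in items:
        pwt = d.get("per_wavelength_tau")
        feats.append(
            Feature(
                tau=np.inf if d["tau"] is None else float(d["tau"]),
                dads=np.asarray(d["dads"], dtype=float),
                per_wavelength_tau=(
                    None
                    if pwt is None
                    else np.array(
                        [np.nan if t is None else float(t) for t in pwt]
                    )
                ),
                flags=tuple(d.get("flags", ())),
            )
        )
    return FeatureSet(feats)


def write_report(
    result: PipelineResult,
    out_dir: str | Path,
    dataset: KineticDataset | None = None,
    config: dict | None = None,
) -> dict:
    """Write a self-describing result directory.

    ``summary.json`` (selected hyperparameters, branch, taus, MSE), the DADS
    as CSV (wavelength x feature), the residual matrix as CSV when the
    dataset is given, and an echo of the effective configuration.  Returns
    the summary dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lam, omega = result.selected
    summary: dict = {
        "schema": REPORT_SCHEMA,
        "lambda": float(lam),
        "omega": float(omega),
        "branch": result.branch,
        "status": result.status,
        "mse": float(result.mse),
        "support_size": int(np.count_nonzero(np.linalg.norm(result.solution.X, axis=1))),
    }
    if result.branch == "sparse" and result.features is not None:
        summary["features"] = feature_set_to_dict(result.features)
        summary["features_kept"] = feature_set_to_dict(result.features_kept)
    if result.refined is not None:
        summary["refined"] = {
            "mse": float(result.refined.mse),
            "converged": bool(result.refined.converged),
            "features": feature_set_to_dict(result.refined.features),
        }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    fs = (
        result.refined.features
        if result.refined is not None
        else (result.features_kept if result.features_kept is not None else None)
    )
    if fs is not None and len(fs) and dataset is not None:
        dads = pd.DataFrame(
            {f"tau={f.tau:.6g}": np.atleast_1d(f.dads) for f in fs},
            index=pd.Index(dataset.wavelengths, name="wavelength"),
        )
        dads.to_csv(out / "dads.csv", float_format="%.12g")
    if dataset is not None:
        from .design import build_designs
        from .solver import _as_lists

        designs = build_designs(dataset.times, result.taugrid)
        As, bs = _as_lists(np.asarray(designs), dataset.signal)
        resid = np.column_stack(
            [b - A @ result.solution.X[:, k] for k, (A, b) in enumerate(zip(As, bs))]
        )
        rdf = pd.DataFrame(
            resid, columns=[f"{w:.10g}" for w in dataset.wavelengths]
        )
        rdf.insert(0, "time", dataset.times)
        rdf.to_csv(out / "residuals.csv", index=False, float_format="%.12g")
    if config is not None:
        (out / "config.json").write_text(json.dumps(config, indent=2, default=str))
    return summary
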