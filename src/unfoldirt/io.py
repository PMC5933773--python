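"""File formats, run configuration and fit output.

Responses are rectangular delimited text (CSV/TSV), one row per person, one
column per item, with integer category codes.  Likert files conventionally
code categories from 1, so the reader shifts by ``base`` (default 1) to the
internal 0-based codes; a configurable missing sentinel maps to the
missingness mask.  Fit output is a tidy item-parameter table plus a
machine-readable JSON manifest carrying the configuration hash and seed so
runs can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .estimate import FitResult, ResponseData
from .exceptions import DataError
from .scoring import SEResult

__all__ = ["RunConfig", "read_responses", "write_fit", "fit_table"]


@dataclass
class RunConfig:
    """Serializable description of one estimation run."""

    # model block
    kernel: str = "UM8"
    n_categories: int = 3
    n_dims: int = 1
    item_dimension: Optional[list[int]] = None
    threshold_mode: Optional[str] = None
    # data block
    data_path: Optional[str] = None
    delimiter: str = ","
    missing: str = "NA"
    category_base: int = 1
    # estimation block
    points_per_dim: int = 50
    quadrature_range: tuple[float, float] = (-4.0, 4.0)
    quadrature_rule: str = "rectangular"
    tol: float = 1e-4
    max_iter: int = 500
    seed: int = 1
    se_method: Optional[str] = None
    # output block
    output_dir: str = "."

    def to_yaml(self, path: Union[str, Path]) -> None:
        payload = asdict(self)
        payload["quadrature_range"] = list(self.quadrature_range)
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text())
        if "quadrature_range" in payload:
            payload["quadrature_range"] = tuple(payload["quadrature_range"])
        return cls(**payload)

    def digest(self) -> str:
        payload = asdict(self)
        payload["quadrature_range"] = list(self.quadrature_range)
        raw = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(raw).hexdigest()[:16]


def read_responses(
    path: Union[str, Path],
    delimiter: str = ",",
    missing: Union[str, int] = "NA",
    base: int = 1,
    header: Optional[int] = None,
    n_categories: Optional[int] = None,
) -> ResponseData:
    """Read a persons x items response matrix from delimited text.

    Codes are shifted by ``base`` to the internal 0..C range; cells equal to
    the ``missing`` sentinel become masked entries.  Out-of-range codes and
    ragged rows raise :class:`DataError` naming the offending cell.
    """
    # pandas silently pads short rows with NaN, so check rectangularity first
    with open(path) as fh:
        widths = [line.count(delimiter) for line in fh if line.strip()]
    if widths and len(set(widths)) > 1:
        bad = next(i for i, w in enumerate(widths) if w != widths[0])
        raise DataError(f"ragged row {bad} in {path}")
    try:
        df = pd.read_csv(
            path, sep=delimiter, header=header, na_values=[str(missing)],
            skipinitialspace=True,
        )
    except pd.errors.ParserError as exc:
        raise DataError(f"malformed response file {path}: {exc}") from exc
    raw = df.to_numpy()
    codes = np.full(raw.shape, -1, dtype=np.int64)
    for (r, c), v in np.ndenumerate(raw):
        if pd.isna(v):
            continue
        try:
            iv = int(v)
        except (TypeError, ValueError) as exc:
            raise DataError(
                f"non-integer code {v!r} at row {r}, column {c} of {path}"
            ) from exc
        codes[r, c] = iv - base
    if np.all(codes < 0):
        raise DataError(f"no observed responses in {path}")
    C = int(codes.max()) if n_categories is None else int(n_categories)
    if np.any(codes > C) or np.any(codes[codes >= 0] < 0):
        bad = np.argwhere(codes > C)[0]
        raise DataError(
            f"code out of range 0..{C} at row {bad[0]}, column {bad[1]}"
        )
    if codes.max() < 1:
        raise DataError("responses show fewer than two categories")
    return ResponseData(codes, C)


def fit_table(result: FitResult, se: Optional[SEResult] = None) -> pd.DataFrame:
    """Tidy (parameter, estimate, SE) table for a fit."""
    names = result.param_names
    est = result.packed()
    tab = pd.DataFrame({"parameter": names, "estimate": est})
    tab["family"] = result.spec.param_families()
    if se is not None and se.hessian_ok:
        tab["se"] = se.se
    else:
        tab["se"] = np.nan        # written as empty cells, not zeros
    return tab


def write_fit(
    result: FitResult,
    se: Optional[SEResult],
    outdir: Union[str, Path],
    config: Optional[RunConfig] = None,
) -> dict[str, Path]:
    """Write the item-parameter table, fit summary and run manifest.

    Files: ``parameters.csv`` (parameter, estimate, SE; SE cells are empty
    when the Hessian was not usable), ``summary.json`` (log-likelihood,
    iteration count, convergence flag) and ``manifest.json`` (tolerances,
    seed, configuration hash) for reproducibility.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    tab = fit_table(result, se)
    paths["parameters"] = outdir / "parameters.csv"
    tab.to_csv(paths["parameters"], index=False, float_format="%.10g")
    summary = {
        "loglik": result.loglik,
        "n_iterations": result.n_iterations,
        "converged": bool(result.converged),
        "kernel": result.spec.kernel,
        "n_items": result.spec.n_items,
        "n_categories": result.spec.n_categories,
        "hessian_ok": bool(se.hessian_ok) if se is not None else None,
    }
    paths["summary"] = outdir / "summary.json"
    paths["summary"].write_text(json.dumps(summary, indent=2))
    manifest = {
        "tol": config.tol if config else 1e-4,
        "max_iter": config.max_iter if config else 500,
        "seed": config.seed if config else None,
        "config_hash": config.digest() if config else None,
        "points_per_dim": config.points_per_dim if config else 50,
        "quadrature_range": list(config.quadrature_range) if config else [-4.0, 4.0],
    }
    paths["manifest"] = outdir / "manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=2))
    return paths
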