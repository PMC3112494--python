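"""JSON and CSV serialization for densities, models and results.

Structured artifacts (densities, full models, model spaces, search results)
are UTF-8 JSON with row-major matrices; tabular data (GLM designs, network
time series) are CSV with a header row, read and written through pandas.
Floats survive a write/read round trip exactly (shortest-repr encoding).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .core import FullModel
from .gaussian import GaussianDensity
from .glm import GLMData
from .search import SearchResult, SwitchSpace

__all__ = [
    "density_to_dict",
    "density_from_dict",
    "full_model_to_dict",
    "full_model_from_dict",
    "load_full_model",
    "save_full_model",
    "load_density",
    "save_density",
    "load_switch_space",
    "search_result_to_dict",
    "load_glm_csv",
    "save_glm_csv",
    "load_series_csv",
    "save_series_csv",
]


def density_to_dict(d: GaussianDensity) -> dict[str, Any]:
    """Serialize a density.  Densities with point-mass coordinates are
    written in covariance form (zero rows/columns), proper ones in precision
    form."""
    out: dict[str, Any] = {"mean": d.mean.tolist()}
    if d.point_mass.any():
        out["covariance"] = d.covariance.tolist()
    else:
        out["precision"] = d.precision.tolist()
    if d.labels is not None:
        out["labels"] = list(d.labels)
    return out


def density_from_dict(obj: dict[str, Any]) -> GaussianDensity:
    if "mean" not in obj:
        raise ValueError("density is missing the 'mean' field")
    mean = np.asarray(obj["mean"], dtype=float)
    labels = tuple(obj["labels"]) if "labels" in obj else None
    if "precision" in obj:
        return GaussianDensity(mean, np.asarray(obj["precision"], dtype=float), labels)
    if "covariance" in obj:
        return GaussianDensity.from_covariance(
            mean, np.asarray(obj["covariance"], dtype=float), labels
        )
    if "variances" in obj:
        return GaussianDensity.from_variances(
            mean, np.asarray(obj["variances"], dtype=float), labels
        )
    raise ValueError("density needs 'precision', 'covariance' or 'variances'")


def full_model_to_dict(fm: FullModel) -> dict[str, Any]:
    return {
        "prior": density_to_dict(fm.prior),
        "posterior": density_to_dict(fm.posterior),
        "free_energy": float(fm.free_energy),
        "meta": _jsonable(dict(fm.meta)),
    }


def full_model_from_dict(obj: dict[str, Any]) -> FullModel:
    for key in ("prior", "posterior"):
        if key not in obj:
            raise ValueError(f"full model is missing the '{key}' field")
    return FullModel(
        prior=density_from_dict(obj["prior"]),
        posterior=density_from_dict(obj["posterior"]),
        free_energy=float(obj.get("free_energy", 0.0)),
        meta=obj.get("meta", {}),
    )


def _read_json(path: str | Path) -> dict[str, Any]:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def _write_json(obj: dict[str, Any], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=1)
        fh.write("\n")


def load_density(path: str | Path) -> GaussianDensity:
    return density_from_dict(_read_json(path))


def save_density(d: GaussianDensity, path: str | Path) -> None:
    _write_json(density_to_dict(d), path)


def load_full_model(path: str | Path) -> FullModel:
    return full_model_from_dict(_read_json(path))


def save_full_model(fm: FullModel, path: str | Path) -> None:
    _write_json(full_model_to_dict(fm), path)


def load_switch_space(path: str | Path, base_prior: GaussianDensity) -> SwitchSpace:
    """Model-space JSON: {"switchable": [...], "gamma": x, "pairs": [[i,j],...]}."""
    obj = _read_json(path)
    if "switchable" not in obj or "gamma" not in obj:
        raise ValueError("model space needs 'switchable' and 'gamma'")
    return SwitchSpace(
        base_prior=base_prior,
        switchable=tuple(int(i) for i in obj["switchable"]),
        gamma=float(obj["gamma"]),
        constraints=tuple(tuple(int(i) for i in g) for g in obj.get("pairs", [])),
    )


def search_result_to_dict(sr: SearchResult) -> dict[str, Any]:
    return {
        "switch_vectors": [list(v) for v in sr.switch_vectors],
        "delta_f": sr.delta_f.tolist(),
        "posterior_probs": sr.posterior_probs.tolist(),
        "best_index": int(sr.best_index),
        "best_switches": list(sr.best_switches),
        "best_delta_f": float(sr.delta_f[sr.best_index]),
        "meta": _jsonable(sr.meta),
    }


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (str, int, float, bool)) or obj is None:
        return obj
    return str(obj)


# --------------------------------------------------------------------- #
# tabular data
# --------------------------------------------------------------------- #
def save_glm_csv(data: GLMData, path: str | Path) -> None:
    """One row per observation: response column 'y', design columns 'x0'...,
    noise-group column 'group'."""
    df = pd.DataFrame(data.X, columns=[f"x{j}" for j in range(data.p)])
    df.insert(0, "y", data.y)
    df["group"] = data.partition
    df.to_csv(path, index=False)


def load_glm_csv(
    path: str | Path, response: str = "y", group: str | None = "group"
) -> GLMData:
    """Read a GLM dataset; every column other than the response and the
    (optional) group column is a regressor.  A missing group column means a
    single noise group."""
    df = pd.read_csv(path)
    if response not in df.columns:
        raise ValueError(f"response column {response!r} not found in {path}")
    part = None
    if group is not None and group in df.columns:
        part = df[group].to_numpy(dtype=int)
        df = df.drop(columns=[group])
    y = df[response].to_numpy(dtype=float)
    X = df.drop(columns=[response]).to_numpy(dtype=float)
    return GLMData(y=y, X=X, partition=part)


def save_series_csv(series: np.ndarray, path: str | Path) -> None:
    """Network time series, bins x nodes, header node_0..node_{n-1}."""
    n = series.shape[1]
    pd.DataFrame(series, columns=[f"node_{i}" for i in range(n)]).to_csv(
        path, index=False
    )


def load_series_csv(path: str | Path) -> np.ndarray:
    return pd.read_csv(path).to_numpy(dtype=float)
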