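"""Feature-table / label-file reading and the run configuration.

Feature files are delimited text with samples as rows: a header of feature
names and a first column of unique sample ids.  Label files have two
columns, sample id and class label.  The delimiter (comma or tab) is
sniffed from the header line unless given.  Internally the mathematics uses
samples as columns; the transpose happens exactly once, here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .solver import Hyperparameters

__all__ = [
    "RunConfig",
    "read_features",
    "write_features",
    "read_labels",
    "write_labels",
    "join_features_labels",
]


def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","


def read_features(path, delimiter: str | None = None) -> tuple[np.ndarray, list[str], list[str]]:
    """Read a feature table.

    Returns ``(X, sample_ids, feature_names)`` with X of shape
    (n_samples, n_features), rows aligned with ``sample_ids``.
    """
    path = Path(path)
    sep = delimiter or _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample id(s) in {path.name}: {dups}")
    non_numeric = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if non_numeric:
        raise ValueError(f"non-numeric feature column(s) in {path.name}: {non_numeric}")
    if df.isna().any().any():
        bad = df.columns[df.isna().any()].tolist()
        raise ValueError(f"missing values in column(s) of {path.name}: {bad}")
    return (
        df.to_numpy(dtype=float),
        [str(i) for i in df.index],
        [str(c) for c in df.columns],
    )


def write_features(path, X, sample_ids, feature_names, delimiter: str = ",") -> None:
    df = pd.DataFrame(np.asarray(X), index=sample_ids, columns=feature_names)
    df.index.name = "sample_id"
    df.to_csv(path, sep=delimiter)


def read_labels(path, delimiter: str | None = None) -> tuple[list[str], np.ndarray]:
    """Read a two-column (sample id, class label) file."""
    path = Path(path)
    sep = delimiter or _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[1] != 2:
        raise ValueError(f"{path.name}: expected 2 columns (id, label), got {df.shape[1]}")
    ids = df.iloc[:, 0].tolist()
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate sample ids in {path.name}")
    return ids, df.iloc[:, 1].to_numpy()


def write_labels(path, sample_ids, labels, delimiter: str = ",") -> None:
    pd.DataFrame({"sample_id": sample_ids, "label": labels}).to_csv(
        path, sep=delimiter, index=False
    )


def join_features_labels(
    X: np.ndarray, feature_ids: list[str], label_ids: list[str], labels: np.ndarray
) -> np.ndarray:
    """Align a label file to a feature table; ids must match 1:1."""
    missing = sorted(set(feature_ids) - set(label_ids))
    if missing:
        raise ValueError(f"sample id(s) without a label: {missing}")
    extra = sorted(set(label_ids) - set(feature_ids))
    if extra:
        raise ValueError(f"label id(s) absent from the feature table: {extra}")
    lookup = dict(zip(label_ids, labels))
    return np.array([lookup[i] for i in feature_ids])


_KNOWN_KEYS = {
    "lambda1", "lambda2", "lambda3", "lambda4", "lambda5",
    "delta", "maxiter", "eps_row", "seed",
    "k_neighbors", "sigma", "n_atoms", "encode_gamma", "n_folds",
    "log_level",
}

LAMBDA_BOUNDS = (1e-6, 1e6)


@dataclass
class RunConfig:
    """Validated configuration for the command-line pipeline."""

    hp: Hyperparameters = field(default_factory=Hyperparameters)
    k_neighbors: int = 5
    sigma: float | str = "median"
    n_atoms: int | None = None
    encode_gamma: float | None = None
    n_folds: int = 5
    log_level: str = "INFO"

    @classmethod
    def from_mapping(cls, mapping: dict | None) -> "RunConfig":
        mapping = dict(mapping or {})
        unknown = set(mapping) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        hp_keys = {k: mapping.pop(k) for k in list(mapping)
                   if k in Hyperparameters().to_dict()}
        hp = Hyperparameters(**{**Hyperparameters().to_dict(), **hp_keys})
        lo, hi = LAMBDA_BOUNDS
        for name in ("lambda1", "lambda2", "lambda3", "lambda4", "lambda5"):
            v = getattr(hp, name)
            if v != 0 and not lo <= v <= hi:
                raise ValueError(f"{name}={v:g} outside the supported range [{lo:g}, {hi:g}]")
        sigma = mapping.pop("sigma", "median")
        if isinstance(sigma, str) and sigma != "median":
            raise ValueError(f"sigma must be a positive number or 'median', got {sigma!r}")
        return cls(hp=hp, sigma=sigma, **mapping)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if data is not None and not isinstance(data, dict):
            raise ValueError("config file must contain a YAML mapping")
        return cls.from_mapping(data)

    def resolved(self) -> dict:
        return {
            **self.hp.to_dict(),
            "k_neighbors": self.k_neighbors,
            "sigma": self.sigma,
            "n_atoms": self.n_atoms,
            "encode_gamma": self.encode_gamma,
            "n_folds": self.n_folds,
            "log_level": self.log_level,
        }
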