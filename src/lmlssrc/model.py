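"""User-facing estimator: the LMLS-SRC model and its fitted results.

``LargeMarginLocalSRC`` is constructed from a labelled feature table
(samples as rows, the ergonomic convention; the internal mathematics uses
samples as columns and transposes exactly once at this boundary).  Its
``fit()`` builds the margin and locality graphs, runs the alternating
optimisation, and returns an :class:`LMLSResults` carrying the learned
dictionary D, codes A, classifier W, the objective trace and prediction /
serialization methods.

Prediction is stateless and per-sample: a new sample x is ridge-coded
against the learned dictionary, a = (D.T D + gamma I)^{-1} D.T x, and
labelled by the argmax of the classifier response W a (ties broken by class
order).  The argmax rule is chosen because W is learned jointly with the
codes; the classical class-wise reconstruction rule remains available in
the plain SRC baseline (:func:`src_baseline_fit_predict`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .graphs import LabelVector, build_locality_graph, build_margin_graph
from .solver import FitTrace, Hyperparameters, fit_lmls

__all__ = [
    "LargeMarginLocalSRC",
    "LMLSResults",
    "PredictionResult",
    "src_baseline_fit_predict",
    "load_model",
]

FORMAT_VERSION = 1


@dataclass(frozen=True)
class PredictionResult:
    """Predicted labels and the K x N classifier score matrix W @ A."""

    labels: np.ndarray
    scores: np.ndarray
    class_ids: np.ndarray


class LargeMarginLocalSRC:
    """Discriminative dictionary learning classifier.

    Parameters
    ----------
    X : (n_samples, n_features) array-like
        Feature table, one row per sample.
    labels : (n_samples,) array-like
        Class labels (integers or strings); at least two classes.
    hp : Hyperparameters, optional
        Trade-off parameters lambda1..lambda5 and loop controls.
    n_atoms : int, optional
        Dictionary size m; defaults to the number of training samples.
    k_neighbors : int
        Neighbourhood size of the locality graph.
    sigma : float or "median"
        Heat-kernel bandwidth; "median" uses the median edge distance.
    encode_gamma : float, optional
        Ridge weight for test-time coding; defaults to lambda1.
    """

    def __init__(
        self,
        X,
        labels,
        hp: Hyperparameters | None = None,
        n_atoms: int | None = None,
        k_neighbors: int = 5,
        sigma: float | str = "median",
        encode_gamma: float | None = None,
    ):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (samples x features)")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        labels = np.asarray(labels)
        if labels.shape != (X.shape[0],):
            raise ValueError("labels length must equal the number of rows of X")
        self.label_vector = LabelVector(labels)
        if self.label_vector.n_classes < 2:
            raise ValueError(
                "need at least two classes: the margin term does not "
                "discriminate within a single class"
            )
        self._Xc = X.T  # internal orientation: samples as columns
        self.hp = hp if hp is not None else Hyperparameters()
        self.n_atoms = n_atoms
        self.k_neighbors = k_neighbors
        self.sigma = sigma
        self.encode_gamma = (
            float(encode_gamma) if encode_gamma is not None else self.hp.lambda1
        )

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, label_col: str, **kwargs
    ) -> "LargeMarginLocalSRC":
        """Build from a DataFrame with a label column; all other columns
        must be numeric features."""
        if label_col not in df.columns:
            raise ValueError(f"label column {label_col!r} not in DataFrame")
        features = df.drop(columns=[label_col])
        return cls(features.to_numpy(dtype=float), df[label_col].to_numpy(), **kwargs)

    def fit(self) -> "LMLSResults":
        """Build the sample graphs and run the alternating optimisation."""
        labels = self.label_vector.labels
        # integer-encode labels for the solver; keep original ids for output
        codes = np.searchsorted(self.label_vector.class_ids, labels)
        margin = build_margin_graph(codes)
        # clamp the neighbourhood to the data size so tiny sets still fit
        k = min(self.k_neighbors, self._Xc.shape[1] - 1)
        locality = build_locality_graph(self._Xc, k, self.sigma)
        D, A, W, trace = fit_lmls(
            self._Xc,
            codes,
            self.hp,
            margin.S_sym,
            locality.L,
            n_atoms=self.n_atoms,
        )
        return LMLSResults(
            model=self,
            dictionary=D,
            coefficients=A,
            classifier=W,
            trace=trace,
            sigma_used=locality.sigma,
        )


class LMLSResults:
    """Fitted LMLS-SRC model: learned blocks, trace and prediction methods."""

    def __init__(
        self,
        model: LargeMarginLocalSRC | None,
        dictionary: np.ndarray,
        coefficients: np.ndarray | None,
        classifier: np.ndarray,
        trace: FitTrace | None = None,
        *,
        class_ids: np.ndarray | None = None,
        hp: Hyperparameters | None = None,
        encode_gamma: float | None = None,
        sigma_used: float | None = None,
    ):
        self.model = model
        self.dictionary = dictionary
        self.coefficients = coefficients
        self.classifier = classifier
        self.trace = trace
        self.sigma_used = sigma_used
        if model is not None:
            self.class_ids = model.label_vector.class_ids
            self.hp = model.hp
            self.encode_gamma = model.encode_gamma
        else:
            assert class_ids is not None and hp is not None
            self.class_ids = class_ids
            self.hp = hp
            self.encode_gamma = encode_gamma if encode_gamma is not None else hp.lambda1

    @property
    def feature_dim(self) -> int:
        return self.dictionary.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.dictionary.shape[1]

    # ---- prediction -----------------------------------------------------

    def encode(self, Xnew, gamma: float | None = None) -> np.ndarray:
        """Ridge-code new samples: columns a = (D'D + gamma I)^{-1} D'x.

        ``Xnew`` is (n_samples, n_features); the returned code matrix is
        (n_atoms, n_samples) to match the training-code orientation.
        """
        Xc = np.asarray(Xnew, dtype=float)
        if Xc.ndim == 1:
            Xc = Xc[None, :]
        if Xc.shape[1] != self.feature_dim:
            raise ValueError(
                f"expected {self.feature_dim} features, got {Xc.shape[1]}"
            )
        g = self.encode_gamma if gamma is None else float(gamma)
        D = self.dictionary
        M = D.T @ D + g * np.eye(self.n_atoms)
        return np.linalg.solve(M, D.T @ Xc.T)

    def predict(self, Xnew) -> PredictionResult:
        """Classify new samples by argmax of the classifier response W a."""
        A = self.encode(Xnew)
        scores = self.classifier @ A
        idx = np.argmax(scores, axis=0)  # argmax takes the lowest index on ties
        return PredictionResult(
            labels=self.class_ids[idx], scores=scores, class_ids=self.class_ids
        )

    # ---- reporting ------------------------------------------------------

    def summary(self) -> str:
        hp = self.hp
        lines = [
            "Large Margin / Local Structure SRC results",
            "=" * 46,
            f"feature dim          {self.feature_dim}",
            f"dictionary atoms     {self.n_atoms}",
            f"classes              {len(self.class_ids)}",
            f"lambda1..5           {hp.lambda1:g}, {hp.lambda2:g}, "
            f"{hp.lambda3:g}, {hp.lambda4:g}, {hp.lambda5:g}",
            f"encode gamma         {self.encode_gamma:g}",
        ]
        if self.sigma_used is not None:
            lines.append(f"locality sigma       {self.sigma_used:.6g}")
        if self.trace is not None:
            lines += [
                f"iterations           {self.trace.n_iterations - 1}",
                f"converged            {self.trace.converged}",
                f"final objective      {self.trace.objective_values[-1]:.6g}",
            ]
        max_atom = float(np.max(np.sum(self.dictionary**2, axis=0)))
        lines.append(f"max ||d_i||^2        {max_atom:.8f}")
        return "\n".join(lines)

    # ---- serialization --------------------------------------------------

    def save(self, path) -> None:
        """Write a single .npz archive of arrays plus a JSON metadata block."""
        meta = {
            "format_version": FORMAT_VERSION,
            "class_ids": [_json_safe(c) for c in self.class_ids],
            "class_dtype": str(self.class_ids.dtype),
            "hyperparameters": self.hp.to_dict(),
            "encode_gamma": self.encode_gamma,
        }
        np.savez(
            path,
            dictionary=self.dictionary,
            classifier=self.classifier,
            metadata=np.array(json.dumps(meta, ensure_ascii=False)),
        )

    @classmethod
    def load(cls, path) -> "LMLSResults":
        with np.load(path, allow_pickle=False) as archive:
            for required in ("dictionary", "classifier", "metadata"):
                if required not in archive:
                    raise ValueError(f"model file is missing field {required!r}")
            meta = json.loads(str(archive["metadata"]))
            if meta.get("format_version") != FORMAT_VERSION:
                raise ValueError(
                    "unsupported model format version "
                    f"{meta.get('format_version')!r} (expected {FORMAT_VERSION})"
                )
            class_ids = np.array(meta["class_ids"], dtype=meta["class_dtype"])
            hp = Hyperparameters(**meta["hyperparameters"])
            return cls(
                model=None,
                dictionary=archive["dictionary"],
                coefficients=None,
                classifier=archive["classifier"],
                class_ids=class_ids,
                hp=hp,
                encode_gamma=float(meta["encode_gamma"]),
            )


def _json_safe(value):
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    return str(value) if not isinstance(value, (int, float, str)) else value


def load_model(path) -> LMLSResults:
    return LMLSResults.load(path)


def src_baseline_fit_predict(
    Xtrain, train_labels, Xtest, gamma: float = 1e-3
) -> PredictionResult:
    """Plain l2-coding sparse representation classifier baseline.

    The dictionary is the raw training columns grouped by class; a test
    sample is ridge-coded over the whole dictionary and assigned to the
    class whose block best reconstructs it (minimum ||x - D_k a_k||_2).
    """
    Xtr = np.asarray(Xtrain, dtype=float).T  # (d, N)
    Xte = np.asarray(Xtest, dtype=float).T
    labels = np.asarray(train_labels)
    lv = LabelVector(labels)
    class_ids = lv.class_ids
    order = np.argsort(np.searchsorted(class_ids, labels), kind="stable")
    D = Xtr[:, order]
    sorted_labels = labels[order]
    M = D.T @ D + gamma * np.eye(D.shape[1])
    A = np.linalg.solve(M, D.T @ Xte)
    n_test = Xte.shape[1]
    errors = np.empty((class_ids.size, n_test))
    for k, cid in enumerate(class_ids):
        block = sorted_labels == cid
        errors[k] = np.linalg.norm(Xte - D[:, block] @ A[block, :], axis=0)
    idx = np.argmin(errors, axis=0)
    return PredictionResult(
        labels=class_ids[idx], scores=-errors, class_ids=class_ids
    )
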