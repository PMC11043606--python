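"""scikit-learn estimator wrapping the tree network.

``BTCNNClassifier`` follows the sklearn contract (``fit`` / ``predict`` /
``predict_proba``, ``get_params`` / ``set_params``, fitted attributes
with a trailing underscore) so it composes with ``clone``, pipelines and
model selection.  Inputs are image stacks ``(n_samples, H, W)`` or
``(n_samples, H, W, C)``; targets may be integer class indices or one-hot
rows.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from ..archspec import BTCNNSpec, default_btcnn_spec
from .network import TrainConfig, build_network, train

__all__ = ["BTCNNClassifier"]


class BTCNNClassifier(ClassifierMixin, BaseEstimator):
    """Balanced binary-tree CNN classifier.

    Parameters
    ----------
    spec
        Architecture description; ``None`` selects the published 4-class
        architecture for 200x200 grayscale input.
    epochs, batch_size, learning_rate
        Training protocol; defaults follow the published setup
        (20 epochs, batch 24, Adam at 1e-4).
    random_state
        Seed driving weight initialisation, shuffling and dropout.
    """

    def __init__(
        self,
        spec: BTCNNSpec | None = None,
        epochs: int = 20,
        batch_size: int = 24,
        learning_rate: float = 1e-4,
        shuffle: bool = True,
        random_state: int | None = None,
    ) -> None:
        self.spec = spec
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.shuffle = shuffle
        self.random_state = random_state

    def _as_images(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 3:
            X = X[..., None]
        if X.ndim != 4:
            raise ValueError("X must be (n_samples, H, W) or (n_samples, H, W, C)")
        return X

    def fit(self, X, y) -> "BTCNNClassifier":
        X = self._as_images(X)
        y = np.asarray(y)
        spec = self.spec if self.spec is not None else default_btcnn_spec()
        n_classes = spec.n_classes
        if y.ndim == 2:  # one-hot rows
            if y.shape[1] != n_classes:
                raise ValueError(
                    f"one-hot labels have {y.shape[1]} columns, spec expects {n_classes}"
                )
            y_idx = y.argmax(axis=1)
            self.classes_ = np.arange(n_classes)
        else:
            self.classes_, y_idx = np.unique(y, return_inverse=True)
            if len(self.classes_) > n_classes:
                raise ValueError(
                    f"{len(self.classes_)} classes in y but spec has {n_classes} outputs"
                )
        onehot = np.zeros((len(y_idx), n_classes), dtype=np.float32)
        onehot[np.arange(len(y_idx)), y_idx] = 1.0

        seed = 0 if self.random_state is None else int(self.random_state)
        self.spec_ = spec
        self.network_ = build_network(spec, seed=seed)
        config = TrainConfig(
            learning_rate=self.learning_rate,
            epochs=self.epochs,
            batch_size=self.batch_size,
            shuffle=self.shuffle,
            seed=seed,
        )
        self.history_ = train(self.network_, X, onehot, config)
        self.n_features_in_ = int(np.prod(X.shape[1:]))
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "network_")
        X = self._as_images(X)
        probs = np.empty((len(X), self.spec_.n_classes), dtype=np.float64)
        step = max(1, self.batch_size)
        for start in range(0, len(X), step):  # bounded memory on big stacks
            probs[start : start + step] = self.network_.forward(X[start : start + step])
        if len(self.classes_) < probs.shape[1]:
            # y carried fewer classes than the spec has outputs
            probs = probs[:, : len(self.classes_)]
            probs = probs / probs.sum(axis=1, keepdims=True)
        return probs

    def predict(self, X) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]
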