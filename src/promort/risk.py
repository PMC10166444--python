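"""Shared logistic risk-model container.

A :class:`RiskModel` stores a fitted logistic regression on the ORIGINAL
feature scale (any standardization used during fitting has already been
folded back into the intercept and coefficients; the centers/scales are kept
for provenance).  It predicts per-patient risk strictly inside (0, 1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = ["RiskModel", "predict_risk"]

_P_FLOOR = 1e-300
_P_CEIL = 1.0 - 1e-16


@dataclass
class RiskModel:
    """Logistic risk model: risk = expit(intercept + X @ coefficients)."""

    feature_names: list
    intercept: float
    coefficients: np.ndarray
    center: Optional[np.ndarray] = None    # standardization used in fitting
    scale: Optional[np.ndarray] = None
    penalty: Optional[float] = None        # lambda of the L1 stage, if any
    adaptive_gamma: Optional[float] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.feature_names) != self.coefficients.size:
            raise ValueError(
                f"{len(self.feature_names)} feature names but "
                f"{self.coefficients.size} coefficients")
        for attr in ("center", "scale"):
            v = getattr(self, attr)
            if v is not None:
                setattr(self, attr, np.asarray(v, dtype=float))

    # -- prediction ---------------------------------------------------------
    def _design(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = [c for c in self.feature_names if c not in X.columns]
            if missing:
                raise ValueError(
                    f"input table is missing model feature(s): {missing[:5]}"
                    + ("..." if len(missing) > 5 else ""))
            mat = X[self.feature_names].to_numpy(dtype=float)
        else:
            mat = np.asarray(X, dtype=float)
            if mat.ndim == 1:
                mat = mat.reshape(1, -1)
            if mat.shape[1] != len(self.feature_names):
                raise ValueError(
                    f"expected {len(self.feature_names)} feature columns, "
                    f"got {mat.shape[1]}")
        if np.isnan(mat).any():
            raise ValueError("input features contain missing values; impute "
                             "before prediction")
        return mat

    def linear_predictor(self, X) -> np.ndarray:
        return self.intercept + self._design(X) @ self.coefficients

    def predict(self, X) -> np.ndarray:
        """Per-patient risk, clipped to the open interval (0, 1)."""
        return np.clip(expit(self.linear_predictor(X)), _P_FLOOR, _P_CEIL)

    @property
    def nonzero_features(self) -> list:
        return [n for n, b in zip(self.feature_names, self.coefficients)
                if b != 0.0]

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "feature_names": list(self.feature_names),
            "intercept": self.intercept,
            "coefficients": self.coefficients.tolist(),
            "center": None if self.center is None else self.center.tolist(),
            "scale": None if self.scale is None else self.scale.tolist(),
            "penalty": self.penalty,
            "adaptive_gamma": self.adaptive_gamma,
            "metadata": self.metadata,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "RiskModel":
        return cls(
            feature_names=list(d["feature_names"]),
            intercept=float(d["intercept"]),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            center=None if d.get("center") is None else np.asarray(d["center"]),
            scale=None if d.get("scale") is None else np.asarray(d["scale"]),
            penalty=d.get("penalty"),
            adaptive_gamma=d.get("adaptive_gamma"),
            metadata=d.get("metadata", {}),
        )

    @classmethod
    def from_json(cls, path) -> "RiskModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def predict_risk(model: RiskModel, X) -> np.ndarray:
    """Functional alias for :meth:`RiskModel.predict`."""
    return model.predict(X)
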