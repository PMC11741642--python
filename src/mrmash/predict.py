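"""Polygenic scoring and prediction-accuracy evaluation."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = ["Prediction", "pgs_score", "evaluate_r2"]


@dataclass
class Prediction:
    """Predicted phenotype matrix for a test set."""

    yhat: np.ndarray
    phenotype_ids: list[str]

    def __post_init__(self) -> None:
        self.yhat = np.asarray(self.yhat, dtype=float)
        if not np.all(np.isfinite(self.yhat)):
            raise ValueError("predictions contain non-finite values")


def pgs_score(
    X_test: np.ndarray,
    B_bar: np.ndarray,
    variant_ids: Optional[Sequence[str]] = None,
    effect_variant_ids: Optional[Sequence[str]] = None,
    phenotype_ids: Optional[Sequence[str]] = None,
    per_chrom_parts: Optional[Sequence[tuple[np.ndarray, np.ndarray]]] = None,
) -> Prediction:
    """Linear polygenic scores ŷ = X_test · B̄.

    When models are fitted per chromosome, pass the (X_part, B_part) pairs in
    ``per_chrom_parts``; scores are additive across parts.  Variant id lists,
    when given for both sides, must match exactly (order included).
    """
    if per_chrom_parts is not None:
        parts = [np.asarray(X, dtype=float) @ np.asarray(B, dtype=float)
                 for X, B in per_chrom_parts]
        yhat = np.sum(parts, axis=0)
    else:
        X_test = np.asarray(X_test, dtype=float)
        B_bar = np.asarray(B_bar, dtype=float)
        if variant_ids is not None and effect_variant_ids is not None:
            mism = [
                (i, a, b)
                for i, (a, b) in enumerate(zip(variant_ids, effect_variant_ids))
                if a != b
            ]
            if len(variant_ids) != len(effect_variant_ids) or mism:
                raise ValueError(
                    "variant ids of genotypes and effects do not align; "
                    f"first mismatches: {mism[:5]}"
                )
        if X_test.shape[1] != B_bar.shape[0]:
            raise ValueError(
                f"X_test has {X_test.shape[1]} variants but B_bar has {B_bar.shape[0]}"
            )
        yhat = X_test @ B_bar
    r = yhat.shape[1] if yhat.ndim == 2 else 1
    ids = list(phenotype_ids) if phenotype_ids is not None else [
        f"ph{t + 1}" for t in range(r)
    ]
    return Prediction(yhat=yhat, phenotype_ids=ids)


def evaluate_r2(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """R² from the regression (with intercept) of true on predicted phenotype.

    Equals the squared Pearson correlation, hence invariant to affine
    transforms of the prediction; its expectation is bounded above by the
    genomic heritability under the simulation model.  A zero-variance
    prediction returns 0 by convention so null fits evaluate cleanly.
    """
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.shape != y_pred.shape:
        raise ValueError(
            f"length mismatch: y_true has {y_true.size}, y_pred has {y_pred.size}"
        )
    n = y_true.size
    if n < 3:
        raise ValueError("need at least 3 test individuals")
    vp = np.var(y_pred)
    vt = np.var(y_true)
    if vp == 0 or vt == 0:
        return 0.0
    c = np.corrcoef(y_true, y_pred)[0, 1]
    return float(c * c)
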