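"""Cox proportional-hazards fits: univariate screening and small signatures.

Univariate fits provide the per-gene Wald P-values that seed the random
walk and the significance screen for the initial feature set; small
multivariate fits are the signature models scored in the exhaustive
combination search. Fitting is by partial-likelihood maximization with the
Efron approximation for tied event times (lifelines defaults). Expression
is used as-is (raw log-expression), with no standardization.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError

from .datasets import Dataset, ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "UnivariateCoxResult",
    "SignatureModel",
    "SingularFitError",
    "univariate_cox",
    "screen",
    "fit_signature",
    "signature_risk",
]


class SingularFitError(ValueError):
    """Raised when the design matrix is singular (e.g. collinear features)."""


@dataclass
class UnivariateCoxResult:
    feature: str
    coefficient: float
    p: float
    converged: bool = True


@dataclass(eq=False)
class SignatureModel:
    """A Cox PH model on a small feature combination.

    The risk score of a sample is the linear predictor sum(beta_i * x_i).
    """

    features: tuple[str, ...]
    coefficients: np.ndarray
    n_train: int

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SignatureModel)
            and self.features == other.features
            and self.n_train == other.n_train
            and np.array_equal(self.coefficients, other.coefficients)
        )

    def __post_init__(self) -> None:
        self.features = tuple(self.features)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape != (len(self.features),):
            raise ValueError("one coefficient per feature required")

    def to_dict(self) -> dict:
        return {
            "features": list(self.features),
            "coefficients": self.coefficients.tolist(),
            "n_train": self.n_train,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SignatureModel":
        return cls(tuple(d["features"]), np.asarray(d["coefficients"]), int(d["n_train"]))


def _surv_frame(ds: Dataset) -> pd.DataFrame:
    return pd.DataFrame({"time": ds.survival.time, "event": ds.survival.event})


def univariate_cox(ds: Dataset, features: list[str]) -> list[UnivariateCoxResult]:
    """Single-predictor Cox fit per feature: coefficient and two-sided Wald P.

    Constant features and non-convergent fits are reported with P = 1 and
    flagged rather than raised, so screening over thousands of genes never
    aborts on a degenerate gene.
    """
    if ds.n_events < 2:
        raise ValueError("univariate Cox screening needs at least 2 events")
    base = _surv_frame(ds)
    X = ds.expression.matrix_for(features)
    out: list[UnivariateCoxResult] = []
    for j, feat in enumerate(features):
        x = X[:, j]
        if np.std(x) == 0:
            warnings.warn(f"feature {feat!r} is constant; reported with P = 1")
            out.append(UnivariateCoxResult(feat, 0.0, 1.0, converged=False))
            continue
        df = base.copy()
        df["x"] = x
        cph = CoxPHFitter()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(df, duration_col="time", event_col="event",
                    fit_options={"precision": 1e-11})
            out.append(
                UnivariateCoxResult(
                    feat,
                    float(cph.params_["x"]),
                    float(cph.summary.loc["x", "p"]),
                )
            )
        except (ConvergenceError, np.linalg.LinAlgError, ValueError):
            logger.warning("univariate Cox did not converge for %r; reported with P = 1", feat)
            out.append(UnivariateCoxResult(feat, 0.0, 1.0, converged=False))
    return out


def screen(results: list[UnivariateCoxResult], cutoff: float = 0.05) -> list[str]:
    """Features with P < cutoff, input order preserved."""
    if cutoff <= 0:
        raise ValueError("screen cutoff must be positive")
    kept = [r.feature for r in results if r.p < cutoff]
    if not kept:
        raise ValueError(f"no feature passed P < {cutoff}; relax the cutoff")
    return kept


def fit_signature(ds: Dataset, features: list[str]) -> SignatureModel:
    """Multivariate Cox PH fit on the given feature combination."""
    features = list(features)
    if len(features) < 1:
        raise ValueError("a signature needs at least one feature")
    if ds.n_events < len(features) + 1:
        raise SingularFitError(
            f"too few events ({ds.n_events}) for {len(features)} features"
        )
    X = ds.expression.matrix_for(features)
    if np.linalg.matrix_rank(X - X.mean(axis=0)) < len(features):
        raise SingularFitError(f"singular design for combination {tuple(features)}")
    df = _surv_frame(ds)
    for j, feat in enumerate(features):
        df[f"f{j}"] = X[:, j]
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event",
                    fit_options={"precision": 1e-11})
    except (ConvergenceError, np.linalg.LinAlgError) as err:
        raise SingularFitError(f"Cox fit failed for {tuple(features)}: {err}") from err
    coefs = np.array([cph.params_[f"f{j}"] for j in range(len(features))])
    return SignatureModel(tuple(features), coefs, ds.n_samples)


def signature_risk(m: SignatureModel, expr: ExpressionMatrix) -> np.ndarray:
    """Linear-predictor risk score per sample (higher = higher risk)."""
    X = expr.matrix_for(list(m.features))
    return X @ m.coefficients
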