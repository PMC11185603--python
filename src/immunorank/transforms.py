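"""Per-feature transform stack: rescale -> impute -> curve -> weight.

Every feature column of the genes-by-features matrix passes, in fixed order,
through

1. **rescale** into [0, 1] (percentile ranks by default, min-max or identity
   optional), so features measured on incommensurate scales (TPM, residue
   counts, probabilities) become comparable;
2. **impute** of missing cells (column minimum by default: absent evidence is
   treated as the weakest observed support);
3. **curve** — a monotone non-linear re-mapping controlled by a per-feature
   parameter ``c`` that sharpens discrimination at the extremes of the scale
   (identity at ``c = 0``);
4. **weight** — multiplication by a signed per-feature weight ``w``
   (negative weights penalize, e.g. normal-tissue expression).

The curving family is the rational map

    f(x; c) = (1 + c) * x / (1 + c * x)          for c >= 0   (concave)
    f(x; c) = x / (1 + |c| * (1 - x))            for c < 0    (convex)

which fixes 0 and 1, is strictly increasing on (0, 1), and satisfies
``f(.; -c)`` = inverse of ``f(.; c)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import rankdata

RESCALE_METHODS = ("percentile", "minmax", "none")
IMPUTE_METHODS = ("min", "mean", "median", "zero")

DEFAULT_W_BOUNDS = (-1.0, 1.0)
DEFAULT_C_BOUNDS = (-5.0, 5.0)


@dataclass
class FeatureSpec:
    """Transform parameters for one feature column."""

    name: str
    rescale_method: str = "percentile"
    impute_method: str = "min"
    curve: float = 0.0
    weight: float = 1.0
    c_bounds: tuple[float, float] = DEFAULT_C_BOUNDS
    w_bounds: tuple[float, float] = DEFAULT_W_BOUNDS

    def __post_init__(self) -> None:
        if self.rescale_method not in RESCALE_METHODS:
            raise ValueError(
                f"unknown rescale method {self.rescale_method!r} for {self.name!r}; "
                f"choose from {RESCALE_METHODS}"
            )
        if self.impute_method not in IMPUTE_METHODS:
            raise ValueError(
                f"unknown impute method {self.impute_method!r} for {self.name!r}; "
                f"choose from {IMPUTE_METHODS}"
            )
        for lo, hi in (self.c_bounds, self.w_bounds):
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"bounds must be finite and ordered: {(lo, hi)}")

    def with_params(self, weight: float | None = None, curve: float | None = None) -> "FeatureSpec":
        out = replace(self)
        if weight is not None:
            out.weight = float(weight)
        if curve is not None:
            out.curve = float(curve)
        return out


def rescale_column(values, method: str = "percentile", name: str = "") -> np.ndarray:
    """Map a raw feature column into [0, 1]; missing cells stay missing.

    percentile: value -> (average rank among non-missing) / n, in (0, 1].
    minmax: (x - min) / (max - min); a constant column maps to 0.5.
    none: identity.
    """
    x = np.asarray(values, dtype=float)
    mask = ~np.isnan(x)
    if not mask.any():
        raise ValueError(f"all-missing feature column {name!r}")
    out = np.full_like(x, np.nan)
    if method == "percentile":
        out[mask] = rankdata(x[mask], method="average") / mask.sum()
    elif method == "minmax":
        lo, hi = x[mask].min(), x[mask].max()
        out[mask] = 0.5 if hi == lo else (x[mask] - lo) / (hi - lo)
    elif method == "none":
        out[mask] = x[mask]
    else:
        raise ValueError(f"unknown rescale method {method!r}")
    return out


def impute_column(values, method: str = "min") -> np.ndarray:
    """Fill missing cells with the column min/mean/median over non-missing, or 0."""
    x = np.asarray(values, dtype=float).copy()
    mask = np.isnan(x)
    if not mask.any():
        return x
    obs = x[~mask]
    if method == "min":
        fill = obs.min()
    elif method == "mean":
        fill = obs.mean()
    elif method == "median":
        fill = float(np.median(obs))
    elif method == "zero":
        fill = 0.0
    else:
        raise ValueError(f"unknown impute method {method!r}")
    x[mask] = fill
    return x


_CURVE_TOL = 1e-9


def curve_values(x, c: float) -> np.ndarray:
    """Apply the rational curving map to values in [0, 1]."""
    arr = np.asarray(x, dtype=float)
    c = float(c)
    if c == 0.0:
        return arr.copy()
    if np.nanmin(arr, initial=0.0) < -_CURVE_TOL or np.nanmax(arr, initial=0.0) > 1 + _CURVE_TOL:
        raise ValueError("curve input outside [0, 1]")
    arr = np.clip(arr, 0.0, 1.0)
    if c >= 0:
        return (1.0 + c) * arr / (1.0 + c * arr)
    a = -c
    return arr / (1.0 + a * (1.0 - arr))


def curve_matrix(X: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Column-wise curving of a 2-D array with one ``c`` per column."""
    c = np.asarray(c, dtype=float)[np.newaxis, :]
    cpos = np.maximum(c, 0.0)
    cneg = np.minimum(c, 0.0)
    pos = (1.0 + cpos) * X / (1.0 + cpos * X)
    neg = X / (1.0 - cneg * (1.0 - X))
    return np.where(c >= 0, pos, neg)


def weight_values(x, w: float) -> np.ndarray:
    """Elementwise weighting ``w * x`` of a curved feature column."""
    return float(w) * np.asarray(x, dtype=float)


@dataclass
class FeatureMatrix:
    """Genes x features matrix with provenance and explicit transform state.

    ``raw`` always holds the untransformed values; ``rescaled`` (still with
    missing cells) and ``curved`` (complete, in [0, 1]) are populated by
    :func:`apply_transforms`. The stack may be applied at most once.
    """

    raw: pd.DataFrame
    provenance: dict = field(default_factory=dict)
    rescaled: pd.DataFrame | None = None
    curved: pd.DataFrame | None = None
    specs: dict | None = None

    @property
    def gene_ids(self) -> list[str]:
        return list(self.raw.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.raw.columns)

    @property
    def is_transformed(self) -> bool:
        return self.curved is not None

    def select(self, features: list[str]) -> "FeatureMatrix":
        missing = [f for f in features if f not in self.raw.columns]
        if missing:
            raise KeyError(f"unknown feature(s) {missing}; available: {self.feature_names}")
        return FeatureMatrix(
            raw=self.raw[features].copy(),
            provenance={f: self.provenance.get(f) for f in features},
        )


def default_specs(feature_names, **overrides) -> dict[str, FeatureSpec]:
    """One default FeatureSpec per feature, optionally overridden by name."""
    specs = {name: FeatureSpec(name=name) for name in feature_names}
    for name, spec in overrides.items():
        if name not in specs:
            raise KeyError(f"override for unknown feature {name!r}")
        specs[name] = spec
    return specs


def apply_transforms(matrix: FeatureMatrix, specs: dict[str, FeatureSpec]) -> FeatureMatrix:
    """Run rescale -> impute -> curve on every column; weighting is deferred
    to scoring so that weight changes do not require re-transforming.

    Returns a new FeatureMatrix; re-transforming an already transformed matrix
    is rejected to keep the order-fixed stack single-shot.
    """
    if matrix.is_transformed:
        raise RuntimeError("feature matrix is already transformed; transform stack is single-shot")
    missing = [f for f in matrix.feature_names if f not in specs]
    if missing:
        raise KeyError(f"no FeatureSpec for feature(s) {missing}")
    rescaled = {}
    curved = {}
    for name in matrix.feature_names:
        spec = specs[name]
        r = rescale_column(matrix.raw[name].to_numpy(), spec.rescale_method, name=name)
        rescaled[name] = r
        filled = impute_column(r, spec.impute_method)
        curved[name] = curve_values(filled, spec.curve)
    idx = matrix.raw.index
    return FeatureMatrix(
        raw=matrix.raw,
        provenance=matrix.provenance,
        rescaled=pd.DataFrame(rescaled, index=idx)[matrix.feature_names],
        curved=pd.DataFrame(curved, index=idx)[matrix.feature_names],
        specs=dict(specs),
    )
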