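"""Per-participant grid search over the 64 candidate SARIMA models.

The candidate grid is the Cartesian product p, q ∈ {0,1,2,3} × P, Q ∈ {0,1}
with d = D = 1 and m = 24 fixed (4 × 4 × 2 × 2 = 64 models).  Models are
numbered 1..64 in lexicographic (p, q, P, Q) order; under this scheme the
most frequently selected model of the study, SARIMA(1,1,1)(0,1,1)[24], is
model #22.  The AIC-optimal converged fit is selected per participant, and
its weights are placed into a fixed-length 8-slot feature vector
[ar1, ar2, ar3, ma1, ma2, ma3, sar1, sma1] with absent orders substituted by
exactly zero, so that every participant contributes the same regression
design regardless of which model won.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sarima import SarimaModel, SarimaResults, SarimaSpec

__all__ = [
    "enumerate_grid",
    "model_number",
    "spec_to_number",
    "GridResult",
    "FeatureVector",
    "FEATURE_NAMES",
    "SarimaGridSearch",
    "select_optimal",
    "extract_features",
]

FEATURE_NAMES = ["ar1", "ar2", "ar3", "ma1", "ma2", "ma3", "sar1", "sma1"]

_P_RANGE = (0, 1, 2, 3)
_Q_RANGE = (0, 1, 2, 3)
_SP_RANGE = (0, 1)
_SQ_RANGE = (0, 1)


def enumerate_grid() -> list[SarimaSpec]:
    """The 64 candidate specs in lexicographic (p, q, P, Q) order."""
    return [
        SarimaSpec(p, 1, q, P, 1, Q, 24)
        for p in _P_RANGE
        for q in _Q_RANGE
        for P in _SP_RANGE
        for Q in _SQ_RANGE
    ]


def spec_to_number() -> dict[tuple[int, ...], int]:
    """Stable 1-based model numbering keyed by the full order tuple."""
    return {spec.as_tuple(): i + 1 for i, spec in enumerate(enumerate_grid())}


def model_number(spec: SarimaSpec) -> int:
    """1-based number of a spec within the enumeration (e.g. #22)."""
    try:
        return spec_to_number()[spec.as_tuple()]
    except KeyError:
        raise ValueError(f"{spec.label()} is not in the candidate grid") from None


@dataclass
class FeatureVector:
    """Zero-substituted 8-weight feature vector of a participant's best model."""

    ar1: float = 0.0
    ar2: float = 0.0
    ar3: float = 0.0
    ma1: float = 0.0
    ma2: float = 0.0
    ma3: float = 0.0
    sar1: float = 0.0
    sma1: float = 0.0

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES], dtype=float)

    def to_dict(self) -> dict[str, float]:
        return {n: float(getattr(self, n)) for n in FEATURE_NAMES}

    @classmethod
    def from_array(cls, values) -> "FeatureVector":
        values = np.asarray(values, dtype=float)
        if values.shape != (8,):
            raise ValueError("feature vector must have exactly 8 entries")
        return cls(**dict(zip(FEATURE_NAMES, map(float, values))))


@dataclass
class GridResult:
    """All 64 fits for one participant plus the AIC-optimal choice."""

    participant_id: str
    fits: list[SarimaResults]
    best_index: int

    @property
    def best_fit(self) -> SarimaResults:
        return self.fits[self.best_index]

    @property
    def best_spec(self) -> SarimaSpec:
        return self.best_fit.spec

    @property
    def best_number(self) -> int:
        return model_number(self.best_spec)

    @property
    def n_converged(self) -> int:
        return sum(f.converged for f in self.fits)

    def aic_table(self) -> pd.DataFrame:
        rows = [
            {
                "model": i + 1,
                "spec": f.spec.label(),
                "aic": f.aic,
                "loglik": f.loglik,
                "converged": f.converged,
            }
            for i, f in enumerate(self.fits)
        ]
        return pd.DataFrame(rows)


class SarimaGridSearch:
    """Fit every candidate model to one hourly series and pick the AIC optimum.

    Ties on AIC are broken by the smaller total parameter count, then by
    enumeration order; non-converged fits are kept in the table with
    AIC = +inf so they are reported but never selected.
    """

    def __init__(self, endog, participant_id: str = "", specs=None, method: str = "ml"):
        self.endog = endog
        self.participant_id = participant_id or getattr(endog, "participant_id", "")
        self.specs = list(specs) if specs is not None else enumerate_grid()
        self.method = method

    def fit(self) -> GridResult:
        values = getattr(self.endog, "values", self.endog)
        fits: list[SarimaResults] = []
        for spec in self.specs:
            result = SarimaModel(values, spec).fit(method=self.method)
            if not result.converged:
                result.aic = math.inf
            fits.append(result)
        keys = [
            (f.aic, f.spec.n_params, i) if f.converged else (math.inf, f.spec.n_params, i)
            for i, f in enumerate(fits)
        ]
        best = min(range(len(fits)), key=lambda i: keys[i])
        if not fits[best].converged:
            raise RuntimeError(
                f"no candidate model converged for participant "
                f"{self.participant_id or '<unnamed>'}"
            )
        return GridResult(self.participant_id, fits, best)


def select_optimal(endog, participant_id: str = "", specs=None, method: str = "ml") -> GridResult:
    """Convenience wrapper: grid-fit ``endog`` and return the GridResult."""
    return SarimaGridSearch(endog, participant_id, specs, method).fit()


def extract_features(result: GridResult) -> FeatureVector:
    """Best-fit weights in the fixed 8 slots; absent orders are exactly 0."""
    best = result.best_fit
    mapping = {
        "ar1": "ar.L1", "ar2": "ar.L2", "ar3": "ar.L3",
        "ma1": "ma.L1", "ma2": "ma.L2", "ma3": "ma.L3",
        "sar1": f"ar.S.L{best.spec.m}", "sma1": f"ma.S.L{best.spec.m}",
    }
    return FeatureVector(**{slot: best.weight(name) for slot, name in mapping.items()})


def features_frame(results: list[GridResult]) -> pd.DataFrame:
    """Features CSV layout: one row per participant plus selection metadata."""
    rows = []
    for res in results:
        row = {"participant_id": res.participant_id}
        row.update(extract_features(res).to_dict())
        row["best_spec"] = res.best_spec.label()
        row["best_model"] = res.best_number
        row["best_aic"] = res.best_fit.aic
        row["n_converged"] = res.n_converged
        rows.append(row)
    return pd.DataFrame(rows)
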