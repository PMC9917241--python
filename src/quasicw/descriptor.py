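"""Optimal descriptor and the one-variable endpoint model.

The descriptor of a quasi-SMILES string is the sum of the correlation
weights of its codes (with multiplicity); the endpoint model is the
straight line

    endpoint_k = C0 + C1 * DCW(T, N)_k

calibrated by ordinary least squares on the active training set.  T is
the rare-code threshold: a code occurring fewer than T times in the
active training set is "rare" and carries weight exactly zero, so it
never influences the model.  N is the number of Monte Carlo epochs the
weights were optimized for (metadata here).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .records import QuasiSmilesRecord, tokenize

__all__ = [
    "WeightTable",
    "LinearModel",
    "DegenerateModelError",
    "mark_rare_codes",
    "build_weight_table",
    "compute_dcw",
    "fit_linear",
    "predict",
]


class DegenerateModelError(ValueError):
    """The descriptor has no variance: no line can be fitted."""


@dataclass
class WeightTable:
    """Correlation weight per code, plus the rare-code set.

    Rare codes always have weight exactly 0.  Codes never seen at build
    time contribute 0 at prediction time and flag the record for the
    applicability-domain report.
    """

    weights: dict
    rare_codes: set = field(default_factory=set)
    threshold_T: int = 1
    epochs_N: int = 0

    def __post_init__(self):
        for code in self.rare_codes:
            self.weights[code] = 0.0

    def weight(self, code: str) -> float:
        if code in self.rare_codes:
            return 0.0
        return self.weights.get(code, 0.0)

    @property
    def active_codes(self) -> list:
        """Non-rare codes, i.e. the parameters the optimizer may move."""
        return sorted(c for c in self.weights if c not in self.rare_codes)


@dataclass(frozen=True)
class LinearModel:
    """Intercept and slope of the endpoint line."""

    c0: float
    c1: float

    def __post_init__(self):
        if not (np.isfinite(self.c0) and np.isfinite(self.c1)):
            raise ValueError("model coefficients must be finite")


def mark_rare_codes(active_records, T: int, alphabet=None) -> set:
    """Codes occurring fewer than ``T`` times in the active training set.

    ``alphabet`` widens the universe beyond the codes seen in the active
    set (so that with T=1, codes absent from the active set are reported
    rare); by default the universe is the active set's own codes.
    """
    if T < 1:
        raise ValueError(f"threshold T must be >= 1, got {T}")
    active_records = list(active_records)
    if not active_records:
        raise ValueError("active training set is empty")
    counts: Counter = Counter()
    for rec in active_records:
        counts.update(tokenize(rec.quasi_smiles))
    universe = set(alphabet) if alphabet is not None else set(counts)
    universe |= set(counts)
    return {c for c in universe if counts[c] < T}


def build_weight_table(
    records, active_ids, T: int = 1, initial: float = 1.0
) -> WeightTable:
    """Initialize a weight table over the full code alphabet of
    ``records``, marking rarity against the active subset."""
    records = list(records)
    active = [r for r in records if r.id in set(active_ids)]
    universe: set = set()
    for rec in records:
        universe.update(tokenize(rec.quasi_smiles))
    rare = mark_rare_codes(active, T, alphabet=universe)
    weights = {c: (0.0 if c in rare else float(initial)) for c in universe}
    return WeightTable(weights=weights, rare_codes=rare, threshold_T=T)


def compute_dcw(codes, wt: WeightTable) -> float:
    """Sum of correlation weights over the code sequence (with
    multiplicity); rare and unknown codes contribute zero."""
    return float(sum(wt.weight(c) for c in codes))


def fit_linear(dcw_values, endpoints) -> LinearModel:
    """Ordinary least squares endpoint ~ descriptor."""
    x = np.asarray(dcw_values, dtype=float)
    y = np.asarray(endpoints, dtype=float)
    if x.size < 3:
        raise ValueError(f"need at least 3 points to fit, got {x.size}")
    sxx = np.sum((x - x.mean()) ** 2)
    if sxx <= 0:
        raise DegenerateModelError("descriptor values are all equal")
    c1 = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    c0 = float(y.mean() - c1 * x.mean())
    return LinearModel(c0=c0, c1=c1)


def predict(record: QuasiSmilesRecord, wt: WeightTable, model: LinearModel) -> float:
    """Apply the calibrated line to one record."""
    return model.c0 + model.c1 * compute_dcw(tokenize(record.quasi_smiles), wt)
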