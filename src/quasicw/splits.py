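"""Four-set split protocol and synthetic data with known ground truth.

The modelling protocol partitions records into an Active training set
(weights are fitted here), a Passive training set (checks that the model
transfers to strings it was not fitted on), a Calibration set (detects
the onset of overtraining) and a Validation set (untouched until the
final quality assessment).  Each set holds about a quarter of the data.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .records import QuasiSmilesRecord, SET_LABELS, tokenize

__all__ = [
    "SplitAssignment",
    "SyntheticTruth",
    "random_split",
    "generate_synthetic",
    "default_synthetic_truth",
    "apply_split",
]

#: Skeleton templates cycled over when building synthetic oxide-like
#: strings; ``{e}`` is replaced by an element code.  They mirror the real
#: alphabet's structural variety (dioxide, sesquioxide, monoxide, mixed).
_SKELETON_TEMPLATES = (
    "O={e}=O",
    "O={e}O{e}=O",
    "{e}=O",
    "{e}=O.O={e}O{e}=O",
)


@dataclass(frozen=True)
class SplitAssignment:
    """Map record id -> set label, with the seed that generated it
    (``None`` for a published/loaded split)."""

    assignment: dict
    seed: int | None = None

    def ids(self, label: str) -> list[int]:
        return [i for i, s in self.assignment.items() if s == label]

    def counts(self) -> dict:
        out = {lab: 0 for lab in SET_LABELS}
        for lab in self.assignment.values():
            out[lab] += 1
        return out


def random_split(records, seed: int) -> SplitAssignment:
    """Assign labels by a seeded uniform shuffle followed by contiguous
    near-quarters in the order A, P, C, V (any remainder goes one record
    per set in that same order)."""
    ids = [r.id for r in records]
    n = len(ids)
    if n < 8:
        raise ValueError(f"need at least 8 records to split, got {n}")
    rng = np.random.default_rng(seed)
    order = [ids[k] for k in rng.permutation(n)]
    base, rem = divmod(n, 4)
    sizes = [base + (1 if k < rem else 0) for k in range(4)]
    assignment = {}
    pos = 0
    for label, size in zip(SET_LABELS, sizes):
        for rid in order[pos : pos + size]:
            assignment[rid] = label
        pos += size
    return SplitAssignment(assignment=assignment, seed=seed)


def apply_split(records, split: SplitAssignment) -> list[QuasiSmilesRecord]:
    """Return copies of ``records`` relabelled according to ``split``."""
    return [
        QuasiSmilesRecord(
            id=r.id,
            quasi_smiles=r.quasi_smiles,
            endpoint=r.endpoint,
            set_label=split.assignment[r.id],
        )
        for r in records
    ]


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth for parameter-recovery experiments: the generating
    model is ``endpoint = c0 + c1 * sum of true weights of the codes``
    plus Gaussian noise."""

    true_weights: dict
    true_c0: float
    true_c1: float
    noise_sd: float = 0.0

    def __post_init__(self):
        if self.noise_sd < 0 or not np.isfinite(self.noise_sd):
            raise ValueError("noise_sd must be finite and >= 0")
        if not any(w != 0 for w in self.true_weights.values()):
            raise ValueError("at least one true weight must be nonzero")


def default_synthetic_truth(
    n_skeletons: int,
    seed: int,
    noise_sd: float = 0.0,
    condition_codes=("[c25,00]", "[c50,00]", "[c100,00]", "[c200,00]"),
) -> SyntheticTruth:
    """A reasonable ground truth mimicking the real data's structure:
    one element code per skeleton with weight ~ U(-3, 3), small skeleton
    punctuation weights and monotonically decreasing condition weights
    (higher dose, lower viability)."""
    rng = np.random.default_rng(seed)
    n_elements = -(-n_skeletons // len(_SKELETON_TEMPLATES))
    weights = {f"[E{k}]": float(rng.uniform(-3, 3)) for k in range(n_elements)}
    weights.update({"O": 0.4, "=": -0.2, ".": 0.1, "(": 0.0, ")": 0.0})
    for j, code in enumerate(condition_codes):
        weights[code] = float(2.0 - 1.5 * j)
    return SyntheticTruth(
        true_weights=weights, true_c0=60.0, true_c1=8.0, noise_sd=noise_sd
    )


def generate_synthetic(
    n_skeletons: int,
    condition_codes,
    truth: SyntheticTruth,
    seed: int,
) -> list[QuasiSmilesRecord]:
    """Enumerate skeleton x condition combinations with endpoints drawn
    from the linear ground-truth model.

    Skeleton ``k`` combines template ``k mod 4`` with element code
    ``[E(k div 4)]``, so each element recurs across several structural
    templates (as oxidation states do in the real data) and every code
    is informed by several records; every string ends with one condition
    code.  Requires ``truth.true_weights`` to contain the needed ``[Ej]``
    entries (see :func:`default_synthetic_truth`).
    """
    condition_codes = list(condition_codes)
    if n_skeletons < 2:
        raise ValueError("need at least 2 skeletons")
    if len(condition_codes) < 2:
        raise ValueError("need at least 2 condition codes")
    rng = np.random.default_rng(seed)
    records = []
    rid = itertools.count(1)
    for k in range(n_skeletons):
        element = f"[E{k // len(_SKELETON_TEMPLATES)}]"
        if element not in truth.true_weights:
            raise ValueError(f"truth lacks a weight for skeleton element {element}")
        skeleton = _SKELETON_TEMPLATES[k % len(_SKELETON_TEMPLATES)].format(e=element)
        for cond in condition_codes:
            qs = skeleton + cond
            dcw = sum(truth.true_weights.get(c, 0.0) for c in tokenize(qs))
            y = truth.true_c0 + truth.true_c1 * dcw
            if truth.noise_sd > 0:
                y += rng.normal(0.0, truth.noise_sd)
            records.append(
                QuasiSmilesRecord(id=next(rid), quasi_smiles=qs, endpoint=float(y))
            )
    return records
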