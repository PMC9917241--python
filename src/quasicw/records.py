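"""Quasi-SMILES records and tokenization.

A quasi-SMILES string encodes a molecular structure (ordinary SMILES
characters) extended with bracketed codes for experimental conditions,
e.g. ``O=[Al]O[Al]=O[c25,00]`` is nano-alumina at 25.00 µg/mL.  The
modelling machinery never interprets chemistry: a string is just an
ordered sequence of *codes*, each of which receives its own correlation
weight.  A code is either a bracketed span ``[...]`` (element, charged
species, or condition code) or a single character (``O``, ``=``, ``.``,
``(``, ``)``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "QuasiSmilesRecord",
    "CodeSequence",
    "InvalidQuasiSmilesError",
    "QuasiSmilesParseError",
    "tokenize",
    "SET_LABELS",
]

#: The four sub-set roles: Active training, Passive training, Calibration,
#: Validation.
SET_LABELS = ("A", "P", "C", "V")


class InvalidQuasiSmilesError(ValueError):
    """Raised for structurally invalid input (empty string, whitespace)."""


class QuasiSmilesParseError(ValueError):
    """Raised for unbalanced brackets; carries the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (position {position})")
        self.position = position


#: A tokenized quasi-SMILES string: ordered list of codes whose
#: concatenation reproduces the source exactly.
CodeSequence = list


def tokenize(quasi_smiles: str) -> CodeSequence:
    """Split a quasi-SMILES string into its codes.

    Bracketed spans ``[...]`` are single codes (this covers element codes
    like ``[Al]``, charged species like ``[O-2]`` and condition codes like
    ``[c200,00]``); every other character is a code by itself.  Codes are
    case-sensitive and whitespace is forbidden.

    >>> tokenize("O=[Al]O[Al]=O[c25,00]")
    ['O', '=', '[Al]', 'O', '[Al]', '=', 'O', '[c25,00]']
    """
    if not quasi_smiles:
        raise InvalidQuasiSmilesError("quasi-SMILES string is empty")
    if any(ch.isspace() for ch in quasi_smiles):
        raise InvalidQuasiSmilesError(
            f"whitespace is forbidden inside quasi-SMILES: {quasi_smiles!r}"
        )
    codes: list[str] = []
    i = 0
    n = len(quasi_smiles)
    while i < n:
        ch = quasi_smiles[i]
        if ch == "[":
            j = quasi_smiles.find("]", i + 1)
            if j < 0:
                raise QuasiSmilesParseError("unclosed '['", i)
            codes.append(quasi_smiles[i : j + 1])
            i = j + 1
        elif ch == "]":
            raise QuasiSmilesParseError("']' without matching '['", i)
        else:
            codes.append(ch)
            i += 1
    return codes


@dataclass(frozen=True)
class QuasiSmilesRecord:
    """One (quasi-SMILES, endpoint) situation — e.g. one oxide at one
    concentration, with the observed percent cell viability.

    Parameters
    ----------
    id : int
        Positive unique identifier.
    quasi_smiles : str
        The code string.
    endpoint : float
        Observed endpoint (percent cell viability here).
    set_label : str or None
        ``"A"`` (active training), ``"P"`` (passive training),
        ``"C"`` (calibration) or ``"V"`` (validation); ``None`` when the
        record has not been assigned to a split yet.
    """

    id: int
    quasi_smiles: str
    endpoint: float
    set_label: str | None = None

    def __post_init__(self):
        if self.id <= 0:
            raise ValueError(f"record id must be positive, got {self.id}")
        if self.set_label is not None and self.set_label not in SET_LABELS:
            raise ValueError(
                f"set_label must be one of {SET_LABELS} or None, "
                f"got {self.set_label!r}"
            )
        import math

        if not math.isfinite(self.endpoint):
            raise ValueError(f"endpoint must be finite, got {self.endpoint}")
        # validates non-empty / bracket balance as a side effect
        tokenize(self.quasi_smiles)

    @property
    def codes(self) -> CodeSequence:
        return tokenize(self.quasi_smiles)


def code_counts(records: Iterable[QuasiSmilesRecord]) -> dict:
    """Total occurrence count of every code over ``records``
    (token multiplicity, not per-record presence)."""
    from collections import Counter

    counts: Counter = Counter()
    for rec in records:
        counts.update(tokenize(rec.quasi_smiles))
    return dict(counts)


def alphabet(records: Iterable[QuasiSmilesRecord]) -> set:
    """Set of distinct codes occurring anywhere in ``records``."""
    return set(code_counts(records))
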