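"""Mechanistic interpretation and applicability domain.

Promoters: across several independent optimization runs, a code whose
weight ends positive in every run promotes endpoint increase; negative
in every run, endpoint decrease; mixed signs leave its role unclear.
For a viability endpoint the decrease promoters are the toxicologically
interesting ones.

Applicability domain: a record's *statistical defect* accumulates, over
its codes, the disagreement between the code's frequency in the active
training set and in the calibration set.  Records whose defect exceeds
twice the mean training defect are flagged out-of-domain.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .records import QuasiSmilesRecord, tokenize

__all__ = [
    "PromoterClassification",
    "CodeFrequencyStats",
    "DomainReport",
    "classify_promoters",
    "code_frequency_stats",
    "statistical_defect",
    "domain_report",
]

CATEGORIES = ("increase", "decrease", "unclear", "rare")


@dataclass(frozen=True)
class PromoterClassification:
    """Per-code category plus the raw per-run weight-sign table."""

    categories: dict  # code -> one of CATEGORIES
    signs: dict  # code -> tuple of per-run signs (-1, 0, +1)

    def codes_in(self, category: str) -> list:
        return sorted(c for c, k in self.categories.items() if k == category)


def classify_promoters(traces) -> PromoterClassification:
    """Classify codes from the weight signs of >= 2 optimization runs.

    A code rare in every run is reported "rare" and not classified.  A
    weight of exactly zero in a non-rare code counts as neither positive
    nor negative, so it lands in "unclear".

    The endpoint model is unchanged by negating all weights together
    with the slope C1, so a raw weight sign carries no meaning on its
    own; each run's signs are therefore taken as sign(weight * C1),
    the direction in which the code actually moves the endpoint.
    """
    traces = list(traces)
    if len(traces) < 2:
        raise ValueError("promoter classification needs at least 2 runs")
    all_codes: set = set()
    for t in traces:
        all_codes.update(t.weight_table.weights)
    categories, signs = {}, {}
    for code in all_codes:
        rare_everywhere = all(
            code in t.weight_table.rare_codes or code not in t.weight_table.weights
            for t in traces
        )
        if rare_everywhere:
            categories[code] = "rare"
            signs[code] = tuple(0 for _ in traces)
            continue
        s = tuple(
            int(np.sign(t.weight_table.weight(code)) * np.sign(t.model.c1))
            for t in traces
        )
        signs[code] = s
        if all(v > 0 for v in s):
            categories[code] = "increase"
        elif all(v < 0 for v in s):
            categories[code] = "decrease"
        else:
            categories[code] = "unclear"
    return PromoterClassification(categories=categories, signs=signs)


@dataclass(frozen=True)
class CodeFrequencyStats:
    """Occurrence counts and proportions of every code in the active
    training (A) and calibration (C) sets."""

    counts_active: dict
    counts_calibration: dict
    total_active: int
    total_calibration: int

    def proportion(self, code: str, which: str) -> float:
        if which == "A":
            total = self.total_active
            n = self.counts_active.get(code, 0)
        else:
            total = self.total_calibration
            n = self.counts_calibration.get(code, 0)
        return n / total if total else 0.0


def code_frequency_stats(active_records, calibration_records) -> CodeFrequencyStats:
    ca: Counter = Counter()
    for r in active_records:
        ca.update(tokenize(r.quasi_smiles))
    cc: Counter = Counter()
    for r in calibration_records:
        cc.update(tokenize(r.quasi_smiles))
    return CodeFrequencyStats(
        counts_active=dict(ca),
        counts_calibration=dict(cc),
        total_active=sum(ca.values()),
        total_calibration=sum(cc.values()),
    )


def statistical_defect(
    record: QuasiSmilesRecord,
    code_stats: CodeFrequencyStats,
    missing_penalty: float = 1.0,
) -> float:
    """Sum over the record's codes (with multiplicity) of

        |P_A(code) - P_C(code)| / (N_A(code) + N_C(code)),

    where P is the proportion of all code occurrences and N the raw
    count in the respective set.  A code absent from both sets has no
    frequency evidence at all and contributes ``missing_penalty``.
    """
    d = 0.0
    for code in tokenize(record.quasi_smiles):
        na = code_stats.counts_active.get(code, 0)
        nc = code_stats.counts_calibration.get(code, 0)
        if na + nc == 0:
            d += missing_penalty
            continue
        pa = code_stats.proportion(code, "A")
        pc = code_stats.proportion(code, "C")
        d += abs(pa - pc) / (na + nc)
    return d


@dataclass(frozen=True)
class DomainReport:
    """Per-record defect and domain flag, plus per-set outlier fractions."""

    defects: dict  # record id -> defect
    in_domain: dict  # record id -> bool
    threshold: float
    outlier_fraction: dict  # set label -> fraction out-of-domain


def domain_report(records, defects: dict, training_ids) -> DomainReport:
    """Flag records whose defect exceeds twice the mean defect of the
    training records (active + passive), and summarize per set."""
    training_ids = set(training_ids)
    train_defects = [defects[r.id] for r in records if r.id in training_ids]
    if not train_defects:
        raise ValueError("no training records among the inputs")
    threshold = 2.0 * float(np.mean(train_defects))
    in_domain = {r.id: defects[r.id] <= threshold for r in records}
    fractions = {}
    for lab in "APCV":
        members = [r for r in records if r.set_label == lab]
        if members:
            out = sum(1 for r in members if not in_domain[r.id])
            fractions[lab] = out / len(members)
    return DomainReport(
        defects=dict(defects),
        in_domain=in_domain,
        threshold=threshold,
        outlier_fraction=fractions,
    )
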