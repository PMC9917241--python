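"""The packaged THP-1 nano-oxide cell-viability dataset.

120 situations: 30 metal nano-oxides x 4 concentrations (25, 50, 100,
200 µg/mL, encoded as condition codes ``[c25,00]`` ... ``[c200,00]``),
with percent cell viability in THP-1 monocytes as the endpoint.  The
table also carries the published model's calculated column and the
published first split's set labels; the calculated column is kept for
verification oracles only and is never used in training.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .records import QuasiSmilesRecord

__all__ = ["load_thp1", "load_thp1_records", "load_split1"]

_FIXTURE = "thp1_nanooxides.tsv"


def load_thp1() -> pd.DataFrame:
    """Return the full dataset as a DataFrame.

    Columns: ``set_label`` (published split-1 assignment), ``id``,
    ``quasi_smiles``, ``endpoint`` (observed viability %), ``calculated``
    (the published model's fitted viability %).
    """
    with resources.files("quasicw").joinpath("data", _FIXTURE).open("r") as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"quasi_smiles": str, "set_label": str})
    return df


def load_thp1_records() -> list[QuasiSmilesRecord]:
    """The dataset as records (set labels from the published split-1)."""
    df = load_thp1()
    return [
        QuasiSmilesRecord(
            id=int(r.id),
            quasi_smiles=r.quasi_smiles,
            endpoint=float(r.endpoint),
            set_label=r.set_label,
        )
        for r in df.itertuples()
    ]


def load_split1():
    """The published split-1 assignment (record id -> A/P/C/V)."""
    from .splits import SplitAssignment

    df = load_thp1()
    return SplitAssignment(
        assignment={int(i): s for i, s in zip(df["id"], df["set_label"])},
        seed=None,
    )
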