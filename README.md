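# quasicw

Correlation-weight QSAR models from quasi-SMILES: Monte Carlo optimal
descriptors with ideality-of-correlation target functions, applied to
metal nano-oxide cytotoxicity.

## The problem

Nanotoxicity data rarely comes as tidy structure–activity tables: the
outcome depends both on what the material is and on how it was tested.
The quasi-SMILES formalism folds both into one string — an ordinary
SMILES for the structure plus bracketed codes for experimental
conditions, e.g. `O=[Al]O[Al]=O[c25,00]` for nano-alumina at
25.00 µg/mL.  The packaged dataset covers 30 metal nano-oxides at four
concentrations (25–200 µg/mL), 120 situations in all, with percent
viability of THP-1 monocytes as the endpoint.

Each distinct token of a quasi-SMILES (a character, or a bracketed
span) is a *code* that receives a correlation weight `CW(code)`.  The
optimal descriptor of record *k* is the multiplicity-weighted sum

    DCW(T, N)_k = Σ CW(code)   over the codes of record k

and the endpoint model is one straight line,

    viability_k = C0 + C1 · DCW(T, N)_k ,

with `C0`, `C1` fit by least squares on the active training set.  Codes
occurring fewer than `T` times in the active training set are *rare*
and carry weight exactly 0.  The weights are tuned for `N` epochs of a
greedy Monte Carlo search maximizing either

    TF0 = r_A + r_P − |r_A − r_P| · 0.1
    TF1 = TF0 + (IIC_C + CII_C) · 0.3

where `r_A`, `r_P` are observed-vs-predicted correlations on the active
and passive training sets, `IIC_C` is the index of ideality of
correlation and `CII_C` the correlation intensity index, both on the
calibration set.  The calibration set also stops the run when its R²
stops improving; the untouched validation set measures predictivity.
Repeated runs from random starts classify codes as promoters of
endpoint increase or decrease, and code-frequency *statistical defects*
delimit the applicability domain.

## Worked example

```python
import quasicw as q

stats = q.stats_only()          # published model, packaged data
print(round(stats["V"].r2, 4))  # 0.7226
print(round(stats["C"].iic, 4)) # 0.75
print(round(stats["C"].cii, 4)) # 0.7744
```

Retraining from scratch on the published split
(`examples/03_train_split1.py`) prints, for seed 1:

```
stopped: epochs exhausted after 300 epochs
model: viability = 9.93 + 7.65 * DCW
non-rare codes: 25
set A: R2 = 0.7445
set P: R2 = 0.7167
set C: R2 = 0.5999
set V: R2 = 0.7692
```

The validation R² near 0.72 is the headline number: how well a model
that never saw those 31 records ranks their cytotoxicity.  The
`examples/` directory holds one short script per capability
(tokenization, published statistics, retraining, promoter/domain
analysis, synthetic-data recovery); a thin `quasicw` command-line tool
exposes the same steps (`quasicw train`, `quasicw stats-only`,
`quasicw promoters`, ...).

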