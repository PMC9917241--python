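"""Monte Carlo optimization of correlation weights.

The weights are tuned by a coordinate-wise greedy Monte Carlo: in each
epoch every non-rare code is visited in seeded random order, its weight
is perturbed by a uniform draw in [-step, +step] modulated over three
orders of magnitude (log-uniform scale factor in [0.01, 10]), the
endpoint line is refit on the active training set, and the move is kept
if and only if the target function does not decrease.  The multi-scale
modulation lets a single pass both escape shallow local optima (large
moves) and refine converged weights (small moves); with probability 1/2
a second, randomly chosen code is perturbed jointly, which lets the
chain traverse the ridges that correlated codes (co-occurring in the
same strings) create in the target surface.  Two target functions:

    TF0 = r_A + r_P - |r_A - r_P| * 0.1
    TF1 = TF0 + (IIC_C + CII_C) * 0.3

where r_A and r_P are the observed-vs-predicted correlations on the
active and passive training sets, and IIC/CII are evaluated on the
calibration set.  The calibration set also guards against overtraining:
if its R² fails to improve for a patience window the run stops there.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .descriptor import LinearModel, WeightTable, build_weight_table
from .metrics import UndefinedStatisticError, cii, iic, pearson_r
from .records import tokenize
from .splits import SplitAssignment

__all__ = [
    "TargetFunctionConfig",
    "OptimizationConfig",
    "EpochStats",
    "RunTrace",
    "tf0",
    "tf1",
    "optimize",
    "multi_run",
]


def tf0(r_active: float, r_passive: float, penalty: float = 0.1) -> float:
    """Balance the two training correlations, penalizing their gap."""
    return r_active + r_passive - abs(r_active - r_passive) * penalty


def tf1(
    tf0_value: float, iic_calibration: float, cii_calibration: float,
    bonus: float = 0.3,
) -> float:
    """TF0 plus the calibration-set ideality/intensity bonus."""
    return tf0_value + (iic_calibration + cii_calibration) * bonus


@dataclass(frozen=True)
class TargetFunctionConfig:
    kind: str = "TF1"
    tf0_penalty: float = 0.1
    tf1_bonus: float = 0.3

    def __post_init__(self):
        if self.kind not in ("TF0", "TF1"):
            raise ValueError(f"kind must be TF0 or TF1, got {self.kind!r}")
        if self.tf0_penalty < 0 or self.tf1_bonus < 0:
            raise ValueError("target-function coefficients must be >= 0")


@dataclass(frozen=True)
class OptimizationConfig:
    threshold_T: int = 1
    epochs_N: int = 300
    step_size: float = 0.5
    seed: int = 0
    n_runs: int = 1
    patience: int = 30
    pair_prob: float = 0.5
    init: str = "ones"  # "ones" or "random" (uniform in [0.5, 1.5])

    def __post_init__(self):
        if self.epochs_N < 0:
            raise ValueError("epochs_N must be >= 0")
        if self.step_size <= 0:
            raise ValueError("step_size must be > 0")
        if self.threshold_T < 1:
            raise ValueError("threshold_T must be >= 1")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if not 0 <= self.pair_prob <= 1:
            raise ValueError("pair_prob must lie in [0, 1]")
        if self.init not in ("ones", "random"):
            raise ValueError("init must be 'ones' or 'random'")


@dataclass(frozen=True)
class EpochStats:
    epoch: int
    tf: float
    r2_active: float
    r2_passive: float
    r2_calibration: float


@dataclass
class RunTrace:
    """Outcome of one optimization run."""

    epochs: list
    weight_table: WeightTable
    model: LinearModel
    stop_reason: str  # "epochs exhausted" | "overtraining detected"
    seed: int

    @property
    def tf_values(self) -> list:
        return [e.tf for e in self.epochs]


class _Problem:
    """Vectorized view of the data: code-count matrix, endpoint vector
    and set masks, with an incremental target-function evaluator."""

    def __init__(self, records, split: SplitAssignment, T: int):
        records = list(records)
        self.records = records
        wt = build_weight_table(records, split.ids("A"), T=T, initial=1.0)
        self.codes = sorted(wt.weights)  # fixed column order
        self.rare = wt.rare_codes
        self.active_cols = [
            j for j, c in enumerate(self.codes) if c not in self.rare
        ]
        index = {c: j for j, c in enumerate(self.codes)}
        self.X = np.zeros((len(records), len(self.codes)))
        for i, rec in enumerate(records):
            for tok in tokenize(rec.quasi_smiles):
                self.X[i, index[tok]] += 1.0
        self.y = np.array([r.endpoint for r in records], dtype=float)
        labels = np.array([split.assignment[r.id] for r in records])
        self.masks = {lab: labels == lab for lab in "APCV"}
        self.T = T

    def initial_weights(self, mode: str, rng) -> np.ndarray:
        w = np.zeros(len(self.codes))
        # randomized starts stay positive: with positive weights the fitted
        # slope starts positive, which anchors the sign convention that the
        # promoter interpretation reads off the final weights
        vals = (
            np.ones(len(self.active_cols))
            if mode == "ones"
            else rng.uniform(0.5, 1.5, size=len(self.active_cols))
        )
        w[self.active_cols] = vals
        return w

    def evaluate(self, dcw: np.ndarray, tfc: TargetFunctionConfig):
        """Target function and fitted line for descriptor vector ``dcw``;
        None if the configuration is degenerate (proposal rejected)."""
        a = self.masks["A"]
        xa, ya = dcw[a], self.y[a]
        sxx = np.sum((xa - xa.mean()) ** 2)
        if sxx <= 0:
            return None
        c1 = float(np.sum((xa - xa.mean()) * (ya - ya.mean())) / sxx)
        if c1 == 0:
            return None
        c0 = float(ya.mean() - c1 * xa.mean())
        pred = c0 + c1 * dcw
        try:
            r_a = pearson_r(ya, pred[a])
            r_p = pearson_r(self.y[self.masks["P"]], pred[self.masks["P"]])
            value = tf0(r_a, r_p, tfc.tf0_penalty)
            if tfc.kind == "TF1":
                yc, pc = self.y[self.masks["C"]], pred[self.masks["C"]]
                value = tf1(value, iic(yc, pc), cii(yc, pc), tfc.tf1_bonus)
        except UndefinedStatisticError:
            return None
        return value, LinearModel(c0=c0, c1=c1)

    def r2_by_set(self, dcw: np.ndarray, model: LinearModel) -> dict:
        pred = model.c0 + model.c1 * dcw
        out = {}
        for lab in "APC":
            m = self.masks[lab]
            try:
                out[lab] = pearson_r(self.y[m], pred[m]) ** 2
            except UndefinedStatisticError:
                out[lab] = float("nan")
        return out

    def weight_table(self, w: np.ndarray, epochs_done: int) -> WeightTable:
        weights = {c: float(w[j]) for j, c in enumerate(self.codes)}
        return WeightTable(
            weights=weights,
            rare_codes=set(self.rare),
            threshold_T=self.T,
            epochs_N=epochs_done,
        )


def optimize(
    records,
    split: SplitAssignment,
    opt_config: OptimizationConfig | None = None,
    tf_config: TargetFunctionConfig | None = None,
) -> RunTrace:
    """Run one Monte Carlo optimization and return its trace.

    The accepted target-function value never decreases within the run.
    Rare codes keep weight exactly zero throughout.  Identical inputs and
    seed reproduce the trace bit for bit.
    """
    opt_config = opt_config or OptimizationConfig()
    tf_config = tf_config or TargetFunctionConfig()
    for lab in "APC":
        if not split.ids(lab):
            raise ValueError(f"split has an empty {lab!r} set")
    problem = _Problem(records, split, opt_config.threshold_T)
    rng = np.random.default_rng(opt_config.seed)

    w = problem.initial_weights(opt_config.init, rng)
    dcw = problem.X @ w
    state = problem.evaluate(dcw, tf_config)
    current_tf = -np.inf if state is None else state[0]
    model = state[1] if state is not None else None

    best_r2c = -np.inf
    best_epoch = 0
    stall = 0
    epochs: list[EpochStats] = []
    stop_reason = "epochs exhausted"

    for epoch in range(1, opt_config.epochs_N + 1):
        n_active = len(problem.active_cols)
        order = rng.permutation(n_active)
        for idx in order:
            j = problem.active_cols[idx]
            # multi-scale proposal: base draw times a log-uniform factor
            delta = rng.uniform(
                -opt_config.step_size, opt_config.step_size
            ) * 10.0 ** rng.uniform(-2.0, 1.0)
            dcw_prop = dcw + delta * problem.X[:, j]
            k = None
            if rng.uniform() < opt_config.pair_prob:
                k = problem.active_cols[rng.integers(n_active)]
                delta_k = rng.uniform(
                    -opt_config.step_size, opt_config.step_size
                ) * 10.0 ** rng.uniform(-2.0, 1.0)
                dcw_prop = dcw_prop + delta_k * problem.X[:, k]
            result = problem.evaluate(dcw_prop, tf_config)
            if result is None:
                continue
            value, prop_model = result
            if value >= current_tf:  # accept iff the target does not decrease
                w[j] += delta
                if k is not None:
                    w[k] += delta_k
                dcw = dcw_prop
                current_tf = value
                model = prop_model
        if model is None:
            continue
        r2s = problem.r2_by_set(dcw, model)
        epochs.append(
            EpochStats(
                epoch=epoch,
                tf=current_tf,
                r2_active=r2s["A"],
                r2_passive=r2s["P"],
                r2_calibration=r2s["C"],
            )
        )
        if r2s["C"] > best_r2c:
            best_r2c = r2s["C"]
            best_epoch = epoch
            stall = 0
        else:
            stall += 1
            if stall >= opt_config.patience:
                stop_reason = "overtraining detected"
                break

    # the calibration set decides *when* to stop: once its R² has gone
    # `patience` epochs without a new best, further tuning is judged to be
    # overtraining and the current (final accepted) state is returned —
    # it sits at most `patience` epochs past the calibration optimum
    if model is None:
        raise UndefinedStatisticError(
            "optimization ended in a degenerate state; "
            "check the data or increase epochs"
        )
    epochs_done = epochs[-1].epoch if epochs else 0
    return RunTrace(
        epochs=epochs,
        weight_table=problem.weight_table(w, epochs_done),
        model=model,
        stop_reason=stop_reason,
        seed=opt_config.seed,
    )


def multi_run(
    records,
    split: SplitAssignment,
    opt_config: OptimizationConfig | None = None,
    tf_config: TargetFunctionConfig | None = None,
) -> list:
    """Independent optimization runs with randomized initial weights.

    Child seeds derive deterministically from ``opt_config.seed``, so the
    whole ensemble reproduces from one master seed.  Used for promoter
    classification, which needs at least two runs.
    """
    opt_config = opt_config or OptimizationConfig(n_runs=3)
    tf_config = tf_config or TargetFunctionConfig()
    if opt_config.n_runs < 2:
        raise ValueError("multi_run needs n_runs >= 2 for classification")
    children = np.random.SeedSequence(opt_config.seed).generate_state(
        opt_config.n_runs
    )
    traces = []
    for child in children:
        cfg = OptimizationConfig(
            threshold_T=opt_config.threshold_T,
            epochs_N=opt_config.epochs_N,
            step_size=opt_config.step_size,
            seed=int(child % (2**31)),
            n_runs=1,
            patience=opt_config.patience,
            pair_prob=opt_config.pair_prob,
            init="random",
        )
        traces.append(optimize(records, split, cfg, tf_config))
    return traces
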