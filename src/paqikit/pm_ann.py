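"""Satellite-to-PM estimation: input screening, L-M network, validation.

The estimator is a small feed-forward network (tanh hidden units, linear
output) trained by Levenberg-Marquardt damped Gauss-Newton on the
sum-of-squared-errors, the classical choice for low-dimensional regression
networks.  Training is repeated over many random train/validation splits
("runs"); the model from the run with the highest validation Pearson
correlation is kept, which both selects a good basin of attraction for the
non-convex fit and yields an honest held-out accuracy estimate.

Before training, candidate inputs are screened by stepwise regression
(forward selection with backward elimination on an ordinary linear model,
partial-F entry/exit tests) so the network spends no capacity on
irrelevant features.

Implementation notes:

* The Jacobian of the network output with respect to all weights is
  computed analytically by reverse accumulation, vectorized over samples.
* Damping follows the classical Marquardt schedule: lambda starts at 1e-3,
  is divided by 10 on an accepted step and multiplied by 10 on a rejected
  one, and the fit aborts above 1e10.
* Inputs and targets are z-scored by training-split statistics; a model
  with no hidden layer is therefore an affine map whose de-standardized
  coefficients converge to the ordinary-least-squares solution (used as a
  correctness oracle in the tests).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .rasters import GridField, StationTable, align_check

__all__ = [
    "AnnModel",
    "TrainReport",
    "StepwiseReport",
    "stepwise_select",
    "train_lm",
    "predict_grid",
    "validate",
]


# ---------------------------------------------------------------------------
# model container and forward pass


@dataclass
class AnnModel:
    """Feed-forward network with input/target standardization statistics."""

    layer_sizes: list[int]
    weights: list[np.ndarray]   # per layer, shape (n_in, n_out)
    biases: list[np.ndarray]    # per layer, shape (n_out,)
    input_center: np.ndarray
    input_scale: np.ndarray
    target_center: float
    target_scale: float
    predictor_names: list[str]
    pollutant: str = "PM2.5"
    activation: str = "tanh"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.layer_sizes[-1] != 1:
            raise ValueError("output layer must have size 1")
        if len(self.weights) != len(self.layer_sizes) - 1:
            raise ValueError("weights/layer_sizes mismatch")
        for k, (w, b) in enumerate(zip(self.weights, self.biases)):
            expect = (self.layer_sizes[k], self.layer_sizes[k + 1])
            if w.shape != expect or b.shape != (expect[1],):
                raise ValueError(f"layer {k} shapes {w.shape}/{b.shape} != {expect}")
        if len(self.predictor_names) != self.layer_sizes[0]:
            raise ValueError("predictor_names must match the input layer size")
        if np.any(self.input_scale == 0) or self.target_scale == 0:
            raise ValueError("standardization scales must be nonzero")

    def standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.input_center) / self.input_scale

    def predict(self, X: np.ndarray) -> np.ndarray:
        """De-standardized prediction for raw predictor rows (n, p)."""
        z = _forward(self.standardize(np.asarray(X, float)),
                     self.weights, self.biases)[-1][:, 0]
        return z * self.target_scale + self.target_center

    def linear_coefficients(self) -> tuple[np.ndarray, float]:
        """(slope vector, intercept) in original units; no-hidden models only."""
        if len(self.layer_sizes) != 2:
            raise ValueError("linear coefficients defined only for [p, 1] models")
        w = self.weights[0][:, 0]
        b = self.biases[0][0]
        slope = w * self.target_scale / self.input_scale
        intercept = (
            self.target_center
            + self.target_scale * (b - float(w @ (self.input_center / self.input_scale)))
        )
        return slope, intercept

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "layer_sizes": self.layer_sizes,
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "input_center": self.input_center.tolist(),
            "input_scale": self.input_scale.tolist(),
            "target_center": self.target_center,
            "target_scale": self.target_scale,
            "predictor_names": self.predictor_names,
            "pollutant": self.pollutant,
            "activation": self.activation,
            "meta": self.meta,
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "AnnModel":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        d = json.loads(text)
        return cls(
            layer_sizes=list(d["layer_sizes"]),
            weights=[np.asarray(w, float) for w in d["weights"]],
            biases=[np.asarray(b, float) for b in d["biases"]],
            input_center=np.asarray(d["input_center"], float),
            input_scale=np.asarray(d["input_scale"], float),
            target_center=float(d["target_center"]),
            target_scale=float(d["target_scale"]),
            predictor_names=list(d["predictor_names"]),
            pollutant=d.get("pollutant", "PM2.5"),
            activation=d.get("activation", "tanh"),
            meta=d.get("meta", {}),
        )


def _forward(
    X: np.ndarray, weights: Sequence[np.ndarray], biases: Sequence[np.ndarray]
) -> list[np.ndarray]:
    """Forward pass; returns activations [A0 .. AL], AL shape (n, 1)."""
    acts = [X]
    a = X
    last = len(weights) - 1
    for k, (w, b) in enumerate(zip(weights, biases)):
        z = a @ w + b
        a = z if k == last else np.tanh(z)
        acts.append(a)
    return acts


def _pack(weights, biases) -> np.ndarray:
    return np.concatenate([np.concatenate([w.ravel(), b]) for w, b in zip(weights, biases)])


def _unpack(theta: np.ndarray, layer_sizes: Sequence[int]):
    weights, biases, pos = [], [], 0
    for n_in, n_out in zip(layer_sizes, layer_sizes[1:]):
        w = theta[pos : pos + n_in * n_out].reshape(n_in, n_out)
        pos += n_in * n_out
        b = theta[pos : pos + n_out]
        pos += n_out
        weights.append(w)
        biases.append(b)
    return weights, biases


def _jacobian(acts: list[np.ndarray], weights: Sequence[np.ndarray]) -> np.ndarray:
    """d(output)/d(theta) for each sample, shape (n, n_params).

    Reverse accumulation: G holds d(out)/d(z_layer) per sample.
    """
    n = acts[0].shape[0]
    L = len(weights)
    G = np.ones((n, 1))
    blocks: list[np.ndarray] = [None] * L  # type: ignore[list-item]
    for l in range(L - 1, -1, -1):
        a_prev = acts[l]
        dW = a_prev[:, :, None] * G[:, None, :]          # (n, in, out)
        blocks[l] = np.concatenate([dW.reshape(n, -1), G], axis=1)
        if l > 0:
            G = (G @ weights[l].T) * (1.0 - acts[l] ** 2)  # tanh'
    return np.concatenate(blocks, axis=1)


# ---------------------------------------------------------------------------
# Levenberg-Marquardt core

_LAMBDA0 = 1e-3
_LAMBDA_MAX = 1e10


class _Diverged(RuntimeError):
    def __init__(self, lam: float):
        super().__init__(f"L-M fit diverged (damping reached {lam:.3g})")
        self.last_lambda = lam


def _fit_lm(
    X: np.ndarray,
    y: np.ndarray,
    layer_sizes: Sequence[int],
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
    patience: int | None = None,
) -> tuple[np.ndarray, list[float], int]:
    """Fit standardized data; returns (theta, accepted-loss trajectory, iters).

    With a validation set and *patience*, training stops early when the
    validation SSE has not improved for *patience* accepted steps, and the
    parameters at the best validation SSE are returned — the standard
    overfitting control for L-M regression networks.  The loss trajectory
    records training SSE at accepted steps and is non-increasing.
    """
    weights, biases = [], []
    for n_in, n_out in zip(layer_sizes, layer_sizes[1:]):
        weights.append(rng.uniform(-0.5, 0.5, size=(n_in, n_out)) / np.sqrt(n_in))
        biases.append(rng.uniform(-0.5, 0.5, size=n_out) / np.sqrt(n_in))
    theta = _pack(weights, biases)
    n_params = theta.size
    early = patience is not None and X_val is not None and len(X_val) >= 2

    def sse_of(th: np.ndarray, A: np.ndarray, t: np.ndarray) -> float:
        w, b = _unpack(th, layer_sizes)
        r = t - _forward(A, w, b)[-1][:, 0]
        return float(r @ r)

    lam = _LAMBDA0
    w, b = _unpack(theta, layer_sizes)
    acts = _forward(X, w, b)
    r = y - acts[-1][:, 0]
    sse = float(r @ r)
    losses = [sse]
    best_theta = theta
    best_losses_len = 1
    if early:
        best_val = sse_of(theta, X_val, y_val)
        fails = 0
    eye = np.eye(n_params)
    it = 0
    while it < max_iter:
        it += 1
        J = _jacobian(acts, w)
        g = J.T @ r
        if np.max(np.abs(g)) < tol:
            break
        JTJ = J.T @ J
        accepted = False
        while not accepted:
            try:
                delta = np.linalg.solve(JTJ + lam * eye, g)
            except np.linalg.LinAlgError:
                delta = None
            if delta is not None:
                sse_new = sse_of(theta + delta, X, y)
                if np.isfinite(sse_new) and sse_new < sse:
                    theta = theta + delta
                    sse = sse_new
                    losses.append(sse)
                    lam = max(lam / 10.0, 1e-14)
                    accepted = True
                    continue
            lam *= 10.0
            if lam > _LAMBDA_MAX:
                # No downhill step even under maximal damping: the fit has
                # stalled.  With a finite loss this is convergence to a
                # stationary point; a non-finite loss is true divergence.
                if np.isfinite(sse):
                    return best_theta, losses[:best_losses_len], it
                raise _Diverged(lam)
        if early:
            val = sse_of(theta, X_val, y_val)
            if val < best_val:
                best_val = val
                best_theta = theta
                best_losses_len = len(losses)
                fails = 0
            else:
                fails += 1
                if fails >= patience:
                    break
        else:
            best_theta = theta
            best_losses_len = len(losses)
        w, b = _unpack(theta, layer_sizes)
        acts = _forward(X, w, b)
        r = y - acts[-1][:, 0]
    return best_theta, losses[:best_losses_len], it


# ---------------------------------------------------------------------------
# repeated random-sampling training


@dataclass
class TrainReport:
    """Per-run validation metrics for repeated random-sampling training."""

    n_runs: int
    split_fraction: float
    runs: pd.DataFrame  # run, r, ape, n_iter, train_sse, diverged
    best_run: int
    loss_trajectory: list[float]  # accepted-step SSE of the best run

    def write_csv(self, path: str | Path) -> None:
        self.runs.to_csv(path, index=False)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.size < 2 or np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def _mean_ape_pct(pred: np.ndarray, obs: np.ndarray) -> float:
    ok = obs > 0
    if not ok.any():
        return float("nan")
    return float(np.mean(np.abs(pred[ok] - obs[ok]) / obs[ok]) * 100.0)


def train_lm(
    table: StationTable,
    layer_sizes: Sequence[int] | None = None,
    n_runs: int = 50,
    split_fraction: float = 0.8,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-10,
    hidden: int = 16,
    patience: int | None = 25,
    predictor_names: Sequence[str] | None = None,
) -> tuple[AnnModel, TrainReport]:
    """Train the L-M network over repeated random train/validation splits.

    Each run draws a fresh split at *split_fraction*, standardizes by the
    training split, initializes weights from a seeded small-uniform scheme
    and optimizes the sum of squared errors with adaptive damping; the
    run's validation split also drives early stopping (*patience* accepted
    steps without validation improvement; ``patience=None`` disables it
    and trains to full convergence).  The returned model is the run with
    the highest validation correlation.

    layer_sizes defaults to [n_predictors, hidden, 1]; pass an explicit
    list (e.g. ``[p, 1]``) for other architectures.
    """
    names = list(predictor_names) if predictor_names is not None else table.predictor_names
    X = table.X(names)
    y = table.y()
    n = len(y)
    if n < 20:
        raise ValueError(f"need at least 20 station rows, got {n}")
    if layer_sizes is None:
        layer_sizes = [X.shape[1], hidden, 1]
    layer_sizes = [int(s) for s in layer_sizes]
    if layer_sizes[0] != X.shape[1]:
        raise ValueError(
            f"layer_sizes[0]={layer_sizes[0]} != number of predictors {X.shape[1]}"
        )
    if layer_sizes[-1] != 1:
        raise ValueError("last layer size must be 1")
    if not (0 < split_fraction < 1):
        raise ValueError("split_fraction must be in (0, 1)")

    n_train = max(2, int(round(split_fraction * n)))
    n_train = min(n_train, n - 1)
    run_seeds = np.random.SeedSequence(seed).spawn(n_runs)

    records = []
    best = None  # (r, run_index, model_parts)
    last_lambda = _LAMBDA0
    for k, ss in enumerate(run_seeds):
        rng = np.random.default_rng(ss)
        perm = rng.permutation(n)
        tr, va = perm[:n_train], perm[n_train:]
        xc = X[tr].mean(axis=0)
        xs = X[tr].std(axis=0)
        xs = np.where(xs == 0, 1.0, xs)
        yc = float(y[tr].mean())
        ysd = float(y[tr].std()) or 1.0
        Xz = (X[tr] - xc) / xs
        yz = (y[tr] - yc) / ysd
        Xvz = (X[va] - xc) / xs
        yvz = (y[va] - yc) / ysd
        try:
            theta, losses, n_iter = _fit_lm(
                Xz, yz, layer_sizes, rng, max_iter, tol,
                X_val=Xvz, y_val=yvz, patience=patience,
            )
        except _Diverged as exc:
            last_lambda = exc.last_lambda
            records.append(
                dict(run=k, r=np.nan, ape=np.nan, n_iter=0,
                     train_sse=np.nan, diverged=True)
            )
            continue
        w, b = _unpack(theta, layer_sizes)
        pred_va = _forward((X[va] - xc) / xs, w, b)[-1][:, 0] * ysd + yc
        r = _pearson(pred_va, y[va])
        ape = _mean_ape_pct(pred_va, y[va])
        records.append(
            dict(run=k, r=r, ape=ape, n_iter=n_iter,
                 train_sse=losses[-1], diverged=False)
        )
        if np.isfinite(r) and (best is None or r > best[0]):
            best = (r, k, (w, b, xc, xs, yc, ysd, losses, tr))
    if best is None:
        raise RuntimeError(
            f"all {n_runs} training runs diverged (last damping {last_lambda:.3g})"
        )

    r_best, k_best, (w, b, xc, xs, yc, ysd, losses, tr_best) = best
    report = TrainReport(
        n_runs=n_runs,
        split_fraction=split_fraction,
        runs=pd.DataFrame.from_records(records),
        best_run=k_best,
        loss_trajectory=losses,
    )
    pollutant = (
        str(table.frame["pollutant"].iloc[0]) if "pollutant" in table.frame else "PM2.5"
    )
    model = AnnModel(
        layer_sizes=layer_sizes,
        weights=w,
        biases=b,
        input_center=xc,
        input_scale=xs,
        target_center=yc,
        target_scale=ysd,
        predictor_names=names,
        pollutant=pollutant,
        meta={
            "n_runs": n_runs,
            "best_run": k_best,
            "best_validation_r": r_best,
            "split_fraction": split_fraction,
            "seed": seed,
            "train_rows": [int(i) for i in tr_best],
        },
    )
    return model, report


def predict_grid(model: AnnModel, fields: Mapping[str, GridField]) -> GridField:
    """Per-cell network prediction over aligned predictor rasters.

    The output mask is the union of the input masks (any missing input
    masks the cell); negative predictions are floored at 0 and the count
    recorded in ``meta['n_floored']``.
    """
    missing = [p for p in model.predictor_names if p not in fields]
    if missing:
        raise KeyError(f"missing predictor field(s): {missing}")
    used = {p: fields[p] for p in model.predictor_names}
    align_check(used)
    first = next(iter(used.values()))
    mask = np.logical_and.reduce([f.mask for f in used.values()])
    X = np.column_stack(
        [np.where(mask, f.values, 0.0).ravel() for f in used.values()]
    )
    pred = model.predict(X).reshape(first.shape)
    n_floored = int(np.count_nonzero((pred < 0) & mask))
    pred = np.clip(pred, 0.0, None)
    out = first.with_values(pred, name=f"{model.pollutant}_est")
    out.mask = mask
    out.meta["n_floored"] = n_floored
    return out


def validate(pred: Sequence[float], obs: Sequence[float]) -> dict[str, float]:
    """Validation metrics: Pearson r and mean absolute percentage error.

    APE is the mean over records of |Y_est - Y_obs| / Y_obs, in percent.
    """
    p = np.asarray(pred, float)
    o = np.asarray(obs, float)
    if p.shape != o.shape or p.ndim != 1:
        raise ValueError("pred and obs must be 1-D of equal length")
    if p.size < 2:
        raise ValueError("need at least 2 records")
    zero = np.flatnonzero(o == 0)
    if zero.size:
        raise ValueError(f"APE undefined: obs is zero at record(s) {zero.tolist()}")
    if np.any(o < 0):
        raise ValueError("observed concentrations must be positive")
    if np.std(p) == 0 or np.std(o) == 0:
        raise ValueError("correlation undefined: zero variance input")
    return {
        "r": float(np.corrcoef(p, o)[0, 1]),
        "ape": float(np.mean(np.abs(p - o) / o) * 100.0),
    }


# ---------------------------------------------------------------------------
# stepwise input screening


@dataclass
class StepwiseReport:
    """Trace of forward-selection / backward-elimination screening."""

    candidates: list[str]
    selected: list[str]  # in order of entry
    steps: list[dict]    # {action: enter|remove, name, p_value}
    alpha_enter: float
    alpha_remove: float


def _rss(X: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Residual sum of squares of OLS with intercept; returns (rss, rank)."""
    A = np.column_stack([np.ones(len(y)), X]) if X.size else np.ones((len(y), 1))
    coef, res, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    fitted = A @ coef
    return float(np.sum((y - fitted) ** 2)), int(rank)


def stepwise_select(
    table: StationTable,
    candidates: Sequence[str] | None = None,
    alpha_enter: float = 0.05,
    alpha_remove: float = 0.10,
) -> StepwiseReport:
    """Screen network inputs by stepwise linear regression.

    Forward selection with backward elimination on an ordinary linear
    model of observed_pm: at each cycle the candidate with the smallest
    partial-F p-value enters if below *alpha_enter*, then included
    variables whose removal p-value exceeds *alpha_remove* leave.
    Deterministic given the table.
    """
    if alpha_enter > alpha_remove:
        raise ValueError("alpha_enter must be <= alpha_remove")
    cand = list(candidates) if candidates is not None else list(table.predictor_names)
    if len(cand) < 2:
        raise ValueError("need at least 2 candidate predictors")
    y = table.y()
    n = len(y)
    if n < 10 * len(cand):
        warnings.warn(
            f"only {n} rows for {len(cand)} candidates (<10x); "
            "stepwise p-values may be unstable",
            stacklevel=2,
        )
    cols = {c: table.frame[c].to_numpy(float) for c in cand}
    for c in list(cand):
        if np.std(cols[c]) == 0:
            warnings.warn(f"dropping constant candidate {c!r}", stacklevel=2)
            cand.remove(c)

    def design(names: Sequence[str]) -> np.ndarray:
        return (
            np.column_stack([cols[c] for c in names]) if names else np.empty((n, 0))
        )

    selected: list[str] = []
    steps: list[dict] = []
    changed = True
    while changed:
        changed = False
        # forward step: best entering candidate by partial-F p-value
        rss_cur, _ = _rss(design(selected), y)
        best_p, best_name = None, None
        for c in cand:
            if c in selected:
                continue
            trial = selected + [c]
            rss_new, rank = _rss(design(trial), y)
            if rank < len(trial) + 1:  # collinear addition: design singular
                continue
            df2 = n - (len(trial) + 1)
            if df2 <= 0 or rss_new <= 0:
                continue
            F = (rss_cur - rss_new) / (rss_new / df2)
            p = float(stats.f.sf(max(F, 0.0), 1, df2))
            if best_p is None or p < best_p:
                best_p, best_name = p, c
        if best_name is not None and best_p < alpha_enter:
            selected.append(best_name)
            steps.append({"action": "enter", "name": best_name, "p_value": best_p})
            changed = True
        # backward step: drop the worst included variable if above alpha_remove
        while len(selected) > 1:
            rss_full, _ = _rss(design(selected), y)
            df2 = n - (len(selected) + 1)
            worst_p, worst_name = None, None
            for c in selected:
                reduced = [s for s in selected if s != c]
                rss_red, _ = _rss(design(reduced), y)
                F = (rss_red - rss_full) / (rss_full / df2)
                p = float(stats.f.sf(max(F, 0.0), 1, df2))
                if worst_p is None or p > worst_p:
                    worst_p, worst_name = p, c
            if worst_p is not None and worst_p > alpha_remove:
                selected.remove(worst_name)
                steps.append({"action": "remove", "name": worst_name, "p_value": worst_p})
                changed = True
            else:
                break
    return StepwiseReport(
        candidates=cand,
        selected=selected,
        steps=steps,
        alpha_enter=alpha_enter,
        alpha_remove=alpha_remove,
    )
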