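"""Model-assessment protocol: stratified Monte-Carlo splitting and metrics.

Small-dataset evaluation is stabilized by repeating random train/test
partitions inside label-quantile strata: the label vector is sorted into
``n_strata`` contiguous, equal-count blocks and each Monte-Carlo (MC)
repetition draws its test molecules within the strata (one per stratum in the
canonical 25/25 configuration).  Per-molecule prediction means/sds as train
and as test, and the MAE / RMSE / r_E distributions over repetitions, are
aggregated into an :class:`EvalReport`.  A nested, stratified 5-fold CV over
the training split selects among discrete model/feature candidates.

Everything is deterministic given (seed, plan): repetition ``i`` uses the seed
sequence ``(seed, i)``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone

from .dataset import SpectroDataset
from .features import (
    FeatureSpec,
    build_features,
    permutation_augment,
    predicted_Re_feature,
)

__all__ = [
    "SplitPlan",
    "Metrics",
    "EvalReport",
    "stratify",
    "mc_split",
    "metrics",
    "nested_cv_select",
    "mc_evaluate",
    "learning_curve",
]

logger = logging.getLogger(__name__)

_HAT_TOKENS = ("Re_hat", "inv_Re_hat")


@dataclass(frozen=True)
class SplitPlan:
    """Monte-Carlo splitting plan (defaults: 25 strata, 25 test, 1000 reps)."""

    n_strata: int = 25
    n_test: int = 25
    n_mc: int = 1000
    seed: int = 0

    def validate(self, n: int) -> None:
        if self.n_strata > n:
            raise ValueError(f"n_strata={self.n_strata} exceeds dataset size {n}")
        if self.n_test > n // 2:
            raise ValueError(f"n_test={self.n_test} exceeds half the dataset ({n})")


def stratify(labels: Sequence[float], n_strata: int) -> np.ndarray:
    """Assign each label to one of ``n_strata`` contiguous quantile blocks.

    Labels are stably sorted; block sizes differ by at most one; ties keep
    input order.  Returns an integer stratum id per input position.
    """
    labels = np.asarray(labels, dtype=float)
    n = labels.shape[0]
    if n < n_strata:
        raise ValueError(f"need at least n_strata={n_strata} labels, got {n}")
    order = np.argsort(labels, kind="stable")
    assignment = np.empty(n, dtype=int)
    for s, block in enumerate(np.array_split(order, n_strata)):
        assignment[block] = s
    return assignment


def mc_split(
    strata: np.ndarray, plan: SplitPlan, rep_index: int
) -> tuple[np.ndarray, np.ndarray]:
    """Draw the (train, test) index split for one MC repetition.

    One test molecule is sampled uniformly per stratum when
    ``n_test == n_strata``; in general test slots are assigned round-robin
    over the strata.  Deterministic given (plan.seed, rep_index).
    """
    strata = np.asarray(strata)
    n = strata.shape[0]
    n_strata = int(strata.max()) + 1
    rng = np.random.default_rng(np.random.SeedSequence([plan.seed, rep_index]))

    quota = np.zeros(n_strata, dtype=int)
    for i in range(plan.n_test):
        quota[i % n_strata] += 1

    test: list[int] = []
    deficit = 0
    for s in range(n_strata):
        members = np.where(strata == s)[0]
        take = quota[s]
        if take > members.shape[0] - 1:  # keep at least one train member
            deficit += take - max(members.shape[0] - 1, 0)
            take = max(members.shape[0] - 1, 0)
        if take:
            test.extend(rng.choice(members, size=take, replace=False))
    if deficit:
        logger.warning("re-balancing %d test slots across strata", deficit)
        pool = np.setdiff1d(np.arange(n), np.asarray(test, dtype=int))
        test.extend(rng.choice(pool, size=deficit, replace=False))
    test_idx = np.sort(np.asarray(test, dtype=int))
    train_idx = np.setdiff1d(np.arange(n), test_idx)
    return train_idx, test_idx


class Metrics(NamedTuple):
    mae: float
    rmse: float
    r_e: float  # percent


def metrics(y_true, y_pred, y_range: Optional[float] = None) -> Metrics:
    """MAE, RMSE and the normalized error r_E = 100·RMSE/range(y) (%).

    ``y_range`` fixes the r_E denominator (by default the full-dataset label
    range is passed in by the evaluation loop so r_E is comparable across
    repetitions); when omitted, the range of ``y_true`` is used.
    """
    y_true = np.asarray(y_true, float)
    y_pred = np.asarray(y_pred, float)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ValueError("y_true and y_pred must be equal-length, nonempty")
    err = y_pred - y_true
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    if y_range is None:
        y_range = float(np.ptp(y_true))
    if y_range <= 0:
        raise ValueError("r_E undefined: label range is zero")
    return Metrics(mae, rmse, 100.0 * rmse / y_range)


def _needs_hat(spec: FeatureSpec) -> bool:
    return any(t in _HAT_TOKENS for t in spec.components)


def _stratified_folds(y: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Fold assignment stratified on the label: sort, shuffle within blocks of k, deal."""
    n = y.shape[0]
    if n < 2 * k:
        raise ValueError(f"need at least {2 * k} samples for {k}-fold CV")
    order = np.argsort(y, kind="stable")
    folds = np.empty(n, dtype=int)
    pos = 0
    while pos < n:
        block = order[pos : pos + k]
        labels = rng.permutation(k)[: block.shape[0]]
        folds[block] = labels
        pos += k
    return folds


def _fit_predict(
    molecules,
    spec: FeatureSpec,
    model,
    train_idx: np.ndarray,
    *,
    seed: int,
):
    """Fit on the training rows of the spec's view; predict every row.

    ``molecules`` must already be the spec's view (one row per molecule, in
    order), so ``train_idx`` indexes both the molecule list and the feature
    matrix.  Hat-token contexts (predicted R_e) are computed from the
    training rows only.  Returns (fm, predictions over all view rows).
    """
    context = {}
    if _needs_hat(spec):
        mask = np.zeros(len(molecules), dtype=bool)
        mask[train_idx] = True
        context["Re_hat"] = predicted_Re_feature(molecules, mask, seed=seed)
    fm = build_features(molecules, spec, context)
    if len(fm) != len(molecules):
        raise ValueError(
            f"spec {spec.name!r} drops rows from the evaluation view "
            f"({len(fm)} of {len(molecules)} usable); align candidate targets"
        )
    train = fm.subset(train_idx)
    if spec.augment:
        train = permutation_augment(train, spec)
    est = clone(model)
    if "random_state" in est.get_params():
        est.set_params(random_state=seed % (2**31 - 1))
    est.fit(train.X, train.y)
    return fm, est.predict(fm.X)


def nested_cv_select(
    molecules,
    train_idx: np.ndarray,
    candidates: Sequence[tuple[FeatureSpec, object]],
    k: int = 5,
    seed: int = 0,
) -> tuple[int, pd.DataFrame]:
    """Pick the candidate (feature spec, model) with lowest mean CV-fold RMSE.

    Folds are stratified on the training labels; augmentation is applied only
    to each fold's training portion; ties resolve to the first candidate.
    Returns (winner index, per-candidate diagnostics).
    """
    if not candidates:
        raise ValueError("no candidates given")
    rows = []
    for ci, (spec, model) in enumerate(candidates):
        fm = build_features(
            molecules,
            spec,
            {"Re_hat": {m.formula: 1.0 for m in molecules}} if _needs_hat(spec) else None,
        )
        y_tr = fm.y[train_idx]
        rng = np.random.default_rng(np.random.SeedSequence([seed, 5, ci]))
        folds = _stratified_folds(y_tr, k, rng)
        fold_rmse = []
        try:
            for f in range(k):
                inner_train = train_idx[folds != f]
                inner_val = train_idx[folds == f]
                fm_all, preds = _fit_predict(
                    molecules, spec, model, inner_train, seed=seed * 31 + ci
                )
                m = metrics(fm_all.y[inner_val], preds[inner_val])
                fold_rmse.append(m.rmse)
            rows.append({"candidate": spec.name, "cv_rmse": float(np.mean(fold_rmse)), "error": ""})
        except Exception as exc:  # candidate-level failure is diagnosed, not fatal
            rows.append({"candidate": spec.name, "cv_rmse": np.inf, "error": str(exc)})
    diag = pd.DataFrame(rows)
    if not np.isfinite(diag["cv_rmse"]).any():
        raise RuntimeError(f"all candidates failed nested CV:\n{diag}")
    winner = int(np.argmin(diag["cv_rmse"].to_numpy()))
    logger.info("nested CV selected %s", diag.loc[winner, "candidate"])
    return winner, diag


@dataclass
class EvalReport:
    """Aggregated Monte-Carlo evaluation results."""

    per_molecule: pd.DataFrame
    per_rep: pd.DataFrame
    y_range: float
    metadata: dict = field(default_factory=dict)
    predictions: Optional[np.ndarray] = None  # (n_reps, n_molecules)
    roles: Optional[np.ndarray] = None  # +1 test, -1 train, 0 skipped

    def aggregate(self) -> dict:
        out: dict = {}
        for split in ("train", "test"):
            out[split] = {}
            for name in ("mae", "rmse", "r_e"):
                col = self.per_rep[f"{split}_{name}"]
                out[split][name.upper() if name != "r_e" else "r_E"] = {
                    "mean": float(col.mean()),
                    "sd": float(col.std(ddof=0)),
                }
        return out

    def summary(self) -> str:
        agg = self.aggregate()
        t = agg["test"]
        return (
            f"test MAE {t['MAE']['mean']:.4g} ± {t['MAE']['sd']:.2g} | "
            f"RMSE {t['RMSE']['mean']:.4g} ± {t['RMSE']['sd']:.2g} | "
            f"r_E {t['r_E']['mean']:.3g} ± {t['r_E']['sd']:.2g} %"
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "metadata": self.metadata,
                "aggregate": self.aggregate(),
                "y_range": self.y_range,
                "per_molecule": self.per_molecule.to_dict(orient="records"),
            },
            default=float,
        )


def mc_evaluate(
    dataset: SpectroDataset | list,
    feature_spec: FeatureSpec,
    model,
    plan: SplitPlan,
    *,
    candidates: Optional[Sequence[tuple[FeatureSpec, object]]] = None,
    store_predictions: bool = True,
) -> EvalReport:
    """Run the full MC train/test protocol for one (feature spec, model) pair.

    Per repetition: stratified split, optional nested CV over ``candidates``,
    permutation augmentation of the training rows, fit, and prediction of
    every molecule in the target view.  Failed repetitions are skipped and
    counted; more than 5% failures aborts.
    """
    molecules = dataset.molecules() if isinstance(dataset, SpectroDataset) else dataset
    context = {"Re_hat": {m.formula: 1.0 for m in molecules}} if _needs_hat(feature_spec) else None
    fm_probe = build_features(molecules, feature_spec, context)
    n = len(fm_probe)
    plan.validate(n)
    y_full = fm_probe.y
    y_range = float(np.ptp(y_full))
    strata = stratify(y_full, plan.n_strata)
    view_mols = [m for m in molecules if m.formula in set(fm_probe.row_ids)]

    n_train_count = np.zeros(n, dtype=int)
    n_test_count = np.zeros(n, dtype=int)
    sums = {k: np.zeros(n) for k in ("train", "train2", "test", "test2", "test_abs")}
    rep_rows = []
    preds_store = np.full((plan.n_mc, n), np.nan) if store_predictions else None
    roles_store = np.zeros((plan.n_mc, n), dtype=np.int8) if store_predictions else None
    failures = 0

    spec = feature_spec
    eff_model = model
    for rep in range(plan.n_mc):
        train_idx, test_idx = mc_split(strata, plan, rep)
        rep_seed = (plan.seed * 1_000_003 + rep) % (2**31 - 1)
        try:
            if candidates:
                winner, _ = nested_cv_select(
                    view_mols, train_idx, candidates, seed=rep_seed
                )
                spec, eff_model = candidates[winner]
            fm, preds = _fit_predict(view_mols, spec, eff_model, train_idx, seed=rep_seed)
        except Exception as exc:
            failures += 1
            logger.warning("rep %d failed: %s", rep, exc)
            if failures > max(0.05 * plan.n_mc, 1):
                raise RuntimeError(
                    f"{failures} failed repetitions out of {rep + 1}; aborting"
                ) from exc
            continue
        m_train = metrics(fm.y[train_idx], preds[train_idx], y_range)
        m_test = metrics(fm.y[test_idx], preds[test_idx], y_range)
        rep_rows.append(
            {
                "rep": rep,
                "train_mae": m_train.mae, "train_rmse": m_train.rmse, "train_r_e": m_train.r_e,
                "test_mae": m_test.mae, "test_rmse": m_test.rmse, "test_r_e": m_test.r_e,
            }
        )
        n_train_count[train_idx] += 1
        n_test_count[test_idx] += 1
        sums["train"][train_idx] += preds[train_idx]
        sums["train2"][train_idx] += preds[train_idx] ** 2
        sums["test"][test_idx] += preds[test_idx]
        sums["test2"][test_idx] += preds[test_idx] ** 2
        sums["test_abs"][test_idx] += np.abs(preds[test_idx] - fm.y[test_idx])
        if store_predictions:
            preds_store[rep] = preds
            roles_store[rep, train_idx] = -1
            roles_store[rep, test_idx] = 1

    def _mean_sd(s, s2, cnt):
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = np.where(cnt > 0, s / np.maximum(cnt, 1), np.nan)
            var = np.where(cnt > 0, s2 / np.maximum(cnt, 1) - mean**2, np.nan)
        return mean, np.sqrt(np.clip(var, 0.0, None))

    tr_mean, tr_sd = _mean_sd(sums["train"], sums["train2"], n_train_count)
    te_mean, te_sd = _mean_sd(sums["test"], sums["test2"], n_test_count)
    with np.errstate(invalid="ignore", divide="ignore"):
        te_abs = np.where(n_test_count > 0, sums["test_abs"] / np.maximum(n_test_count, 1), np.nan)

    per_molecule = pd.DataFrame(
        {
            "formula": fm_probe.row_ids,
            "y_true": y_full,
            "n_train": n_train_count,
            "n_test": n_test_count,
            "train_mean": tr_mean,
            "train_sd": tr_sd,
            "test_mean": te_mean,
            "test_sd": te_sd,
            "test_abs_err_mean": te_abs,
        }
    )
    report = EvalReport(
        per_molecule=per_molecule,
        per_rep=pd.DataFrame(rep_rows),
        y_range=y_range,
        metadata={
            "feature_spec": feature_spec.to_dict(),
            "model": repr(model),
            "plan": {"n_strata": plan.n_strata, "n_test": plan.n_test,
                     "n_mc": plan.n_mc, "seed": plan.seed},
            "n_molecules": n,
            "failures": failures,
        },
        predictions=preds_store,
        roles=roles_store,
    )
    logger.info("mc_evaluate %s: %s", feature_spec.name, report.summary())
    return report


def _stratified_subsample(
    idx: np.ndarray, y: np.ndarray, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Pick ``size`` of ``idx`` spread over the label range (one per quantile block)."""
    if size >= idx.shape[0]:
        return idx
    order = idx[np.argsort(y[idx], kind="stable")]
    picks = [rng.choice(block) for block in np.array_split(order, size)]
    return np.sort(np.asarray(picks, dtype=int))


def learning_curve(
    dataset: SpectroDataset | list,
    feature_spec: FeatureSpec,
    model,
    sizes: Sequence[int],
    n_mc: int = 500,
    plan: Optional[SplitPlan] = None,
) -> pd.DataFrame:
    """Train/test error versus training-set size N (mean ± sd over MC reps).

    For each N the usual stratified MC split is drawn, the training split is
    stratified-subsampled down to N, and the model is fitted and scored as in
    :func:`mc_evaluate`.  Sizes below the minimum fit size are skipped and
    logged.
    """
    molecules = dataset.molecules() if isinstance(dataset, SpectroDataset) else dataset
    plan = plan or SplitPlan(n_mc=n_mc)
    plan = SplitPlan(plan.n_strata, plan.n_test, n_mc, plan.seed)
    context = {"Re_hat": {m.formula: 1.0 for m in molecules}} if _needs_hat(feature_spec) else None
    fm_probe = build_features(molecules, feature_spec, context)
    n = len(fm_probe)
    plan.validate(n)
    y_full = fm_probe.y
    y_range = float(np.ptp(y_full))
    strata = stratify(y_full, plan.n_strata)
    view_mols = [m for m in molecules if m.formula in set(fm_probe.row_ids)]
    min_fit = len(feature_spec.components) + 2

    rows = []
    for size in sizes:
        if size < min_fit:
            logger.warning("skipping N=%d (< minimum fit size %d)", size, min_fit)
            continue
        per_rep = {"train_rmse": [], "test_rmse": [], "train_mae": [], "test_mae": []}
        for rep in range(plan.n_mc):
            train_idx, test_idx = mc_split(strata, plan, rep)
            rng = np.random.default_rng(np.random.SeedSequence([plan.seed, 7919, size, rep]))
            sub_train = _stratified_subsample(train_idx, y_full, size, rng)
            rep_seed = (plan.seed * 1_000_003 + 7919 * size + rep) % (2**31 - 1)
            fm, preds = _fit_predict(view_mols, feature_spec, model, sub_train, seed=rep_seed)
            m_tr = metrics(fm.y[sub_train], preds[sub_train], y_range)
            m_te = metrics(fm.y[test_idx], preds[test_idx], y_range)
            per_rep["train_rmse"].append(m_tr.rmse)
            per_rep["test_rmse"].append(m_te.rmse)
            per_rep["train_mae"].append(m_tr.mae)
            per_rep["test_mae"].append(m_te.mae)
        row = {"N": size}
        for key, vals in per_rep.items():
            row[f"{key}_mean"] = float(np.mean(vals))
            row[f"{key}_sd"] = float(np.std(vals, ddof=0))
        rows.append(row)
    return pd.DataFrame(rows)
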