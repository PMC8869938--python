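"""Predictive-mean-matching imputation with mode aggregation.

Missing (``"NE"``) molecular or pathological calls are filled by PMM:
each target column is regressed on the clinicopathological predictors over
the complete cases (categorical targets through one indicator regression
per level), regression coefficients are perturbed by a draw from their
sampling distribution, the missing cases' predictions are matched to the
``k`` nearest complete-case predictions, and one of those donors' observed
values is donated at random.  Because values are donated, every imputed
cell is a member of the target's observed category set.

:func:`pmm_mode_impute` repeats this over ``n_runs`` independently seeded
runs and keeps, per cell, the most frequent donated value, with ties
broken by the fixed schema category order.  The per-cell vote counts are
returned as an explicit log, and the whole procedure is deterministic
given the master seed.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CATEGORICAL_VOCAB, NE, Cohort

__all__ = ["ImputationConfig", "ImputationLog", "pmm_single_run", "pmm_mode_impute"]

#: Predictors used when the config does not name any: the
#: clinicopathological variables (the molecular calls are the usual targets).
DEFAULT_PREDICTORS = [
    "age_years",
    "histology",
    "grade",
    "myometrial_invasion",
    "figo_stage",
    "lvsi",
]

DEFAULT_TARGETS = ["pole_variant", "mmr_status", "p53_ihc", "ctnnb1_exon3"]


@dataclass(frozen=True)
class ImputationConfig:
    n_runs: int = 1000
    k_donors: int = 5
    predictor_columns: tuple = tuple(DEFAULT_PREDICTORS)
    target_columns: tuple = tuple(DEFAULT_TARGETS)
    seed: int = 0

    def __post_init__(self):
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.k_donors < 1:
            raise ValueError("k_donors must be >= 1")


@dataclass
class ImputationLog:
    """Per-cell record of donated values across runs."""

    # (patient_id, column) -> {value: votes}
    votes: dict = field(default_factory=dict)
    # (patient_id, column) -> chosen value
    chosen: dict = field(default_factory=dict)
    notes: list = field(default_factory=list)


def _is_missing(series: pd.Series) -> pd.Series:
    return (series == NE) | (series == "")


def _design_matrix(df: pd.DataFrame, predictors) -> np.ndarray:
    """Intercept + standardized numerics + one-hot categoricals.

    Predictor NE values form their own indicator level, so no row is ever
    dropped for predictor missingness.
    """
    cols = [np.ones(len(df))]
    for col in predictors:
        if col in CATEGORICAL_VOCAB or df[col].dtype == object:
            for level in sorted(df[col].astype(str).unique())[1:]:
                cols.append((df[col].astype(str) == level).to_numpy(float))
        else:
            x = df[col].to_numpy(float)
            sd = x.std()
            cols.append((x - x.mean()) / sd if sd > 0 else np.zeros(len(df)))
    return np.column_stack(cols)


def _draw_predictions(
    X_obs: np.ndarray, Y_obs: np.ndarray, X_all: np.ndarray, rng: np.random.Generator
) -> np.ndarray | None:
    """Posterior-perturbed linear predictions for every row (mice's norm draw).

    Returns None when the complete-case design is too degenerate to solve.
    """
    n, p = X_obs.shape
    xtx = X_obs.T @ X_obs
    try:
        xtx_inv = np.linalg.pinv(xtx)
        beta_hat = xtx_inv @ X_obs.T @ Y_obs
    except np.linalg.LinAlgError:  # pragma: no cover - pinv rarely fails
        return None
    resid = Y_obs - X_obs @ beta_hat
    dof = max(n - np.linalg.matrix_rank(xtx), 1)
    preds = np.empty((X_all.shape[0], Y_obs.shape[1]))
    # symmetric square root of (X'X)^-1 for the coefficient perturbation
    w, V = np.linalg.eigh(xtx_inv)
    root = V @ np.diag(np.sqrt(np.clip(w, 0, None))) @ V.T
    for j in range(Y_obs.shape[1]):
        s2 = float(resid[:, j] @ resid[:, j]) / dof
        sigma2 = s2 * dof / rng.chisquare(dof)
        beta_star = beta_hat[:, j] + np.sqrt(sigma2) * (root @ rng.standard_normal(p))
        preds[:, j] = X_all @ beta_star
    return preds


def pmm_single_run(
    cohort: Cohort, config: ImputationConfig, run_seed: int
) -> tuple[Cohort, ImputationLog]:
    """One PMM pass: fill every missing target cell with a donated value."""
    rng = np.random.default_rng(run_seed)
    df = cohort.df.copy()
    log = ImputationLog()
    X_all = _design_matrix(df, config.predictor_columns)

    for col in config.target_columns:
        miss = _is_missing(df[col])
        if not miss.any():
            continue
        obs_idx = np.flatnonzero(~miss)
        miss_idx = np.flatnonzero(miss.to_numpy())
        if obs_idx.size < config.k_donors:
            raise ValueError(
                f"target {col!r}: only {obs_idx.size} complete cases, "
                f"need at least k_donors={config.k_donors}"
            )
        observed = df[col].iloc[obs_idx].astype(str)
        levels = sorted(observed.unique())
        if len(levels) == 1:
            # nothing to regress on: every donor carries the same value
            df.iloc[miss_idx, df.columns.get_loc(col)] = levels[0]
            for i in miss_idx:
                log.chosen[(df["patient_id"].iloc[i], col)] = levels[0]
            continue
        Y_obs = np.column_stack([(observed == lv).to_numpy(float) for lv in levels])
        preds = _draw_predictions(X_all[obs_idx], Y_obs, X_all, rng)
        if preds is None:
            log.notes.append(f"{col}: degenerate predictors; empirical donor draw")
            donors = rng.choice(obs_idx, size=miss_idx.size, replace=True)
        else:
            donors = np.empty(miss_idx.size, dtype=int)
            pred_obs = preds[obs_idx]
            for k, i in enumerate(miss_idx):
                d2 = ((pred_obs - preds[i]) ** 2).sum(axis=1)
                nearest = np.argpartition(d2, config.k_donors - 1)[: config.k_donors]
                donors[k] = obs_idx[nearest[rng.integers(config.k_donors)]]
        values = df[col].iloc[donors].to_numpy()
        df.iloc[miss_idx, df.columns.get_loc(col)] = values
        for i, v in zip(miss_idx, values):
            log.chosen[(df["patient_id"].iloc[i], col)] = v
    return Cohort(df, {**cohort.provenance, "imputed": f"pmm run {run_seed}"}), log


def _category_order(col: str, values) -> list[str]:
    """Fixed tie-break order: schema vocabulary order, then lexicographic."""
    if col in CATEGORICAL_VOCAB:
        vocab = CATEGORICAL_VOCAB[col]
        return sorted(values, key=lambda v: (vocab.index(v) if v in vocab else len(vocab), v))
    return sorted(values)


def pmm_mode_impute(
    cohort: Cohort, config: ImputationConfig
) -> tuple[Cohort, ImputationLog]:
    """Fill each missing cell with its modal donated value over ``n_runs``.

    Run-level seeds derive from ``config.seed`` through a SeedSequence, so
    the whole aggregation is bit-reproducible.  Modal ties break by the
    fixed schema category order and are noted in the log.
    """
    seq = np.random.SeedSequence(config.seed)
    run_seeds = seq.generate_state(config.n_runs, dtype=np.uint32)
    votes: dict = {}
    for rs in run_seeds:
        _, run_log = pmm_single_run(cohort, config, int(rs))
        for key, value in run_log.chosen.items():
            votes.setdefault(key, Counter())[value] += 1

    df = cohort.df.copy()
    log = ImputationLog(votes={k: dict(c) for k, c in votes.items()})
    pid_to_row = {pid: i for i, pid in enumerate(df["patient_id"])}
    for (pid, col), counter in votes.items():
        top = max(counter.values())
        winners = [v for v, c in counter.items() if c == top]
        if len(winners) > 1:
            winners = _category_order(col, winners)
            log.notes.append(
                f"modal tie at ({pid}, {col}): {sorted(counter.items())} -> {winners[0]}"
            )
        choice = winners[0]
        df.iloc[pid_to_row[pid], df.columns.get_loc(col)] = choice
        log.chosen[(pid, col)] = choice
    return Cohort(df, {**cohort.provenance, "imputed": f"pmm mode of {config.n_runs} runs"}), log
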