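"""Attack evaluation: success rates, transferability, countermeasure.

An impersonator example succeeds when the identification model both
predicts the target user (top-1) and assigns it confidence at or above a
threshold (default 0.20 — far above random-guess confidence).  The
success rate (SR) of an attack is the percentage of attacked users whose
example succeeds.  This module also replays examples against other
classifier families trained on the same split (transferability), runs
the confidence-omission countermeasure (attacking a binary-decision
oracle), and compares generated profiles to ground-truth mean profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats as sps

from .features import N_HOURS
from .ga import AttackResult, GAConfig, attack_all_users
from .oracle import LabeledDataset, ModelSpec, make_oracle, train_model

__all__ = [
    "AttackReport",
    "ProfileComparison",
    "SuccessCriterion",
    "TransferReport",
    "compare_profile",
    "countermeasure_experiment",
    "estimate_active_period",
    "ground_truth_profile",
    "is_success",
    "success_rate",
    "summarize_attacks",
    "transferability",
]


@dataclass(frozen=True)
class SuccessCriterion:
    """Attack success rule: top-1 agreement plus a confidence floor."""

    threshold: float = 0.20
    require_top1: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.threshold <= 1:
            raise ValueError("threshold must lie in [0, 1]")

    def without_threshold(self) -> "SuccessCriterion":
        """The relaxed rule: top-1 agreement only (threshold 0)."""
        return replace(self, threshold=0.0)


def is_success(x_star: np.ndarray, t: str, model, criterion: SuccessCriterion) -> bool:
    """Does the model classify x* as user t with enough confidence?

    Judged on the model's true confidence scores regardless of the oracle
    mode the attack itself saw.
    """
    oracle = make_oracle(model)  # fresh wrapper; judging queries are free
    x_star = np.asarray(x_star, dtype=float).reshape(1, N_HOURS)
    conf = float(oracle.query(x_star, t))
    if criterion.require_top1 and oracle.label_query(x_star) != str(t):
        return False
    return conf >= criterion.threshold


def success_rate(flags) -> float:
    """Percentage of successes, rounded half-up to one decimal (52/55 -> 94.5)."""
    flags = list(flags)
    if not flags:
        raise ValueError("success rate of an empty set is undefined")
    pct = 100.0 * sum(bool(f) for f in flags) / len(flags)
    return math.floor(pct * 10 + 0.5) / 10


@dataclass
class AttackReport:
    """Aggregate outcome of one attack campaign over many target users."""

    preset: str
    successes: dict[str, bool]
    success_rate: float
    mean_generations: float
    mean_queries: float
    binary_mode: bool = False
    patience_enabled: bool = True

    def to_dict(self) -> dict:
        return {
            "preset": self.preset,
            "success_rate": self.success_rate,
            "n_users": len(self.successes),
            "n_successes": sum(self.successes.values()),
            "mean_generations": self.mean_generations,
            "mean_queries": self.mean_queries,
            "binary_mode": self.binary_mode,
            "patience_enabled": self.patience_enabled,
            "successes": self.successes,
        }


def summarize_attacks(
    results: list[AttackResult],
    model,
    criterion: SuccessCriterion,
    preset: str = "custom",
    binary_mode: bool = False,
    patience_enabled: bool = True,
) -> AttackReport:
    """Judge every result against the model and aggregate."""
    if not results:
        raise ValueError("no attack results to summarize")
    successes = {
        r.target_user: is_success(r.best_genome, r.target_user, model, criterion)
        for r in results
    }
    return AttackReport(
        preset=preset,
        successes=successes,
        success_rate=success_rate(successes.values()),
        mean_generations=float(np.mean([r.generations_run for r in results])),
        mean_queries=float(np.mean([r.query_count for r in results])),
        binary_mode=binary_mode,
        patience_enabled=patience_enabled,
    )


@dataclass
class TransferReport:
    """SR of replayed impersonator examples per transfer-model family."""

    rows: dict[str, dict[str, float]] = field(default_factory=dict)
    # rows[name] = {"with_threshold": SR, "no_threshold": SR}

    def to_dict(self) -> dict:
        return dict(self.rows)


def transferability(
    examples: list[tuple[np.ndarray, str]],
    specs: list[ModelSpec],
    train: LabeledDataset,
    criterion: SuccessCriterion = SuccessCriterion(),
    seed: int = 0,
) -> TransferReport:
    """Replay successful (x*, target) pairs against other model families.

    Every spec is trained on the same training split the original target
    model saw; each example is judged twice — with the full criterion and
    with the threshold dropped (top-1 agreement only).
    """
    if not examples:
        raise ValueError("no impersonator examples to transfer")
    report = TransferReport()
    relaxed = criterion.without_threshold()
    for spec in specs:
        model = train_model(spec, train, seed=seed)
        with_thr = [is_success(x, t, model, criterion) for x, t in examples]
        without = [is_success(x, t, model, relaxed) for x, t in examples]
        report.rows[spec.name] = {
            "with_threshold": success_rate(with_thr),
            "no_threshold": success_rate(without),
        }
        assert report.rows[spec.name]["with_threshold"] <= report.rows[spec.name]["no_threshold"]
    return report


def countermeasure_experiment(
    model,
    users: list[str],
    config: GAConfig,
    criterion: SuccessCriterion = SuccessCriterion(),
    disable_patience: bool = False,
) -> tuple[AttackReport, list[AttackResult]]:
    """Attack a confidence-omitting model (binary decisions only).

    The GA sees only 0/1 fitness from the binary oracle; final success is
    still judged on the underlying model's true confidence with the full
    criterion.  With patience disabled, runs go to max_generations (the
    flat fitness landscape otherwise stops them after ``patience``
    generations).
    """
    if disable_patience:
        config = replace(config, patience=config.max_generations)
    binary = make_oracle(model, mode="binary")
    results = attack_all_users(binary, users, config)
    report = summarize_attacks(
        results,
        model,
        criterion,
        preset=f"binary(pop={config.population_size})",
        binary_mode=True,
        patience_enabled=not disable_patience,
    )
    return report, results


def ground_truth_profile(train: LabeledDataset, t: str) -> np.ndarray:
    """The target user's mean training profile (per-feature mean)."""
    rows = train.X[train.y.astype(str) == str(t)]
    if len(rows) == 0:
        raise KeyError(f"unknown user {t!r}")
    return rows.mean(axis=0)


@dataclass
class ProfileComparison:
    """Impersonator vs ground-truth profile similarity for one target."""

    target_user: str
    impersonator: np.ndarray
    ground_truth: np.ndarray
    initial_random: np.ndarray
    correlation: float  # NaN when either profile is constant
    rms_difference: float

    def hourly_table(self) -> dict[str, list[float]]:
        """Hour-by-hour values for heatmap-style external plotting."""
        return {
            "hour": list(range(1, N_HOURS + 1)),
            "impersonator": self.impersonator.tolist(),
            "ground_truth": self.ground_truth.tolist(),
            "initial_random": self.initial_random.tolist(),
        }


def compare_profile(
    x_star: np.ndarray,
    ground_truth: np.ndarray,
    initial_random: np.ndarray,
    target_user: str = "",
) -> ProfileComparison:
    """Correlation and RMS difference between impersonator and ground truth."""
    x_star = np.asarray(x_star, dtype=float)
    ground_truth = np.asarray(ground_truth, dtype=float)
    if np.ptp(x_star) == 0 or np.ptp(ground_truth) == 0:
        corr = float("nan")
    else:
        corr = float(sps.pearsonr(x_star, ground_truth).statistic)
    return ProfileComparison(
        target_user=target_user,
        impersonator=x_star,
        ground_truth=ground_truth,
        initial_random=np.asarray(initial_random, dtype=float),
        correlation=corr,
        rms_difference=float(np.sqrt(np.mean((x_star - ground_truth) ** 2))),
    )


def estimate_active_period(
    profile: np.ndarray, activity_threshold: float
) -> tuple[int, int] | tuple[None, None]:
    """Guess wake/sleep hours from a 24-hour profile.

    Returns 1-based hour labels (h1..h24): the first hour of the longest
    contiguous above-threshold run (circular) and the hour after that run
    ends.  Hour label k covers clock time [k-1:00, k:00), so a wake label
    of 7 means activity started between 06:00 and 07:00.  An all-above or
    all-below profile has no transition: (None, None).
    """
    profile = np.asarray(profile, dtype=float)
    above = profile > activity_threshold
    if above.all() or not above.any():
        return None, None
    doubled = np.concatenate([above, above])
    best_start, best_len = 0, 0
    run_start, run_len = None, 0
    for i, flag in enumerate(doubled):
        if flag:
            if run_start is None:
                run_start, run_len = i, 0
            run_len += 1
            if run_start < N_HOURS and run_len > best_len:
                best_start, best_len = run_start, min(run_len, N_HOURS)
        else:
            run_start, run_len = None, 0
    wake = best_start % N_HOURS + 1
    sleep = (best_start + best_len) % N_HOURS + 1
    return wake, sleep
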