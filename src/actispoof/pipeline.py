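"""End-to-end orchestration: simulate -> extract -> train -> attack -> evaluate.

The workflow mirrors the attack study design: biometric profiles train a
target model and a zoo of transfer models on the same per-user split;
the GA attacks the target model's confidence oracle once per user; the
resulting impersonator examples are judged on the target model, replayed
against the transfer models, and the whole campaign is repeated against
a binary-decision (confidence-omitting) oracle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import evaluation, features, ga, oracle, simulate

__all__ = ["PipelineResult", "extract_features", "run_pipeline"]


@dataclass
class PipelineResult:
    """All artifacts of one full campaign."""

    seed: int
    identification: oracle.IdentificationReport | None
    attack_report: evaluation.AttackReport
    attack_results: list[ga.AttackResult]
    transfer_report: evaluation.TransferReport | None
    countermeasure_report: evaluation.AttackReport | None
    target_model: object
    train: oracle.LabeledDataset
    test: oracle.LabeledDataset
    query_count: int = 0
    comparisons: list[evaluation.ProfileComparison] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "identification": self.identification.to_dict() if self.identification else None,
            "attack": self.attack_report.to_dict(),
            "transfer": self.transfer_report.to_dict() if self.transfer_report else None,
            "countermeasure": (
                self.countermeasure_report.to_dict() if self.countermeasure_report else None
            ),
            "oracle_query_count": self.query_count,
            "per_user": [
                {
                    "target_user": r.target_user,
                    "best_fitness": r.best_fitness,
                    "generations_run": r.generations_run,
                    "query_count": r.query_count,
                }
                for r in self.attack_results
            ],
        }

    def write(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        out = directory / "report.json"
        out.write_text(json.dumps(self.to_dict(), indent=2))
        if self.comparisons:
            import csv

            with open(directory / "profiles.csv", "w", newline="") as fh:
                writer = csv.writer(fh)
                writer.writerow(
                    ["target_user", "series"] + [f"h{i}" for i in range(1, 25)]
                )
                for c in self.comparisons:
                    tab = c.hourly_table()
                    for name in ("impersonator", "ground_truth", "initial_random"):
                        writer.writerow([c.target_user, name] + tab[name])
        return out


def extract_features(
    recordings: list[features.UserRecording],
) -> features.FeatureMatrix:
    """Recordings -> pooled, normalized per-day feature matrix."""
    profiles: list[features.DailyProfile] = []
    for rec in recordings:
        profiles.extend(features.extract_daily_profiles(rec))
    return features.normalize(profiles)


def run_pipeline(
    cohort: simulate.CohortConfig | None = None,
    recordings: list[features.UserRecording] | None = None,
    preset: str = "strong",
    seed: int = 0,
    criterion: evaluation.SuccessCriterion | None = None,
    ga_config: ga.GAConfig | None = None,
    split_fraction: float = 0.5,
    with_identification: bool = True,
    with_transfer: bool = True,
    with_countermeasure: bool = True,
    disable_patience_countermeasure: bool = False,
) -> PipelineResult:
    """Run the full campaign on a synthetic cohort or supplied recordings.

    ``seed`` drives every stage: cohort generation (if no recordings are
    given), the train/test split, model fitting and the per-user GA
    seeds.
    """
    criterion = criterion or evaluation.SuccessCriterion()
    if recordings is None:
        cohort = cohort or simulate.CohortConfig(seed=seed)
        recordings, _ = simulate.generate_cohort(cohort)
    matrix = extract_features(recordings)
    dataset = oracle.LabeledDataset.from_feature_matrix(matrix)

    stage_seeds = np.random.SeedSequence(seed, spawn_key=(7,)).generate_state(4)
    train, test = oracle.split_per_user(
        dataset, split_fraction, seed=int(stage_seeds[0]) % 2**31
    )
    target_spec = oracle.ModelSpec("random_forest")
    model = oracle.train_model(target_spec, train, seed=int(stage_seeds[1]) % 2**31)

    identification = None
    if with_identification:
        identification = oracle.evaluate_identification(
            target_spec, dataset, iterations=10, fraction=split_fraction,
            seed=int(stage_seeds[2]) % 2**31,
        )

    config = ga_config or ga.preset_config(preset, seed=int(stage_seeds[3]) % 2**31)
    conf_oracle = oracle.make_oracle(model, mode="confidence")
    users = dataset.labels
    results = ga.attack_all_users(conf_oracle, users, config)
    report = evaluation.summarize_attacks(results, model, criterion, preset=preset)

    comparisons = []
    for r in results:
        gt = evaluation.ground_truth_profile(train, r.target_user)
        initial = np.random.default_rng(config.seed).random(config.dimension)
        comparisons.append(
            evaluation.compare_profile(r.best_genome, gt, initial, r.target_user)
        )

    transfer = None
    if with_transfer:
        successful = [
            (r.best_genome, r.target_user)
            for r in results
            if report.successes[r.target_user]
        ]
        if successful:
            transfer = evaluation.transferability(
                successful, list(oracle.TRANSFER_SPECS), train, criterion,
                seed=int(stage_seeds[1]) % 2**31,
            )

    countermeasure = None
    if with_countermeasure:
        countermeasure, _ = evaluation.countermeasure_experiment(
            model, users, config, criterion,
            disable_patience=disable_patience_countermeasure,
        )

    return PipelineResult(
        seed=seed,
        identification=identification,
        attack_report=report,
        attack_results=results,
        transfer_report=transfer,
        countermeasure_report=countermeasure,
        target_model=model,
        train=train,
        test=test,
        query_count=conf_oracle.query_count,
        comparisons=comparisons,
    )
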