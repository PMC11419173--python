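"""Canonical desk-scale study configurations.

These frozen settings define the package's reference experiment: a
60-patient paired-batch cohort with a morphology-borne prognostic signal
and a strong between-batch stain shift, evaluated with 2 folds of
15 test subjects.  The planted effect size is calibrated so that
same-batch slide-level AUC lands in the high-signal regime reported for
this kind of outcome-prediction task (AUC ~ 0.8-1.0), while the
within-batch slide-to-slide staining jitter and the between-batch shift
make the learned scorer's cross-batch transfer the quantity under test.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import synthetic
from .classifier import ScorerConfig
from .evaluate import ExperimentConfig, FoldPlan, build_manifest, make_fold_plan, run_experiment
from .synthetic import SyntheticSlideStore, default_profiles


@dataclass(frozen=True)
class StudyConditions:
    """The reference cross-batch study settings."""

    n_patients: int = 60
    met_fraction: float = 0.5
    effect_size: float = 0.25
    signal_channel: str = "morphology"
    shift_rotation_deg: float = 20.0  # strong between-batch hue shift
    shift_intensity_ratio: float = 0.5  # batch B renders much lighter
    noise_sd: float = 0.03
    slide_height: int = 768
    slide_width: int = 768
    tiles_per_slide: int = 20
    test_block_size: int = 15
    n_folds: int = 2
    epochs: int = 10
    learning_rate: float = 3e-3
    batch_size: int = 16


DEFAULT_CONDITIONS = StudyConditions()


def build_study(
    seed: int,
    conditions: StudyConditions = DEFAULT_CONDITIONS,
    identical_profiles: bool = False,
):
    """Cohort, slide store, manifest and fold plan for one study arm."""
    patients = synthetic.sample_cohort(
        conditions.n_patients,
        conditions.met_fraction,
        conditions.effect_size,
        seed=seed,
        signal_channel=conditions.signal_channel,
    )
    profile_a, profile_b = default_profiles(
        conditions.shift_rotation_deg,
        conditions.shift_intensity_ratio,
        conditions.noise_sd,
    )
    if identical_profiles:
        profile_b = profile_a
    store = SyntheticSlideStore(
        patients,
        profile_a,
        profile_b,
        conditions.slide_height,
        conditions.slide_width,
        seed=seed,
    )
    manifest = build_manifest(patients, seed=seed)
    plan = make_fold_plan(
        conditions.n_patients, conditions.test_block_size, conditions.n_folds
    )
    return patients, store, manifest, plan


def study_experiment_config(
    conditions: StudyConditions = DEFAULT_CONDITIONS,
    n_permutations: int = 999,
) -> ExperimentConfig:
    return ExperimentConfig(
        tiles_per_slide=conditions.tiles_per_slide,
        scorer=ScorerConfig(
            learning_rate=conditions.learning_rate,
            batch_size=conditions.batch_size,
            epochs=conditions.epochs,
        ),
        n_permutations=n_permutations,
        n_bootstrap=n_permutations,
    )


def run_confound_study(
    seed: int,
    conditions: StudyConditions = DEFAULT_CONDITIONS,
    identical_profiles: bool = False,
    normalization: str = "none",
) -> dict:
    """Train on batch A, test same- and cross-batch; return the report."""
    _, store, manifest, plan = build_study(seed, conditions, identical_profiles)
    config = study_experiment_config(conditions)
    _, report = run_experiment(
        manifest, store, "A", normalization, plan, config, seed=seed
    )
    return report
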