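"""Cross-batch generalization study harness.

Builds the contiguous-block fold plan (e.g. 154 subjects, 36-subject test
blocks counted down from the end: 119-154, 83-118, 47-82), trains the
tile scorer on one batch, scores held-out subjects' slides from the same
and the other staining batch, and summarizes AUC_same-batch versus
AUC_cross-batch per normalization mode with permutation and paired
bootstrap significance tests under Bonferroni correction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import classifier, gan, stains, tiling
from ._rng import child_seed, rng_from

log = logging.getLogger(__name__)

NORMALIZATION_MODES = ("none", "traditional", "generative")


# ---------------------------------------------------------------------------
# fold plan


@dataclass(frozen=True)
class FoldPlan:
    n_subjects: int
    folds: tuple  # of (test_indices, train_indices), 1-based numpy arrays


def make_fold_plan(n_subjects: int, test_block_size: int, n_folds: int) -> FoldPlan:
    """Contiguous test blocks counted down from subject ``n_subjects``.

    Fold k (k = 1..n_folds) tests the block ending at
    ``n_subjects - (k-1) * test_block_size``; training is the complement.
    """
    for name, v in (
        ("n_subjects", n_subjects),
        ("test_block_size", test_block_size),
        ("n_folds", n_folds),
    ):
        if not isinstance(v, (int, np.integer)) or v < 1:
            raise ValueError(f"{name} must be a positive integer")
    if n_folds * test_block_size > n_subjects:
        raise ValueError(
            f"{n_folds} folds x {test_block_size} test subjects exceed {n_subjects}"
        )
    all_idx = np.arange(1, n_subjects + 1)
    folds = []
    for k in range(1, n_folds + 1):
        end = n_subjects - (k - 1) * test_block_size
        test = np.arange(end - test_block_size + 1, end + 1)
        train = all_idx[~np.isin(all_idx, test)]
        folds.append((test, train))
    return FoldPlan(n_subjects=n_subjects, folds=tuple(folds))


# ---------------------------------------------------------------------------
# metrics and tests


def roc_auc(scores, labels) -> float:
    """Mann-Whitney AUC: P(score_pos > score_neg) + 0.5 P(tie)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)
    return float(
        (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    )


def roc_points(scores, labels) -> pd.DataFrame:
    """(FPR, TPR, threshold) points of the empirical ROC curve."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    order = np.argsort(-scores, kind="stable")
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    tp = np.concatenate([[0], np.cumsum(labels[order] == 1)])
    fp = np.concatenate([[0], np.cumsum(labels[order] == 0)])
    thr = np.concatenate([[np.inf], scores[order]])
    return pd.DataFrame({"fpr": fp / n_neg, "tpr": tp / n_pos, "threshold": thr})


def binarized_accuracy(scores, labels, threshold: float = 0.5) -> float:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if scores.size == 0:
        raise ValueError("inputs must be non-empty")
    return float(np.mean((scores >= threshold).astype(int) == labels))


def auc_null_test(scores, labels, n_permutations: int = 9999, seed: int = 0) -> float:
    """One-sided label-permutation test against a no-signal null.

    p = (1 + #{permuted AUC >= observed}) / (n_permutations + 1).
    """
    if n_permutations < 100:
        warnings.warn("fewer than 100 permutations gives a coarse p-value")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    observed = roc_auc(scores, labels)
    ranks = rankdata(scores)
    n_pos = int(np.sum(labels == 1))
    n_neg = labels.size - n_pos
    rng = rng_from(seed, "null-perm")
    perm = np.tile(labels == 1, (n_permutations, 1))
    perm = rng.permuted(perm, axis=1)
    rank_sums = perm @ ranks
    null_auc = (rank_sums - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    exceed = int(np.sum(null_auc >= observed - 1e-12))
    return (1 + exceed) / (n_permutations + 1)


def compare_auc_test(
    scores_x, scores_y, labels, n_bootstrap: int = 9999, seed: int = 0
) -> float:
    """One-sided paired bootstrap of AUC(x) > AUC(y) over shared subjects.

    Subjects are resampled with replacement; p is the add-one-corrected
    fraction of replicates with AUC(x) - AUC(y) <= 0.
    """
    scores_x = np.asarray(scores_x, dtype=float)
    scores_y = np.asarray(scores_y, dtype=float)
    labels = np.asarray(labels)
    if not (scores_x.shape == scores_y.shape == labels.shape):
        raise ValueError("paired inputs must have equal length")
    n = labels.size
    rng = rng_from(seed, "boot")
    count_le = 0
    done = 0
    while done < n_bootstrap:
        idx = rng.integers(n, size=n)
        lab = labels[idx]
        if lab.min() == lab.max():  # single-class resample: redraw
            continue
        delta = roc_auc(scores_x[idx], lab) - roc_auc(scores_y[idx], lab)
        if delta <= 0:
            count_le += 1
        done += 1
    return (1 + count_le) / (n_bootstrap + 1)


def bonferroni_alpha(alpha: float, m: int) -> float:
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if not isinstance(m, (int, np.integer)) or m < 1:
        raise ValueError("m must be a positive integer")
    return alpha / m


def cohort_accounting(
    n_enrolled: int, n_disqualified: int, n_met_pos: int, n_met_neg: int
) -> dict:
    """Consistency check of a study's patient accounting."""
    qualifying = n_enrolled - n_disqualified
    return {
        "n_enrolled": n_enrolled,
        "n_disqualified": n_disqualified,
        "n_qualifying": qualifying,
        "n_met_pos": n_met_pos,
        "n_met_neg": n_met_neg,
        "class_counts_consistent": n_met_pos + n_met_neg == qualifying,
    }


# ---------------------------------------------------------------------------
# manifest


def stratified_order(items, labels, rng) -> list:
    """Shuffle each class separately, then interleave proportionally
    (largest remainder), so contiguous blocks stay class-balanced."""
    labels = np.asarray(labels)
    pos = [it for it, lab in zip(items, labels) if lab == 1]
    neg = [it for it, lab in zip(items, labels) if lab == 0]
    rng.shuffle(pos)
    rng.shuffle(neg)
    n, n_pos = len(items), len(pos)
    ordered, taken_pos = [], 0
    for rank in range(1, n + 1):
        if taken_pos < round(rank * n_pos / n) and taken_pos < len(pos):
            ordered.append(pos[taken_pos])
            taken_pos += 1
        else:
            ordered.append(neg[rank - 1 - taken_pos])
    return ordered


def build_manifest(patients, seed: int = 0, stratify: bool = True) -> pd.DataFrame:
    """Randomize patients into indices 1..n, one row per (patient, batch).

    With ``stratify`` (default) the two outcome classes are shuffled
    separately and interleaved proportionally, so every contiguous test
    block carries both classes at close to the cohort prevalence — the
    balanced-fold layout such studies print.
    """
    rng = rng_from(seed, "manifest")
    if stratify:
        ordered = stratified_order(patients, [p.label for p in patients], rng)
    else:
        ordered = [patients[i] for i in rng.permutation(len(patients))]
    rows = []
    for rank, p in enumerate(ordered, start=1):
        for batch in ("A", "B"):
            rows.append(
                {
                    "patient_id": p.patient_id,
                    "randomized_index": rank,
                    "label": p.label,
                    "batch": batch,
                    "tissue_seed": p.tissue_seed,
                }
            )
    return pd.DataFrame(rows)


def validate_manifest(manifest: pd.DataFrame) -> None:
    dup = manifest.duplicated(subset=["patient_id", "batch"])
    if dup.any():
        raise ValueError("each (patient, batch) must appear exactly once")
    counts = manifest.groupby("patient_id")["batch"].nunique()
    missing = counts[counts < 2]
    if len(missing):
        raise ValueError(
            f"subject(s) missing a batch: {sorted(missing.index.tolist())}"
        )


# ---------------------------------------------------------------------------
# experiment


@dataclass
class ExperimentConfig:
    tiles_per_slide: int = 100  # training and scoring tiles per slide
    target_tiles_per_slide: int = 100  # stain-target estimation tiles
    scorer: classifier.ScorerConfig = field(default_factory=classifier.ScorerConfig)
    stain: stains.StainConfig = field(default_factory=stains.StainConfig)
    gan: gan.GanConfig = field(default_factory=gan.GanConfig)
    n_permutations: int = 9999
    n_bootstrap: int = 9999
    binarize_threshold: float = 0.5
    gan_per_slide: bool = True  # per-test-slide generative training
    normalize_training: bool = False


@dataclass
class EvalResult:
    fold_id: int
    train_batch: str
    normalization: str
    auc_same_batch: float
    auc_cross_batch: float
    accuracy_same: float
    accuracy_cross: float
    p_null_same: float
    p_null_cross: float
    p_compare_vs_original: float | None = None
    # held-out slide scores/labels backing the AUCs (JSON-safe lists)
    scores_same: list = field(default_factory=list)
    scores_cross: list = field(default_factory=list)
    labels_same: list = field(default_factory=list)
    labels_cross: list = field(default_factory=list)


def _slide_tiles(store, row, n_tiles, seed):
    slide = store.slide(int(row.patient_id), row.batch)
    mask = tiling.tissue_mask(slide)
    return tiling.sample_tiles(
        slide,
        mask,
        n_tiles,
        seed=child_seed(seed, "tiles", int(row.patient_id), row.batch),
        slide_id=f"p{int(row.patient_id)}{row.batch}",
        patient_id=int(row.patient_id),
        batch=row.batch,
        label=int(row.label),
    )


def _score_slides(scorer, slide_tiles):
    preds = [classifier.predict_slide(scorer, tiles) for tiles in slide_tiles]
    scores = np.array([p.slide_score for p in preds])
    labels = np.array([p.label for p in preds])
    return preds, scores, labels


def run_experiment(
    manifest: pd.DataFrame,
    slide_store,
    train_batch: str,
    normalization: str,
    fold_plan: FoldPlan,
    config: ExperimentConfig | None = None,
    seed: int = 0,
) -> tuple[list[EvalResult], dict]:
    """Train on one batch per fold; test same-batch and cross-batch.

    Training always sees original-color tiles; for ``traditional`` or
    ``generative`` normalization the *test* tiles are normalized toward
    the training set before scoring (the flow of the normalized study
    arms).  Returns per-fold results plus a report dict with 3-fold mean
    AUCs in a two-column (same/cross batch) layout.
    """
    if train_batch not in ("A", "B"):
        raise ValueError("train_batch must be 'A' or 'B'")
    if normalization not in NORMALIZATION_MODES:
        raise ValueError(f"normalization must be one of {NORMALIZATION_MODES}")
    config = config or ExperimentConfig()
    validate_manifest(manifest)
    cross_batch = "B" if train_batch == "A" else "A"

    results = []
    for fold_id, (test_idx, train_idx) in enumerate(fold_plan.folds, start=1):
        train_rows = manifest[
            manifest.randomized_index.isin(train_idx) & (manifest.batch == train_batch)
        ]
        test_rows_same = manifest[
            manifest.randomized_index.isin(test_idx) & (manifest.batch == train_batch)
        ]
        test_rows_cross = manifest[
            manifest.randomized_index.isin(test_idx) & (manifest.batch == cross_batch)
        ]
        if len(test_rows_cross) < len(test_rows_same):
            have = set(test_rows_cross.patient_id)
            missing = [
                int(p) for p in test_rows_same.patient_id if int(p) not in have
            ]
            raise ValueError(f"missing batch {cross_batch} for subject(s) {missing}")
        train_pids = set(train_rows.patient_id)
        test_pids = set(test_rows_same.patient_id) | set(test_rows_cross.patient_id)
        assert not (train_pids & test_pids), "train/test patient leakage"

        fold_seed = child_seed(seed, "fold", fold_id)
        train_tiles: list[tiling.Tile] = []
        train_slides = []
        for row in train_rows.itertuples():
            tiles = _slide_tiles(slide_store, row, config.tiles_per_slide, fold_seed)
            train_tiles.extend(tiles)
            train_slides.append(slide_store.slide(int(row.patient_id), row.batch))

        scorer_cfg = classifier.ScorerConfig(
            **{
                **config.scorer.__dict__,
                "seed": child_seed(fold_seed, "scorer"),
            }
        )
        scorer = classifier.train_scorer(train_tiles, scorer_cfg)

        target = None
        if normalization == "traditional":
            target = stains.fit_normalization_target(
                train_slides,
                tiles_per_slide=config.target_tiles_per_slide,
                seed=child_seed(fold_seed, "stain-target"),
                config=config.stain,
            )
        reference_tiles = train_tiles if normalization == "generative" else None

        def prepare(tiles, slide_tag):
            if normalization == "none":
                return tiles
            if normalization == "traditional":
                return [normed
                        for t in tiles
                        for normed in [stains.normalize_tile(t, target, config.stain)]]
            # generative: per-test-slide translation toward the training set
            g_cfg = gan.GanConfig(
                **{
                    **config.gan.__dict__,
                    "seed": child_seed(fold_seed, "gan", slide_tag),
                }
            )
            normalizer = gan.train_generative_normalizer(tiles, reference_tiles, g_cfg)
            return [gan.apply_generative_normalizer(normalizer, t) for t in tiles]

        def collect(rows):
            raw, prepared = [], []
            for row in rows.itertuples():
                tiles = _slide_tiles(slide_store, row, config.tiles_per_slide, fold_seed)
                raw.append(tiles)
                prepared.append(prepare(tiles, f"p{int(row.patient_id)}{row.batch}"))
            return raw, prepared

        raw_same, prep_same = collect(test_rows_same)
        raw_cross, prep_cross = collect(test_rows_cross)

        _, s_same, y_same = _score_slides(scorer, prep_same)
        _, s_cross, y_cross = _score_slides(scorer, prep_cross)

        p_compare = None
        if normalization != "none":
            _, s_same_raw, _ = _score_slides(scorer, raw_same)
            p_compare = compare_auc_test(
                s_same,
                s_same_raw,
                y_same,
                n_bootstrap=config.n_bootstrap,
                seed=child_seed(fold_seed, "compare"),
            )

        results.append(
            EvalResult(
                fold_id=fold_id,
                train_batch=train_batch,
                normalization=normalization,
                auc_same_batch=roc_auc(s_same, y_same),
                auc_cross_batch=roc_auc(s_cross, y_cross),
                accuracy_same=binarized_accuracy(
                    s_same, y_same, config.binarize_threshold
                ),
                accuracy_cross=binarized_accuracy(
                    s_cross, y_cross, config.binarize_threshold
                ),
                p_null_same=auc_null_test(
                    s_same, y_same, config.n_permutations, child_seed(fold_seed, "null-s")
                ),
                p_null_cross=auc_null_test(
                    s_cross, y_cross, config.n_permutations, child_seed(fold_seed, "null-c")
                ),
                p_compare_vs_original=p_compare,
                scores_same=[float(v) for v in s_same],
                scores_cross=[float(v) for v in s_cross],
                labels_same=[int(v) for v in y_same],
                labels_cross=[int(v) for v in y_cross],
            )
        )
        log.info(
            "fold %d (%s, train %s): AUC same %.3f cross %.3f",
            fold_id,
            normalization,
            train_batch,
            results[-1].auc_same_batch,
            results[-1].auc_cross_batch,
        )

    report = {
        "train_batch": train_batch,
        "normalization": normalization,
        "n_folds": len(fold_plan.folds),
        "folds": [r.__dict__ for r in results],
        "mean_auc_same_batch": float(np.mean([r.auc_same_batch for r in results])),
        "mean_auc_cross_batch": float(np.mean([r.auc_cross_batch for r in results])),
        "columns": {
            train_batch: float(np.mean([r.auc_same_batch for r in results])),
            cross_batch: float(np.mean([r.auc_cross_batch for r in results])),
        },
    }
    return results, report


def run_study(
    manifest: pd.DataFrame,
    slide_store,
    fold_plan: FoldPlan,
    train_batch: str = "A",
    modes=("none", "traditional", "generative"),
    config: ExperimentConfig | None = None,
    seed: int = 0,
) -> dict:
    """Run all normalization arms and assemble the two-column summary table

    (rows: normalization modes; columns: same-batch / cross-batch test
    sets; cells: 3-fold mean AUC), mirroring the usual results layout of
    this kind of batch-effect study.
    """
    table = {}
    all_results = {}
    for mode in modes:
        results, report = run_experiment(
            manifest, slide_store, train_batch, mode, fold_plan, config, seed
        )
        table[mode] = report["columns"]
        all_results[mode] = results
    return {
        "train_batch": train_batch,
        "table": table,
        "results": {
            mode: [r.__dict__ for r in results] for mode, results in all_results.items()
        },
    }


def render_report(report: dict) -> str:
    """Plain-text rendering of a study table."""
    train_batch = report["train_batch"]
    cross = "B" if train_batch == "A" else "A"
    lines = [
        f"Train on batch {train_batch}",
        f"{'Testing set':<22}{'Batch ' + train_batch:>10}{'Batch ' + cross:>10}",
    ]
    label = {
        "none": "Original H&E",
        "traditional": "Traditional method",
        "generative": "Generative method",
    }
    for mode, cells in report["table"].items():
        lines.append(
            f"{label.get(mode, mode):<22}{cells[train_batch]:>10.2f}{cells[cross]:>10.2f}"
        )
    return "\n".join(lines)
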