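"""The intersection clock: per-test-sample retrained elastic-net age prediction.

Bisulfite-sequencing datasets cover different CpG sites in every sample, so a
fixed-site clock loses most of its features on a new sample. The intersection
clock instead runs the whole training procedure once per test sample:

1. intersect the CpG sites of the training table with the sites covered in
   the test sample;
2. restrict the training table to the intersected sites;
3. partition the training samples into five near-equal folds (seeded); for
   each fold, fit an elastic-net regression of age on methylation percentages
   using the other four fifths, choosing the penalty strength lambda by inner
   10-fold cross-validation (minimum mean squared error along a standard
   lambda path, mixing parameter alpha = 0.5);
4. each of the five clocks predicts the test sample; the predicted age is
   their arithmetic mean.

Pooled held-out predictions (each training sample predicted exactly once, by
the clock not trained on its fold) give the per-test-sample cross-validation
performance: Pearson r and the median absolute error in years. A test sample
is admitted only if it shares at least ``min_intersection`` (default 10,000)
CpG sites with the training table; no imputation is ever performed.

Predictors are standardized before the penalized fit (coefficients are
reported back on the methylation-percent scale) and ages enter in years,
untransformed. Negative predicted ages are reported as-is.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps
from sklearn.linear_model import ElasticNetCV
from sklearn.model_selection import KFold

from .methylation_io import CpGCoordinate, FeatureTable, MethylationCallSet

logger = logging.getLogger("isectclock")


class ClockConfigError(ValueError):
    """Invalid configuration or incompatible inputs."""


class DegenerateTrainingError(ValueError):
    """Training target or design unusable (constant ages, too few samples)."""


@dataclass
class ClockConfig:
    """Tunable parameters of the intersection-clock workflow.

    alpha
        Elastic-net mixing parameter (1 = lasso, 0 = ridge); default 0.5.
    inner_splits
        Folds of the inner cross-validation that selects lambda; default 10.
    outer_folds
        Folds of the outer cross-validation producing the clock ensemble;
        default 5.
    min_intersection
        Minimum number of intersected CpG sites for a test sample to be
        admitted; default 10,000.
    rng_seed
        Seed for all randomness (fold partitions, inner CV shuffles).
    n_lambdas
        Number of penalty values on the lambda path; default 100.
    share_fold_partition
        If True, one outer fold partition (derived from rng_seed alone) is
        reused for every test sample instead of re-drawing a per-sample
        partition; the per-sample re-draw is the default.
    """

    alpha: float = 0.5
    inner_splits: int = 10
    outer_folds: int = 5
    min_intersection: int = 10_000
    rng_seed: int = 0
    n_lambdas: int = 100
    max_iter: int = 1000
    share_fold_partition: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ClockConfigError("alpha must be in [0, 1]")
        if self.outer_folds < 2:
            raise ClockConfigError("outer_folds must be >= 2")
        if self.inner_splits < 2:
            raise ClockConfigError("inner_splits must be >= 2")
        if self.min_intersection < 1:
            raise ClockConfigError("min_intersection must be >= 1")


@dataclass
class ClockModel:
    """One trained penalized linear clock (one outer fold).

    ``coef`` is aligned with ``sites`` and expressed in years per
    methylation-percent; the predicted age of a sample with percent vector x
    is ``intercept + coef @ x``.
    """

    intercept: float
    coef: np.ndarray
    sites: pd.MultiIndex
    lambda_: float
    alpha: float
    fold_id: int

    @property
    def weights(self) -> dict[CpGCoordinate, float]:
        """Mapping site -> coefficient, restricted to nonzero coefficients."""
        nz = np.nonzero(self.coef)[0]
        return {
            CpGCoordinate(self.sites[i][0], int(self.sites[i][1])): float(self.coef[i])
            for i in nz
        }

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.coef))

    def predict_vector(self, x: np.ndarray) -> float:
        return float(self.intercept + self.coef @ np.asarray(x, dtype=float))


@dataclass
class IntersectionResult:
    """CpG sites common to the training table and one test sample."""

    test_sample_id: str
    sites: pd.MultiIndex
    n_sites: int

    def site_list(self) -> list[CpGCoordinate]:
        return [CpGCoordinate(c, int(p)) for c, p in self.sites]


@dataclass
class PredictionResult:
    """Outcome of the intersection-clock workflow for one test sample."""

    test_sample_id: str
    n_intersected_sites: int
    admitted: bool
    fold_predictions: Optional[list[float]] = None
    predicted_age: float = float("nan")
    cv_r: float = float("nan")
    cv_medae: float = float("nan")
    models: Optional[list[ClockModel]] = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# Workflow steps
# ---------------------------------------------------------------------------

def intersect_sites(training: FeatureTable, test: MethylationCallSet) -> IntersectionResult:
    """Sorted intersection of training-table sites with the test sample's sites."""
    if training.n_sites == 0:
        raise ClockConfigError("training table has no sites")
    if training.assembly != test.assembly:
        raise ClockConfigError(
            f"assembly mismatch: training on {training.assembly!r}, "
            f"test sample {test.sample_id!r} on {test.assembly!r}"
        )
    common = training.sites.intersection(test.coordinates).sort_values()
    return IntersectionResult(test_sample_id=test.sample_id, sites=common, n_sites=len(common))


def restrict(training: FeatureTable, sites) -> FeatureTable:
    """Training table limited to ``sites`` (must all be present), order preserved."""
    if not isinstance(sites, pd.MultiIndex):
        sites = pd.MultiIndex.from_tuples(list(sites), names=["chrom", "pos"])
    indexer = training.sites.get_indexer(sites)
    if (indexer < 0).any():
        missing = sites[indexer < 0][0]
        raise ClockConfigError(f"site {missing} not present in training table")
    return FeatureTable(
        sample_ids=list(training.sample_ids),
        ages=training.ages.copy(),
        sites=sites,
        values=training.values[:, indexer],
        group_labels=list(training.group_labels) if training.group_labels else None,
        assembly=training.assembly,
    )


def _check_trainable(ages: np.ndarray, config: ClockConfig) -> None:
    if np.ptp(ages) == 0:
        raise DegenerateTrainingError("all training ages identical; clock target is degenerate")


def train_one_clock(
    restricted_training: FeatureTable,
    config: ClockConfig,
    fold_assignment: np.ndarray,
    fold_id: int,
    inner_seed: int | None = None,
) -> tuple[ClockModel, np.ndarray, np.ndarray]:
    """Fit the clock for one outer fold.

    Trains on the samples whose ``fold_assignment`` differs from ``fold_id``
    (four fifths under the default fivefold partition), selecting lambda by
    inner ``config.inner_splits``-fold cross-validation, and predicts the
    held-out fold. Returns (model, holdout_predictions, holdout_row_indices).
    """
    fold_assignment = np.asarray(fold_assignment)
    train_mask = fold_assignment != fold_id
    hold_mask = ~train_mask
    if hold_mask.sum() == 0:
        raise ClockConfigError(f"fold {fold_id} holds out no samples")
    X = restricted_training.values
    y = restricted_training.ages
    _check_trainable(y[train_mask], config)
    n_train = int(train_mask.sum())
    if n_train < config.inner_splits + 1:
        raise DegenerateTrainingError(
            f"{n_train} training samples cannot support {config.inner_splits}-fold inner CV"
        )
    if inner_seed is None:
        inner_seed = int(
            np.random.SeedSequence([config.rng_seed, 7919, fold_id]).generate_state(1)[0] % 2**31
        )
    Xt = X[train_mask]
    mean = Xt.mean(axis=0)
    sd = Xt.std(axis=0)
    scale = np.where(sd > 0, sd, 1.0)  # constant columns stay at zero after centering
    Xs = (Xt - mean) / scale
    inner_cv = KFold(n_splits=config.inner_splits, shuffle=True, random_state=inner_seed)
    enet = ElasticNetCV(
        l1_ratio=config.alpha,
        alphas=config.n_lambdas,
        cv=inner_cv,
        max_iter=config.max_iter,
        random_state=0,
    )
    enet.fit(Xs, y[train_mask])
    coef = enet.coef_ / scale
    intercept = float(enet.intercept_ - np.dot(enet.coef_, mean / scale))
    model = ClockModel(
        intercept=intercept,
        coef=coef,
        sites=restricted_training.sites,
        lambda_=float(enet.alpha_),
        alpha=config.alpha,
        fold_id=fold_id,
    )
    holdout_idx = np.nonzero(hold_mask)[0]
    holdout_pred = X[holdout_idx] @ coef + intercept
    return model, holdout_pred, holdout_idx


def _sample_seed_sequence(config: ClockConfig, sample_id: str) -> np.random.SeedSequence:
    if config.share_fold_partition:
        return np.random.SeedSequence([config.rng_seed, 104729])
    # crc32 of the sample id keeps the stream independent of cohort order
    return np.random.SeedSequence([config.rng_seed, zlib.crc32(sample_id.encode("utf-8"))])


def _fold_partition(n: int, outer_folds: int, ss: np.random.SeedSequence) -> np.ndarray:
    """Random partition of n samples into near-equal folds labelled 1..outer_folds."""
    rng = np.random.default_rng(ss)
    order = rng.permutation(n)
    assignment = np.empty(n, dtype=int)
    for f, chunk in enumerate(np.array_split(order, outer_folds), start=1):
        assignment[chunk] = f
    return assignment


def predict_sample(
    training: FeatureTable,
    test: MethylationCallSet,
    config: ClockConfig,
    keep_models: bool = False,
    _clock_cache: dict | None = None,
) -> PredictionResult:
    """Run the complete intersection-clock workflow for one test sample."""
    inter = intersect_sites(training, test)
    if inter.n_sites < config.min_intersection:
        logger.info(
            "sample %s: %d intersected sites < %d — not admitted",
            test.sample_id, inter.n_sites, config.min_intersection,
        )
        return PredictionResult(
            test_sample_id=test.sample_id,
            n_intersected_sites=inter.n_sites,
            admitted=False,
        )
    _check_trainable(training.ages, config)

    cache_key = None
    cached = None
    if _clock_cache is not None and config.share_fold_partition:
        cache_key = tuple(map(tuple, inter.sites))
        cached = _clock_cache.get(cache_key)

    if cached is None:
        restricted = restrict(training, inter.sites)
        # canonical row order: folds depend on sample ids, never on row order
        canon = np.argsort(np.asarray(restricted.sample_ids, dtype=object), kind="stable")
        restricted = FeatureTable(
            sample_ids=[restricted.sample_ids[i] for i in canon],
            ages=restricted.ages[canon],
            sites=restricted.sites,
            values=restricted.values[canon],
            group_labels=(
                [restricted.group_labels[i] for i in canon] if restricted.group_labels else None
            ),
            assembly=restricted.assembly,
        )
        ss = _sample_seed_sequence(config, test.sample_id)
        part_ss, inner_ss = ss.spawn(2)
        fold_assignment = _fold_partition(restricted.n_samples, config.outer_folds, part_ss)
        inner_seeds = inner_ss.generate_state(config.outer_folds) % 2**31

        models: list[ClockModel] = []
        oof = np.full(restricted.n_samples, np.nan)
        for fold_id in range(1, config.outer_folds + 1):
            model, hold_pred, hold_idx = train_one_clock(
                restricted, config, fold_assignment, fold_id,
                inner_seed=int(inner_seeds[fold_id - 1]),
            )
            models.append(model)
            oof[hold_idx] = hold_pred
        cv_r = float(_sps.pearsonr(restricted.ages, oof)[0])
        cv_medae = float(np.median(np.abs(oof - restricted.ages)))
        if cache_key is not None:
            _clock_cache[cache_key] = (models, cv_r, cv_medae)
    else:
        models, cv_r, cv_medae = cached

    x_test = _test_vector(test, inter.sites)
    fold_predictions = [m.predict_vector(x_test) for m in models]
    predicted_age = float(np.mean(fold_predictions))
    logger.info(
        "sample %s: %d intersected sites, admitted; predicted age %.2f y (cv_r=%.3f, MedAE=%.2f y)",
        test.sample_id, inter.n_sites, predicted_age, cv_r, cv_medae,
    )
    return PredictionResult(
        test_sample_id=test.sample_id,
        n_intersected_sites=inter.n_sites,
        admitted=True,
        fold_predictions=fold_predictions,
        predicted_age=predicted_age,
        cv_r=cv_r,
        cv_medae=cv_medae,
        models=models if keep_models else None,
    )


def _test_vector(test: MethylationCallSet, sites: pd.MultiIndex) -> np.ndarray:
    sub = test.data.loc[sites]
    cov = (sub["meth"] + sub["unmeth"]).to_numpy(float)
    if (cov <= 0).any():
        raise ClockConfigError(
            f"zero-coverage intersected site in test sample {test.sample_id}; "
            "apply the coverage filter first"
        )
    return 100.0 * sub["meth"].to_numpy(float) / cov


def predict_cohort(
    training: FeatureTable,
    tests: Sequence[MethylationCallSet],
    config: ClockConfig,
    keep_models: bool = False,
) -> list[PredictionResult]:
    """Run :func:`predict_sample` independently for every test sample.

    Results follow the input order. When ``config.share_fold_partition`` is
    set, clocks are cached across test samples with identical intersections
    (the partition is then sample-independent, so the five fits coincide).
    """
    cache: dict = {}
    results = []
    for test in tests:
        try:
            results.append(
                predict_sample(training, test, config, keep_models=keep_models,
                               _clock_cache=cache)
            )
        except Exception as exc:
            raise type(exc)(f"sample {test.sample_id!r}: {exc}") from exc
    return results


def write_predictions_tsv(
    results: Sequence[PredictionResult],
    path,
    labels: Mapping[str, str] | None = None,
    outer_folds: int = 5,
) -> None:
    """One row per test sample: id, group, intersection size, admission, fold
    predictions, ensemble prediction, and training-CV performance."""
    rows = []
    for r in results:
        row = {
            "sample_id": r.test_sample_id,
            "group": labels.get(r.test_sample_id, "") if labels else "",
            "n_intersected_sites": r.n_intersected_sites,
            "admitted": r.admitted,
        }
        preds = r.fold_predictions or []
        for i in range(outer_folds):
            row[f"fold_pred_{i + 1}"] = preds[i] if i < len(preds) else np.nan
        row["predicted_age"] = r.predicted_age
        row["cv_r"] = r.cv_r
        row["cv_medae"] = r.cv_medae
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.17g")
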