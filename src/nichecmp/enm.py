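"""Presence-only suitability models, TSS evaluation, and ensemble consensus.

Two presence-only algorithms are built in:

* **envelope score** — a quantitative BIOCLIM: a site scores the fraction of
  environmental layers whose value falls inside the training presences'
  (percentile-trimmed) range envelope;
* **Mahalanobis distance** — covariance-scaled distance to the training
  centroid, mapped to [0, 1] through the chi-square(k) survival function
  (k = number of layers), which is monotone decreasing in distance and equals
  1 at the centroid.

Replicate design: occurrences are split into random train/test subsets
(default ten 70%/30% splits); each fitted replicate is binarized at the ROC
threshold balancing omission and commission errors (|sensitivity −
specificity| minimized over candidate thresholds) against 1:1 pseudo-absences,
and scored with the True Skill Statistic TSS = sensitivity + specificity − 1.
Replicates with TSS above an acceptance cutoff (default 0.4) are averaged
into a per-cell consensus fraction.

External algorithms (e.g. maximum-entropy or rule-set learners run in outside
software) attach through the :class:`SdmAlgorithm` protocol and flow through
the same thresholding/TSS/consensus machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, runtime_checkable

import numpy as np
from scipy import stats

from .errors import (
    ArgumentError,
    DegenerateInputError,
    EmptyConsensusError,
    SamplingError,
    SchemaError,
    UndefinedStatisticError,
)
from .grids import EnvGrid, OccurrenceSet

__all__ = [
    "SuitabilityMap",
    "EvaluationSplit",
    "ConsensusMap",
    "SdmAlgorithm",
    "EnvelopeModel",
    "MahalanobisModel",
    "fit_envelope",
    "predict_envelope",
    "fit_mahalanobis",
    "predict_mahalanobis",
    "split_data",
    "sample_pseudo_absences",
    "roc_threshold",
    "tss",
    "tss_from_confusion",
    "run_ensemble",
    "consensus",
    "cross_prediction",
    "reciprocal_projection",
    "ALGORITHMS",
]


@dataclass
class SuitabilityMap:
    """Per-cell suitability in [0, 1] plus the parameters that produced it."""

    values: np.ndarray  # (n_rows, n_cols), nan on nodata
    algorithm: str
    params: dict

    def scores_at(self, cell_ids: np.ndarray) -> np.ndarray:
        return self.values.ravel()[np.asarray(cell_ids, dtype=int)]


@dataclass
class EvaluationSplit:
    """One replicate's bookkeeping: partition, threshold, and skill."""

    index: int
    algorithm: str
    train_cells: np.ndarray
    test_cells: np.ndarray
    pseudo_absence_cells: np.ndarray
    threshold: float
    sensitivity: float
    specificity: float
    tss: float


@dataclass
class ConsensusMap:
    """Per-cell fraction of accepted binary replicates predicting presence."""

    fraction: np.ndarray
    n_accepted: int
    cutoff: float


# -- algorithms ---------------------------------------------------------------


@dataclass
class EnvelopeModel:
    layer_names: list[str]
    lower: np.ndarray
    upper: np.ndarray
    percentile: float


def fit_envelope(train_env: np.ndarray, percentile: float = 0.0,
                 layer_names: list[str] | None = None) -> EnvelopeModel:
    """Per-layer [lower, upper] envelope at the symmetric training percentile.

    ``percentile = 0`` gives the min–max envelope; ``percentile = 0.25``
    trims to the central 50% of training values per layer.
    """
    X = np.asarray(train_env, dtype=float).reshape(len(train_env), -1)
    if X.shape[0] < 2:
        raise DegenerateInputError("envelope needs at least 2 training presences")
    if not 0.0 <= percentile < 0.5:
        raise ArgumentError("percentile must be in [0, 0.5)")
    names = layer_names or [f"layer{i + 1}" for i in range(X.shape[1])]
    return EnvelopeModel(
        layer_names=list(names),
        lower=np.quantile(X, percentile, axis=0),
        upper=np.quantile(X, 1.0 - percentile, axis=0),
        percentile=percentile,
    )


def predict_envelope(model: EnvelopeModel, grid: EnvGrid) -> SuitabilityMap:
    """Suitability = fraction of layers inside the envelope (values in {0, 1/k, ..., 1})."""
    if len(model.lower) != grid.n_layers:
        raise SchemaError("envelope bounds do not cover the grid layers")
    v = grid.values
    inside = (v >= model.lower[:, None, None]) & (v <= model.upper[:, None, None])
    suit = inside.mean(axis=0).astype(float)
    suit[grid.nodata_mask] = np.nan
    return SuitabilityMap(
        values=suit,
        algorithm="envelope",
        params={
            "lower": model.lower.tolist(),
            "upper": model.upper.tolist(),
            "percentile": model.percentile,
        },
    )


@dataclass
class MahalanobisModel:
    layer_names: list[str]
    centroid: np.ndarray
    covariance: np.ndarray
    regularized: bool


def fit_mahalanobis(train_env: np.ndarray, ridge: float = 1e-6,
                    layer_names: list[str] | None = None) -> MahalanobisModel:
    """Training centroid and sample covariance, ridge-regularized if needed.

    When there are no more presences than layers (or the covariance is
    otherwise singular) a ridge ``ridge × mean(diag) × I`` is added and the
    fallback flagged in the model record. A constant layer leaves nothing to
    regularize toward and is a degenerate input.
    """
    X = np.asarray(train_env, dtype=float).reshape(len(train_env), -1)
    n, k = X.shape
    if n < 2:
        raise DegenerateInputError("Mahalanobis fit needs at least 2 presences")
    if np.any(X.std(axis=0) == 0):
        raise DegenerateInputError("constant layer in training data; covariance is degenerate")
    centroid = X.mean(axis=0)
    cov = np.cov(X.T, ddof=1).reshape(k, k)
    regularized = False
    if n <= k or np.linalg.matrix_rank(cov) < k:
        cov = cov + ridge * np.trace(cov) / k * np.eye(k)
        regularized = True
        if np.linalg.matrix_rank(cov) < k:
            raise DegenerateInputError("covariance irrecoverably singular after regularization")
    names = layer_names or [f"layer{i + 1}" for i in range(k)]
    return MahalanobisModel(
        layer_names=list(names), centroid=centroid, covariance=cov, regularized=regularized
    )


def predict_mahalanobis(model: MahalanobisModel, grid: EnvGrid) -> SuitabilityMap:
    """Suitability = chi-square(k) survival function of the squared distance."""
    if model.centroid.size != grid.n_layers:
        raise SchemaError("Mahalanobis parameters do not cover the grid layers")
    flat = grid.values.reshape(grid.n_layers, -1).T - model.centroid
    d2 = np.einsum("ij,ij->i", flat, np.linalg.solve(model.covariance, flat.T).T)
    suit = stats.chi2.sf(d2, df=grid.n_layers).reshape(grid.shape)
    suit[grid.nodata_mask] = np.nan
    return SuitabilityMap(
        values=suit,
        algorithm="mahalanobis",
        params={
            "centroid": model.centroid.tolist(),
            "covariance": model.covariance.tolist(),
            "regularized": model.regularized,
        },
    )


@runtime_checkable
class SdmAlgorithm(Protocol):
    """Plug-in contract: fit on training environments, predict a suitability map.

    External algorithms (wrappers around outside software) implement this
    protocol and register under :data:`ALGORITHMS`; the ensemble handles
    thresholding, TSS and consensus uniformly.
    """

    name: str

    def fit(self, train_env: np.ndarray, layer_names: list[str]) -> object: ...

    def predict(self, model: object, grid: EnvGrid) -> SuitabilityMap: ...


class _Envelope:
    name = "envelope"

    def __init__(self, percentile: float = 0.0):
        self.percentile = percentile

    def fit(self, train_env, layer_names):
        return fit_envelope(train_env, self.percentile, layer_names)

    def predict(self, model, grid):
        return predict_envelope(model, grid)


class _Mahalanobis:
    name = "mahalanobis"

    def fit(self, train_env, layer_names):
        return fit_mahalanobis(train_env, layer_names=layer_names)

    def predict(self, model, grid):
        return predict_mahalanobis(model, grid)


ALGORITHMS: dict[str, SdmAlgorithm] = {
    "envelope": _Envelope(),
    "mahalanobis": _Mahalanobis(),
}


# -- evaluation ---------------------------------------------------------------


def split_data(
    occ: OccurrenceSet, train_fraction: float = 0.7, n_splits: int = 10,
    seed: int | None = None,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Random train/test partitions of the occurrence cells."""
    n = len(occ)
    if n < 10:
        raise ArgumentError("need at least 10 occurrence cells to split")
    if not 0.0 < train_fraction < 1.0:
        raise ArgumentError("train_fraction must be in (0, 1)")
    if n_splits < 1:
        raise ArgumentError("n_splits must be >= 1")
    n_train = int(round(train_fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    rng = np.random.default_rng(seed)
    splits = []
    for _ in range(n_splits):
        perm = rng.permutation(occ.cell_ids)
        splits.append((perm[:n_train], perm[n_train:]))
    return splits


def sample_pseudo_absences(
    grid: EnvGrid, background_mask: np.ndarray, exclude: np.ndarray,
    n: int, seed: int | None = None,
) -> np.ndarray:
    """Draw n distinct background cells outside the exclusion set."""
    eligible = np.asarray(background_mask, bool) & ~grid.nodata_mask
    ids = np.flatnonzero(eligible.ravel())
    ids = np.setdiff1d(ids, np.asarray(exclude, dtype=int))
    if ids.size < n:
        raise SamplingError(f"only {ids.size} eligible background cells; need {n}")
    rng = np.random.default_rng(seed)
    return rng.choice(ids, size=n, replace=False)


def roc_threshold(presence_scores: np.ndarray, absence_scores: np.ndarray) -> float:
    """Threshold balancing omission and commission errors.

    Candidates are the observed scores; the winner minimizes
    |sensitivity − specificity|, ties broken by larger sensitivity +
    specificity, then by the smallest threshold. A cell is predicted present
    iff its score >= threshold.
    """
    pres = np.asarray(presence_scores, dtype=float)
    absn = np.asarray(absence_scores, dtype=float)
    if pres.size == 0 or absn.size == 0:
        raise ArgumentError("both score sets must be non-empty")
    cands = np.unique(np.concatenate([pres, absn]))
    sens = (pres[None, :] >= cands[:, None]).mean(axis=1)
    spec = (absn[None, :] < cands[:, None]).mean(axis=1)
    gap = np.abs(sens - spec)
    best = np.flatnonzero(gap == gap.min())
    total = sens[best] + spec[best]
    best = best[total == total.max()]
    return float(cands[best.min()])


def tss(sensitivity: float, specificity: float) -> float:
    """True Skill Statistic = sensitivity + specificity − 1, in [−1, 1]."""
    return float(sensitivity + specificity - 1.0)


def tss_from_confusion(tp: int, fn: int, tn: int, fp: int) -> float:
    """TSS from a confusion table; both margins must be non-empty."""
    if min(tp, fn, tn, fp) < 0:
        raise ArgumentError("confusion counts must be non-negative")
    if tp + fn == 0 or tn + fp == 0:
        raise UndefinedStatisticError("a confusion-table margin is empty")
    return tss(tp / (tp + fn), tn / (tn + fp))


def run_ensemble(
    occ: OccurrenceSet,
    grid: EnvGrid,
    background_mask: np.ndarray,
    algorithms: tuple[str, ...] | dict[str, SdmAlgorithm] = ("envelope", "mahalanobis"),
    n_splits: int = 10,
    train_fraction: float = 0.7,
    seed: int | None = None,
) -> tuple[list[np.ndarray], list[EvaluationSplit]]:
    """Fit algorithm × split replicates; binarize and score each one.

    For every split, each algorithm is fitted on the training presences'
    environments (typically PCA component layers), scores the whole grid,
    and is thresholded by :func:`roc_threshold` on the held-out test
    presences versus freshly drawn 1:1 pseudo-absences. Returns the binary
    maps and their evaluations (``len = n_algorithms × n_splits``).
    """
    if isinstance(algorithms, dict):
        algos = algorithms
    else:
        try:
            algos = {name: ALGORITHMS[name] for name in algorithms}
        except KeyError as e:
            raise ArgumentError(f"unknown algorithm {e.args[0]!r}") from None
    ss = np.random.SeedSequence(seed)
    split_seed, pa_seed = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2)]
    splits = split_data(occ, train_fraction, n_splits, seed=split_seed)
    pa_rng = np.random.default_rng(pa_seed)

    maps: list[np.ndarray] = []
    evals: list[EvaluationSplit] = []
    for idx, (train, test) in enumerate(splits):
        pa = sample_pseudo_absences(
            grid, background_mask, exclude=occ.cell_ids, n=test.size,
            seed=int(pa_rng.integers(2**31)),
        )
        train_env = grid.env_at(train)
        for name, algo in algos.items():
            model = algo.fit(train_env, list(grid.layer_names))
            suit = algo.predict(model, grid)
            thr = roc_threshold(suit.scores_at(test), suit.scores_at(pa))
            binary = np.where(np.isnan(suit.values), False, suit.values >= thr)
            sens = float(np.mean(suit.scores_at(test) >= thr))
            spec = float(np.mean(suit.scores_at(pa) < thr))
            maps.append(binary)
            evals.append(
                EvaluationSplit(
                    index=idx, algorithm=name, train_cells=train, test_cells=test,
                    pseudo_absence_cells=pa, threshold=thr,
                    sensitivity=sens, specificity=spec, tss=tss(sens, spec),
                )
            )
    return maps, evals


def consensus(
    binary_maps: list[np.ndarray], tss_values: list[float], cutoff: float = 0.4
) -> ConsensusMap:
    """Average the binary replicates whose TSS exceeds the cutoff."""
    if len(binary_maps) == 0:
        raise ArgumentError("need at least one map")
    if len(binary_maps) != len(tss_values):
        raise ArgumentError("one TSS value per map required")
    accepted = [m for m, t in zip(binary_maps, tss_values) if t > cutoff]
    if not accepted:
        raise EmptyConsensusError(
            f"no replicate map exceeded the TSS cutoff {cutoff}; "
            "inspect the evaluations before lowering it"
        )
    fraction = np.mean([m.astype(float) for m in accepted], axis=0)
    return ConsensusMap(fraction=fraction, n_accepted=len(accepted), cutoff=cutoff)


def cross_prediction(consensus_map: ConsensusMap, occ: OccurrenceSet,
                     presence_cut: float = 0.5) -> float:
    """Fraction of a species' occurrence cells inside consensus presence."""
    return float(np.mean(consensus_map.fraction.ravel()[occ.cell_ids] >= presence_cut))


def reciprocal_projection(
    occ_fit: OccurrenceSet,
    occ_eval: OccurrenceSet,
    grid: EnvGrid,
    background_fit: np.ndarray,
    tss_cutoff: float = 0.4,
    presence_cut: float = 0.5,
    seed: int | None = None,
    **ensemble_kwargs,
) -> float:
    """Fit an ensemble on one species, score how well it predicts the other.

    The consensus is built from the ensemble fitted on ``occ_fit`` over its
    own background and projected across the whole grid; the return value is
    the fraction of ``occ_eval`` cells falling in consensus presence
    (consensus fraction >= ``presence_cut``). Under a conserved niche this
    fraction is high; after niche divergence it collapses.
    """
    maps, evals = run_ensemble(occ_fit, grid, background_fit, seed=seed, **ensemble_kwargs)
    cons = consensus(maps, [e.tss for e in evals], cutoff=tss_cutoff)
    return cross_prediction(cons, occ_eval, presence_cut)
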