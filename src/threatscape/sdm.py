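"""Ensemble species distribution modelling from presence-only records.

The model follows the classic presence / pseudo-absence ensemble recipe:

* three pseudo-absence sets, each a random one-third of the eligible
  background cells;
* for every (learner, pseudo-absence set, replicate) triple, a model is fit
  on a stratified 70/30 split with class weights balancing total presence
  and absence weight, and evaluated on the held-out 30% with rank-based AUC
  and the true skill statistic (TSS = sensitivity + specificity - 1) at the
  TSS-maximising threshold;
* variable importance is a permutation measure: one minus the Pearson
  correlation between predictions on the original and on the
  variable-shuffled data, averaged over permutations;
* runs with AUC >= 0.7 enter an unweighted per-cell mean ensemble, which is
  binarized at the 10th percentile of ensemble suitability at the training
  presences.

:class:`EnsembleSDM` is the model object (data + configuration);
:meth:`EnsembleSDM.fit` returns an :class:`EnsembleSDMResult` carrying the
per-run table, the ensemble map and its evaluation, and ``summary()``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .grid import GridSpec, RasterLayer
from .occurrences import OccurrenceSet

logger = logging.getLogger(__name__)

__all__ = [
    "PseudoAbsenceSet",
    "LearnerAdapter",
    "ModelRun",
    "EnsemblePrediction",
    "BinarySuitabilityMap",
    "EnsembleSDM",
    "EnsembleSDMResult",
    "draw_pseudo_absences",
    "auc",
    "tss",
    "best_tss_threshold",
    "permutation_importance",
    "fit_all",
    "build_ensemble",
    "binarize_p10",
    "default_learners",
]


# ---------------------------------------------------------------------------
# evaluation metrics
# ---------------------------------------------------------------------------


def auc(scores_pos: Sequence[float], scores_neg: Sequence[float]) -> float:
    """Rank-based ROC AUC: P(pos > neg) + 0.5 P(tie) (Mann-Whitney form)."""
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("auc requires at least one score in each class")
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def tss(sensitivity: float, specificity: float) -> float:
    """True skill statistic: sensitivity + specificity - 1, in [-1, 1]."""
    if not (0.0 <= sensitivity <= 1.0 and 0.0 <= specificity <= 1.0):
        raise ValueError("sensitivity and specificity must lie in [0, 1]")
    return sensitivity + specificity - 1.0


def best_tss_threshold(scores_pos: Sequence[float], scores_neg: Sequence[float]) -> tuple[float, float]:
    """Threshold (predict positive iff score >= t) maximising TSS.

    Candidates are the midpoints of consecutive sorted unique scores; ties
    resolve to the lowest threshold.  With a single unique score the rule
    degenerates to all-positive and TSS is 0.
    """
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be nonempty")
    uniq = np.unique(np.concatenate([pos, neg]))
    if uniq.size == 1:
        return float(uniq[0]), 0.0
    cands = (uniq[:-1] + uniq[1:]) / 2.0
    sens = (pos[:, None] >= cands[None, :]).mean(axis=0)
    spec = (neg[:, None] < cands[None, :]).mean(axis=0)
    tss_vals = sens + spec - 1.0
    best = int(np.argmax(tss_vals))  # argmax returns the first (lowest) maximiser
    return float(cands[best]), float(tss_vals[best])


def permutation_importance(
    predict: Callable[[np.ndarray], np.ndarray],
    features: np.ndarray,
    var_idx: int,
    n_perm: int = 10,
    seed: int = 0,
) -> float:
    """Permutation importance of one variable for a fitted model.

    Shuffles the variable's column, recomputes predictions, and averages
    ``1 - Pearson r`` between original and shuffled predictions over
    ``n_perm`` permutations; clipped to [0, 1].  Constant predictions make
    the correlation undefined and are treated as unchanged (importance 0).
    """
    base = np.asarray(predict(features), dtype=float)
    if np.ptp(base) == 0:
        warnings.warn("constant predictions; permutation importance set to 0", stacklevel=2)
        return 0.0
    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(n_perm):
        shuffled = features.copy()
        rng.shuffle(shuffled[:, var_idx])
        pred = np.asarray(predict(shuffled), dtype=float)
        if np.ptp(pred) == 0:
            vals.append(1.0)  # shuffling collapsed the signal entirely
            continue
        r = np.corrcoef(base, pred)[0, 1]
        vals.append(1.0 - r)
    return float(np.clip(np.mean(vals), 0.0, 1.0))


# ---------------------------------------------------------------------------
# learners
# ---------------------------------------------------------------------------


@dataclass
class LearnerAdapter:
    """Pluggable learner: any classifier exposing fit(+weights) and a
    [0, 1] suitability prediction, deterministic given a seed."""

    name: str
    factory: Callable[[int], object]
    weight_param: str = "sample_weight"

    def fit(self, features: np.ndarray, labels: np.ndarray, weights: np.ndarray, seed: int):
        est = self.factory(seed)
        est.fit(features, labels, **{self.weight_param: weights})
        return est

    def predict(self, fitted, features: np.ndarray) -> np.ndarray:
        p = fitted.predict_proba(features)[:, 1]
        return np.clip(p, 0.0, 1.0)


def _glm_factory(seed: int):
    return Pipeline(
        [
            ("scale", StandardScaler()),
            ("clf", LogisticRegression(max_iter=1000, random_state=seed)),
        ]
    )


def default_learners(fast: bool = False) -> list[LearnerAdapter]:
    """Regularised-linear (GLM-role) and boosted-tree (GBM-role) adapters.

    ``fast=True`` shrinks the boosting ensemble for small-sample test work.
    """
    n_estimators = 30 if fast else 100
    return [
        LearnerAdapter("GLM", _glm_factory, weight_param="clf__sample_weight"),
        LearnerAdapter(
            "GBM",
            lambda seed: GradientBoostingClassifier(n_estimators=n_estimators, random_state=seed),
        ),
    ]


def random_forest_adapter(n_estimators: int = 100) -> LearnerAdapter:
    return LearnerAdapter(
        "RF",
        lambda seed: RandomForestClassifier(n_estimators=n_estimators, random_state=seed, n_jobs=1),
    )


# ---------------------------------------------------------------------------
# pseudo-absences
# ---------------------------------------------------------------------------


@dataclass
class PseudoAbsenceSet:
    set_id: int
    cell_ids: list[tuple[int, int]]
    seed: int


def draw_pseudo_absences(
    grid: GridSpec,
    presences: OccurrenceSet,
    n_sets: int = 3,
    fraction: float = 1.0 / 3.0,
    seed: int = 0,
    valid_mask: np.ndarray | None = None,
) -> list[PseudoAbsenceSet]:
    """Random pseudo-absence sets from the eligible background.

    Eligible cells are non-missing (per ``valid_mask``, default all) and do
    not contain a presence.  Each set samples ``round(fraction * eligible)``
    cells without replacement, independently per set.
    """
    if valid_mask is None:
        valid_mask = np.ones(grid.shape, dtype=bool)
    eligible = valid_mask.copy()
    for row, col in presences.cells():
        if 0 <= row < grid.n_rows and 0 <= col < grid.n_cols:
            eligible[row, col] = False
    elig_idx = np.flatnonzero(eligible.ravel())
    size = int(round(fraction * elig_idx.size))
    if size > elig_idx.size:
        raise ValueError(f"requested {size} pseudo-absences but only {elig_idx.size} eligible cells")
    sets = []
    for k in range(1, n_sets + 1):
        ss = np.random.SeedSequence([seed, k])
        set_seed = int(ss.generate_state(1)[0] % (2**31))
        rng = np.random.default_rng(set_seed)
        chosen = rng.choice(elig_idx, size=size, replace=False)
        cells = [(int(i // grid.n_cols), int(i % grid.n_cols)) for i in np.sort(chosen)]
        sets.append(PseudoAbsenceSet(set_id=k, cell_ids=cells, seed=set_seed))
    return sets


# ---------------------------------------------------------------------------
# model runs and ensembles
# ---------------------------------------------------------------------------


@dataclass
class ModelRun:
    learner: str
    pa_set: int
    replicate: int
    split_seed: int
    auc: float
    tss: float
    tss_threshold: float
    importance: dict[str, float]
    prediction: RasterLayer
    test_cells: np.ndarray  # (n_test, 2) row/col
    test_labels: np.ndarray
    failed: bool = False


@dataclass
class EnsemblePrediction:
    species: str
    member_runs: list[ModelRun]
    mean_map: RasterLayer
    ensemble_auc: float
    ensemble_tss: float
    ensemble_tss_threshold: float


@dataclass
class BinarySuitabilityMap:
    species: str
    threshold: float
    map: RasterLayer


def _stack_features(layers: list[RasterLayer]) -> tuple[np.ndarray, np.ndarray]:
    """(valid_mask, features-at-valid-cells) for a layer stack."""
    stack = np.stack([lay.values for lay in layers])
    valid = np.all(np.isfinite(stack), axis=0)
    feats = stack[:, valid].T
    return valid, feats


def fit_all(
    species: str,
    layers: list[RasterLayer],
    presences: OccurrenceSet,
    pa_sets: list[PseudoAbsenceSet],
    learners: list[LearnerAdapter],
    n_replicates: int = 100,
    train_fraction: float = 0.7,
    seed: int = 0,
    min_presences: int = 15,
    n_perm: int = 10,
    compute_importance: bool = True,
) -> list[ModelRun]:
    """Fit |learners| x |pa_sets| x n_replicates presence/absence models.

    Each run draws a fresh stratified train/test split (train_fraction for
    training), balances classes by weight (total presence weight = total
    pseudo-absence weight), evaluates on the held-out fraction, and predicts
    over all non-missing cells.  Learner failures are recorded as failed
    runs, never silently dropped.
    """
    grid = presences.grid
    pres_cells = presences.cells()
    if len(pres_cells) < min_presences:
        raise ValueError(
            f"{species}: only {len(pres_cells)} presence cells after thinning (< {min_presences})"
        )
    valid, all_feats = _stack_features(layers)
    var_names = [lay.name for lay in layers]
    stack = np.stack([lay.values for lay in layers])

    def cell_features(cells: list[tuple[int, int]]) -> np.ndarray:
        rows = np.array([c[0] for c in cells])
        cols = np.array([c[1] for c in cells])
        return stack[:, rows, cols].T

    pres_cells = [c for c in pres_cells if valid[c]]
    X_pres = cell_features(pres_cells)

    runs: list[ModelRun] = []
    for li, learner in enumerate(learners):
        for pa in pa_sets:
            pa_cells = [c for c in pa.cell_ids if valid[c]]
            X_abs = cell_features(pa_cells)
            X = np.vstack([X_pres, X_abs])
            y = np.concatenate([np.ones(len(X_pres)), np.zeros(len(X_abs))])
            cells_arr = np.array(pres_cells + pa_cells)
            for rep in range(1, n_replicates + 1):
                ss = np.random.SeedSequence([seed, li, pa.set_id, rep])
                split_seed = int(ss.generate_state(1)[0] % (2**31))
                idx = np.arange(len(y))
                tr, te = train_test_split(
                    idx,
                    train_size=train_fraction,
                    stratify=y,
                    random_state=split_seed,
                )
                w = np.empty(tr.size)
                y_tr = y[tr]
                for cls in (0.0, 1.0):
                    m = y_tr == cls
                    w[m] = 0.5 * tr.size / max(m.sum(), 1)
                try:
                    fitted = learner.fit(X[tr], y_tr, w, split_seed)
                    s_te = learner.predict(fitted, X[te])
                except Exception:  # noqa: BLE001 - any learner failure is recorded
                    logger.exception(
                        "run failed: learner=%s pa_set=%d replicate=%d", learner.name, pa.set_id, rep
                    )
                    runs.append(
                        ModelRun(
                            learner.name, pa.set_id, rep, split_seed,
                            np.nan, np.nan, np.nan, {},
                            RasterLayer(grid, np.full(grid.shape, np.nan), species),
                            np.empty((0, 2), dtype=int), np.empty(0), failed=True,
                        )
                    )
                    continue
                pos, neg = s_te[y[te] == 1], s_te[y[te] == 0]
                run_auc = auc(pos, neg)
                thr, run_tss = best_tss_threshold(pos, neg)
                importance: dict[str, float] = {}
                if compute_importance:
                    pred_fn = lambda F: learner.predict(fitted, F)  # noqa: B023
                    for vi, vname in enumerate(var_names):
                        importance[vname] = permutation_importance(
                            pred_fn, X[tr], vi, n_perm=n_perm, seed=split_seed + vi
                        )
                pred = np.full(grid.shape, np.nan)
                pred[valid] = learner.predict(fitted, all_feats)
                runs.append(
                    ModelRun(
                        learner=learner.name,
                        pa_set=pa.set_id,
                        replicate=rep,
                        split_seed=split_seed,
                        auc=run_auc,
                        tss=run_tss,
                        tss_threshold=thr,
                        importance=importance,
                        prediction=RasterLayer(grid, pred, f"{species}:{learner.name}:{pa.set_id}:{rep}"),
                        test_cells=cells_arr[te],
                        test_labels=y[te],
                    )
                )
    return runs


def build_ensemble(runs: list[ModelRun], auc_gate: float = 0.7, species: str = "") -> EnsemblePrediction:
    """Unweighted mean ensemble over runs with AUC >= auc_gate.

    Ensemble AUC/TSS are evaluated by reading the mean map at each member
    run's held-out cells, pooled across members.
    """
    members = [r for r in runs if not r.failed and r.auc >= auc_gate]
    if not members:
        raise ValueError(f"no runs passed the AUC >= {auc_gate} ensemble gate")
    grid = members[0].prediction.grid
    preds = np.stack([r.prediction.values for r in members])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns stay NaN
        mean_vals = np.nanmean(preds, axis=0)
    mean_map = RasterLayer(grid, mean_vals, name=f"{species}:ensemble")
    pooled_scores, pooled_labels = [], []
    for r in members:
        s = mean_vals[r.test_cells[:, 0], r.test_cells[:, 1]]
        ok = np.isfinite(s)
        pooled_scores.append(s[ok])
        pooled_labels.append(r.test_labels[ok])
    scores = np.concatenate(pooled_scores)
    labels = np.concatenate(pooled_labels)
    pos, neg = scores[labels == 1], scores[labels == 0]
    ens_auc = auc(pos, neg)
    thr, ens_tss = best_tss_threshold(pos, neg)
    return EnsemblePrediction(
        species=species,
        member_runs=members,
        mean_map=mean_map,
        ensemble_auc=ens_auc,
        ensemble_tss=ens_tss,
        ensemble_tss_threshold=thr,
    )


def binarize_p10(ens: EnsemblePrediction, presences: OccurrenceSet) -> BinarySuitabilityMap:
    """Binary range map at the 10th percentile of suitability at presences.

    The threshold is the linearly-interpolated 10th percentile of ensemble
    suitability at the presence cells; a cell is suitable iff its mean
    suitability >= threshold.
    """
    grid = ens.mean_map.grid
    cells = [c for c in presences.cells() if 0 <= c[0] < grid.n_rows and 0 <= c[1] < grid.n_cols]
    vals = np.array([ens.mean_map.values[c] for c in cells])
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no presence cell has a defined ensemble suitability")
    if vals.size < 10:
        warnings.warn(
            f"only {vals.size} presence cells for the 10th-percentile threshold", stacklevel=2
        )
    threshold = float(np.percentile(vals, 10))
    out = np.where(np.isfinite(ens.mean_map.values), (ens.mean_map.values >= threshold).astype(float), np.nan)
    return BinarySuitabilityMap(
        species=ens.species,
        threshold=threshold,
        map=RasterLayer(grid, out, name=f"{ens.species}:binary"),
    )


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------


class EnsembleSDM:
    """Ensemble SDM for one species: data plus fitting configuration.

    Parameters
    ----------
    presences
        Cleaned, thinned presence records on the analysis grid.
    layers
        Predictor rasters sharing that grid.
    learners
        Learner adapters; defaults to the GLM-role and GBM-role pair.
    n_pa_sets, pa_fraction
        Pseudo-absence design: ``n_pa_sets`` independent random draws of
        ``pa_fraction`` of the eligible background cells.
    auc_gate
        Minimum per-run AUC for ensemble membership.
    """

    def __init__(
        self,
        presences: OccurrenceSet,
        layers: list[RasterLayer],
        learners: list[LearnerAdapter] | None = None,
        n_pa_sets: int = 3,
        pa_fraction: float = 1.0 / 3.0,
        auc_gate: float = 0.7,
        train_fraction: float = 0.7,
        min_presences: int = 15,
        n_perm: int = 10,
        compute_importance: bool = True,
    ) -> None:
        self.presences = presences
        self.layers = layers
        self.learners = learners if learners is not None else default_learners()
        self.n_pa_sets = n_pa_sets
        self.pa_fraction = pa_fraction
        self.auc_gate = auc_gate
        self.train_fraction = train_fraction
        self.min_presences = min_presences
        self.n_perm = n_perm
        self.compute_importance = compute_importance

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, species: str, layers: list[RasterLayer], grid: GridSpec, **kwargs
    ) -> "EnsembleSDM":
        """Build from a species/x/y dataframe (already cleaned and thinned)."""
        from .occurrences import OccurrenceRecord

        recs = [
            OccurrenceRecord(species=species, x=float(r.x), y=float(r.y))
            for r in df[df["species"] == species].itertuples()
        ]
        return cls(OccurrenceSet(species, recs, grid), layers, **kwargs)

    def fit(self, n_replicates: int = 100, seed: int = 0) -> "EnsembleSDMResult":
        valid, _ = _stack_features(self.layers)
        pa_sets = draw_pseudo_absences(
            self.presences.grid,
            self.presences,
            n_sets=self.n_pa_sets,
            fraction=self.pa_fraction,
            seed=seed,
            valid_mask=valid,
        )
        runs = fit_all(
            self.presences.species,
            self.layers,
            self.presences,
            pa_sets,
            self.learners,
            n_replicates=n_replicates,
            train_fraction=self.train_fraction,
            seed=seed,
            min_presences=self.min_presences,
            n_perm=self.n_perm,
            compute_importance=self.compute_importance,
        )
        ensemble = build_ensemble(runs, auc_gate=self.auc_gate, species=self.presences.species)
        return EnsembleSDMResult(self, runs, ensemble, seed=seed)


class EnsembleSDMResult:
    """Fitted ensemble: per-run metrics, the consensus map, and summaries."""

    def __init__(self, model: EnsembleSDM, runs: list[ModelRun], ensemble: EnsemblePrediction, seed: int) -> None:
        self.model = model
        self.runs = runs
        self.ensemble = ensemble
        self.seed = seed

    @property
    def species(self) -> str:
        return self.model.presences.species

    @property
    def mean_map(self) -> RasterLayer:
        return self.ensemble.mean_map

    @property
    def auc_(self) -> float:
        return self.ensemble.ensemble_auc

    @property
    def tss_(self) -> float:
        return self.ensemble.ensemble_tss

    def runs_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "learner": [r.learner for r in self.runs],
                "pa_set": [r.pa_set for r in self.runs],
                "replicate": [r.replicate for r in self.runs],
                "auc": [r.auc for r in self.runs],
                "tss": [r.tss for r in self.runs],
                "tss_threshold": [r.tss_threshold for r in self.runs],
                "failed": [r.failed for r in self.runs],
            }
        )

    def importance_table(self) -> pd.DataFrame:
        """Mean permutation importance per variable over successful runs."""
        rows = [r.importance for r in self.runs if not r.failed and r.importance]
        if not rows:
            return pd.DataFrame(columns=["variable", "importance"])
        df = pd.DataFrame(rows).mean().sort_values(ascending=False)
        return df.rename_axis("variable").reset_index(name="importance")

    def binarize(self) -> BinarySuitabilityMap:
        return binarize_p10(self.ensemble, self.model.presences)

    def plot_map(self, ax=None, kind: str = "suitability"):
        """Quick-look map of the ensemble suitability or its binary range.

        Requires matplotlib; returns the axes.
        """
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if kind == "suitability":
            data, title = self.mean_map.values, f"{self.species}: ensemble suitability"
        elif kind == "binary":
            data, title = self.binarize().map.values, f"{self.species}: binary range"
        else:
            raise ValueError(f"unknown kind {kind!r}")
        im = ax.imshow(data, vmin=0, vmax=1, interpolation="nearest")
        ax.figure.colorbar(im, ax=ax, shrink=0.8)
        ax.set_title(title)
        ax.set_xticks([])
        ax.set_yticks([])
        return ax

    def summary(self) -> str:
        tbl = self.runs_table()
        ok = tbl[~tbl.failed]
        lines = [
            f"Ensemble SDM results: {self.species}",
            "=" * 46,
            f"presence cells            {len(self.model.presences.cells()):>8d}",
            f"runs (total / passed gate){len(self.runs):>5d} / {len(self.ensemble.member_runs)}",
            f"AUC gate                  {self.model.auc_gate:>8.2f}",
            f"mean run AUC              {ok.auc.mean():>8.3f}",
            f"mean run TSS              {ok.tss.mean():>8.3f}",
            f"ensemble AUC              {self.auc_:>8.3f}",
            f"ensemble TSS              {self.tss_:>8.3f}",
            "-" * 46,
            "per-learner mean AUC / TSS:",
        ]
        for name, grp in ok.groupby("learner"):
            lines.append(f"  {name:<8s} {grp.auc.mean():.3f} / {grp.tss.mean():.3f}")
        imp = self.importance_table()
        if not imp.empty:
            lines.append("top variables (permutation importance):")
            for _, r in imp.head(5).iterrows():
                lines.append(f"  {r.variable:<12s} {r.importance:.3f}")
        return "\n".join(lines)
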