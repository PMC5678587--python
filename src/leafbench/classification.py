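"""Species classification over the image-type x strategy dataset grid.

The evaluation design crosses nine image types with three preprocessing
strategies into 27 datasets and scores each with a linear SVM over repeated
random splits.  Splits are *observation-consistent*: each observation (one
leaf individual, nine images) is assigned to train or test as a whole, per
species at a 70/30 ratio, and the same assignment is reused for all 27
datasets within a replicate — so any two cells of the grid are compared on
identical individuals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import GridSearchCV
from sklearn.svm import SVC

from ._rng import substream
from .synthetic import IMAGE_TYPES

__all__ = [
    "DATASET_KEYS",
    "SplitConfig",
    "SvmConfig",
    "AccuracyResult",
    "make_splits",
    "train_eval",
    "aggregate",
    "run_grid",
]

STRATEGIES = ("none", "crop", "segment")

#: the 27 evaluation datasets
DATASET_KEYS = tuple((t, s) for t in IMAGE_TYPES for s in STRATEGIES)


@dataclass(frozen=True)
class SplitConfig:
    """One train/test assignment of observations, shared by all 27 datasets."""

    replicate_id: int
    assignment: Mapping[str, str]      # observation_id -> "train" | "test"

    def train_ids(self) -> set:
        return {o for o, side in self.assignment.items() if side == "train"}

    def test_ids(self) -> set:
        return {o for o, side in self.assignment.items() if side == "test"}


@dataclass
class SvmConfig:
    C: float = 1.0
    tune: bool = False                      # inner-CV grid over C
    c_grid: tuple = (0.01, 0.1, 1.0, 10.0)
    inner_folds: int = 3


@dataclass
class ReplicateResult:
    replicate_id: int
    accuracy: float                          # percent correct on test images
    confusion: np.ndarray                    # counts, observed x predicted
    species: tuple                           # row/column order of confusion


@dataclass
class AccuracyResult:
    mean_acc: float                          # percent
    sd_acc: float                            # percent, sample sd over replicates
    per_species_acc: dict                    # species -> percent
    confusion: np.ndarray                    # row-normalized, observed x predicted
    species: tuple
    n_replicates: int


def make_splits(manifest: pd.DataFrame, train_frac: float = 0.7,
                n_splits: int = 100, seed: int = 0) -> list[SplitConfig]:
    """Observation-level stratified random splits, ``n_splits`` replicates.

    Per species, ``floor(train_frac * n_obs)`` observations train and the
    rest test, so the test side is never empty.  Replicate k draws from its
    own sub-stream of ``seed`` and is reproducible in isolation.
    """
    obs = manifest[["observation_id", "species_id"]].drop_duplicates("observation_id")
    counts = obs.groupby("species_id", sort=True)["observation_id"].agg(list)
    too_few = [sp for sp, ids in counts.items() if len(ids) < 2]
    if too_few:
        raise ValueError(f"species with < 2 observations: {too_few}")
    splits = []
    for k in range(n_splits):
        rng = substream(seed, "split", k)
        assignment: dict[str, str] = {}
        for sp, ids in counts.items():
            ids = sorted(ids)
            n_train = int(np.floor(train_frac * len(ids)))
            n_train = max(1, min(n_train, len(ids) - 1))
            perm = rng.permutation(len(ids))
            for j, idx in enumerate(perm):
                assignment[ids[idx]] = "train" if j < n_train else "test"
        splits.append(SplitConfig(replicate_id=k + 1, assignment=assignment))
    return splits


def _xy(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    feat_cols = [c for c in table.columns if c.startswith("f") and c[1:].isdigit()]
    return table[feat_cols].to_numpy(), table["species_id"].to_numpy()


def train_eval(features: pd.DataFrame, key: tuple[str, str], split: SplitConfig,
               svm: SvmConfig | None = None) -> ReplicateResult:
    """Fit a linear SVM on the train side of ``split`` and score the test side.

    ``features`` must contain the rows of the dataset ``key`` (one image per
    observation for that image type and strategy).  Multi-class handling is
    one-vs-one.  Raises if a species is absent from the training fold.
    """
    svm = svm or SvmConfig()
    image_type, strategy = key
    sel = features[(features["image_type"] == image_type)
                   & (features["strategy"] == strategy)]
    if sel.empty:
        raise ValueError(f"feature table has no rows for dataset {key}")
    is_train = sel["observation_id"].map(split.assignment).to_numpy()
    train, test = sel[is_train == "train"], sel[is_train == "test"]
    x_tr, y_tr = _xy(train)
    x_te, y_te = _xy(test)
    species = tuple(sorted(features["species_id"].unique()))
    missing = set(species) - set(y_tr)
    if missing:
        raise ValueError(f"species absent from training fold: {sorted(missing)}")

    if svm.tune:
        search = GridSearchCV(SVC(kernel="linear"), {"C": list(svm.c_grid)},
                              cv=svm.inner_folds, n_jobs=1)
        search.fit(x_tr, y_tr)
        clf = search.best_estimator_
    else:
        clf = SVC(kernel="linear", C=svm.C)
        clf.fit(x_tr, y_tr)
    y_pred = clf.predict(x_te)

    acc = 100.0 * float(np.mean(y_pred == y_te))
    index = {sp: i for i, sp in enumerate(species)}
    confusion = np.zeros((len(species), len(species)))
    for obs, pred in zip(y_te, y_pred):
        confusion[index[obs], index[pred]] += 1
    return ReplicateResult(replicate_id=split.replicate_id, accuracy=acc,
                           confusion=confusion, species=species)


def aggregate(replicates: Sequence[ReplicateResult]) -> AccuracyResult:
    """Mean and sample sd of accuracy over replicates, per-species rates,
    and the row-normalized confusion matrix of the pooled counts.

    A species missing from some replicate's test fold contributes to the
    per-species average only where it appears.
    """
    if not replicates:
        raise ValueError("no replicates to aggregate")
    accs = np.array([r.accuracy for r in replicates])
    species = replicates[0].species
    counts = np.sum([r.confusion for r in replicates], axis=0)
    row_tot = counts.sum(axis=1, keepdims=True)
    confusion = np.divide(counts, row_tot, out=np.zeros_like(counts),
                          where=row_tot > 0)
    per_species = {}
    for i, sp in enumerate(species):
        rates = [100.0 * r.confusion[i, i] / r.confusion[i].sum()
                 for r in replicates if r.confusion[i].sum() > 0]
        per_species[sp] = float(np.mean(rates)) if rates else float("nan")
    return AccuracyResult(
        mean_acc=float(accs.mean()),
        sd_acc=float(accs.std(ddof=1)) if len(accs) > 1 else 0.0,
        per_species_acc=per_species,
        confusion=confusion,
        species=species,
        n_replicates=len(replicates),
    )


def run_grid(features: pd.DataFrame, splits: Iterable[SplitConfig],
             svm: SvmConfig | None = None,
             keys: Sequence[tuple[str, str]] | None = None,
             ) -> dict[tuple[str, str], AccuracyResult]:
    """Evaluate every dataset key over the shared splits.

    ``features`` holds all strategies' rows (long format); ``keys`` defaults
    to the full 27-cell grid and may be restricted to the combinations
    actually present.
    """
    splits = list(splits)
    if keys is None:
        keys = [k for k in DATASET_KEYS
                if ((features["image_type"] == k[0])
                    & (features["strategy"] == k[1])).any()]
    results = {}
    for key in keys:
        reps = [train_eval(features, key, split, svm) for split in splits]
        results[key] = aggregate(reps)
    return results
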