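"""Patient-level analysis from per-cell labels.

Once every cell carries a domain (or cell-type) label, a patient is
summarized by the *proportions* of each label among their cells — a
simple compositional vector that turns a million-cell cohort into a
patients x labels matrix.  Unsupervised structure is read off the top
principal components (with per-component group t-tests); discriminative
power is measured by stratified k-fold cross-validated classification
with stock classifiers (KNN by default, any fit/predict object works).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("mender")


@dataclass
class CohortRepresentation:
    """Patients x labels proportion matrix; rows sum to 1."""

    proportions: pd.DataFrame  # index: patient_id, columns: label vocabulary
    source: str = "domain"

    @property
    def patients(self) -> np.ndarray:
        return self.proportions.index.to_numpy()

    @property
    def labels(self) -> np.ndarray:
        return self.proportions.columns.to_numpy()

    def matrix(self) -> np.ndarray:
        return self.proportions.to_numpy(float)


def patient_representation(cell_labels, patient_id, source: str = "domain") -> CohortRepresentation:
    """Per-patient label-proportion vectors over the cohort-wide vocabulary."""
    cell_labels = np.asarray(cell_labels)
    patient_id = np.asarray(patient_id)
    if len(cell_labels) != len(patient_id):
        raise ValueError("cell_labels and patient_id differ in length")
    counts = pd.crosstab(pd.Series(patient_id, name="patient"), pd.Series(cell_labels, name="label"))
    totals = counts.sum(axis=1)
    empty = totals[totals == 0].index
    if len(empty):
        logger.warning("patients with no cells excluded: %s", list(empty))
        counts = counts.drop(index=empty)
        totals = totals.drop(index=empty)
    props = counts.div(totals, axis=0)
    return CohortRepresentation(proportions=props, source=source)


def embed_patients(
    repr: CohortRepresentation,
    groups=None,
    n_components: int = 2,
    seed: int = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Centered PCA of patient proportions plus per-PC group t-tests.

    For each retained component and each group (one-vs-rest), a
    two-sided two-sample t-test on the component scores; groups with
    fewer than 2 patients are skipped.
    """
    from .states import _pca

    X = repr.matrix()
    if X.shape[0] < 3:
        raise ValueError("need at least 3 patients")
    k = min(n_components, X.shape[1], X.shape[0] - 1)
    if np.allclose(X, X[0]):
        logger.warning("all patients identical; scores are zero and tests skipped")
        return np.zeros((X.shape[0], k)), pd.DataFrame(
            columns=["component", "group", "t", "pvalue"]
        )
    scores = _pca(X, k)
    tests = []
    if groups is not None:
        groups = np.asarray(groups)
        for g in pd.unique(groups):
            inside = groups == g
            if inside.sum() < 2 or (~inside).sum() < 2:
                logger.warning("group %r has <2 patients on one side; t-test skipped", g)
                continue
            for c in range(scores.shape[1]):
                t, p = stats.ttest_ind(scores[inside, c], scores[~inside, c])
                tests.append({"component": c + 1, "group": g, "t": float(t), "pvalue": float(p)})
    return scores, pd.DataFrame(tests, columns=["component", "group", "t", "pvalue"])


class _KNNDefault:
    def __init__(self, n_neighbors: int = 5):
        from sklearn.neighbors import KNeighborsClassifier

        self._clf = KNeighborsClassifier(n_neighbors=n_neighbors)

    def fit(self, X, y):
        self._clf.fit(X, y)
        return self

    def predict(self, X):
        return self._clf.predict(X)


def classify_patients(
    repr: CohortRepresentation,
    groups,
    classifier=None,
    folds: int = 5,
    repeats: int = 1,
    seed: int = 0,
    n_pcs: int | None = None,
) -> dict:
    """Stratified k-fold cross-validated group classification accuracy.

    When ``n_pcs`` is given, features are the top principal components
    fitted on each training fold only (no leakage from test patients).
    Returns mean accuracy and the per-fold accuracies.
    """
    from sklearn.model_selection import StratifiedKFold

    from .states import _pca

    X = repr.matrix()
    groups = np.asarray(groups)
    if len(groups) != X.shape[0]:
        raise ValueError("groups must have one entry per patient")
    _, counts = np.unique(groups, return_counts=True)
    if counts.min() < folds:
        raise ValueError(
            f"smallest group has {counts.min()} patients < folds={folds}; reduce folds"
        )
    accs = []
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + rep)
        for train, test in skf.split(X, groups):
            Xtr, Xte = X[train], X[test]
            if n_pcs is not None:
                k = min(n_pcs, Xtr.shape[1], Xtr.shape[0] - 1)
                mu = Xtr.mean(axis=0, keepdims=True)
                Xc = Xtr - mu
                _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
                comps = Vt[:k]
                Xtr = Xc @ comps.T
                Xte = (Xte - mu) @ comps.T
            clf = classifier() if callable(classifier) else (classifier or _KNNDefault())
            clf.fit(Xtr, groups[train])
            pred = clf.predict(Xte)
            accs.append(float(np.mean(pred == groups[test])))
    return {
        "mean_accuracy": float(np.mean(accs)),
        "fold_accuracies": accs,
        "folds": folds,
        "repeats": repeats,
        "n_pcs": n_pcs,
        "seed": seed,
    }
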