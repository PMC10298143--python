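"""Cell-level analyses on allele-frequency profiles.

The cell–cell distance is one minus the absolute pairwise Pearson
correlation of AF profiles over sites where both cells have coverage.
Embedding (t-SNE on the precomputed distance matrix) and donor
classification (random forest on AF features) delegate to scikit-learn;
this module owns the inputs, seeds and contracts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.manifold import TSNE
from sklearn.model_selection import StratifiedKFold, cross_val_predict

from .allele_matrices import AlleleFrequencyMatrix
from .reference_io import Variant
from .variant_stats import DonorLabels

log = logging.getLogger(__name__)

#: classifier encoding for "no coverage" — deliberately outside [0, 1] so
#: tree models can split dropout away from any real frequency
MISSING_AF_SENTINEL = -1.0


@dataclass
class CellDistanceMatrix:
    """Symmetric cell–cell distances in [0, 1] with zero diagonal.

    ``n_fallback_pairs`` counts pairs assigned the maximal distance 1
    because they shared too few covered sites or a profile was constant
    (correlation undefined).
    """

    values: np.ndarray
    cell_ids: list[str]
    n_fallback_pairs: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.cell_ids)


@dataclass
class DonorPrediction:
    """Held-out donor predictions for every labeled cell."""

    cell_ids: list[str]
    true_donor: list[str]
    predicted_donor: list[str]
    accuracy: float
    scheme: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.cell_ids,
                "true": self.true_donor,
                "predicted": self.predicted_donor,
            }
        )


def _site_matrix(af: AlleleFrequencyMatrix, sites: Sequence[Variant]) -> np.ndarray:
    rows = [af.row_of(v) for v in sites]
    return af.values[rows, :]


def correlation_distance(
    af: AlleleFrequencyMatrix,
    sites: Sequence[Variant],
    min_shared_sites: int = 20,
) -> CellDistanceMatrix:
    """1 − |Pearson r| between cell AF profiles over shared covered sites.

    For each cell pair the correlation uses only sites non-missing in
    both cells. Pairs with fewer than ``min_shared_sites`` shared sites,
    or where either profile is constant over the shared sites, get the
    maximal distance 1 (counted in ``n_fallback_pairs``). Note the
    absolute value: perfectly anti-correlated profiles also get distance
    0, a documented consequence of the formula.
    """
    if len(af.cell_ids) < 2:
        raise ValueError("need at least 2 cells")
    if not sites:
        raise ValueError("empty site list")
    X = _site_matrix(af, sites)  # sites × cells
    n_cells = X.shape[1]
    ok = ~np.isnan(X)
    D = np.zeros((n_cells, n_cells))
    n_fallback = 0
    for i in range(n_cells):
        xi = X[:, i]
        for j in range(i + 1, n_cells):
            shared = ok[:, i] & ok[:, j]
            d = 1.0
            if shared.sum() >= max(min_shared_sites, 2):
                a = xi[shared]
                b = X[shared, j]
                sa = a.std()
                sb = b.std()
                if sa > 0 and sb > 0:
                    r = float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))
                    d = 1.0 - abs(max(-1.0, min(1.0, r)))
                else:
                    n_fallback += 1
            else:
                n_fallback += 1
            D[i, j] = D[j, i] = d
    if n_fallback:
        log.info(
            "correlation_distance: %d/%d pairs fell back to distance 1",
            n_fallback,
            n_cells * (n_cells - 1) // 2,
        )
    return CellDistanceMatrix(
        values=D, cell_ids=list(af.cell_ids), n_fallback_pairs=n_fallback
    )


def embed_cells(
    dist: CellDistanceMatrix,
    perplexity: float = 10.0,
    seed: int = 0,
) -> pd.DataFrame:
    """2-D t-SNE of the precomputed distance matrix.

    Deterministic for a fixed seed. Coordinates carry no units. The
    perplexity must be below (n_cells − 1) / 3 for a meaningful
    neighbourhood size.
    """
    n = len(dist.cell_ids)
    if perplexity >= (n - 1) / 3:
        raise ValueError(
            f"perplexity {perplexity} too large for {n} cells "
            f"(needs perplexity < {(n - 1) / 3:.1f})"
        )
    tsne = TSNE(
        n_components=2,
        metric="precomputed",
        init="random",
        perplexity=perplexity,
        random_state=seed,
    )
    coords = tsne.fit_transform(dist.values)
    return pd.DataFrame(coords, index=dist.cell_ids, columns=["dim1", "dim2"])


def classify_donors(
    af: AlleleFrequencyMatrix,
    sites: Sequence[Variant],
    labels: DonorLabels,
    seed: int = 0,
    scheme: str = "out_of_bag",
    n_folds: int = 5,
    n_estimators: int = 500,
) -> DonorPrediction:
    """Random-forest donor prediction from AF features with held-out
    accuracy.

    Features are the AFs at ``sites``; missing entries are encoded as
    the out-of-range sentinel −1 rather than imputed. ``out_of_bag``
    (default) scores each cell with the trees that did not see it during
    bagging; ``k_fold`` uses stratified cross-validated predictions.
    """
    if not sites:
        raise ValueError("empty feature set")
    cells = [c for c in af.cell_ids if c in labels.mapping]
    missing_cells = [c for c in labels.mapping if c not in set(af.cell_ids)]
    if missing_cells:
        raise ValueError(
            f"{len(missing_cells)} labeled cells absent from the matrix"
        )
    y = np.array([labels.mapping[c] for c in cells])
    donors, counts = np.unique(y, return_counts=True)
    if len(donors) < 2:
        raise ValueError("need at least 2 donors")
    if counts.min() < 5:
        small = donors[counts < 5]
        raise ValueError(f"every donor needs >= 5 labeled cells; too few: {small}")
    col = {c: i for i, c in enumerate(af.cell_ids)}
    X = _site_matrix(af, sites)[:, [col[c] for c in cells]].T
    X = np.where(np.isnan(X), MISSING_AF_SENTINEL, X)
    if scheme == "out_of_bag":
        clf = RandomForestClassifier(
            n_estimators=n_estimators,
            random_state=seed,
            oob_score=True,
            bootstrap=True,
        )
        clf.fit(X, y)
        proba = clf.oob_decision_function_
        never_oob = np.isnan(proba).any(axis=1)
        if never_oob.any():  # pragma: no cover - vanishing for many trees
            log.warning("%d cells never out-of-bag; scored in-bag", never_oob.sum())
            proba = np.where(np.isnan(proba), 0.0, proba)
        pred = clf.classes_[np.argmax(proba, axis=1)]
    elif scheme == "k_fold":
        clf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
        cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        pred = cross_val_predict(clf, X, y, cv=cv)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    accuracy = float(np.mean(pred == y))
    return DonorPrediction(
        cell_ids=cells,
        true_donor=list(y),
        predicted_donor=list(pred),
        accuracy=accuracy,
        scheme=scheme,
    )
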