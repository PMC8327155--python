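"""Microbiome-based dietary-niche prediction.

The dietary niche of a host is inferred from which gut bacteria it carries:
taxa whose presence pattern across hosts correlates with a diet-based
distance matrix (Mantel) are retained, host communities are mapped by a
presence/absence PCA, and the first-axis coordinate feeds a binomial
logistic regression separating carnivorous (wolf-like, 0) from omnivorous
(dog-like, 1) hosts.  A new (e.g. ancient) sample is projected onto the
stored basis and classified at a probability threshold of 0.5.  Predictive
power is assessed by exhaustive leave-1-out and leave-2-out cross-
validation with the full procedure (selection included) refit per fold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.linear_model import LogisticRegression
from skbio.stats.distance import DistanceMatrix

from .hosts import HostMeta
from .stats import batch_mantel

logger = logging.getLogger(__name__)

__all__ = [
    "CARNIVOROUS",
    "OMNIVOROUS",
    "DietModel",
    "diet_distance",
    "select_diet_taxa",
    "fit_diet_model",
    "predict_diet",
    "cross_validate",
    "labels_from_meta",
    "default_canid_diets",
]

CARNIVOROUS = "carnivorous"   # wolf-like, logistic response 0
OMNIVOROUS = "omnivorous"     # dog-like, logistic response 1

#: inverse ridge strength of the logistic fit; a weak penalty keeps the fit
#: finite under the perfect separation expected with a handful of hosts
#: while leaving threshold-0.5 decisions unchanged.
_LOGISTIC_C = 100.0


def diet_distance(meta: list[HostMeta]) -> DistanceMatrix:
    """Euclidean distances between hosts' food-consumption fraction vectors."""
    with_diet = [m for m in meta if m.diet is not None]
    if len(with_diet) < 2:
        raise ValueError("need diet profiles for at least 2 hosts")
    cats = sorted({c for m in with_diet for c in m.diet})
    for m in with_diet:
        if set(m.diet) != set(cats):
            raise ValueError(f"host {m.host_id!r}: diet categories "
                             f"{sorted(m.diet)} do not match {cats}")
    x = np.array([[m.diet[c] for c in cats] for m in with_diet])
    return DistanceMatrix(squareform(pdist(x)),
                          ids=[m.host_id for m in with_diet])


def select_diet_taxa(table: pd.DataFrame, diet_dm: DistanceMatrix,
                     alpha: float = 0.05, n_perm: int = 999, seed=None,
                     fdr: bool = False) -> list[str]:
    """Retain taxa whose presence-mismatch distances track diet distances.

    Per taxon, a Mantel test between the hosts' presence-mismatch distance
    (0 if both or neither carry the taxon, 1 otherwise) and the diet
    distance matrix; taxa with p <= alpha survive.  Constant taxa are
    skipped.  ``fdr=True`` applies BH adjustment before thresholding
    (off by default).
    """
    ids = [str(i) for i in table.index]
    fac = np.asarray(diet_dm.filter(ids).data, float)
    pres = (table.to_numpy() > 0).astype(float)
    names, rows = [], []
    iu = np.triu_indices(len(ids), 1)
    for j, taxon in enumerate(table.columns):
        x = pres[:, j]
        if x.min() == x.max():
            logger.info("taxon %s constant across hosts, skipped", taxon)
            continue
        rows.append(np.abs(x[iu[0]] - x[iu[1]]))
        names.append(str(taxon))
    if not names:
        return []
    _, pvals = batch_mantel(np.array(rows), fac, n_perm=n_perm, seed=seed)
    if fdr and pvals.size:
        from .stats import bh_fdr
        pvals = bh_fdr(pvals)
    return [t for t, p in zip(names, pvals) if p <= alpha]


@dataclass
class DietModel:
    taxa: list[str]               # selected taxa, in basis order
    center: np.ndarray            # column means of the presence matrix
    axis1: np.ndarray             # unit loading vector of PCA axis 1
    intercept: float
    slope: float                  # logistic coefficient on axis-1 score
    threshold: float = 0.5

    def __post_init__(self):
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie in (0, 1)")
        norm = float(np.linalg.norm(self.axis1))
        if abs(norm - 1.0) > 1e-8:
            raise ValueError("axis-1 loadings must be unit norm")

    def score(self, presence: np.ndarray) -> float:
        return float((presence - self.center) @ self.axis1)

    def probability(self, presence: np.ndarray) -> float:
        z = self.intercept + self.slope * self.score(presence)
        return float(1.0 / (1.0 + np.exp(-z)))


def fit_diet_model(table: pd.DataFrame, labels: dict,
                   threshold: float = 0.5) -> DietModel:
    """Presence/absence PCA (axis 1) + binomial logistic regression.

    ``labels`` maps host id to "carnivorous" or "omnivorous".  The table is
    binarised and column-centred (no scaling); axis 1 of the PCA is the
    leading right singular vector, sign-fixed so its largest-magnitude
    loading is positive; a weakly ridge-penalised logistic regression of
    the class on the axis-1 score completes the model.
    """
    hosts = [str(h) for h in table.index]
    y = np.array([{CARNIVOROUS: 0, OMNIVOROUS: 1}[labels[h]] for h in hosts])
    if len(set(y)) < 2:
        raise ValueError("both diet classes must be present to fit")
    if len(hosts) < 3:
        raise ValueError("need at least 3 hosts")
    x = (table.to_numpy() > 0).astype(float)
    center = x.mean(axis=0)
    xc = x - center
    _, _, vt = np.linalg.svd(xc, full_matrices=False)
    axis1 = vt[0]
    if axis1[np.argmax(np.abs(axis1))] < 0:
        axis1 = -axis1
    scores = xc @ axis1
    # balanced class weights: with a handful of hosts per class, an
    # unbalanced prior otherwise dominates the intercept and biases
    # held-out predictions toward the training majority
    clf = LogisticRegression(C=_LOGISTIC_C, solver="lbfgs",
                             class_weight="balanced")
    clf.fit(scores.reshape(-1, 1), y)
    return DietModel(taxa=[str(t) for t in table.columns], center=center,
                     axis1=axis1, intercept=float(clf.intercept_[0]),
                     slope=float(clf.coef_[0, 0]), threshold=threshold)


def predict_diet(model: DietModel, profile) -> tuple[float, str]:
    """(probability of an omnivorous dog-like diet, assigned class).

    ``profile`` is a mapping / pandas Series of taxon -> presence; taxa the
    model knows but the profile lacks are treated as absent (logged).
    Probability >= threshold assigns the omnivorous class (ties go to
    omnivorous).
    """
    if isinstance(profile, pd.Series):
        profile = profile.to_dict()
    profile = {str(k): v for k, v in profile.items()}
    overlap = [t for t in model.taxa if t in profile]
    if not overlap:
        raise ValueError("profile shares no taxa with the model")
    missing = [t for t in model.taxa if t not in profile]
    if missing:
        logger.info("%d model taxa missing from profile, treated as absent",
                    len(missing))
    vec = np.array([1.0 if profile.get(t, 0) > 0 else 0.0
                    for t in model.taxa])
    prob = model.probability(vec)
    label = OMNIVOROUS if prob >= model.threshold else CARNIVOROUS
    return prob, label


def cross_validate(table: pd.DataFrame, labels: dict,
                   diet_dm: DistanceMatrix, alpha: float = 0.05,
                   n_perm: int = 999, seed=None,
                   holdout_sizes: tuple = (1, 2),
                   selection: str = "fold", threshold: float = 0.5,
                   ) -> tuple[float, pd.DataFrame]:
    """Exhaustive leave-k-out cross-validation of the full diet pipeline.

    Enumerates every hold-out set of each size in ``holdout_sizes`` (for 9
    hosts and sizes (1, 2): 9 + 36 = 45 splits), refits selection + PCA +
    logistic regression on the training hosts, and predicts the held-out
    hosts at the 0.5 threshold.  ``selection="fold"`` (default) selects
    taxa within each training fold — no information leaks from the test
    hosts; ``selection="full"`` selects once on all hosts, the leakage-
    prone variant kept only for comparison.  Returns (mean accuracy over
    all predictions, per-prediction record).
    """
    if selection not in ("fold", "full"):
        raise ValueError(f"unknown selection mode {selection!r}")
    hosts = [str(h) for h in table.index]
    if len(hosts) < 4:
        raise ValueError("need at least 4 hosts for cross-validation")
    ss = np.random.SeedSequence(seed)
    sel_all = None
    if selection == "full":
        sel_all = select_diet_taxa(
            table, diet_dm, alpha=alpha, n_perm=n_perm,
            seed=int(ss.spawn(1)[0].generate_state(1)[0] % 2**31))
    records = []
    for k in holdout_sizes:
        for held in combinations(hosts, k):
            train = [h for h in hosts if h not in held]
            y_train = {h: labels[h] for h in train}
            if len(set(y_train.values())) < 2:
                records.append({"held_out": "+".join(held), "skipped": True,
                                "reason": "single-class training set"})
                continue
            if selection == "fold":
                sub = int(ss.spawn(1)[0].generate_state(1)[0] % 2**31)
                sel = select_diet_taxa(table.loc[train], diet_dm,
                                       alpha=alpha, n_perm=n_perm, seed=sub)
            else:
                sel = sel_all
            if not sel:
                records.append({"held_out": "+".join(held), "skipped": True,
                                "reason": "no taxa selected"})
                continue
            model = fit_diet_model(table.loc[train, sel], y_train,
                                   threshold=threshold)
            for h in held:
                prob, pred = predict_diet(model, table.loc[h])
                records.append({"held_out": "+".join(held), "host": h,
                                "skipped": False, "prob": prob,
                                "predicted": pred, "truth": labels[h],
                                "correct": pred == labels[h]})
    df = pd.DataFrame(records)
    scored = df[~df["skipped"]] if "skipped" in df else df
    accuracy = float(scored["correct"].mean()) if len(scored) else float("nan")
    return accuracy, df


def labels_from_meta(meta: list[HostMeta]) -> dict:
    """wolf -> carnivorous, dog -> omnivorous; ancient hosts are excluded
    (they are what the model predicts)."""
    out = {}
    for m in meta:
        if m.group == "wolf":
            out[m.host_id] = CARNIVOROUS
        elif m.group == "dog":
            out[m.host_id] = OMNIVOROUS
    return out


def default_canid_diets(meta: list[HostMeta]) -> list[HostMeta]:
    """Attach study-style diet profiles: wolves eat vertebrate prey only;
    dogs span 10-40% carbohydrate/fibre consumption."""
    dogs = [m for m in meta if m.group == "dog"]
    carb = np.linspace(0.1, 0.4, len(dogs)) if dogs else []
    out = []
    di = 0
    for m in meta:
        if m.group == "wolf":
            diet = {"vertebrate_prey": 1.0, "carbohydrate_fibre": 0.0}
        elif m.group == "dog":
            diet = {"vertebrate_prey": 1.0 - float(carb[di]),
                    "carbohydrate_fibre": float(carb[di])}
            di += 1
        else:
            diet = None
        out.append(HostMeta(m.host_id, m.group, diet))
    return out
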