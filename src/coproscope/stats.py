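"""Distance-matrix statistics used throughout the pipeline.

The Mantel permutation test is implemented here (vectorised over
permutations) because the time-sliced analysis calls it once per slice per
factor, the permutation envelopes re-use its machinery, and the null-
calibration suites run it by the hundreds.  PERMANOVA, PCoA and the
Procrustes superimposition lean on scikit-bio/scipy; the pseudo-F test
against a *distance-matrix* predictor (used per bacterial lineage) has no
library counterpart and is written here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import procrustes as _procrustes
from skbio.stats.distance import DistanceMatrix
from skbio.stats.distance import permanova as _skbio_permanova
from statsmodels.stats.multitest import multipletests

__all__ = [
    "MantelResult",
    "mantel_test",
    "batch_mantel",
    "distance_pseudo_f",
    "permanova_groups",
    "pcoa",
    "PCoAResult",
    "procrustes_test",
    "bh_fdr",
]

_EPS = 1e-12


def _as_square(d, ids=None):
    """Coerce to (ndarray, ids); reorder to `ids` when given."""
    if isinstance(d, DistanceMatrix):
        if ids is not None:
            missing = set(ids) - set(d.ids)
            if missing:
                raise ValueError(f"distance matrix missing ids: {sorted(missing)}")
            d = d.filter(ids)
        return np.asarray(d.data, dtype=float), list(d.ids)
    arr = np.asarray(d, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("expected a square distance matrix")
    if not np.allclose(arr, arr.T):
        raise ValueError("distance matrix is not symmetric")
    return arr, ids


def _condensed(mat: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(mat.shape[0], 1)
    return mat[iu]


def _perm_condensed(mat: np.ndarray, perms: np.ndarray) -> np.ndarray:
    """Condensed vectors of `mat` under each row/column permutation."""
    iu = np.triu_indices(mat.shape[0], 1)
    return mat[perms[:, iu[0]], perms[:, iu[1]]]


def _pearson_many(v: np.ndarray, m: np.ndarray) -> np.ndarray:
    """Pearson r of vector `v` against each row of matrix `m`."""
    vc = v - v.mean()
    mc = m - m.mean(axis=1, keepdims=True)
    denom = np.sqrt((vc ** 2).sum() * (mc ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, mc @ vc / denom, 0.0)


@dataclass(frozen=True)
class MantelResult:
    r: float
    r2: float
    p: float
    n_perm: int


#: below this many objects the Mantel null is enumerated exactly
_EXACT_N = 8

_PERM_CACHE: dict = {}


def _all_permutations(n: int) -> np.ndarray:
    if n not in _PERM_CACHE:
        from itertools import permutations as _iperm
        _PERM_CACHE[n] = np.array(list(_iperm(range(n))))
    return _PERM_CACHE[n]


def _null_perms(n: int, n_perm: int, seed, exact: bool | None):
    """(permutation array, exact?) for an n-object permutation null."""
    if exact is None:
        exact = n <= _EXACT_N
    if exact:
        return _all_permutations(n), True
    rng = np.random.default_rng(seed)
    return np.array([rng.permutation(n) for _ in range(n_perm)]), False


def batch_mantel(responses: np.ndarray, factor_sq: np.ndarray,
                 n_perm: int = 999, seed=None, exact: bool | None = None,
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Mantel r and permutation p for many responses against one factor.

    ``responses`` holds condensed (upper-triangle) response distance
    vectors, one per row; all share one permutation null of the factor
    matrix (permuting either matrix's labels yields the same null).
    Two-sided on |r|.  Rows with zero variance get r = 0, p = 1.
    """
    v_f = _condensed(factor_sq)
    n = factor_sq.shape[0]
    perms, is_exact = _null_perms(n, n_perm, seed, exact)
    pc = _perm_condensed(factor_sq, perms)
    pc = pc - pc.mean(axis=1, keepdims=True)
    pnorm = np.sqrt((pc ** 2).sum(axis=1))
    vc = responses - responses.mean(axis=1, keepdims=True)
    vnorm = np.sqrt((vc ** 2).sum(axis=1))
    ok = (vnorm > 0) & (v_f.std() > 0)
    r_obs = np.zeros(len(responses))
    pvals = np.ones(len(responses))
    if ok.any():
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = (pc @ vc[ok].T) / np.outer(pnorm, vnorm[ok])
        corr = np.nan_to_num(corr)
        fc = v_f - v_f.mean()
        r = (vc[ok] @ fc) / (vnorm[ok] * np.sqrt((fc ** 2).sum()))
        hits = (np.abs(corr) >= np.abs(r)[None, :] - _EPS).sum(axis=0)
        if is_exact:
            p = hits / len(perms)
        else:
            p = (1 + hits) / (len(perms) + 1)
        r_obs[ok], pvals[ok] = r, p
    return r_obs, pvals


def mantel_test(d1, d2, n_perm: int = 999, seed=None,
                alternative: str = "two-sided",
                exact: bool | None = None) -> MantelResult:
    """Mantel test with Pearson correlation between two distance matrices.

    The observed statistic is the Pearson correlation of the strictly-upper-
    triangle entries.  The null jointly permutes rows/columns of ``d2``;
    with Monte-Carlo sampling, p = (1 + #{permuted statistic >= observed})
    / (n_perm + 1); for n <= 8 objects (or ``exact=True``) all n!
    permutations are enumerated instead, giving a deterministic exact p.
    Two-sided on |r| by default (``alternative="greater"`` one-sided).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if alternative not in ("two-sided", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    m1, ids = _as_square(d1)
    m2, _ = _as_square(d2, ids=ids)
    n = m1.shape[0]
    if n < 3:
        raise ValueError("Mantel test needs at least 3 objects")
    v1, v2 = _condensed(m1), _condensed(m2)
    if v1.std() == 0 or v2.std() == 0:
        raise ValueError("constant distance matrix: Mantel r undefined")
    r = float(np.corrcoef(v1, v2)[0, 1])

    perms, exact = _null_perms(n, n_perm, seed, exact)
    r_perm = _pearson_many(v1, _perm_condensed(m2, perms))
    if alternative == "two-sided":
        hits = int((np.abs(r_perm) >= np.abs(r) - _EPS).sum())
    else:
        hits = int((r_perm >= r - _EPS).sum())
    if exact:
        p = hits / len(perms)          # identity permutation counts itself
        n_used = len(perms)
    else:
        p = (1 + hits) / (n_perm + 1)
        n_used = n_perm
    return MantelResult(r=r, r2=r * r, p=p, n_perm=n_used)


def distance_pseudo_f(response, predictor, n_perm: int = 999,
                      seed=None) -> tuple[float, float]:
    """Pseudo-F of one distance matrix regressed on another, permutation p.

    Fits a simple linear regression of the condensed response distances on
    the condensed predictor distances; F = R^2 / (1 - R^2) * (m - 2) over
    the m host pairs.  The null permutes host labels of the response.
    Used per bacterial lineage, where the response is the lineage's
    presence-mismatch distance and the predictor is the host phylogeny or
    ecology matrix.
    """
    m_resp, ids = _as_square(response)
    m_pred, _ = _as_square(predictor, ids=ids)
    n = m_resp.shape[0]
    v_y, v_x = _condensed(m_resp), _condensed(m_pred)
    m = v_y.size
    if v_y.std() == 0:
        raise ValueError("constant response distances: pseudo-F undefined")
    if v_x.std() == 0:
        raise ValueError("constant predictor distances: pseudo-F undefined")

    def _f(rows):
        r = _pearson_many(v_x, rows)
        r2 = r ** 2
        return r2 / np.maximum(1 - r2, _EPS) * (m - 2)

    f_obs = float(_f(v_y[None, :])[0])
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    f_perm = _f(_perm_condensed(m_resp, perms))
    p = (1 + int((f_perm >= f_obs - _EPS).sum())) / (n_perm + 1)
    return f_obs, p


def permanova_groups(d, groups, n_perm: int = 999,
                     seed=None) -> tuple[float, float]:
    """PERMANOVA pseudo-F of a distance matrix against group labels.

    Among/within sum-of-squares partition of the (squared) distances with a
    group-label permutation test (delegated to scikit-bio).
    """
    if isinstance(d, DistanceMatrix):
        dm = d
    else:
        arr, _ = _as_square(d)
        dm = DistanceMatrix(arr, ids=[str(i) for i in range(arr.shape[0])])
    groups = list(groups)
    if len(groups) != dm.shape[0]:
        raise ValueError("one group label per host required")
    if len(set(groups)) < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    res = _skbio_permanova(dm, groups, permutations=n_perm, seed=seed)
    return float(res["test statistic"]), float(res["p-value"])


@dataclass
class PCoAResult:
    coordinates: pd.DataFrame      # hosts x positive axes, decreasing eigval
    eigvals: np.ndarray            # all eigenvalues, decreasing (incl. <0)
    explained: np.ndarray          # fraction of positive-eigenvalue sum


def pcoa(d) -> PCoAResult:
    """Classical metric scaling (principal coordinates analysis).

    Double-centres the squared distances and eigendecomposes; axes with
    positive eigenvalues are returned scaled to sqrt(eigenvalue), negative
    eigenvalues are reported untouched.
    """
    arr, ids = _as_square(d)
    n = arr.shape[0]
    if n < 3:
        raise ValueError("PCoA needs at least 3 objects")
    if ids is None:
        ids = [str(i) for i in range(n)]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (arr ** 2) @ j
    vals, vecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = 1e-10 * max(abs(vals).max(), 1.0)
    pos = vals > tol
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    cols = [f"PCo{i + 1}" for i in range(int(pos.sum()))]
    explained = vals[pos] / vals[pos].sum() if pos.any() else np.array([])
    return PCoAResult(
        coordinates=pd.DataFrame(coords, index=ids, columns=cols),
        eigvals=vals, explained=explained)


def procrustes_test(coords1, coords2, n_perm: int = 999,
                    seed=None) -> tuple[float, float]:
    """Procrustes m^2 with a row-permutation non-randomness test.

    Superimposes configuration 2 onto configuration 1 by translation,
    scaling and orthogonal rotation (reflection allowed); m^2 is the
    minimised standardised residual.  The null permutes the row order of
    configuration 2; p = (1 + #{m^2_perm <= m^2_obs}) / (n_perm + 1).
    """
    a = np.asarray(coords1, dtype=float)
    b = np.asarray(coords2, dtype=float)
    if a.shape[0] != b.shape[0]:
        raise ValueError("configurations must have matching rows")
    if a.shape[0] < 3:
        raise ValueError("Procrustes test needs at least 3 points")
    k = max(a.shape[1], b.shape[1])
    a = np.pad(a, ((0, 0), (0, k - a.shape[1])))
    b = np.pad(b, ((0, 0), (0, k - b.shape[1])))
    _, _, m2 = _procrustes(a, b)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        _, _, m2p = _procrustes(a, b[rng.permutation(b.shape[0])])
        if m2p <= m2 + _EPS:
            hits += 1
    return float(m2), (1 + hits) / (n_perm + 1)


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
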