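"""Patristic distances between phyla and their relation to exponent divergence.

Phylum-level distance is the mean patristic (branch-path) distance over all
tip pairs with one tip in each phylum.  Exponent divergence between two
phyla is either the absolute slope difference |beta_p - beta_q| or the slope
quotient max/min (defined only for slopes of the same sign).  The
association between the two matrices is a plain correlation over the
upper-triangle phylum pairs; an optional Mantel permutation test quantifies
it against label permutations.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import dendropy
import numpy as np
from scipy import stats

from cogscale.errors import InsufficientDataError, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    d: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.labels), len(self.labels)):
            raise ValidationError("distance matrix shape mismatch")
        if not np.allclose(d, d.T):
            raise ValidationError("distance matrix not symmetric")
        if not np.allclose(np.diag(d), 0.0):
            raise ValidationError("distance matrix diagonal not zero")
        if not np.isfinite(d).all():
            raise ValidationError("non-finite distances")
        object.__setattr__(self, "d", d)

    def reorder(self, labels) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(tuple(labels), self.d[np.ix_(idx, idx)])


@dataclass(frozen=True)
class DivergenceMatrix:
    labels: tuple[str, ...]
    mode: str  # "abs_diff" | "quotient"
    v: np.ndarray  # symmetric; NaN marks undefined pairs (sign changes)

    def __post_init__(self) -> None:
        if self.mode not in ("abs_diff", "quotient"):
            raise ValidationError(f"unknown divergence mode {self.mode!r}")
        v = np.asarray(self.v, dtype=float)
        object.__setattr__(self, "v", v)


def patristic_phylum_matrix(
    tree: dendropy.Tree,
    mapping: dict,
) -> DistanceMatrix:
    """Average patristic distance between every pair of phyla.

    ``mapping`` sends tip labels to phylum names; tips absent from the
    mapping are ignored (their count is logged).  d[p, q] is the mean over
    all (tip in p, tip in q) pairs of the branch-length path distance.
    """
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is not None and edge.length is None:
            raise ValidationError("tree has edges without branch lengths")
    pdm = tree.phylogenetic_distance_matrix()
    by_phylum: dict[str, list] = {}
    n_unmapped = 0
    for taxon in tree.taxon_namespace:
        phylum = mapping.get(taxon.label)
        if phylum is None:
            n_unmapped += 1
            continue
        by_phylum.setdefault(phylum, []).append(taxon)
    if n_unmapped:
        logger.info("patristic_phylum_matrix: %d unmapped tips ignored", n_unmapped)
    if len(by_phylum) < 2:
        raise InsufficientDataError("need >= 2 phyla with mapped tips")
    labels = tuple(sorted(by_phylum))
    n = len(labels)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        pairs = [
            pdm.patristic_distance(a, b)
            for a in by_phylum[labels[i]]
            for b in by_phylum[labels[j]]
        ]
        d[i, j] = d[j, i] = float(np.mean(pairs))
    return DistanceMatrix(labels, d)


def exponent_divergence(slopes: dict, mode: str = "abs_diff") -> DivergenceMatrix:
    """Pairwise divergence of per-phylum scaling exponents for one category.

    ``abs_diff``: |beta_p - beta_q| (diagonal 0).  ``quotient``:
    max/min >= 1 for same-sign slopes, NaN when the signs differ
    (diagonal 1).
    """
    defined = {p: s for p, s in slopes.items() if np.isfinite(s)}
    if len(defined) < 2:
        raise InsufficientDataError("need >= 2 phyla with defined slopes")
    labels = tuple(sorted(defined))
    beta = np.array([defined[p] for p in labels])
    n = len(labels)
    if mode == "abs_diff":
        v = np.abs(beta[:, None] - beta[None, :])
    elif mode == "quotient":
        v = np.full((n, n), np.nan)
        np.fill_diagonal(v, 1.0)
        for i, j in itertools.combinations(range(n), 2):
            a, b = beta[i], beta[j]
            if a * b > 0:
                q = max(abs(a), abs(b)) / min(abs(a), abs(b))
                v[i, j] = v[j, i] = q
    else:
        raise ValidationError(f"unknown divergence mode {mode!r}")
    return DivergenceMatrix(labels, mode, v)


def _upper_pairs(dm: DistanceMatrix, vm: DivergenceMatrix):
    if dm.labels != vm.labels:
        common = [l for l in dm.labels if l in vm.labels]
        if len(common) < 3:
            raise InsufficientDataError("fewer than 3 shared phyla")
        dm = dm.reorder(common)
        idx = [vm.labels.index(l) for l in common]
        vm = DivergenceMatrix(tuple(common), vm.mode, vm.v[np.ix_(idx, idx)])
    iu = np.triu_indices(len(dm.labels), k=1)
    x, y = dm.d[iu], vm.v[iu]
    keep = np.isfinite(y)
    return x[keep], y[keep]


def distance_divergence_association(
    dm: DistanceMatrix,
    vm: DivergenceMatrix,
    method: str = "spearman",
    *,
    mantel_permutations: int = 0,
    seed: int = 0,
):
    """Correlation between phylogenetic distance and exponent divergence.

    Computed over upper-triangle phylum pairs with defined divergence.
    Returns ``(statistic, n_pairs)``; with ``mantel_permutations > 0``
    returns ``(statistic, n_pairs, mantel_p)`` where the p-value comes from
    permuting phylum labels of the divergence matrix.  Pairs sharing a
    phylum are not independent; no correction is applied beyond the
    optional Mantel test.
    """
    if method not in ("pearson", "spearman"):
        raise ValidationError(f"method must be pearson or spearman, got {method!r}")
    if len(dm.labels) < 3:
        raise InsufficientDataError("need >= 3 phyla")
    x, y = _upper_pairs(dm, vm)
    if len(x) < 3:
        raise InsufficientDataError("fewer than 3 defined pairs")
    corr = stats.pearsonr if method == "pearson" else stats.spearmanr
    stat = float(corr(x, y).statistic)
    if mantel_permutations <= 0:
        return stat, len(x)
    rng = np.random.default_rng(seed)
    n = len(dm.labels)
    count = 0
    for _ in range(mantel_permutations):
        perm = rng.permutation(n)
        vperm = DivergenceMatrix(dm.labels, vm.mode, vm.v[np.ix_(perm, perm)])
        xp, yp = _upper_pairs(dm, vperm)
        if len(xp) < 3:
            continue
        if abs(float(corr(xp, yp).statistic)) >= abs(stat):
            count += 1
    p = (count + 1) / (mantel_permutations + 1)
    return stat, len(x), p
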