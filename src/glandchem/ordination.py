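"""Ordination: principal coordinates (classical scaling) and non-metric MDS.

PCoA follows Gower: square the dissimilarities, double-center
G = -1/2 J A J with A = (d_ij^2) and J = I - 11'/n, and eigendecompose.
Axes from positive eigenvalues are the real configuration (scaled by
sqrt(lambda)); negative eigenvalues — expected for semi-metric input such as
Bray-Curtis — are kept separately as "imaginary" axes so dispersion analysis
can correct squared distances with them.

nMDS minimizes Kruskal stress-1,

    stress = sqrt( sum (dhat_ij - theta(d_ij))^2 / sum dhat_ij^2 ),

where dhat are configuration distances and theta is the monotone (isotonic)
regression of dhat on the rank order of the input dissimilarities, by
iterative majorization (Guttman transform) with a monotone-regression step
each iteration.  Ties in the input are handled by the primary (weak)
approach, which is what least-squares isotonic regression on tied
predictors yields.  Several starts are used (one seeded from PCoA, the rest
random) and the lowest-stress configuration is kept.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression

from .dissimilarity import DissimilarityMatrix
from .profile_io import ProfileError

logger = logging.getLogger(__name__)

_EIG_TOL = 1e-9  # relative cutoff separating signal from numerically-zero eigenvalues


@dataclass
class PCoAResult:
    sample_ids: list[str]
    coordinates: np.ndarray            # (n, m) real axes, scaled by sqrt(eigenvalue)
    imaginary_coordinates: np.ndarray  # (n, m') axes for negative eigenvalues
    eigenvalues: np.ndarray            # all n, descending
    variance_explained: np.ndarray     # per real axis, over the positive part

    @property
    def has_negative_eigenvalues(self) -> bool:
        return self.imaginary_coordinates.shape[1] > 0


@dataclass
class NMDSResult:
    sample_ids: list[str]
    coordinates: np.ndarray
    stress: float
    n_iterations: int
    converged: bool
    best_of: int
    stress_history: list[float]


def gower_center(d_values: np.ndarray) -> np.ndarray:
    """G = -1/2 J A J for A = d^2; the workhorse shared with PERMANOVA."""
    a = -0.5 * np.asarray(d_values, dtype=float) ** 2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def pcoa(d: DissimilarityMatrix) -> PCoAResult:
    if d.n < 3:
        raise ProfileError("PCoA needs at least 3 samples")
    g = gower_center(d.values)
    eigval, eigvec = np.linalg.eigh(g)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    scale = np.abs(eigval).max()
    tol = _EIG_TOL * max(scale, 1.0)
    pos = eigval > tol
    neg = eigval < -tol
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    imag = eigvec[:, neg] * np.sqrt(-eigval[neg])
    pos_sum = eigval[pos].sum()
    var = eigval[pos] / pos_sum if pos_sum > 0 else np.zeros(0)
    if neg.any():
        logger.info(
            "PCoA: %d negative eigenvalues (semi-metric input), most negative %.3g",
            int(neg.sum()), eigval.min(),
        )
    return PCoAResult(list(d.sample_ids), coords, imag, eigval, var)


def _kruskal_stress(dhat: np.ndarray, disp: np.ndarray) -> float:
    denom = float((dhat**2).sum())
    if denom == 0:
        return 0.0
    return float(np.sqrt(((dhat - disp) ** 2).sum() / denom))


def nmds(
    d: DissimilarityMatrix,
    k: int = 3,
    n_starts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-7,
    seed: int = 0,
) -> NMDSResult:
    """Best-of-``n_starts`` Kruskal non-metric MDS in ``k`` dimensions.

    Deterministic for a fixed seed.  Within a start, an iteration is accepted
    only if it does not increase stress, so the stress history is
    non-increasing by contract; a start that stalls is cut short.
    """
    if k < 1:
        raise ProfileError("nMDS dimension must be >= 1")
    if d.n < 3:
        raise ProfileError("nMDS needs at least 3 samples")
    rng = np.random.default_rng(seed)
    dvec = squareform(d.values, checks=False)
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")

    def disparities(dhat: np.ndarray) -> np.ndarray:
        # primary (weak) tie treatment: tied dissimilarities ordered by their
        # current configuration distances before the monotone fit
        order = np.lexsort((dhat, dvec))
        fitted = iso.fit_transform(np.arange(dvec.size), dhat[order])
        out = np.empty_like(fitted)
        out[order] = fitted
        return out

    inits: list[np.ndarray] = []
    try:
        pc = pcoa(d)
        m = min(k, pc.coordinates.shape[1])
        init0 = np.zeros((d.n, k))
        init0[:, :m] = pc.coordinates[:, :m]
        inits.append(init0)
    except ProfileError:
        pass
    while len(inits) < max(1, n_starts):
        inits.append(rng.normal(size=(d.n, k)))

    best: NMDSResult | None = None
    for s, x0 in enumerate(inits):
        x = x0 - x0.mean(axis=0)
        dhat = pdist(x)
        disp = disparities(dhat)
        stress = _kruskal_stress(dhat, disp)
        history = [stress]
        converged = False
        for it in range(1, max_iter + 1):
            # Guttman transform toward the current disparities
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(dhat > 0, disp / dhat, 0.0)
            b = squareform(-ratio, checks=False)
            np.fill_diagonal(b, -b.sum(axis=1))
            x_new = b @ x / d.n
            dhat_new = pdist(x_new)
            disp_new = disparities(dhat_new)
            stress_new = _kruskal_stress(dhat_new, disp_new)
            if stress_new > stress:  # reject: stress-1 must not increase
                converged = True
                break
            x, dhat, disp = x_new, dhat_new, disp_new
            improved = stress - stress_new
            stress = stress_new
            history.append(stress)
            if improved < tol:
                converged = True
                break
        if not converged:
            warnings.warn(f"nMDS start {s} did not converge in {max_iter} iterations")
        cand = NMDSResult(
            list(d.sample_ids), x - x.mean(axis=0), stress,
            n_iterations=len(history) - 1, converged=converged,
            best_of=len(inits), stress_history=history,
        )
        if best is None or cand.stress < best.stress:
            best = cand
    assert best is not None
    return best
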