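"""Duplicate/relative detection and ancestry structure.

Kinship uses the PLINK-style method-of-moments estimator of genome-wide IBD
sharing from per-variant IBS states given allele frequencies; pairs with
PI_HAT above a threshold (default 0.25, flagging duplicates, first- and
second-degree relatives) are resolved by dropping the lower-call-rate
member.  Ancestry structure uses classical metric MDS (double-centered
squared-distance eigendecomposition) of pairwise IBS distances, with
bivariate-normal density outlier removal on a chosen component pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datamodel import MISSING, GenotypeMatrix, logger


@dataclass(frozen=True)
class KinshipEstimate:
    sample_a: str
    sample_b: str
    ibs_distance: float
    p_ibd0: float
    p_ibd1: float
    p_ibd2: float
    pi_hat: float
    low_confidence: bool = False


@dataclass(frozen=True)
class MDSCoordinates:
    sample_ids: tuple[str, ...]
    coords: np.ndarray  # n_samples x k, columns ordered by decreasing eigenvalue
    eigenvalues: np.ndarray

    @property
    def k(self) -> int:
        return self.coords.shape[1]

    def component(self, i: int) -> np.ndarray:
        """1-based component accessor (c1 = component(1))."""
        return self.coords[:, i - 1]


# ---------------------------------------------------------------------------
# IBS / IBD machinery

def _onehot(g: GenotypeMatrix) -> tuple[np.ndarray, ...]:
    c = g.codes
    return ((c == 0).astype(np.float64), (c == 1).astype(np.float64),
            (c == 2).astype(np.float64), (c != MISSING).astype(np.float64))


def _ibd_weights(g: GenotypeMatrix) -> tuple[np.ndarray, ...]:
    """Per-variant IBS-state probabilities under IBD 0 and 1.

    Allele frequencies are estimated from the same sample, so the naive
    plug-in probabilities (2p²q² etc.) are biased; instead each pair's
    alleles are treated as draws without replacement from the observed
    allele pool (counts n_a minor, n_A major, T total), the finite-sample
    correction used by the standard genome-wide MoM IBD estimator.  Without
    it, IBD-sharing estimates for unrelated pairs are systematically
    inflated at panel-scale variant counts.
    """
    valid = g.codes != MISSING
    t = 2 * valid.sum(axis=0).astype(float)          # alleles observed
    na = np.where(valid, g.codes, 0).sum(axis=0).astype(float)  # minor count
    nb = t - na
    t = np.maximum(t, 4)

    def fall(x, k):  # falling factorial x(x-1)...(x-k+1)
        out = np.ones_like(x)
        for i in range(k):
            out = out * np.clip(x - i, 0, None)
        return out

    t4 = fall(t, 4)
    t2 = fall(t, 2)
    w_ibs0_ibd0 = 2 * fall(na, 2) * fall(nb, 2) / t4
    w_ibs2_ibd0 = (fall(na, 4) + fall(nb, 4)
                   + 4 * na * nb * (na - 1) * (nb - 1)) / t4
    w_ibs1_ibd0 = 1 - w_ibs0_ibd0 - w_ibs2_ibd0
    w_ibs2_ibd1 = (fall(na, 2) + fall(nb, 2)) / t2
    w_ibs1_ibd1 = 2 * na * nb / t2
    return w_ibs0_ibd0, w_ibs1_ibd0, w_ibs2_ibd0, w_ibs1_ibd1, w_ibs2_ibd1


def _pair_matrices(g: GenotypeMatrix):
    """Pairwise IBS-state counts and expected-state sums over shared-valid
    variants, for all sample pairs at once."""
    i0, i1, i2, v = _onehot(g)
    n_ibs0 = i0 @ i2.T + i2 @ i0.T
    n_ibs2 = i0 @ i0.T + i1 @ i1.T + i2 @ i2.T
    n_valid = v @ v.T
    n_ibs1 = n_valid - n_ibs0 - n_ibs2
    w00, w10, w20, w11, w21 = _ibd_weights(g)
    # per-pair sums of each weight over variants valid in both samples
    sums = {name: (v * w) @ v.T
            for name, w in (("s0_ibd0", w00), ("s1_ibd0", w10), ("s2_ibd0", w20),
                            ("s1_ibd1", w11), ("s2_ibd1", w21))}
    return n_ibs0, n_ibs1, n_ibs2, n_valid, sums


def _mom_ibd(n0, n1, n2, n_valid, sums):
    """Method-of-moments IBD state probabilities, clamped and renormalized."""
    with np.errstate(invalid="ignore", divide="ignore"):
        p0 = n0 / sums["s0_ibd0"]
        p1 = (n1 - p0 * sums["s1_ibd0"]) / sums["s1_ibd1"]
        p2 = (n2 - p0 * sums["s2_ibd0"] - p1 * sums["s2_ibd1"]) / n_valid
    p = np.stack([p0, p1, p2])
    p = np.clip(np.nan_to_num(p, nan=0.0), 0.0, 1.0)
    tot = p.sum(axis=0)
    tot = np.where(tot > 0, tot, 1.0)
    p /= tot
    return p[0], p[1], p[2]


def kinship_matrix(g: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(pi_hat, ibs_distance, n_shared_valid) matrices over all sample pairs."""
    n0, n1, n2, n_valid, sums = _pair_matrices(g)
    p0, p1, p2 = _mom_ibd(n0, n1, n2, n_valid, sums)
    pi_hat = p1 / 2 + p2
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = (n1 + 2 * n0) / (2 * n_valid)
    return pi_hat, np.nan_to_num(dist, nan=0.0), n_valid


def estimate_kinship(g: GenotypeMatrix, pair: tuple[str, str]) -> KinshipEstimate:
    """Method-of-moments IBD estimate for one sample pair.

    Estimates with fewer than 100 shared-valid variants are flagged
    low-confidence; fewer than 2 is a domain error.
    """
    ids = [s.id for s in g.samples]
    ia, ib = ids.index(pair[0]), ids.index(pair[1])
    sub = g.subset_samples(np.array([ia, ib]))
    n0, n1, n2, n_valid, sums = _pair_matrices(sub)
    if n_valid[0, 1] < 2:
        raise ValueError(f"pair {pair}: fewer than 2 informative variants")
    # recompute weights on the full matrix's allele frequencies
    w00, w10, w20, w11, w21 = _ibd_weights(g)
    va = g.codes[ia] != MISSING
    vb = g.codes[ib] != MISSING
    both = va & vb
    sums = {"s0_ibd0": w00[both].sum(), "s1_ibd0": w10[both].sum(),
            "s2_ibd0": w20[both].sum(), "s1_ibd1": w11[both].sum(),
            "s2_ibd1": w21[both].sum()}
    p0, p1, p2 = _mom_ibd(n0[0, 1], n1[0, 1], n2[0, 1], n_valid[0, 1], sums)
    pi = float(p1 / 2 + p2)
    return KinshipEstimate(
        sample_a=pair[0], sample_b=pair[1],
        ibs_distance=float((n1[0, 1] + 2 * n0[0, 1]) / (2 * n_valid[0, 1])),
        p_ibd0=float(p0), p_ibd1=float(p1), p_ibd2=float(p2), pi_hat=pi,
        low_confidence=bool(n_valid[0, 1] < 100))


def exclude_related(
    g: GenotypeMatrix, pi_hat_max: float = 0.25
) -> tuple[GenotypeMatrix, list[str]]:
    """Drop samples until no pair has PI_HAT above the threshold.

    From each flagged pair the lower-call-rate member is dropped (ties: the
    later sample in panel order); edges involving dropped samples vanish, so
    the final set always passes a full recheck.
    """
    pi_hat, _, _ = kinship_matrix(g)
    n = g.n_samples
    call = (g.codes != MISSING).mean(axis=1)
    iu = np.triu_indices(n, k=1)
    flagged = [(pi_hat[i, j], i, j) for i, j in zip(*iu) if pi_hat[i, j] > pi_hat_max]
    flagged.sort(key=lambda t: (-t[0], t[1], t[2]))
    removed: set[int] = set()
    for _, i, j in flagged:
        if i in removed or j in removed:
            continue
        if call[i] < call[j]:
            removed.add(i)
        elif call[j] < call[i]:
            removed.add(j)
        else:
            removed.add(max(i, j))
    keep = np.array([i not in removed for i in range(n)])
    excluded_ids = [g.samples[i].id for i in sorted(removed)]
    if excluded_ids:
        logger.info("exclude_related: removed %d samples (PI_HAT > %g): %s",
                    len(excluded_ids), pi_hat_max, ", ".join(excluded_ids))
    return g.subset_samples(keep), excluded_ids


# ---------------------------------------------------------------------------
# MDS and outlier removal

def mds_components(g: GenotypeMatrix, k: int = 4) -> MDSCoordinates:
    """Classical metric MDS of pairwise IBS distances.

    Double-centers the squared-distance matrix and eigendecomposes;
    components are ordered by decreasing eigenvalue (stable index order on
    ties) and signed so each component's largest-magnitude loading is
    positive, making the output reproducible across runs.
    """
    n = g.n_samples
    if k > min(n - 1, g.n_variants):
        raise ValueError(f"k={k} exceeds min(n_samples - 1, n_variants)")
    _, dist, _ = kinship_matrix(g)
    if np.allclose(dist, 0):
        raise ValueError("degenerate input: all samples identical")
    d2 = dist**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    b = (b + b.T) / 2
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(-evals, kind="stable")
    evals, evecs = evals[order], evecs[:, order]
    lam = np.clip(evals[:k], 0, None)
    coords = evecs[:, :k] * np.sqrt(lam)
    for c in range(k):
        imax = np.argmax(np.abs(coords[:, c]))
        if coords[imax, c] < 0:
            coords[:, c] = -coords[:, c]
    return MDSCoordinates(sample_ids=tuple(s.id for s in g.samples),
                          coords=coords, eigenvalues=evals[:k])


def _normal_scores(x: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal transformation (Blom-style offsets)."""
    n = x.size
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - 0.375) / (n + 0.25))


def outlier_filter(
    coords: MDSCoordinates,
    which: tuple[int, int] = (1, 3),
    density_quantile: float = 0.01,
    transform: str = "normal-score",
) -> tuple[list[str], list[str]]:
    """Remove low-density points under a bivariate-normal fit to a component
    pair (default c1/c3, 1-based).

    Each component is transformed first (default: rank-based normal scores,
    robust to the heavy tails that motivate transformation; "identity" keeps
    the raw values).  A bivariate normal is fit by sample mean/covariance;
    points whose fitted density h falls below the ``density_quantile`` of
    all fitted densities are removed.  quantile 0 removes nothing.

    Returns (kept sample ids, removed sample ids).
    """
    x = coords.component(which[0]).astype(float)
    y = coords.component(which[1]).astype(float)
    if transform == "normal-score":
        x, y = _normal_scores(x), _normal_scores(y)
    elif transform != "identity":
        raise ValueError(f"unknown transform {transform!r}")
    xy = np.column_stack([x, y])
    mean = xy.mean(axis=0)
    cov = np.cov(xy, rowvar=False)
    if np.linalg.matrix_rank(cov) < 2:
        raise ValueError("singular covariance: density fit undefined")
    h = stats.multivariate_normal(mean=mean, cov=cov).pdf(xy)
    if density_quantile <= 0:
        thresh = -np.inf
    else:
        thresh = np.quantile(h, density_quantile, method="higher")
    removed_mask = h < thresh
    kept = [sid for sid, r in zip(coords.sample_ids, removed_mask) if not r]
    removed = [sid for sid, r in zip(coords.sample_ids, removed_mask) if r]
    return kept, removed
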