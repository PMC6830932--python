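"""Pairwise linkage disequilibrium from unphased genotypes.

Haplotype frequencies for a pair of biallelic variants are estimated by EM
over the double-heterozygote phase ambiguity; D' and r² follow from the
fitted frequencies.  A profile-likelihood grid over D' gives the one-sided
confidence bounds used for Gabriel-style "strong LD" block calling with the
conventional 0.7–0.98 bounds.

Missing data are handled pairwise-complete: samples missing either genotype
are excluded from that pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import MISSING, GenotypeMatrix

EM_TOL = 1e-10
EM_MAX_ITER = 1000


class LDUndefinedError(ValueError):
    """LD is undefined (a variant is monomorphic among informative samples)."""


@dataclass(frozen=True)
class LDResult:
    variant_a: str
    variant_b: str
    d_prime: float
    r2: float
    d_prime_ci: tuple[float, float]
    n_informative: int


@dataclass(frozen=True)
class LDBlock:
    chrom: str
    variant_ids: tuple[str, ...]
    start_pos: int
    end_pos: int

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)


# ---------------------------------------------------------------------------
# EM haplotype frequencies

def _joint_table(g: GenotypeMatrix, ja: int, jb: int) -> np.ndarray:
    """3x3 table of joint minor-dose counts, pairwise-complete."""
    a = g.codes[:, ja]
    b = g.codes[:, jb]
    ok = (a != MISSING) & (b != MISSING)
    t = np.bincount(3 * a[ok].astype(int) + b[ok].astype(int), minlength=9)
    return t.reshape(3, 3)


def em_from_table(t: np.ndarray) -> np.ndarray:
    """EM haplotype frequencies (f11, f10, f01, f00) from a 3x3 joint
    genotype-count table (indices = minor-allele dose at each locus).

    Initialized at linkage equilibrium; iterates until the largest absolute
    frequency change is below 1e-10 or 1000 iterations.
    """
    t = np.asarray(t, dtype=float)
    n = t.sum()
    if n == 0:
        raise LDUndefinedError("no informative samples")
    pa = (2 * t[2, :].sum() + t[1, :].sum()) / (2 * n)
    pb = (2 * t[:, 2].sum() + t[:, 1].sum()) / (2 * n)
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        raise LDUndefinedError("monomorphic variant among informative samples")

    # haplotype counts known regardless of phase (minor allele = '1')
    base11 = 2 * t[2, 2] + t[2, 1] + t[1, 2]
    base10 = 2 * t[2, 0] + t[2, 1] + t[1, 0]
    base01 = 2 * t[0, 2] + t[0, 1] + t[1, 2]
    base00 = 2 * t[0, 0] + t[0, 1] + t[1, 0]
    n_dh = t[1, 1]  # double heterozygotes: (11,00) vs (10,01)

    f = np.array([pa * pb, pa * (1 - pb), (1 - pa) * pb, (1 - pa) * (1 - pb)])
    for _ in range(EM_MAX_ITER):
        coup = f[0] * f[3]
        rep = f[1] * f[2]
        alpha = coup / (coup + rep) if coup + rep > 0 else 0.5
        new = np.array([
            base11 + n_dh * alpha,
            base10 + n_dh * (1 - alpha),
            base01 + n_dh * (1 - alpha),
            base00 + n_dh * alpha,
        ]) / (2 * n)
        if np.abs(new - f).max() < EM_TOL:
            f = new
            break
        f = new
    return f


def em_haplotype_freqs(g: GenotypeMatrix, a: str, b: str) -> np.ndarray:
    """Haplotype frequencies (f_mm, f_mM, f_Mm, f_MM) for a variant pair,
    where lowercase m denotes each variant's minor allele."""
    return em_from_table(_joint_table(g, g.variant_index(a), g.variant_index(b)))


def ld_statistics(freqs: np.ndarray) -> tuple[float, float]:
    """(D', r²) from four haplotype frequencies (f11, f10, f01, f00).

    D = f11 - pA pB; D' = |D| / D_max with the usual sign-dependent bound;
    r² = D² / (pA (1-pA) pB (1-pB)).
    """
    f = np.asarray(freqs, dtype=float)
    if f.min() < -1e-9 or abs(f.sum() - 1) > 1e-6:
        raise ValueError("haplotype frequencies must be non-negative and sum to 1")
    pa = f[0] + f[1]
    pb = f[0] + f[2]
    if pa <= 0 or pa >= 1 or pb <= 0 or pb >= 1:
        raise LDUndefinedError("marginal allele frequency of 0 or 1")
    d = f[0] - pa * pb
    if d >= 0:
        d_max = min(pa * (1 - pb), (1 - pa) * pb)
    else:
        d_max = min(pa * pb, (1 - pa) * (1 - pb))
    d_prime = abs(d) / d_max if d_max > 0 else 0.0
    r2 = d * d / (pa * (1 - pa) * pb * (1 - pb))
    return float(min(d_prime, 1.0)), float(min(r2, 1.0))


# ---------------------------------------------------------------------------
# D' confidence bounds (profile-likelihood grid)

def _genotype_probs(f: np.ndarray) -> np.ndarray:
    """3x3 joint genotype probabilities from haplotype frequencies under
    random mating (Hardy-Weinberg at the haplotype level)."""
    dose_a = np.array([1, 1, 0, 0])
    dose_b = np.array([1, 0, 1, 0])
    probs = np.zeros((3, 3))
    for h1 in range(4):
        for h2 in range(4):
            probs[dose_a[h1] + dose_a[h2], dose_b[h1] + dose_b[h2]] += f[h1] * f[h2]
    return probs


def d_prime_ci_from_table(t: np.ndarray, n_grid: int = 101) -> tuple[float, float]:
    """Profile-likelihood bounds on D' from a 3x3 joint genotype table.

    Allele frequencies are fixed at their sample estimates and the sign of D
    at the EM solution's sign; the multinomial log-likelihood is evaluated on
    an ``n_grid``-point grid of D' in [0, 1], exponentiated to a normalized
    weight, and the 5th/95th weighted percentiles reported (a two-sided 90%
    interval, matching the conventional strong-LD definition).
    """
    t = np.asarray(t, dtype=float)
    f_hat = em_from_table(t)
    pa = f_hat[0] + f_hat[1]
    pb = f_hat[0] + f_hat[2]
    d_hat = f_hat[0] - pa * pb
    sign = 1.0 if d_hat >= 0 else -1.0
    if sign > 0:
        d_max = min(pa * (1 - pb), (1 - pa) * pb)
    else:
        d_max = min(pa * pb, (1 - pa) * (1 - pb))

    grid = np.linspace(0.0, 1.0, n_grid)
    loglik = np.empty(n_grid)
    for i, dp in enumerate(grid):
        d = sign * dp * d_max
        f = np.array([pa * pb + d, pa * (1 - pb) - d,
                      (1 - pa) * pb - d, (1 - pa) * (1 - pb) + d])
        f = np.clip(f, 0.0, 1.0)
        probs = _genotype_probs(f)
        with np.errstate(divide="ignore"):
            lp = np.where(t > 0, np.log(np.where(probs > 0, probs, 1e-300)), 0.0)
        loglik[i] = (t * lp).sum()
    w = np.exp(loglik - loglik.max())
    w /= w.sum()
    cum = np.cumsum(w)
    lower = float(grid[np.searchsorted(cum, 0.05)])
    upper = float(grid[min(np.searchsorted(cum, 0.95), n_grid - 1)])
    return lower, upper


def d_prime_ci(g: GenotypeMatrix, a: str, b: str,
               n_grid: int = 101) -> tuple[float, float]:
    return d_prime_ci_from_table(
        _joint_table(g, g.variant_index(a), g.variant_index(b)), n_grid=n_grid)


def ld_pair(g: GenotypeMatrix, a: str, b: str) -> LDResult:
    """Full pairwise LD summary (D', r², D' CI, informative n)."""
    t = _joint_table(g, g.variant_index(a), g.variant_index(b))
    f = em_from_table(t)
    dp, r2 = ld_statistics(f)
    ci = d_prime_ci_from_table(t)
    return LDResult(variant_a=a, variant_b=b, d_prime=dp, r2=r2,
                    d_prime_ci=ci, n_informative=int(t.sum()))


def r2_matrix(g: GenotypeMatrix, idx: list[int] | None = None) -> np.ndarray:
    """Pairwise EM-based r² among the given variant indices (default all).

    Pairs where LD is undefined (a monomorphic member) get r² = 0.
    """
    if idx is None:
        idx = list(range(g.n_variants))
    m = len(idx)
    out = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            try:
                f = em_from_table(_joint_table(g, idx[i], idx[j]))
                _, r2 = ld_statistics(f)
            except LDUndefinedError:
                r2 = 0.0
            out[i, j] = out[j, i] = r2
    return out


# ---------------------------------------------------------------------------
# block calling

def call_blocks(
    g: GenotypeMatrix,
    lower_bound: float = 0.7,
    upper_bound: float = 0.98,
    strong_fraction: float = 0.95,
) -> list[LDBlock]:
    """Gabriel-style LD blocks from D' confidence bounds.

    A pair is in "strong LD" when its D' CI lower bound >= ``lower_bound``
    and upper bound >= ``upper_bound``.  Blocks are maximal runs of
    consecutive variants (panel position order, per chromosome) in which at
    least ``strong_fraction`` of the informative pairs are strong-LD;
    non-overlapping, assigned greedily longest-first.  This is a simplified
    rule (no recombination-pair bookkeeping), intended for descriptive use.
    """
    by_chrom: dict[str, list[int]] = {}
    for j in sorted(range(g.n_variants),
                    key=lambda j: (g.variants[j].chrom, g.variants[j].pos)):
        by_chrom.setdefault(g.variants[j].chrom, []).append(j)

    blocks: list[LDBlock] = []
    for chrom, idx in by_chrom.items():
        m = len(idx)
        if m < 2:
            continue
        strong = np.zeros((m, m), dtype=bool)
        informative = np.zeros((m, m), dtype=bool)
        for i in range(m):
            for j in range(i + 1, m):
                try:
                    tab = _joint_table(g, idx[i], idx[j])
                    lo, hi = d_prime_ci_from_table(tab)
                except LDUndefinedError:
                    continue
                informative[i, j] = True
                strong[i, j] = lo >= lower_bound and hi >= upper_bound

        candidates = [(i, j) for i in range(m) for j in range(i + 1, m)]
        candidates.sort(key=lambda ij: (-(ij[1] - ij[0]), ij[0]))
        taken = np.zeros(m, dtype=bool)
        for i, j in candidates:
            if taken[i:j + 1].any():
                continue
            sub_inf = informative[i:j + 1, i:j + 1]
            n_inf = int(sub_inf.sum())
            if n_inf == 0:
                continue
            frac = strong[i:j + 1, i:j + 1].sum() / n_inf
            if frac >= strong_fraction:
                members = idx[i:j + 1]
                blocks.append(LDBlock(
                    chrom=chrom,
                    variant_ids=tuple(g.variants[k].id for k in members),
                    start_pos=min(g.variants[k].pos for k in members),
                    end_pos=max(g.variants[k].pos for k in members)))
                taken[i:j + 1] = True
    blocks.sort(key=lambda b: (b.chrom, b.start_pos))
    return blocks
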