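"""Conditional two-SNP genotype-combination analysis.

For a chosen *test* SNP, the sample is partitioned by its three genotypes
and the *target* SNP is tested against phenotype with a genotypic (2xK
Pearson) test within each stratum; stratum chi-squares and degrees of
freedom are summed (independent partitions), and the combined statistic is
referred to the chi-square upper tail.  Test SNPs are the panel variants
with the smallest permutation-corrected p under three single-SNP statistics
(genotypic, F, max(dominant, recessive)); the full scan over (test, target)
pairs is corrected family-wise by min-P permutation.  A flagged genotype
combination can be summarized as a carrier 2x2 table with a Woolf-CI odds
ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .association import Contingency2x2, odds_ratio_woolf
from .datamodel import MISSING, GenotypeMatrix, logger


@dataclass(frozen=True)
class StratumStat:
    test_genotype: int
    chi2: float
    df: int
    n: int


@dataclass(frozen=True)
class PairResult:
    test_snp: str
    target_snp: str
    stratum_stats: tuple[StratumStat, ...]
    combined_chi2: float
    combined_df: int
    p: float
    corrected_p: float | None = None
    degenerate: bool = False


@dataclass(frozen=True)
class ComboResult:
    table: Contingency2x2
    odds_ratio: float | None
    ci95: tuple[float, float] | None
    case_prop: float
    control_prop: float


@dataclass(frozen=True)
class TestSnpSelection:
    selected_ids: tuple[str, ...]
    corrected_p: dict[str, dict[str, float]] = field(default_factory=dict)
    seed: int = 0


# ---------------------------------------------------------------------------
# stratified pair test

def _stratum_test(tab: np.ndarray) -> tuple[float, int]:
    """Pearson 2xK chi-square on a stratum's phenotype x genotype table,
    after dropping empty genotype columns.  Degenerate strata (one nonempty
    column, or an empty phenotype row) contribute (0, 0) so the combined df
    is never inflated."""
    tab = tab[:, tab.sum(axis=0) > 0]
    if tab.shape[1] < 2 or tab.sum(axis=1).min() == 0:
        return 0.0, 0
    x, _, df, _ = stats.chi2_contingency(tab, correction=False)
    return float(x), int(df)


def conditional_pair(g: GenotypeMatrix, test_snp: str, target_snp: str) -> PairResult:
    """Genotype test of the target SNP within each test-SNP genotype stratum,
    combined by summing stratum chi-squares and degrees of freedom."""
    jt = g.variant_index(test_snp)
    js = g.variant_index(target_snp)
    gt = g.codes[:, jt]
    gs = g.codes[:, js]
    pheno_case = g.case_mask
    use = (gt != MISSING) & (gs != MISSING) & (g.case_mask | g.control_mask)

    strata = []
    combined_chi2, combined_df = 0.0, 0
    for t_geno in (0, 1, 2):
        sel = use & (gt == t_geno)
        tab = np.zeros((2, 3))
        for s_geno in (0, 1, 2):
            tab[0, s_geno] = int((sel & pheno_case & (gs == s_geno)).sum())
            tab[1, s_geno] = int((sel & ~pheno_case & (gs == s_geno)).sum())
        x, df = _stratum_test(tab)
        strata.append(StratumStat(test_genotype=t_geno, chi2=x, df=df,
                                  n=int(tab.sum())))
        combined_chi2 += x
        combined_df += df

    degenerate = combined_df == 0
    p = 1.0 if degenerate else float(stats.chi2.sf(combined_chi2, combined_df))
    return PairResult(test_snp=test_snp, target_snp=target_snp,
                      stratum_stats=tuple(strata), combined_chi2=combined_chi2,
                      combined_df=combined_df, p=p, degenerate=degenerate)


# ---------------------------------------------------------------------------
# vectorized permutation machinery shared by selection and the scan

def _perm_phenotypes(pheno: np.ndarray, n_perm: int,
                     rng: np.random.Generator, block: int = 2000):
    """Yield blocks of permuted 0/1 phenotype matrices (n_block x n)."""
    done = 0
    while done < n_perm:
        nb = min(block, n_perm - done)
        yield rng.permuted(np.tile(pheno, (nb, 1)), axis=1)
        done += nb


def _chi2_2xk_from_counts(c: np.ndarray, n_g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized 2xK Pearson chi-square over the trailing axis.

    ``c``: cases per genotype column (…, K); ``n_g``: fixed column totals
    (broadcastable).  Empty columns must already carry n_g = 0 and are
    ignored.  Returns (chi2, df) with df = nonempty columns - 1 (0 where the
    phenotype margin is degenerate)."""
    n = n_g.sum(axis=-1)
    cc = c.sum(axis=-1)
    nonempty = n_g > 0
    k = nonempty.sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        e = n_g * (cc[..., None] / n[..., None])
        dev = np.where(nonempty, (c - e) ** 2 / np.where(nonempty, n_g, 1), 0.0)
        x = dev.sum(axis=-1) * n**2 / (n * cc * (n - cc))
    ok = (k >= 2) & (cc > 0) & (cc < n)
    x = np.where(ok, x, 0.0)
    df = np.where(ok, k - 1, 0)
    return x, df


def _f_from_counts(c: np.ndarray, n_g: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized one-way ANOVA F of the 0/1 phenotype across genotype groups."""
    n = n_g.sum(axis=-1)
    cc = c.sum(axis=-1)
    nonempty = n_g > 0
    k = nonempty.sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        m = np.where(nonempty, c / np.where(nonempty, n_g, 1), 0.0)
        grand = (cc / n)[..., None]
        ssb = (np.where(nonempty, n_g, 0) * (m - grand) ** 2).sum(axis=-1)
        ssw = (np.where(nonempty, n_g, 0) * m * (1 - m)).sum(axis=-1)
        df1 = k - 1
        df2 = n - k
        f = (ssb / np.maximum(df1, 1)) / (ssw / np.maximum(df2, 1))
    ok = (df1 >= 1) & (df2 >= 1) & (ssw > 0)
    return np.where(ok, f, 0.0), df1, df2


def _max_dr_from_counts(c: np.ndarray, n_g: np.ndarray) -> np.ndarray:
    """Vectorized max(dominant, recessive) 2x2 chi-square.

    ``c``/``n_g`` columns are minor-allele dose 0,1,2."""
    n = n_g.sum(axis=-1)
    cc = c.sum(axis=-1)
    out = np.zeros(np.broadcast_shapes(cc.shape, n.shape))
    for expo_cols in ((1, 2), (2,)):
        a = sum(c[..., j] for j in expo_cols)
        n_exp = sum(n_g[..., j] for j in expo_cols)
        b = cc - a
        cC = n_exp - a
        d = n - n_exp - b
        den = n_exp * (n - n_exp) * cc * (n - cc)
        with np.errstate(invalid="ignore", divide="ignore"):
            x = n * (a * d - b * cC) ** 2 / den
        out = np.maximum(out, np.where(den > 0, x, 0.0))
    return out


def _dose_indicators(g: GenotypeMatrix, use: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(samples x variants x 3) genotype indicators and fixed column totals."""
    codes = g.codes[use]
    ind = np.stack([(codes == d) for d in (0, 1, 2)], axis=2).astype(np.float64)
    return ind, ind.sum(axis=0)


def select_test_snps(
    g: GenotypeMatrix, n_perm: int = 10_000, seed: int = 0, n_select: int = 4,
) -> TestSnpSelection:
    """Pick the ``n_select`` variants with the smallest permutation-corrected
    p over three statistics: the genotypic 2xK test, the phenotype-indicator
    F test, and the max(dominant, recessive) chi-square.

    Each statistic family is corrected family-wise by min-P/max-T over the
    panel from a shared set of phenotype permutations; each variant scores
    its minimum corrected p across the three.  Ties break toward the larger
    observed (max-test) statistic, then panel order.
    """
    use = g.case_mask | g.control_mask
    pheno = np.where(g.case_mask, 1.0, 0.0)[use]
    ind, n_g = _dose_indicators(g, use)
    n_samp, m, _ = ind.shape
    flat = ind.reshape(n_samp, m * 3)

    c_obs = (pheno @ flat).reshape(m, 3)
    x_obs, df_obs = _chi2_2xk_from_counts(c_obs, n_g)
    p_geno_obs = np.where(df_obs > 0, stats.chi2.sf(x_obs, np.maximum(df_obs, 1)), 1.0)
    f_obs, df1_o, df2_o = _f_from_counts(c_obs, n_g)
    p_f_obs = np.where(df1_o > 0, stats.f.sf(f_obs, np.maximum(df1_o, 1),
                                             np.maximum(df2_o, 1)), 1.0)
    max_obs = _max_dr_from_counts(c_obs, n_g)

    rng = np.random.default_rng(seed)
    cnt = {k: np.zeros(m) for k in
           ("geno_corr", "geno_point", "f_corr", "f_point", "max_corr", "max_point")}
    for perms in _perm_phenotypes(pheno, n_perm, rng):
        c = (perms @ flat).reshape(perms.shape[0], m, 3)
        x, df = _chi2_2xk_from_counts(c, n_g[None])
        p_geno = np.where(df > 0, stats.chi2.sf(x, np.maximum(df, 1)), 1.0)
        cnt["geno_point"] += (p_geno <= p_geno_obs + 1e-12).sum(axis=0)
        cnt["geno_corr"] += (p_geno.min(axis=1)[:, None] <= p_geno_obs + 1e-12).sum(axis=0)
        fstat, df1, df2 = _f_from_counts(c, n_g[None])
        p_f = np.where(df1 > 0, stats.f.sf(fstat, np.maximum(df1, 1),
                                           np.maximum(df2, 1)), 1.0)
        cnt["f_point"] += (p_f <= p_f_obs + 1e-12).sum(axis=0)
        cnt["f_corr"] += (p_f.min(axis=1)[:, None] <= p_f_obs + 1e-12).sum(axis=0)
        mx = _max_dr_from_counts(c, n_g[None])
        cnt["max_point"] += (mx >= max_obs - 1e-12).sum(axis=0)
        cnt["max_corr"] += (mx.max(axis=1)[:, None] >= max_obs - 1e-12).sum(axis=0)

    corr = {k: (1 + cnt[k]) / (n_perm + 1) for k in cnt}
    min_corr = np.minimum(np.minimum(corr["geno_corr"], corr["f_corr"]),
                          corr["max_corr"])
    order = sorted(range(m), key=lambda j: (min_corr[j], -max_obs[j], j))
    n_select = min(n_select, m)
    if m < 4:
        logger.warning("select_test_snps: panel smaller than 4; selecting all")
    selected = tuple(g.variants[j].id for j in order[:n_select])
    per_variant = {
        g.variants[j].id: {
            "genotypic": float(corr["geno_corr"][j]),
            "f": float(corr["f_corr"][j]),
            "max": float(corr["max_corr"][j]),
        } for j in range(m)}
    return TestSnpSelection(selected_ids=selected, corrected_p=per_variant, seed=seed)


def conditional_scan(
    g: GenotypeMatrix,
    selection: TestSnpSelection,
    n_perm: int = 10_000,
    seed: int = 0,
    targets: list[str] | None = None,
) -> list[PairResult]:
    """All (test, target) pairs, corrected family-wise by min-P permutation.

    Per permutation of the phenotype labels every pair's combined stratified
    chi-square is recomputed (strata and their degrees of freedom are fixed
    by the genotypes); corrected p for a pair is the fraction of
    permutations whose scan-wide minimum p undercuts the pair's observed p.
    Results are ranked by corrected then pointwise p.
    """
    target_ids = targets if targets is not None else [v.id for v in g.variants]
    pairs = [(t, s) for t in selection.selected_ids for s in target_ids if s != t]
    use = g.case_mask | g.control_mask
    pheno = np.where(g.case_mask, 1.0, 0.0)[use]
    codes = g.codes[use]
    n_samp = codes.shape[0]

    observed = [conditional_pair(g, t, s) for t, s in pairs]
    p_obs = np.array([r.p for r in observed])

    # per pair: 9-category indicator (3 test x 3 target genotypes); samples
    # missing either genotype fall in no category
    n_pairs = len(pairs)
    ind = np.zeros((n_samp, n_pairs, 9), dtype=np.float64)
    dfs = np.zeros(n_pairs, dtype=np.int64)
    for k, (t, s) in enumerate(pairs):
        gt = codes[:, g.variant_index(t)]
        gs = codes[:, g.variant_index(s)]
        ok = (gt != MISSING) & (gs != MISSING)
        cat = 3 * gt[ok].astype(int) + gs[ok].astype(int)
        ind[np.flatnonzero(ok), k, cat] = 1.0
        dfs[k] = observed[k].combined_df
    flat = ind.reshape(n_samp, n_pairs * 9)
    n_cat = ind.sum(axis=0)  # n_pairs x 9

    rng = np.random.default_rng(seed)
    point_cnt = np.zeros(n_pairs)
    min_cnt = np.zeros(n_pairs)
    safe_df = np.maximum(dfs, 1)
    for perms in _perm_phenotypes(pheno, n_perm, rng, block=500):
        c = (perms @ flat).reshape(perms.shape[0], n_pairs, 9)
        chi = np.zeros((perms.shape[0], n_pairs))
        for st in range(3):
            x, _ = _chi2_2xk_from_counts(c[:, :, 3 * st:3 * st + 3],
                                         n_cat[None, :, 3 * st:3 * st + 3])
            chi += x
        p = np.where(dfs[None] > 0, stats.chi2.sf(chi, safe_df[None]), 1.0)
        point_cnt += (p <= p_obs[None] + 1e-12).sum(axis=0)
        min_cnt += (p.min(axis=1)[:, None] <= p_obs[None] + 1e-12).sum(axis=0)

    results = []
    for k, r in enumerate(observed):
        results.append(PairResult(
            test_snp=r.test_snp, target_snp=r.target_snp,
            stratum_stats=r.stratum_stats, combined_chi2=r.combined_chi2,
            combined_df=r.combined_df,
            p=float((1 + point_cnt[k]) / (n_perm + 1)),
            corrected_p=float((1 + min_cnt[k]) / (n_perm + 1)),
            degenerate=r.degenerate))
    results.sort(key=lambda r: (r.corrected_p, r.p, r.test_snp, r.target_snp))
    return results


# ---------------------------------------------------------------------------
# combined-genotype odds ratio

def combo_genotype_or(
    g: GenotypeMatrix,
    snp_a: str, genotype_set_a: set[int],
    snp_b: str, genotype_set_b: set[int],
) -> ComboResult:
    """Carrier 2x2 table and Woolf-CI odds ratio for a genotype combination.

    A carrier is a sample whose genotype at ``snp_a`` is in
    ``genotype_set_a`` *and* at ``snp_b`` in ``genotype_set_b`` (intersection
    by definition, so carrier counts never exceed either single-SNP count);
    samples missing either genotype are excluded.
    """
    for name, s in (("genotype_set_a", genotype_set_a), ("genotype_set_b", genotype_set_b)):
        if not s or not s.issubset({0, 1, 2}):
            raise ValueError(f"{name} must be a nonempty subset of {{0,1,2}}")
    ga = g.codes[:, g.variant_index(snp_a)]
    gb = g.codes[:, g.variant_index(snp_b)]
    ok = (ga != MISSING) & (gb != MISSING)
    carrier = ok & np.isin(ga, list(genotype_set_a)) & np.isin(gb, list(genotype_set_b))
    ca = g.case_mask & ok
    co = g.control_mask & ok
    t = Contingency2x2(
        a=int((carrier & ca).sum()), b=int((~carrier & ca).sum()),
        c=int((carrier & co).sum()), d=int((~carrier & co).sum()))
    if t.a + t.c == 0:
        raise ValueError("no carriers of the genotype combination")
    orr, ci = odds_ratio_woolf(t)
    return ComboResult(
        table=t, odds_ratio=orr, ci95=ci,
        case_prop=float(t.a / (t.a + t.b)) if t.a + t.b else float("nan"),
        control_prop=float(t.c / (t.c + t.d)) if t.c + t.d else float("nan"))
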