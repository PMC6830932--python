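"""Single-SNP case-control association tests.

Implements the per-variant tests used for a candidate-panel case-control
study: genotypic (2xK Pearson), dominant/recessive collapsed 2x2 chi-square
(no continuity correction by default), allelic 2x2, a max(dominant,
recessive) permutation test, odds ratios with Woolf confidence intervals,
a covariate-free logistic-regression cross-check, and max-T permutation
correction for testing many variants at once.

Models are defined with respect to the minor allele: "dominant" collapses
carriers of >= 1 minor allele against non-carriers, "recessive" collapses
minor-allele homozygotes against the rest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datamodel import MISSING, GenotypeCountRow, GenotypeMatrix

DOMINANT = "dominant"
RECESSIVE = "recessive"
GENOTYPIC = "genotypic"
ALLELIC = "allelic"
MAX = "max"

COLLAPSED_MODELS = (DOMINANT, RECESSIVE)


@dataclass(frozen=True)
class Contingency2x2:
    """Collapsed 2x2 table: (cases exposed, cases unexposed,
    controls exposed, controls unexposed).  "Exposed" is defined by the
    collapsing model (dominant: minor-allele carrier; recessive:
    minor-allele homozygote)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def has_zero_margin(self) -> bool:
        return (self.a + self.b == 0 or self.c + self.d == 0
                or self.a + self.c == 0 or self.b + self.d == 0)


@dataclass(frozen=True)
class AssocResult:
    variant_id: str
    model: str
    chi2: float
    df: int
    p: float
    odds_ratio: float | None = None
    ci95: tuple[float, float] | None = None
    table: Contingency2x2 | tuple | None = None
    degenerate: bool = False


@dataclass(frozen=True)
class PermutationResult:
    variant_id: str
    model: str
    pointwise_p: float
    corrected_p: float
    n_permutations: int
    seed: int


# ---------------------------------------------------------------------------
# collapsing and 2x2 machinery

def collapse(row: GenotypeCountRow, model: str) -> Contingency2x2:
    """Collapse a genotype-count row to a 2x2 table under a 1-df model."""
    hm_ca, het_ca, hM_ca = row.case_counts
    hm_co, het_co, hM_co = row.control_counts
    if model == DOMINANT:
        return Contingency2x2(hm_ca + het_ca, hM_ca, hm_co + het_co, hM_co)
    if model == RECESSIVE:
        return Contingency2x2(hm_ca, het_ca + hM_ca, hm_co, het_co + hM_co)
    if model == ALLELIC:
        return Contingency2x2(2 * hm_ca + het_ca, 2 * hM_ca + het_ca,
                              2 * hm_co + het_co, 2 * hM_co + het_co)
    raise ValueError(f"collapse undefined for model {model!r}")


def chi2_2x2(t: Contingency2x2, continuity: bool = False) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, 1 df.

    No continuity correction by default (the variant that matches standard
    PLINK model tests); pass ``continuity=True`` for the Yates-corrected
    statistic.  A zero margin yields (0.0, 1.0).
    """
    a, b, c, d = t.cells
    if t.total == 0:
        raise ValueError("empty table")
    if t.has_zero_margin:
        return 0.0, 1.0
    n = t.total
    diff = abs(a * d - b * c)
    if continuity:
        diff = max(0.0, diff - n / 2)
    x = n * diff * diff / ((a + b) * (c + d) * (a + c) * (b + d))
    return float(x), float(stats.chi2.sf(x, 1))


def odds_ratio_woolf(
    t: Contingency2x2, haldane: bool = False
) -> tuple[float | None, tuple[float, float] | None]:
    """Odds ratio ad/(bc) with the Woolf 95% CI
    exp(ln OR +/- 1.96 * sqrt(1/a + 1/b + 1/c + 1/d)).

    With a zero cell the OR is undefined and (None, None) is returned unless
    ``haldane`` is set, which adds 0.5 to every cell (Haldane-Anscombe).
    """
    a, b, c, d = (float(x) for x in t.cells)
    if min(a, b, c, d) == 0:
        if not haldane:
            return None, None
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    orr = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = float(np.exp(np.log(orr) - 1.959963984540054 * se))
    hi = float(np.exp(np.log(orr) + 1.959963984540054 * se))
    return float(orr), (lo, hi)


def model_test(row: GenotypeCountRow, model: str,
               continuity: bool = False) -> AssocResult:
    """Collapsed 1-df test with OR and Woolf CI for one count row."""
    t = collapse(row, model)
    x, p = chi2_2x2(t, continuity=continuity)
    orr, ci = odds_ratio_woolf(t)
    return AssocResult(variant_id=row.variant.id, model=model, chi2=x, df=1,
                       p=p, odds_ratio=orr, ci95=ci, table=t,
                       degenerate=t.has_zero_margin)


# ---------------------------------------------------------------------------
# genotypic and F tests

def _case_control_2xk(row: GenotypeCountRow) -> np.ndarray:
    tab = np.array([row.case_counts, row.control_counts], dtype=float)
    return tab[:, tab.sum(axis=0) > 0]  # drop empty genotype columns


def genotypic_test(row: GenotypeCountRow) -> tuple[float, int, float]:
    """Pearson chi-square on the 2xK genotype table (K <= 3 after dropping
    empty columns), df = K - 1."""
    tab = _case_control_2xk(row)
    k = tab.shape[1]
    if k < 2 or tab.sum(axis=1).min() == 0:
        return 0.0, max(k - 1, 0), 1.0
    x, p, df, _ = stats.chi2_contingency(tab, correction=False)
    return float(x), int(df), float(p)


def f_test(row: GenotypeCountRow) -> tuple[float, int, int, float]:
    """One-way ANOVA F of the 0/1 phenotype indicator across genotype groups.

    Computed in closed form from the counts; equivalent to expanding each
    count into per-sample phenotype indicators and running a standard
    one-way ANOVA with df1 = K - 1, df2 = N - K.
    """
    tab = _case_control_2xk(row)
    k = tab.shape[1]
    n_g = tab.sum(axis=0)          # group sizes
    case_g = tab[0]                # cases per group
    n = n_g.sum()
    if k < 2 or n <= k:
        return 0.0, max(k - 1, 0), max(int(n - k), 0), 1.0
    grand = case_g.sum() / n
    means = case_g / n_g
    ss_between = float((n_g * (means - grand) ** 2).sum())
    # within-group sum of squares of a 0/1 variable: n_g * m * (1 - m)
    ss_within = float((n_g * means * (1 - means)).sum())
    df1, df2 = k - 1, int(n - k)
    if ss_within == 0:
        return (np.inf if ss_between > 0 else 0.0), df1, df2, (0.0 if ss_between > 0 else 1.0)
    f = (ss_between / df1) / (ss_within / df2)
    return float(f), df1, df2, float(stats.f.sf(f, df1, df2))


# ---------------------------------------------------------------------------
# permutation machinery on count rows

def _expand_row(row: GenotypeCountRow) -> tuple[np.ndarray, np.ndarray]:
    """Expand a count row into per-sample genotype codes and phenotype (1=case)."""
    geno, pheno = [], []
    for code, n_ca, n_co in zip((2, 1, 0), row.case_counts, row.control_counts):
        geno += [code] * (n_ca + n_co)
        pheno += [1] * n_ca + [0] * n_co
    return np.array(geno, dtype=np.int8), np.array(pheno, dtype=np.int8)


def _dom_rec_chi2_from_counts(a_dom: np.ndarray, n_dom: int,
                              a_rec: np.ndarray, n_rec: int,
                              n_case: int, n: int) -> np.ndarray:
    """Vectorized max(dominant, recessive) chi2 given case counts among the
    exposed for each model; margins fixed."""
    out = np.zeros(np.shape(a_dom), dtype=float)
    for a_exp, n_exp in ((a_dom, n_dom), (a_rec, n_rec)):
        if n_exp == 0 or n_exp == n or n_case == 0 or n_case == n:
            continue
        b = n_case - a_exp
        c = n_exp - a_exp
        d = n - n_exp - b
        num = n * (a_exp * d - b * c) ** 2
        den = n_exp * (n - n_exp) * n_case * (n - n_case)
        out = np.maximum(out, num / den)
    return out


def max_test(row: GenotypeCountRow, n_perm: int = 10000,
             seed: int = 0) -> tuple[float, float]:
    """Max of the dominant and recessive chi-squares; p by phenotype-label
    permutation with genotypes fixed: p = (1 + #{stat* >= stat}) / (n_perm + 1)."""
    if n_perm < 1000:
        raise ValueError("n_perm must be >= 1000")
    t_dom = collapse(row, DOMINANT)
    t_rec = collapse(row, RECESSIVE)
    x_dom, _ = chi2_2x2(t_dom)
    x_rec, _ = chi2_2x2(t_rec)
    stat = max(x_dom, x_rec)
    if t_dom.has_zero_margin and t_rec.has_zero_margin:
        return stat, 1.0

    geno, pheno = _expand_row(row)
    n = geno.size
    n_case = int(pheno.sum())
    dom = (geno >= 1).astype(np.int64)
    rec = (geno == 2).astype(np.int64)
    n_dom, n_rec = int(dom.sum()), int(rec.sum())

    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(pheno, (n_perm, 1)), axis=1).astype(np.int64)
    a_dom = perms @ dom
    a_rec = perms @ rec
    stats_star = _dom_rec_chi2_from_counts(a_dom, n_dom, a_rec, n_rec, n_case, n)
    p = (1 + int((stats_star >= stat - 1e-12).sum())) / (n_perm + 1)
    return stat, float(p)


# ---------------------------------------------------------------------------
# logistic regression cross-check

def logistic_dominant(row: GenotypeCountRow, model: str = DOMINANT
                      ) -> tuple[float, float, float, float]:
    """Covariate-free logistic regression of phenotype on the collapsed binary
    exposure.  Returns (beta, se, wald_p, OR = exp(beta)); without covariates
    exp(beta) equals the 2x2 cross-product odds ratio.

    Raises ValueError on separation (a zero cell).
    """
    import statsmodels.api as sm

    t = collapse(row, model)
    if min(t.cells) == 0:
        raise ValueError("zero cell: logistic estimate does not exist (separation)")
    y = np.array([1] * (t.a + t.b) + [0] * (t.c + t.d))
    x = np.array([1] * t.a + [0] * t.b + [1] * t.c + [0] * t.d)
    design = sm.add_constant(x.astype(float))
    fit = sm.Logit(y, design).fit(disp=0)
    beta = float(fit.params[1])
    se = float(fit.bse[1])
    return beta, se, float(fit.pvalues[1]), float(np.exp(beta))


# ---------------------------------------------------------------------------
# max-T correction across a panel

def _binary_exposures(g: GenotypeMatrix, model: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-variant binary exposure matrix and validity mask (samples x variants)."""
    codes = g.codes
    valid = codes != MISSING
    if model == DOMINANT:
        expo = (codes >= 1) & valid
    elif model == RECESSIVE:
        expo = (codes == 2) & valid
    else:
        raise ValueError(f"model {model!r} not supported for vectorized max-T")
    return expo.astype(np.float64), valid.astype(np.float64)


def _chi2_matrix(a: np.ndarray, n_exp: np.ndarray, n_case: np.ndarray,
                 n: np.ndarray) -> np.ndarray:
    """Vectorized 2x2 chi2 from cases-exposed ``a`` with per-variant margins."""
    b = n_case - a
    c = n_exp - a
    d = n - n_exp - b
    den = n_exp * (n - n_exp) * n_case * (n - n_case)
    with np.errstate(invalid="ignore", divide="ignore"):
        x = n * (a * d - b * c) ** 2 / den
    return np.where(den > 0, x, 0.0)


def permutation_maxT(g: GenotypeMatrix, model: str = DOMINANT,
                     n_perm: int = 100_000, seed: int = 0,
                     ) -> list[PermutationResult]:
    """Westfall-Young max-T family-wise correction over a panel.

    Per permutation of the phenotype labels every variant's collapsed
    chi-square is recomputed and the experiment-wide maximum recorded;
    corrected p = (1 + #{max* >= observed}) / (n_perm + 1).  Pointwise p is
    the per-variant permutation p from the same permutations.
    """
    pheno = np.where(g.case_mask, 1.0, 0.0)
    use = g.case_mask | g.control_mask
    pheno = pheno[use]
    expo, valid = _binary_exposures(g.subset_samples(use), model)
    n_samp = pheno.size

    n_exp = expo.sum(axis=0)
    n_tot = valid.sum(axis=0)
    n_case_obs = pheno @ valid
    a_obs = pheno @ expo
    obs = _chi2_matrix(a_obs, n_exp, n_case_obs, n_tot)

    rng = np.random.default_rng(seed)
    # permute in blocks to bound memory at ~perm_block x n_samples floats
    block = max(1, min(n_perm, int(4e7 // max(n_samp, 1))))
    count_point = np.zeros(g.n_variants)
    count_max = np.zeros(g.n_variants)
    done = 0
    while done < n_perm:
        nb = min(block, n_perm - done)
        perms = rng.permuted(np.tile(pheno, (nb, 1)), axis=1)
        a = perms @ expo                    # nb x variants
        n_case = perms @ valid
        x = _chi2_matrix(a, n_exp, n_case, n_tot)
        count_point += (x >= obs - 1e-12).sum(axis=0)
        count_max += (x.max(axis=1)[:, None] >= obs - 1e-12).sum(axis=0)
        done += nb

    results = []
    for j, v in enumerate(g.variants):
        results.append(PermutationResult(
            variant_id=v.id, model=model,
            pointwise_p=float((1 + count_point[j]) / (n_perm + 1)),
            corrected_p=float((1 + count_max[j]) / (n_perm + 1)),
            n_permutations=n_perm, seed=seed))
    return results
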