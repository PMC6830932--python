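"""Synthetic genotype/phenotype data with the structure a candidate-panel
case-control analysis assumes.

The generator emulates a retrospective (case-control) design: genotypes are
drawn from case- and control-specific genotype distributions obtained by
Bayes inversion of a penetrance model at a nominal disease prevalence
(default 0.01).  Controls follow Hardy-Weinberg proportions at each
variant's minor-allele frequency; at effect variants the per-genotype
penetrance is scaled so that the collapsed-table odds ratio equals the
configured value.

Structural features and their deterministic placement:

* LD blocks: consecutive variant runs generated by first-order copying of a
  latent uniform along each haplotype (the uniform is retained with the
  block's correlation parameter, else redrawn), which preserves each
  variant's marginal MAF exactly while inducing positive dependence.
  Blocks are placed left-to-right from the first variant, separated by
  three free variants; :func:`block_indices` returns the placement.
* Relative pairs (parent/offspring-like: one shared haplotype) occupy the
  first control indices, duplicate pairs the next ones, and ancestry
  outliers (all MAFs shifted by ``outlier_shift``, clamped to [0.01, 0.99])
  the last control indices; see :func:`planted_relative_pairs`,
  :func:`planted_duplicate_pairs`, :func:`planted_outlier_indices`.
* Missingness is applied uniformly at random at the configured rate, after
  everything else (duplicates therefore share genotypes but not missingness
  patterns).

Default cohort and panel sizes (435 cases, 138 controls, 895 variants)
mirror the discovery-study conditions the package is designed around.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .datamodel import (
    CASE,
    CONTROL,
    MISSING,
    GenotypeCountRow,
    GenotypeMatrix,
    Sample,
    Variant,
)

DOMINANT = "dominant"
RECESSIVE = "recessive"
GENOTYPIC = "genotypic"

_BLOCK_GAP = 3  # free variants between planted LD blocks


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticConfig:
    n_cases: int = 435
    n_controls: int = 138
    n_variants: int = 895
    maf_range: tuple[float, float] = (0.01, 0.5)
    ld_blocks: tuple[tuple[int, float], ...] = ()
    effect_variants: tuple[tuple[int, str, float], ...] = ()
    missing_rate: float = 0.01
    n_duplicates: int = 0
    n_relative_pairs: int = 0
    n_ancestry_outliers: int = 0
    outlier_shift: float = 0.2
    prevalence: float = 0.01
    seed: int = 0
    variants_per_chrom: int = 50

    def __post_init__(self) -> None:
        if not (0 < self.maf_range[0] <= self.maf_range[1] <= 0.5):
            raise ConfigError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if not (0 <= self.missing_rate < 1):
            raise ConfigError("missing_rate must be in [0, 1)")
        if not (0 < self.prevalence < 1):
            raise ConfigError("prevalence must be in (0, 1)")
        for idx, model, orr in self.effect_variants:
            if not (0 <= idx < self.n_variants):
                raise ConfigError(f"effect variant index {idx} out of range")
            if model not in (DOMINANT, RECESSIVE, GENOTYPIC):
                raise ConfigError(f"unknown effect model {model!r}")
            if orr <= 0:
                raise ConfigError("odds ratios must be > 0")
        used = sum(size for size, _ in self.ld_blocks) + _BLOCK_GAP * len(self.ld_blocks)
        if used > self.n_variants:
            raise ConfigError("ld_blocks do not fit in the panel")
        n_planted = 2 * self.n_relative_pairs + 2 * self.n_duplicates + self.n_ancestry_outliers
        if n_planted > self.n_controls:
            raise ConfigError("planted relatives/duplicates/outliers exceed n_controls")


# ---------------------------------------------------------------------------
# planted-structure placement (all deterministic given the config)

def block_indices(cfg: SyntheticConfig) -> list[list[int]]:
    """Variant indices of each planted LD block, in configured order."""
    out, start = [], 0
    for size, _rho in cfg.ld_blocks:
        out.append(list(range(start, start + size)))
        start += size + _BLOCK_GAP
    return out


def planted_relative_pairs(cfg: SyntheticConfig) -> list[tuple[int, int]]:
    c0 = cfg.n_cases
    return [(c0 + 2 * r, c0 + 2 * r + 1) for r in range(cfg.n_relative_pairs)]


def planted_duplicate_pairs(cfg: SyntheticConfig) -> list[tuple[int, int]]:
    d0 = cfg.n_cases + 2 * cfg.n_relative_pairs
    return [(d0 + 2 * k, d0 + 2 * k + 1) for k in range(cfg.n_duplicates)]


def planted_outlier_indices(cfg: SyntheticConfig) -> list[int]:
    n = cfg.n_cases + cfg.n_controls
    return list(range(n - cfg.n_ancestry_outliers, n))


# ---------------------------------------------------------------------------
# penetrance model

def genotype_distributions(
    maf: float, model: str, odds_ratio: float, prevalence: float = 0.01
) -> tuple[np.ndarray, np.ndarray]:
    """Case- and control-conditional genotype distributions (index = minor
    dose 0/1/2) under a penetrance model.

    The population genotype distribution is HWE at ``maf``; per-genotype
    disease odds are multiplied by 1, OR, OR (dominant), 1, 1, OR
    (recessive) or 1, OR, OR^2 (genotypic, multiplicative); the baseline
    penetrance is solved so the population prevalence matches.  Bayes'
    rule then gives P(g | case) and P(g | control) — the distributions a
    retrospective design samples from.
    """
    if not (0 < maf <= 0.5):
        raise ConfigError("maf must be in (0, 0.5]")
    p = maf
    pop = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
    if model == DOMINANT:
        mult = np.array([1.0, odds_ratio, odds_ratio])
    elif model == RECESSIVE:
        mult = np.array([1.0, 1.0, odds_ratio])
    elif model == GENOTYPIC:
        mult = np.array([1.0, odds_ratio, odds_ratio**2])
    else:
        raise ConfigError(f"unknown model {model!r}")
    log_mult = np.log(mult)

    def prev_at(logit0: float) -> float:
        f = 1 / (1 + np.exp(-(logit0 + log_mult)))
        return float((pop * f).sum()) - prevalence

    logit0 = brentq(prev_at, -40, 40)
    f = 1 / (1 + np.exp(-(logit0 + log_mult)))
    p_case = pop * f / prevalence
    p_control = pop * (1 - f) / (1 - prevalence)
    return p_case, p_control


def simulate_count_row(
    maf: float, model: str, odds_ratio: float,
    n_case: int, n_control: int, seed: int,
    variant_id: str = "sim1",
) -> GenotypeCountRow:
    """One Table-2-style genotype-count row drawn under a penetrance model.

    Triples are (hom_minor, het, hom_major) and sum exactly to the group
    sizes (no missingness on this fast path).
    """
    rng = np.random.default_rng(seed)
    p_case, p_control = genotype_distributions(maf, model, odds_ratio)
    ca = rng.multinomial(n_case, p_case)
    co = rng.multinomial(n_control, p_control)
    v = Variant(id=variant_id, chrom="1", pos=1, allele_major="A", allele_minor="B")
    # multinomial index is minor dose (0,1,2); triples are (hom-minor, het, hom-major)
    return GenotypeCountRow(variant=v,
                            case_counts=(int(ca[2]), int(ca[1]), int(ca[0])),
                            control_counts=(int(co[2]), int(co[1]), int(co[0])))


# ---------------------------------------------------------------------------
# full matrix simulation

def _haplotypes(cfg: SyntheticConfig, mafs: np.ndarray,
                rng: np.random.Generator, n: int) -> np.ndarray:
    """n x 2 x m haplotype minor-allele indicators with planted LD blocks."""
    m = cfg.n_variants
    u = rng.random((n, 2, m))
    for members, (_, rho) in zip(block_indices(cfg), cfg.ld_blocks):
        for prev, cur in zip(members, members[1:]):
            copy = rng.random((n, 2)) < rho
            u[:, :, cur] = np.where(copy, u[:, :, prev], u[:, :, cur])
    return (u < mafs).astype(np.int8)


def simulate_genotypes(cfg: SyntheticConfig) -> GenotypeMatrix:
    """Generate a full genotype matrix per the config; fully determined by
    ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_cases + cfg.n_controls
    m = cfg.n_variants
    mafs = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=m)

    hap = _haplotypes(cfg, mafs, rng, n)
    codes = hap.sum(axis=1).astype(np.int8)

    # effect variants: redraw the column from the case/control-specific
    # genotype distributions (overrides any block correlation at that column)
    case_rows = np.arange(cfg.n_cases)
    ctrl_rows = np.arange(cfg.n_cases, n)
    for idx, model, orr in cfg.effect_variants:
        p_case, p_ctrl = genotype_distributions(mafs[idx], model, orr, cfg.prevalence)
        codes[case_rows, idx] = rng.choice(3, size=case_rows.size, p=p_case)
        codes[ctrl_rows, idx] = rng.choice(3, size=ctrl_rows.size, p=p_ctrl)

    # relatives: offspring = one parental haplotype + one fresh population draw
    for parent, child in planted_relative_pairs(cfg):
        fresh = (rng.random(m) < mafs).astype(np.int8)
        codes[child] = hap[parent, 0] + fresh

    for orig, dup in planted_duplicate_pairs(cfg):
        codes[dup] = codes[orig]

    # ancestry outliers: independent HWE draws at shifted MAFs
    shifted = np.clip(mafs + cfg.outlier_shift, 0.01, 0.99)
    for i in planted_outlier_indices(cfg):
        h = (rng.random((2, m)) < shifted).astype(np.int8)
        codes[i] = h.sum(axis=0)

    if cfg.missing_rate > 0:
        mask = rng.random((n, m)) < cfg.missing_rate
        codes[mask] = MISSING

    variants = []
    pos = 0
    for j in range(m):
        chrom = str(1 + (j // cfg.variants_per_chrom) % 22)
        pos = 10_000 + 5_000 * (j % cfg.variants_per_chrom)
        variants.append(Variant(id=f"snp{j:04d}", chrom=chrom,
                                pos=pos + 1_000_000 * (j // (cfg.variants_per_chrom * 22)),
                                allele_major="A", allele_minor="B"))
    samples = [Sample(id=f"case{i:04d}", phenotype=CASE) for i in range(cfg.n_cases)]
    samples += [Sample(id=f"ctrl{i:04d}", phenotype=CONTROL)
                for i in range(cfg.n_controls)]
    return GenotypeMatrix(samples=samples, variants=variants, codes=codes)


# ---------------------------------------------------------------------------
# planted two-locus (carrier-combination) pairs

def simulate_combo_pair(
    n_case: int = 435,
    n_control: int = 138,
    case_carrier_prop: float = 0.13,
    control_carrier_prop: float = 0.01,
    maf_a: float = 0.35,
    maf_b: float = 0.1,
    seed: int = 0,
) -> GenotypeMatrix:
    """Two-variant matrix with a planted pure-epistasis carrier combination.

    The flagged combination is "carries >= 1 minor allele at A and is
    major-allele homozygous at B"; its frequency is exactly
    ``case_carrier_prop`` / ``control_carrier_prop`` in expectation.  The
    construction is pure two-locus interaction: variant A's genotype
    distribution is HWE at ``maf_a`` in both groups, and variant B's
    *marginal* distribution is also identical across groups — the groups
    differ only in how B's genotypes associate with A's strata.  Within the
    A-carrier strata cases are enriched for B hom-major at the rate the
    carrier proportion dictates; within the A hom-major stratum the
    enrichment is reversed exactly so the B marginals cancel.  Marginal
    single-SNP tests are therefore null in expectation while the stratified
    conditional test sees strong within-stratum contrasts.
    """
    rng = np.random.default_rng(seed)
    w = np.array([(1 - maf_a) ** 2, 2 * maf_a * (1 - maf_a), maf_a**2])
    w_carrier = w[1] + w[2]
    hwe_b0 = (1 - maf_b) ** 2
    alpha = {  # P(g_b = 0 | A-carrier stratum) per group
        "case": case_carrier_prop / w_carrier,
        "control": control_carrier_prop / w_carrier,
    }
    if max(alpha.values()) > 1:
        raise ConfigError("carrier proportion exceeds the A-carrier stratum mass")
    # shared marginal P(g_b = 0); the stratum-0 rate absorbs the difference
    m0 = w[0] * hwe_b0 + (case_carrier_prop + control_carrier_prop) / 2
    beta = {grp: (m0 - prop) / w[0]
            for grp, prop in (("case", case_carrier_prop),
                              ("control", control_carrier_prop))}
    if not all(0 <= b <= 1 for b in beta.values()):
        raise ConfigError("carrier proportions incompatible with maf_a/maf_b")
    # split of non-zero g_b between het and hom-minor (HWE-conditional)
    split = np.array([2 * maf_b * (1 - maf_b), maf_b**2])
    split = split / split.sum()

    def draw(n: int, grp: str) -> np.ndarray:
        g_a = rng.choice(3, size=n, p=w).astype(np.int8)
        p_b0 = np.where(g_a == 0, beta[grp], alpha[grp])
        b_zero = rng.random(n) < p_b0
        g_b = np.where(b_zero, 0,
                       1 + (rng.random(n) < split[1])).astype(np.int8)
        return np.column_stack([g_a, g_b])

    codes = np.vstack([draw(n_case, "case"), draw(n_control, "control")])
    variants = [
        Variant(id="comboA", chrom="1", pos=1000, allele_major="A", allele_minor="B"),
        Variant(id="comboB", chrom="1", pos=2000, allele_major="A", allele_minor="B"),
    ]
    samples = [Sample(id=f"case{i:04d}", phenotype=CASE) for i in range(n_case)]
    samples += [Sample(id=f"ctrl{i:04d}", phenotype=CONTROL) for i in range(n_control)]
    return GenotypeMatrix(samples=samples, variants=variants, codes=codes)
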