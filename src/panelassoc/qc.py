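"""Variant-level quality control: MAF, call rate, Hardy-Weinberg exact test,
and r²-redundancy pruning, with full exclusion accounting.

Filters are applied in a fixed order — MAF, then missingness, then HWE, then
redundancy — and each excluded variant is reported under the first filter it
fails, so the accounting always balances: n_final + exclusions = n_input.
MAF and HWE are evaluated in the control sample (association at true risk
loci distorts case-sample HWE; control-only testing is the field convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .datamodel import MISSING, GenotypeMatrix, logger
from .ld import r2_matrix


@dataclass
class QCReport:
    n_input: int
    n_excluded_maf: int = 0
    n_excluded_missing: int = 0
    n_excluded_hwe: int = 0
    n_excluded_redundant: int = 0
    exclusion_reasons: dict[str, str] = field(default_factory=dict)

    @property
    def n_final(self) -> int:
        return (self.n_input - self.n_excluded_maf - self.n_excluded_missing
                - self.n_excluded_hwe - self.n_excluded_redundant)

    def summary(self) -> str:
        return (
            f"{self.n_input} variants in; excluded {self.n_excluded_maf} (MAF), "
            f"{self.n_excluded_missing} (missingness), {self.n_excluded_hwe} (HWE), "
            f"{self.n_excluded_redundant} (redundant); {self.n_final} variants out"
        )

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("variant\treason\n")
            for vid, reason in self.exclusion_reasons.items():
                fh.write(f"{vid}\t{reason}\n")


def hwe_exact_test(counts: tuple[int, int, int]) -> float:
    """Two-sided exact test for Hardy-Weinberg equilibrium.

    ``counts`` is (hom_minor, het, hom_major).  Conditional on the observed
    allele counts, the number of heterozygotes follows
    P(n_het) ∝ n! / (n_hm! n_het! n_hM!) * 2^n_het; the two-sided p sums the
    probabilities of all heterozygote counts at most as probable as the one
    observed (Wigginton-style exact test).

    Monomorphic samples admit no departure, so p = 1.
    """
    hm, het, hM = counts
    if min(hm, het, hM) < 0:
        raise ValueError("negative genotype count")
    n = hm + het + hM
    if n == 0:
        raise ValueError("HWE undefined for an all-zero genotype triple")
    n_minor = 2 * hm + het
    n_major = 2 * hM + het
    if n_minor == 0 or n_major == 0:
        return 1.0

    rare = min(n_minor, n_major)
    # log-probabilities over all feasible het counts (parity of `rare` fixed)
    hets = np.arange(rare % 2, rare + 1, 2)
    lgn = math.lgamma(n + 1)
    logp = np.array([
        lgn
        - math.lgamma((rare - h) // 2 + 1)
        - math.lgamma(h + 1)
        - math.lgamma((2 * n - rare - h) // 2 + 1)
        + h * math.log(2.0)
        for h in hets
    ])
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = np.flatnonzero(hets == het)
    if obs.size == 0:
        raise ValueError(f"inconsistent genotype triple {counts}")
    p_obs = probs[obs[0]]
    # relative tolerance guards against float noise deciding tail membership
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def control_genotype_counts(g: GenotypeMatrix) -> np.ndarray:
    """Per-variant (hom_minor, het, hom_major) counts in controls."""
    codes = g.codes[g.control_mask]
    return np.stack([(codes == 2).sum(axis=0),
                     (codes == 1).sum(axis=0),
                     (codes == 0).sum(axis=0)], axis=1)


def apply_variant_filters(
    g: GenotypeMatrix,
    maf_min: float = 0.05,
    call_rate_min: float = 0.94,
    hwe_alpha: float | None = None,
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply MAF, call-rate and HWE filters with exclusion accounting.

    MAF and the HWE exact test use the control sample; the call rate uses all
    samples.  ``hwe_alpha`` defaults to the Bonferroni-style 0.05 / n_input
    (the denominator is an explicit parameter because genotyping studies may
    denominate over a larger array-wide variant set).
    """
    if not g.control_mask.any():
        raise ValueError("no control samples: control-based filters are undefined")
    n_input = g.n_variants
    if hwe_alpha is None:
        hwe_alpha = 0.05 / n_input
    report = QCReport(n_input=n_input)

    ctrl_maf = g.maf(mask=g.control_mask)
    ctrl_maf = np.minimum(ctrl_maf, 1 - ctrl_maf)  # fold within controls
    call_rate = np.asarray(g.call_rate())
    ctrl_counts = control_genotype_counts(g)

    keep = np.ones(n_input, dtype=bool)
    for j, v in enumerate(g.variants):
        if not (ctrl_maf[j] >= maf_min):  # NaN-safe: NaN fails
            report.exclusion_reasons[v.id] = "maf"
            report.n_excluded_maf += 1
            keep[j] = False
        elif call_rate[j] < call_rate_min:
            report.exclusion_reasons[v.id] = "missingness"
            report.n_excluded_missing += 1
            keep[j] = False
        elif ctrl_counts[j].sum() > 0 and hwe_exact_test(tuple(ctrl_counts[j])) < hwe_alpha:
            report.exclusion_reasons[v.id] = "hwe"
            report.n_excluded_hwe += 1
            keep[j] = False

    out = g.subset_variants(keep)
    logger.info("apply_variant_filters: %s", report.summary())
    return out, report


def prune_redundant(
    g: GenotypeMatrix, r2_max: float = 0.994,
    report: QCReport | None = None,
) -> tuple[GenotypeMatrix, list[str]]:
    """Drop variants nearly duplicating an earlier one (pairwise r² > r2_max).

    Greedy left-to-right scan in position order per chromosome; a variant is
    dropped when its EM-based r² with any retained earlier variant on the
    same chromosome exceeds the threshold, so the first-seen member of each
    redundant set is kept.  Idempotent.
    """
    if not (0 < r2_max <= 1):
        raise ValueError("r2_max must be in (0, 1]")
    order = sorted(range(g.n_variants),
                   key=lambda j: (g.variants[j].chrom, g.variants[j].pos))
    dropped: list[str] = []
    keep = np.ones(g.n_variants, dtype=bool)
    by_chrom: dict[str, list[int]] = {}
    for j in order:
        by_chrom.setdefault(g.variants[j].chrom, []).append(j)
    for chrom, idx in by_chrom.items():
        r2 = r2_matrix(g, idx)
        retained: list[int] = []
        for k, j in enumerate(idx):
            if any(r2[k, kk] > r2_max for kk in retained):
                keep[j] = False
                dropped.append(g.variants[j].id)
            else:
                retained.append(k)
    if report is not None:
        for vid in dropped:
            report.exclusion_reasons[vid] = "redundant"
        report.n_excluded_redundant += len(dropped)
    logger.info("prune_redundant: dropped %d of %d variants at r2 > %g",
                len(dropped), g.n_variants, r2_max)
    return g.subset_variants(keep), dropped
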