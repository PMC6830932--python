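"""Genotype/phenotype data model and text-format IO.

Conventions enforced throughout the package:

* Genotype codes count copies of the **minor** allele (0, 1, 2), so a
  "recessive" model always means recessive for the minor allele.  The minor
  allele is defined on the combined case+control sample; ties in allele
  frequency are broken lexicographically (the alphabetically later allele is
  called minor).  A single orientation keeps odds-ratio directions consistent
  across every downstream analysis; the control-only allele frequency is
  still available for QC filtering.
* Missing genotypes carry a dedicated sentinel (-1), never 0.
* Coordinates are 1-based (PLINK/VCF convention).
* Genotype-count triples are ordered (hom-minor, het, hom-major).

Supported formats: PLINK text ``.ped``/``.map`` (read/write), minimal VCF 4.x
with GT genotypes (read, biallelic records only; write for round-trip use),
and TSV genotype-count tables (read/write).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger("panelassoc")

MISSING = -1

CASE = "case"
CONTROL = "control"
UNKNOWN = "unknown"

_PED_PHENO = {"1": CONTROL, "2": CASE, "0": UNKNOWN, "-9": UNKNOWN}
_PED_PHENO_INV = {CONTROL: "1", CASE: "2", UNKNOWN: "0"}


class FormatError(ValueError):
    """Malformed input file."""


@dataclass(frozen=True)
class Variant:
    id: str
    chrom: str
    pos: int
    allele_major: str
    allele_minor: str
    gene_label: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.id}: position must be >= 1, got {self.pos}")
        if self.allele_major == self.allele_minor:
            raise ValueError(f"{self.id}: major and minor allele are identical")


@dataclass(frozen=True)
class Sample:
    id: str
    phenotype: str = UNKNOWN

    def __post_init__(self) -> None:
        if self.phenotype not in (CASE, CONTROL, UNKNOWN):
            raise ValueError(f"invalid phenotype {self.phenotype!r}")


@dataclass(frozen=True)
class GenotypeCountRow:
    """A Table-2-style row: per-group genotype counts for one variant.

    Count triples are (hom_minor, het, hom_major).
    """

    variant: Variant
    case_counts: tuple[int, int, int]
    control_counts: tuple[int, int, int]

    def __post_init__(self) -> None:
        for trip in (self.case_counts, self.control_counts):
            if len(trip) != 3 or any(c < 0 for c in trip):
                raise ValueError(f"{self.variant.id}: invalid count triple {trip}")

    @property
    def n_case(self) -> int:
        return sum(self.case_counts)

    @property
    def n_control(self) -> int:
        return sum(self.control_counts)


@dataclass
class GenotypeMatrix:
    """Samples x variants matrix of minor-allele dosage codes.

    ``codes[i, j]`` counts copies of ``variants[j].allele_minor`` carried by
    ``samples[i]``; missing genotypes are the ``MISSING`` sentinel (-1).
    """

    samples: list[Sample]
    variants: list[Variant]
    codes: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"codes shape {self.codes.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        bad = ~np.isin(self.codes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype codes must be in {0,1,2,MISSING}")
        ids = [v.id for v in self.variants]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate variant ids")
        sids = [s.id for s in self.samples]
        if len(set(sids)) != len(sids):
            raise ValueError("duplicate sample ids")
        self._vindex = {v: i for i, v in enumerate(ids)}

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_index(self, variant_id: str) -> int:
        try:
            return self._vindex[variant_id]
        except KeyError:
            raise KeyError(f"unknown variant id {variant_id!r}") from None

    def phenotype_mask(self, phenotype: str) -> np.ndarray:
        return np.array([s.phenotype == phenotype for s in self.samples])

    @property
    def case_mask(self) -> np.ndarray:
        return self.phenotype_mask(CASE)

    @property
    def control_mask(self) -> np.ndarray:
        return self.phenotype_mask(CONTROL)

    def subset_samples(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return GenotypeMatrix(
            samples=[self.samples[i] for i in idx],
            variants=list(self.variants),
            codes=self.codes[idx, :].copy(),
        )

    def subset_variants(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return GenotypeMatrix(
            samples=list(self.samples),
            variants=[self.variants[i] for i in idx],
            codes=self.codes[:, idx].copy(),
        )

    def call_rate(self, variant_id: str | int | None = None) -> np.ndarray | float:
        """Call rate of one variant, or all per-variant rates when id is None."""
        if variant_id is None:
            return (self.codes != MISSING).mean(axis=0)
        j = variant_id if isinstance(variant_id, int) else self.variant_index(variant_id)
        return float((self.codes[:, j] != MISSING).mean())

    def sample_call_rates(self) -> np.ndarray:
        return (self.codes != MISSING).mean(axis=1)

    def maf(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Minor-allele frequency per variant, optionally within a sample mask.

        By construction codes count the dataset-wide minor allele, so within
        a subgroup the value may exceed 0.5.
        """
        codes = self.codes if mask is None else self.codes[mask]
        valid = codes != MISSING
        n_alleles = 2 * valid.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(valid, codes, 0).sum(axis=0) / n_alleles
        return np.where(n_alleles > 0, freq, np.nan)


# ---------------------------------------------------------------------------
# minor-allele orientation

def _orient_minor(allele_pairs: np.ndarray, a1: str, a2: str) -> tuple[str, str]:
    """Return (major, minor) for one variant from whole-sample allele counts.

    ``allele_pairs`` is the flat array of observed allele strings ('0' =
    missing already removed).  Ties broken lexicographically: the later
    allele is minor.
    """
    n1 = int((allele_pairs == a1).sum())
    n2 = int((allele_pairs == a2).sum())
    if n1 > n2:
        return a1, a2
    if n2 > n1:
        return a2, a1
    # tie: lexicographically smaller allele is major
    return (a1, a2) if a1 < a2 else (a2, a1)


# ---------------------------------------------------------------------------
# PLINK text

def read_plink_text(ped_path: str | Path, map_path: str | Path) -> GenotypeMatrix:
    """Read a PLINK text fileset (.ped + .map) into a GenotypeMatrix.

    .ped columns: FID IID PAT MAT SEX PHENO allele1 allele2 [allele1 allele2 ...]
    .map columns: chrom, variant id, genetic distance, position.
    Phenotype codes: 1 = control, 2 = case, 0/-9 = unknown.  '0 0' allele
    pairs become MISSING.
    """
    map_rows = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise FormatError(f"{map_path}:{ln}: expected 4 columns, got {len(parts)}")
            map_rows.append((parts[0], parts[1], int(parts[3])))
    m = len(map_rows)

    sample_rows: list[tuple[str, str]] = []
    allele_cols: list[list[tuple[str, str]]] = []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise FormatError(
                    f"{ped_path}:{ln}: expected {6 + 2 * m} fields for {m} "
                    f".map variants, got {len(parts)}"
                )
            iid, pheno_code = parts[1], parts[5]
            pheno = _PED_PHENO.get(pheno_code, UNKNOWN)
            sample_rows.append((iid, pheno))
            allele_cols.append(
                [(parts[6 + 2 * j], parts[7 + 2 * j]) for j in range(m)]
            )

    n = len(sample_rows)
    codes = np.full((n, m), MISSING, dtype=np.int8)
    variants = []
    for j, (chrom, vid, pos) in enumerate(map_rows):
        obs = np.array(
            [a for i in range(n) for a in allele_cols[i][j] if a != "0"]
        )
        alleles = sorted(set(obs.tolist()))
        if len(alleles) > 2:
            raise FormatError(f"variant {vid!r} is not biallelic: alleles {alleles}")
        if len(alleles) == 0:
            raise FormatError(f"variant {vid!r} has no called genotypes")
        if len(alleles) == 1:
            # monomorphic: invent the complementary allele label so the type
            # invariant (major != minor) holds; code is uniformly 0.
            major, minor = alleles[0], alleles[0] + "*"
        else:
            major, minor = _orient_minor(obs, alleles[0], alleles[1])
        variants.append(Variant(id=vid, chrom=chrom, pos=pos,
                                allele_major=major, allele_minor=minor))
        for i in range(n):
            a, b = allele_cols[i][j]
            if a == "0" or b == "0":
                continue
            codes[i, j] = (a == minor) + (b == minor)

    samples = [Sample(id=sid, phenotype=ph) for sid, ph in sample_rows]
    logger.info("read_plink_text: %d samples, %d variants from %s", n, m, ped_path)
    return GenotypeMatrix(samples=samples, variants=variants, codes=codes)


def write_plink_text(g: GenotypeMatrix, ped_path: str | Path, map_path: str | Path) -> None:
    """Write a GenotypeMatrix as a PLINK text fileset."""
    with open(map_path, "w") as fh:
        for v in g.variants:
            fh.write(f"{v.chrom}\t{v.id}\t0\t{v.pos}\n")
    with open(ped_path, "w") as fh:
        for i, s in enumerate(g.samples):
            fields = [s.id, s.id, "0", "0", "0", _PED_PHENO_INV[s.phenotype]]
            for j, v in enumerate(g.variants):
                c = g.codes[i, j]
                if c == MISSING:
                    fields += ["0", "0"]
                elif c == 0:
                    fields += [v.allele_major, v.allele_major]
                elif c == 1:
                    fields += [v.allele_major, v.allele_minor]
                else:
                    fields += [v.allele_minor, v.allele_minor]
            fh.write(" ".join(fields) + "\n")
    logger.info("write_plink_text: wrote %d samples, %d variants to %s",
                g.n_samples, g.n_variants, ped_path)


# ---------------------------------------------------------------------------
# VCF

def read_vcf_minimal(
    vcf_path: str | Path,
    phenotypes: dict[str, str] | None = None,
) -> tuple[GenotypeMatrix, int]:
    """Read a GT-only VCF into a GenotypeMatrix.

    Multi-allelic records are skipped with a warning; the skip count is
    returned alongside the matrix.  The minor allele is recomputed from the
    file (tie-break as in :func:`read_plink_text`), never assumed to be ALT.
    VCF carries no phenotype; an optional ``phenotypes`` mapping
    (sample id -> 'case'/'control') assigns them.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=True)
    sample_ids = list(vcf.samples)
    n = len(sample_ids)
    variants: list[Variant] = []
    cols: list[np.ndarray] = []
    n_skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_skipped += 1
            logger.warning("read_vcf_minimal: skipping multi-allelic record %s:%d",
                           rec.CHROM, rec.POS)
            continue
        # gts012: 0=hom-ref, 1=het, 2=hom-alt, 3=unknown
        alt_dose = np.asarray(rec.gt_types, dtype=np.int8)
        missing = alt_dose == 3
        valid = ~missing
        n_alleles = 2 * int(valid.sum())
        if n_alleles == 0:
            raise FormatError(f"variant {rec.ID or rec.POS} has no called genotypes")
        alt_freq = int(alt_dose[valid].sum()) / n_alleles
        ref, alt = rec.REF, rec.ALT[0]
        if alt_freq < 0.5:
            major, minor = ref, alt
            codes = alt_dose.copy()
        elif alt_freq > 0.5:
            major, minor = alt, ref
            codes = (2 - alt_dose).astype(np.int8)
        else:  # tie: lexicographically later allele is minor
            if ref < alt:
                major, minor = ref, alt
                codes = alt_dose.copy()
            else:
                major, minor = alt, ref
                codes = (2 - alt_dose).astype(np.int8)
        codes[missing] = MISSING
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        variants.append(Variant(id=vid, chrom=rec.CHROM, pos=rec.POS,
                                allele_major=major, allele_minor=minor))
        cols.append(codes)
    vcf.close()

    codes = (np.column_stack(cols) if cols
             else np.empty((n, 0), dtype=np.int8))
    phenotypes = phenotypes or {}
    samples = [Sample(id=sid, phenotype=phenotypes.get(sid, UNKNOWN))
               for sid in sample_ids]
    logger.info("read_vcf_minimal: %d samples, %d variants (%d skipped) from %s",
                n, len(variants), n_skipped, vcf_path)
    return GenotypeMatrix(samples=samples, variants=variants, codes=codes), n_skipped


def write_vcf_minimal(g: GenotypeMatrix, vcf_path: str | Path) -> None:
    """Write a minimal VCF 4.2 (GT only).  REF = major allele, ALT = minor."""
    chroms = []
    for v in g.variants:
        if v.chrom not in chroms:
            chroms.append(v.chrom)
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=panelassoc\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(s.id for s in g.samples) + "\n")
        order = sorted(range(g.n_variants),
                       key=lambda j: (chroms.index(g.variants[j].chrom),
                                      g.variants[j].pos))
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for j in order:
            v = g.variants[j]
            gts = "\t".join(gt_map[int(c)] for c in g.codes[:, j])
            fh.write(f"{v.chrom}\t{v.pos}\t{v.id}\t{v.allele_major}\t"
                     f"{v.allele_minor}\t.\tPASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# count tables

def read_count_table(tsv_path: str | Path) -> list[GenotypeCountRow]:
    """Read a TSV of per-SNP genotype-count rows.

    Columns: snp, chrom, pos, case_counts, control_counts (and optionally
    gene, model); count fields are slash-separated triples ordered
    hom-minor/het/hom-major, e.g. ``56/219/159``.
    """
    rows: list[GenotypeCountRow] = []
    with open(tsv_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for req in ("snp", "chrom", "pos", "case_counts", "control_counts"):
            if req not in idx:
                raise FormatError(f"{tsv_path}: missing column {req!r}")
        for ln, line in enumerate(fh, 2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")

            def triple(fieldname: str) -> tuple[int, int, int]:
                raw = parts[idx[fieldname]]
                bits = raw.split("/")
                if len(bits) != 3:
                    raise FormatError(
                        f"{tsv_path}:{ln}: count triple {raw!r} must have 3 fields")
                try:
                    t = tuple(int(b) for b in bits)
                except ValueError:
                    raise FormatError(
                        f"{tsv_path}:{ln}: non-integer count in {raw!r}") from None
                return t  # type: ignore[return-value]

            gene = parts[idx["gene"]] if "gene" in idx else None
            variant = Variant(
                id=parts[idx["snp"]],
                chrom=parts[idx["chrom"]],
                pos=int(parts[idx["pos"]]),
                allele_major="A", allele_minor="B",  # alleles not carried by count tables
                gene_label=gene or None,
            )
            rows.append(GenotypeCountRow(
                variant=variant,
                case_counts=triple("case_counts"),
                control_counts=triple("control_counts"),
            ))
    logger.info("read_count_table: %d rows from %s", len(rows), tsv_path)
    return rows


def read_count_table_models(tsv_path: str | Path) -> dict[str, str]:
    """Per-row reported model ('D'/'R') if the table carries a model column."""
    models: dict[str, str] = {}
    with open(tsv_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        if "model" not in idx:
            return models
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            models[parts[idx["snp"]]] = parts[idx["model"]]
    return models


def write_count_table(rows: list[GenotypeCountRow], tsv_path: str | Path) -> None:
    with open(tsv_path, "w") as fh:
        fh.write("snp\tchrom\tpos\tgene\tcase_counts\tcontrol_counts\n")
        for r in rows:
            v = r.variant
            fh.write(
                f"{v.id}\t{v.chrom}\t{v.pos}\t{v.gene_label or ''}\t"
                f"{'/'.join(map(str, r.case_counts))}\t"
                f"{'/'.join(map(str, r.control_counts))}\n"
            )


def counts_from_matrix(g: GenotypeMatrix, variant_id: str) -> GenotypeCountRow:
    """Tally one variant's genotype-count row from a matrix with phenotypes."""
    j = g.variant_index(variant_id)
    col = g.codes[:, j]

    def tally(mask: np.ndarray) -> tuple[int, int, int]:
        sub = col[mask]
        return (int((sub == 2).sum()), int((sub == 1).sum()), int((sub == 0).sum()))

    return GenotypeCountRow(
        variant=g.variants[j],
        case_counts=tally(g.case_mask),
        control_counts=tally(g.control_mask),
    )
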