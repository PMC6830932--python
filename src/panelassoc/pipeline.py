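"""End-to-end pipeline orchestration.

Two entry surfaces exist because published association studies typically
print only genotype-count tables:

* **matrix mode** (:func:`run_full`): genotype matrix in, full workflow out —
  relatedness exclusion, ancestry outlier removal, variant QC, LD pruning
  and blocks, single-SNP association with permutation correction, and the
  conditional two-SNP scan; every stage's accounting is reconciled in a run
  log.
* **count-table mode** (:func:`run_table2_mode`): a per-SNP genotype-count
  table in, the dominant/recessive test, odds ratio and Woolf CI per row out
  — the surface used to reproduce a published top-signals table.

All randomness flows from the single config seed.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import association as assoc
from . import conditional as cond
from . import ld as ldmod
from . import qc as qcmod
from . import relatedness as rel
from .datamodel import (
    GenotypeCountRow,
    GenotypeMatrix,
    counts_from_matrix,
    logger,
    read_count_table,
    read_count_table_models,
)

TABLE2_FIXTURE = Path(__file__).parent / "data" / "table2_counts.tsv"

_MODEL_CODE = {"D": assoc.DOMINANT, "R": assoc.RECESSIVE}


@dataclass
class PipelineConfig:
    maf_min: float = 0.05
    call_rate_min: float = 0.94
    hwe_alpha: float | None = None      # default 0.05 / n_input
    prune_r2: float = 0.994
    pi_hat_max: float = 0.25
    mds_k: int = 4
    mds_pair: tuple[int, int] = (1, 3)
    outlier_quantile: float = 0.01
    n_perm: int = 100_000
    n_test_snps: int = 4
    top_p: float = 0.01                 # reporting threshold for the signals table
    seed: int = 0
    run_conditional: bool = True
    call_ld_blocks: bool = True

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


@dataclass
class PipelineResult:
    config: PipelineConfig
    qc_report: qcmod.QCReport
    excluded_related: list[str]
    excluded_outliers: list[str]
    pruned: list[str]
    association: pd.DataFrame
    ld_blocks: list[ldmod.LDBlock]
    conditional: list[cond.PairResult]
    log_lines: list[str]


def _assoc_table(rows: list[GenotypeCountRow],
                 models: dict[str, str] | None = None) -> pd.DataFrame:
    """Per-row dominant and recessive tests; the reported model is the one
    given per row (count-table mode) or the smaller-p model."""
    records = []
    for row in rows:
        res = {m: assoc.model_test(row, m)
               for m in (assoc.DOMINANT, assoc.RECESSIVE)}
        if models and row.variant.id in models:
            best = _MODEL_CODE[models[row.variant.id]]
        else:
            best = min(res, key=lambda m: res[m].p)
        r = res[best]
        records.append({
            "snp": row.variant.id,
            "chrom": row.variant.chrom,
            "pos": row.variant.pos,
            "gene": row.variant.gene_label or "",
            "test": "D" if best == assoc.DOMINANT else "R",
            "case_counts": "/".join(map(str, row.case_counts)),
            "control_counts": "/".join(map(str, row.control_counts)),
            "p": r.p,
            "OR": r.odds_ratio,
            "ci_low": r.ci95[0] if r.ci95 else np.nan,
            "ci_high": r.ci95[1] if r.ci95 else np.nan,
            "p_dominant": res[assoc.DOMINANT].p,
            "p_recessive": res[assoc.RECESSIVE].p,
        })
    return pd.DataFrame.from_records(records)


def run_table2_mode(count_table_path: str | Path = TABLE2_FIXTURE) -> pd.DataFrame:
    """Reproduce a printed top-signals table from its genotype counts."""
    rows = read_count_table(count_table_path)
    models = read_count_table_models(count_table_path)
    return _assoc_table(rows, models=models)


def run_full(g: GenotypeMatrix, cfg: PipelineConfig | None = None,
             out_dir: str | Path | None = None) -> PipelineResult:
    """Execute the full workflow on a genotype matrix.

    Stage order: relatedness exclusion -> ancestry outlier filter -> variant
    QC (MAF, call rate, HWE) -> r² redundancy pruning -> LD blocks ->
    single-SNP association with max-T permutation correction -> conditional
    two-SNP scan.
    """
    cfg = cfg or PipelineConfig()
    log: list[str] = []
    t0 = time.time()

    def stage(msg: str) -> None:
        line = f"[{time.time() - t0:7.2f}s] {msg}"
        log.append(line)
        logger.info(line)

    stage(f"input: {g.n_samples} samples x {g.n_variants} variants")

    g1, excl_rel = rel.exclude_related(g, pi_hat_max=cfg.pi_hat_max)
    stage(f"relatedness: excluded {len(excl_rel)} samples (PI_HAT > {cfg.pi_hat_max})")

    coords = rel.mds_components(g1, k=cfg.mds_k)
    kept_ids, excl_out = rel.outlier_filter(
        coords, which=cfg.mds_pair, density_quantile=cfg.outlier_quantile)
    keep = np.array([s.id in set(kept_ids) for s in g1.samples])
    g2 = g1.subset_samples(keep)
    stage(f"ancestry: excluded {len(excl_out)} MDS density outliers")

    n_in = g2.n_variants
    g3, report = qcmod.apply_variant_filters(
        g2, maf_min=cfg.maf_min, call_rate_min=cfg.call_rate_min,
        hwe_alpha=cfg.hwe_alpha)
    g4, pruned = qcmod.prune_redundant(g3, r2_max=cfg.prune_r2, report=report)
    stage(f"QC: {n_in} variants in; {report.n_excluded_maf} excluded on MAF, "
          f"{report.n_excluded_missing} on missingness, {report.n_excluded_hwe} "
          f"on HWE, {report.n_excluded_redundant} redundant (r2 > {cfg.prune_r2}); "
          f"final set of {report.n_final} variants")

    blocks = ldmod.call_blocks(g4) if cfg.call_ld_blocks else []
    if cfg.call_ld_blocks:
        stage(f"LD: {len(blocks)} blocks called (D' CI bounds 0.7-0.98)")

    rows = [counts_from_matrix(g4, v.id) for v in g4.variants]
    table = _assoc_table(rows)
    perm = {m: assoc.permutation_maxT(g4, model=m, n_perm=cfg.n_perm,
                                      seed=cfg.seed + i)
            for i, m in enumerate((assoc.DOMINANT, assoc.RECESSIVE))}
    corr = []
    for _, row in table.iterrows():
        model = assoc.DOMINANT if row["test"] == "D" else assoc.RECESSIVE
        pr = next(p for p in perm[model] if p.variant_id == row["snp"])
        corr.append(pr.corrected_p)
    table["corrected_p"] = corr
    table = table.sort_values("p", kind="stable").reset_index(drop=True)
    stage(f"association: {int((table['p'] < cfg.top_p).sum())} variants at "
          f"p < {cfg.top_p}; best corrected p = {table['corrected_p'].min():.4g}")

    pair_results: list[cond.PairResult] = []
    if cfg.run_conditional and g4.n_variants >= 2:
        selection = cond.select_test_snps(
            g4, n_perm=min(cfg.n_perm, 2000), seed=cfg.seed + 17,
            n_select=cfg.n_test_snps)
        pair_results = cond.conditional_scan(
            g4, selection, n_perm=min(cfg.n_perm, 2000), seed=cfg.seed + 29)
        best = pair_results[0]
        stage(f"conditional scan: {len(pair_results)} pairs from "
              f"{len(selection.selected_ids)} test SNPs; best pair "
              f"{best.test_snp} x {best.target_snp} corrected p = {best.corrected_p:.4g}")

    result = PipelineResult(
        config=cfg, qc_report=report, excluded_related=excl_rel,
        excluded_outliers=excl_out, pruned=pruned, association=table,
        ld_blocks=blocks, conditional=pair_results, log_lines=log)
    if out_dir is not None:
        _write_bundle(result, coords, Path(out_dir))
    return result


def _write_bundle(res: PipelineResult, coords: rel.MDSCoordinates,
                  out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "config.json").write_text(res.config.to_json())
    res.qc_report.write_tsv(out_dir / "qc_exclusions.tsv")
    res.association.to_csv(out_dir / "association.tsv", sep="\t", index=False)
    with open(out_dir / "ld_blocks.tsv", "w") as fh:
        fh.write("chrom\tstart\tend\tn_variants\tids\n")
        for b in res.ld_blocks:
            fh.write(f"{b.chrom}\t{b.start_pos}\t{b.end_pos}\t{b.n_variants}\t"
                     f"{','.join(b.variant_ids)}\n")
    pd.DataFrame({
        "sample": coords.sample_ids,
        **{f"c{i+1}": coords.coords[:, i] for i in range(coords.k)},
    }).to_csv(out_dir / "mds.tsv", sep="\t", index=False)
    if res.conditional:
        pd.DataFrame.from_records([{
            "test_snp": r.test_snp, "target_snp": r.target_snp,
            "combined_chi2": r.combined_chi2, "combined_df": r.combined_df,
            "p": r.p, "corrected_p": r.corrected_p,
        } for r in res.conditional]).to_csv(
            out_dir / "conditional_scan.tsv", sep="\t", index=False)
    (out_dir / "run.log").write_text("\n".join(res.log_lines) + "\n")
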