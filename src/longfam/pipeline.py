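"""End-to-end orchestration: files in, association tables and diagnostics out.

This is the function the command line wraps.  It strings the modules together
in the order a practitioner would: pedigree -> kinship -> unrelated subset;
genotypes -> MAF -> common/rare split -> burden sets; LD pruning -> PCA ->
projection; medication preadjustment -> views; cached-null scans over the
design grid; two-stage refinement of the repeated/pedigree cell; thresholds,
genomic-control lambdas and QQ plots.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype_burden import (
    build_burden_sets,
    compute_maf,
    read_annotation,
    read_genotypes,
    select_burden_variants,
)
from .lmm import ModelSpec, null_model_cache
from .pedigree import compute_kinship, extract_unrelated, read_pedigree
from .phenotypes import make_view, medication_preadjust, read_phenotypes
from .scan import (
    ScanConfig,
    bonferroni_threshold,
    genomic_lambda,
    qq_data,
    run_scan,
    two_stage_refine,
)
from .stratification import ld_prune, pca_unrelated, project_relatives

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    snp_results: pd.DataFrame
    burden_results: pd.DataFrame
    refined: pd.DataFrame | None
    thresholds: dict
    lambdas: dict
    counts: dict


def run_pipeline(
    genotypes: str | Path,
    ped: str | Path,
    pheno: str | Path,
    annot: str | Path,
    out: str | Path,
    trait: str = "SBP",
    genotype_format: str = "vcf",
    cfg: ScanConfig | None = None,
    two_stage: bool = True,
    make_plots: bool = True,
) -> PipelineResult:
    """Run the full association pipeline and write results under ``out``."""
    outdir = Path(out)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "scan.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("longfam")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        return _run(
            genotypes, ped, pheno, annot, outdir, trait, genotype_format,
            cfg or ScanConfig(trait=trait), two_stage, make_plots,
        )
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(genotypes, ped_path, pheno_path, annot_path, outdir, trait,
         genotype_format, cfg, two_stage, make_plots) -> PipelineResult:
    counts: dict = {}

    pedigree = read_pedigree(ped_path)
    km = compute_kinship(pedigree)
    unrelated = extract_unrelated(pedigree, km)
    counts["subjects"] = pedigree.n_members
    counts["pedigrees"] = len(pedigree.family_ids)
    counts["unrelated"] = len(unrelated)
    logger.info("pedigree: %(subjects)d subjects, %(pedigrees)d families, "
                "%(unrelated)d unrelated", counts)

    gm = read_genotypes(genotypes, fmt=genotype_format)
    missing = set(km.subject_ids) - set(gm.subject_ids)
    if missing:
        raise ValueError(
            f"pedigree subjects absent from genotypes: {sorted(missing)[:10]}"
        )
    gm = gm.subset_subjects(km.subject_ids)
    maf = compute_maf(gm)
    common_mask = maf >= 0.05
    common_ids = [v for v, keep in common_mask.items() if keep]
    counts["variants"] = gm.n_variants
    counts["common_snps"] = len(common_ids)
    logger.info("genotypes: %d variants, %d common (MAF >= 5%%)",
                gm.n_variants, len(common_ids))

    annotation = read_annotation(annot_path)
    selected = select_burden_variants(gm, annotation, maf=maf)
    burden_sets = build_burden_sets(gm, selected, maf=maf)
    counts["transcripts_retained"] = len(burden_sets)
    logger.info("burden: %d transcripts retained after filters", len(burden_sets))

    pruned = ld_prune(gm, unrelated)
    counts["pruned_snps"] = len(pruned)
    k = min(cfg.n_pcs, max(len(unrelated) - 1, 0), len(pruned))
    pc = pca_unrelated(gm, pruned, unrelated, k=k)
    pc = project_relatives(pc, gm)
    pcs = pc.scores if k > 0 else None
    logger.info("stratification: %d pruned SNPs, %d PCs", len(pruned), k)

    phenotypes = medication_preadjust(read_phenotypes(pheno_path, trait=trait))

    snp_markers = pd.DataFrame(
        gm.dosage[:, gm.variant_index(common_ids)],
        index=gm.subject_ids, columns=common_ids,
    )
    burden_markers = pd.DataFrame(
        {bs.transcript: bs.scores for bs in burden_sets},
        index=gm.subject_ids,
    )
    snp_results = run_scan(cfg, snp_markers, phenotypes, km, unrelated, pcs=pcs)
    burden_results = run_scan(cfg, burden_markers, phenotypes, km, unrelated, pcs=pcs)

    refined = None
    if two_stage and "repeated" in cfg.views and "pedigree_sample" in cfg.designs:
        cell = snp_results[
            (snp_results["view"] == "repeated")
            & (snp_results["design"] == "pedigree_sample")
        ]
        view = make_view(phenotypes, "repeated")
        spec = ModelSpec("M4_family_subject", "repeated", "pedigree_sample")
        null4 = null_model_cache(spec, view, covariates=pcs, km=km)
        positions = gm.variants["pos"]
        refined = two_stage_refine(
            cell, cfg.top_k,
            refit=lambda vid: null4.refit(snp_markers[vid], marker_name=vid),
            positions=positions,
        )
        refined.to_csv(outdir / "refined_m4.tsv", sep="\t", index=False)

    thresholds = {}
    for label, frame in (("common_snps", snp_results), ("transcripts", burden_results)):
        m = frame["marker_id"].nunique()
        if m:
            th = bonferroni_threshold(cfg.alpha, m)
            thresholds[label] = dict(m_tests=m, raw=th.raw, rounded=th.rounded)
            logger.info("Bonferroni (%s): m=%d raw=%.4g rounded=%.2g",
                        label, m, th.raw, th.rounded)

    lambdas = {}
    for (view, design), grp in snp_results.groupby(["view", "design"]):
        p = grp["p_value"].dropna()
        if len(p):
            lam = genomic_lambda(p, warn_small=False)
            lambdas[f"{view}/{design}"] = lam
            if make_plots:
                _qq_plot(p, outdir / f"qq_{view}_{design}.png",
                         f"{view} / {design} (lambda={lam:.3f})")

    snp_results.to_csv(outdir / "snp_results.tsv", sep="\t", index=False)
    burden_results.to_csv(outdir / "burden_results.tsv", sep="\t", index=False)
    pd.Series({k: str(v) for k, v in {**counts, **thresholds}.items()}).to_csv(
        outdir / "summary.tsv", sep="\t", header=False
    )
    with open(outdir / "pruned_snps.txt", "w") as fh:
        fh.write("\n".join(pruned) + "\n")
    if pcs is not None:
        pcs.to_csv(outdir / "pc_scores.tsv", sep="\t")

    return PipelineResult(
        snp_results=snp_results,
        burden_results=burden_results,
        refined=refined,
        thresholds=thresholds,
        lambdas=lambdas,
        counts=counts,
    )


def _qq_plot(p_values, path, title: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    exp, obs = qq_data(np.asarray(p_values))
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(exp, obs, s=6, color="steelblue")
    lim = max(exp.max(), obs.max()) * 1.05
    ax.plot([0, lim], [0, lim], color="grey", lw=1)
    ax.set_xlabel("expected $-\\log_{10} p$")
    ax.set_ylabel("observed $-\\log_{10} p$")
    ax.set_title(title, fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
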