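"""Gene-dropping simulator for pedigrees, genotypes, and longitudinal phenotypes.

The generator mirrors the statistical structure the analysis assumes: founders
draw alleles from population frequencies, descendants receive one random
allele per parent (Mendelian gene dropping), and phenotypes follow the full
family/longitudinal mixed model — a polygenic effect with covariance
sigma_g^2 * 2 Psi from the pedigree kinship, a subject random intercept, a
linear age trend plus sex and smoking effects, marker effects for designated
causal variants, and an antihypertensive-medication offset subtracted from the
stored raw values so that the preadjustment step recovers the latent trait.

Default scales emulate the motivating study design scaled to desk size:
20 three-generation pedigrees of 12 (4 founders each) plus 100 singleton
founders, three visits per subject, variance components (4, 2, 4) mm Hg^2.
An optional two-subpopulation mode draws founder allele frequencies with
Balding-Nichols divergence and supports a stratified phenotype mean shift.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_burden import (
    FUNCTIONAL_CATEGORIES,
    GenotypeMatrix,
    TranscriptAnnotation,
)
from .pedigree import KinshipMatrix, Pedigree, compute_kinship
from .phenotypes import MEDICATION_OFFSET, LongitudinalPhenotypes

__all__ = [
    "PedigreeTemplate",
    "SimulationConfig",
    "SimulatedData",
    "simulate_pedigrees",
    "gene_drop",
    "build_annotation",
    "simulate_phenotypes",
    "simulate_dataset",
    "write_fam",
    "write_vcf",
    "write_dosage_tsv",
    "write_annotation_tsv",
    "write_phenotype_tsv",
    "write_dataset",
]


@dataclass(frozen=True)
class PedigreeTemplate:
    """Three-generation template: a founder couple, their children (some of
    whom marry founder spouses), and grandchildren."""

    n_children: int = 4
    n_married: int = 2
    n_grandchildren: int = 2

    def __post_init__(self) -> None:
        if self.n_married > self.n_children:
            raise ValueError("n_married cannot exceed n_children")
        if self.n_children < 1:
            raise ValueError("template must have at least one child (no founders rule)")

    @property
    def size(self) -> int:
        return 2 + self.n_children + self.n_married * (1 + self.n_grandchildren)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset."""

    seed: int = 0
    # sample structure
    n_pedigrees: int = 20
    template: PedigreeTemplate = field(default_factory=PedigreeTemplate)
    n_unrelated_extra: int = 100
    n_visits: int = 3
    visit_spacing_years: float = 5.0
    # variants
    n_common: int = 300
    common_maf_range: tuple = (0.05, 0.5)
    n_transcripts: int = 20
    rare_per_transcript: int = 8
    rare_maf_range: tuple = (0.002, 0.05)
    # effects (trait units mm Hg; marker effects per allele / per burden unit)
    causal_common_index: int | None = None
    beta_common: float = 0.0
    causal_transcript_index: int | None = None
    beta_burden: float = 0.0
    intercept: float = 100.0
    gamma_age: float = 0.5
    gamma_sex: float = 3.0
    gamma_smoke: float = 5.0
    # variance components (mm Hg^2)
    sigma2_g: float = 4.0
    sigma2_b: float = 2.0
    sigma2_e: float = 4.0
    # covariate / medication processes
    smoking_prob: float = 0.25
    medication_prob: float = 0.2
    trait: str = "SBP"
    # two-subpopulation admixture scenario
    n_subpops: int = 1
    fst: float = 0.05
    subpop_shift: float = 0.0

    def __post_init__(self) -> None:
        if min(self.sigma2_g, self.sigma2_b, self.sigma2_e) < 0:
            raise ValueError("variance components must be nonnegative")
        if self.n_visits < 1:
            raise ValueError("need at least one visit")
        for lo, hi in (self.common_maf_range, self.rare_maf_range):
            if not (0.0 < lo <= hi <= 0.5):
                raise ValueError("MAF ranges must lie in (0, 0.5]")


@dataclass
class SimulatedData:
    """Everything one replicate produces, ready for the pipeline."""

    cfg: SimulationConfig
    ped: Pedigree
    km: KinshipMatrix
    gm: GenotypeMatrix
    annotation: TranscriptAnnotation
    phenotypes: LongitudinalPhenotypes
    true_maf: pd.Series
    common_ids: list
    transcript_members: dict
    causal_common: str | None
    causal_transcript: str | None
    subpop_of: pd.Series | None


# ---------------------------------------------------------------------------
# pedigrees


def simulate_pedigrees(cfg: SimulationConfig) -> Pedigree:
    """n_pedigrees independent template copies plus singleton founders.

    Deterministic: the structure has no randomness.  Member ids encode
    pedigree and index (``P03I05``), singletons are ``U017``; sexes alternate
    so every couple is male/female.
    """
    t = cfg.template
    rows = []
    for p in range(cfg.n_pedigrees):
        fid = f"F{p:03d}"

        def iid(k: int) -> str:
            return f"P{p:03d}I{k:02d}"

        k = 0
        fa, mo = iid(k), iid(k + 1)
        rows.append(dict(fid=fid, iid=fa, father=None, mother=None, sex="male"))
        rows.append(dict(fid=fid, iid=mo, father=None, mother=None, sex="female"))
        k += 2
        children = []
        for c in range(t.n_children):
            cid = iid(k)
            k += 1
            sex = "male" if c % 2 == 0 else "female"
            rows.append(dict(fid=fid, iid=cid, father=fa, mother=mo, sex=sex))
            children.append((cid, sex))
        for c in range(t.n_married):
            cid, sex = children[c]
            spouse = iid(k)
            k += 1
            s_sex = "female" if sex == "male" else "male"
            rows.append(dict(fid=fid, iid=spouse, father=None, mother=None, sex=s_sex))
            g_fa, g_mo = (cid, spouse) if sex == "male" else (spouse, cid)
            for g in range(t.n_grandchildren):
                gid = iid(k)
                k += 1
                rows.append(
                    dict(
                        fid=fid, iid=gid, father=g_fa, mother=g_mo,
                        sex="male" if g % 2 == 0 else "female",
                    )
                )
    for u in range(cfg.n_unrelated_extra):
        uid = f"U{u:03d}"
        rows.append(
            dict(
                fid=uid, iid=uid, father=None, mother=None,
                sex="male" if u % 2 == 0 else "female",
            )
        )
    members = pd.DataFrame(
        rows, columns=["fid", "iid", "father", "mother", "sex"]
    ).astype(object)
    return Pedigree(members=members)


def _generation_of(ped: Pedigree) -> pd.Series:
    """Generation depth per member; married-in founders inherit their
    co-parent's generation so simulated ages stay coherent."""
    gen: dict = {}
    members = ped.members
    pending = list(members.itertuples())
    while pending:
        rest = []
        for row in pending:
            if row.father is None:
                gen.setdefault(row.iid, 0)
            elif row.father in gen and row.mother in gen:
                g = max(gen[row.father], gen[row.mother]) + 1
                gen[row.iid] = g
            else:
                rest.append(row)
                continue
        if len(rest) == len(pending):
            break
        pending = rest
    # lift married-in founders to their partner's generation
    for row in members.itertuples():
        if row.father is not None:
            g_child = gen[row.iid]
            for par in (row.father, row.mother):
                gen[par] = max(gen[par], g_child - 1)
    return pd.Series([gen[r.iid] for r in members.itertuples()],
                     index=members["iid"].tolist())


# ---------------------------------------------------------------------------
# genotypes


def _assign_subpops(ped: Pedigree, cfg: SimulationConfig, rng) -> pd.Series | None:
    if cfg.n_subpops <= 1:
        return None
    fam_ids = ped.family_ids
    fam_pop = {fid: i % cfg.n_subpops for i, fid in enumerate(fam_ids)}
    pops = [fam_pop[r.fid] for r in ped.members.itertuples()]
    return pd.Series(pops, index=ped.members["iid"].tolist())


def gene_drop(
    ped: Pedigree,
    mafs: np.ndarray,
    rng: np.random.Generator,
    chrom: str = "3",
    positions: np.ndarray | None = None,
    variant_ids: list | None = None,
    subpop_of: pd.Series | None = None,
    fst: float = 0.05,
) -> GenotypeMatrix:
    """Mendelian gene dropping at independent biallelic loci.

    Founders draw two alleles i.i.d. Bernoulli(MAF) per variant; non-founders
    inherit one uniformly chosen allele from each parent; dosage is the allele
    sum.  Under a subpopulation assignment, founder frequencies are drawn per
    subpopulation from the Balding-Nichols beta with divergence ``fst``.
    """
    mafs = np.asarray(mafs, dtype=float)
    m = mafs.size
    members = ped.members
    n = len(members)
    if positions is None:
        positions = np.arange(1, m + 1) * 1000
    if variant_ids is None:
        variant_ids = [f"{chrom}_{p}" for p in positions]

    if subpop_of is not None:
        n_pops = int(subpop_of.max()) + 1
        a = mafs * (1.0 - fst) / fst
        b = (1.0 - mafs) * (1.0 - fst) / fst
        pop_freq = np.stack([rng.beta(a, b) for _ in range(n_pops)])
        pop_freq = np.clip(pop_freq, 1e-4, 0.9999)
    else:
        pop_freq = mafs[None, :]

    alleles = np.zeros((n, 2, m), dtype=np.int8)
    idx = {iid: i for i, iid in enumerate(members["iid"])}
    for row in members.itertuples():
        i = idx[row.iid]
        if row.father is None:
            pop = 0 if subpop_of is None else int(subpop_of[row.iid])
            freq = pop_freq[pop]
            alleles[i, 0] = rng.random(m) < freq
            alleles[i, 1] = rng.random(m) < freq
        else:
            f, mo = idx[row.father], idx[row.mother]
            alleles[i, 0] = alleles[f, rng.integers(0, 2, m).astype(np.int8), np.arange(m)]
            alleles[i, 1] = alleles[mo, rng.integers(0, 2, m).astype(np.int8), np.arange(m)]
    dosage = alleles.sum(axis=1).astype(float)
    variants = pd.DataFrame(
        dict(chrom=chrom, pos=positions, ref="A", alt="G", flipped=False),
        index=variant_ids,
    )
    return GenotypeMatrix(
        subject_ids=members["iid"].tolist(),
        variant_ids=list(variant_ids),
        dosage=dosage,
        variants=variants,
    )


def build_annotation(
    common_ids: list,
    transcript_members: dict[str, list],
    rng: np.random.Generator,
) -> TranscriptAnnotation:
    """Annotation table: functional categories for transcript members, plus
    'other' decoy records for a sample of common variants."""
    cats = sorted(FUNCTIONAL_CATEGORIES)
    rows = []
    for transcript, variants in transcript_members.items():
        for v in variants:
            rows.append(
                dict(
                    variant_id=v,
                    transcript=transcript,
                    category=cats[int(rng.integers(0, len(cats)))],
                )
            )
    for v in common_ids[: max(1, len(common_ids) // 10)]:
        rows.append(dict(variant_id=v, transcript="NR_DECOY.1", category="other"))
    return TranscriptAnnotation(records=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# phenotypes


def simulate_phenotypes(
    ped: Pedigree,
    km: KinshipMatrix,
    gm: GenotypeMatrix,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    causal_common: str | None = None,
    causal_burden: pd.Series | None = None,
    subpop_of: pd.Series | None = None,
) -> LongitudinalPhenotypes:
    """Longitudinal traits under the full family/longitudinal mixed model.

    The latent trait is marker effects + covariate effects + polygenic effect
    (MVN with covariance sigma_g^2 * 2 Psi per family) + subject intercept +
    i.i.d. residual; ages rise by ``visit_spacing_years`` per visit.  Stored
    raw values subtract the medication offset on treated records, so
    :func:`longfam.phenotypes.medication_preadjust` recovers the latent value
    record by record.
    """
    subjects = km.subject_ids
    n = len(subjects)
    T = cfg.n_visits

    if causal_common is not None and causal_common not in gm.variant_ids:
        raise KeyError(f"causal marker {causal_common!r} not in genotype matrix")

    # polygenic effect, blockwise Cholesky of sigma_g^2 * 2 Psi
    g = np.zeros(n)
    if cfg.sigma2_g > 0:
        fam = km.family_ids
        start = 0
        for i in range(1, n + 1):
            if i == n or fam[i] != fam[start]:
                block = 2.0 * km.psi[start:i, start:i]
                L = np.linalg.cholesky(block + 1e-10 * np.eye(i - start))
                g[start:i] = np.sqrt(cfg.sigma2_g) * (L @ rng.standard_normal(i - start))
                start = i
    b = np.sqrt(cfg.sigma2_b) * rng.standard_normal(n)

    gen = _generation_of(ped).reindex(subjects)
    base_age = 65.0 - 25.0 * gen.to_numpy(float) + rng.uniform(-5, 5, n)
    base_age = np.clip(base_age, 8.0, 95.0)
    sex_of = dict(zip(ped.members["iid"], ped.members["sex"]))
    sex = np.array([1 if sex_of[s] == "male" else 0 for s in subjects])
    smoke = (rng.random(n) < cfg.smoking_prob).astype(int)

    marker_term = np.zeros(n)
    if causal_common is not None and cfg.beta_common != 0.0:
        j = gm.variant_index([causal_common])[0]
        dose = pd.Series(gm.dosage[:, j], index=gm.subject_ids).reindex(subjects)
        marker_term += cfg.beta_common * dose.to_numpy(float)
    if causal_burden is not None and cfg.beta_burden != 0.0:
        marker_term += cfg.beta_burden * causal_burden.reindex(subjects).to_numpy(float)

    shift = np.zeros(n)
    if subpop_of is not None and cfg.subpop_shift != 0.0:
        shift = cfg.subpop_shift * subpop_of.reindex(subjects).to_numpy(float)

    offset = MEDICATION_OFFSET[cfg.trait]
    recs = []
    for t in range(T):
        age_t = base_age + t * cfg.visit_spacing_years
        eps = np.sqrt(cfg.sigma2_e) * rng.standard_normal(n)
        latent = (
            cfg.intercept
            + marker_term
            + cfg.gamma_age * age_t
            + cfg.gamma_sex * sex
            + cfg.gamma_smoke * smoke
            + shift
            + g
            + b
            + eps
        )
        med = (rng.random(n) < cfg.medication_prob).astype(int)
        recs.append(
            pd.DataFrame(
                dict(
                    subject_id=subjects,
                    visit=t + 1,
                    value=latent - offset * med,
                    age=age_t,
                    sex=sex,
                    smoke=smoke,
                    med=med,
                )
            )
        )
    data = pd.concat(recs, ignore_index=True)
    # family-major subject order, visits ascending
    order = {s: i for i, s in enumerate(subjects)}
    data = data.sort_values(
        ["subject_id", "visit"], key=lambda c: c.map(order) if c.name == "subject_id" else c,
        kind="stable",
    ).reset_index(drop=True)
    return LongitudinalPhenotypes(data=data, trait=cfg.trait)


# ---------------------------------------------------------------------------
# one-stop replicate


def simulate_dataset(cfg: SimulationConfig) -> SimulatedData:
    """Generate one complete replicate (pedigree, genotypes, annotation, phenotypes)."""
    rng = np.random.default_rng(cfg.seed)
    ped = simulate_pedigrees(cfg)
    km = compute_kinship(ped)
    subpop_of = _assign_subpops(ped, cfg, rng)

    lo, hi = cfg.common_maf_range
    common_maf = rng.uniform(lo, hi, cfg.n_common)
    rlo, rhi = cfg.rare_maf_range
    n_rare = cfg.n_transcripts * cfg.rare_per_transcript
    rare_maf = np.exp(rng.uniform(np.log(rlo), np.log(rhi), n_rare))
    mafs = np.concatenate([common_maf, rare_maf])
    positions = np.arange(1, mafs.size + 1) * 1000
    gm = gene_drop(
        ped, mafs, rng, positions=positions,
        subpop_of=subpop_of, fst=cfg.fst,
    )
    common_ids = gm.variant_ids[: cfg.n_common]
    rare_ids = gm.variant_ids[cfg.n_common :]
    transcript_members = {
        f"NM_{1000 + t}.1": rare_ids[
            t * cfg.rare_per_transcript : (t + 1) * cfg.rare_per_transcript
        ]
        for t in range(cfg.n_transcripts)
    }
    annotation = build_annotation(common_ids, transcript_members, rng)

    causal_common = (
        common_ids[cfg.causal_common_index]
        if cfg.causal_common_index is not None
        else None
    )
    causal_transcript = None
    causal_burden = None
    if cfg.causal_transcript_index is not None:
        causal_transcript = list(transcript_members)[cfg.causal_transcript_index]
        cols = gm.variant_index(transcript_members[causal_transcript])
        causal_burden = pd.Series(
            gm.dosage[:, cols].sum(axis=1), index=gm.subject_ids
        )
    phenotypes = simulate_phenotypes(
        ped, km, gm, cfg, rng,
        causal_common=causal_common,
        causal_burden=causal_burden,
        subpop_of=subpop_of,
    )
    return SimulatedData(
        cfg=cfg,
        ped=ped,
        km=km,
        gm=gm,
        annotation=annotation,
        phenotypes=phenotypes,
        true_maf=pd.Series(mafs, index=gm.variant_ids),
        common_ids=list(common_ids),
        transcript_members=transcript_members,
        causal_common=causal_common,
        causal_transcript=causal_transcript,
        subpop_of=subpop_of,
    )


# ---------------------------------------------------------------------------
# writers: the exact formats the pipeline reads


_SEX_OUT = {"male": "1", "female": "2", "unknown": "0"}


def write_fam(ped: Pedigree, path) -> None:
    with open(path, "w") as fh:
        for row in ped.members.itertuples():
            fh.write(
                "\t".join(
                    [
                        str(row.fid),
                        str(row.iid),
                        row.father or "0",
                        row.mother or "0",
                        _SEX_OUT[row.sex],
                        "-9",
                    ]
                )
                + "\n"
            )


_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Plain-text VCF 4.2 with hard GT calls (dosages must be integral)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n##source=longfam-simdata\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(s) for s in gm.subject_ids)
            + "\n"
        )
        for j, vid in enumerate(gm.variant_ids):
            meta = gm.variants.iloc[j]
            col = gm.dosage[:, j]
            calls = [
                "./." if np.isnan(d) else _GT_CODE[int(round(d))] for d in col
            ]
            fh.write(
                "\t".join(
                    [
                        str(meta["chrom"]), str(int(meta["pos"])), str(vid),
                        str(meta["ref"]), str(meta["alt"]), ".", "PASS", ".", "GT",
                    ]
                    + calls
                )
                + "\n"
            )


def write_dosage_tsv(gm: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(gm.dosage, index=gm.subject_ids, columns=gm.variant_ids)
    df.to_csv(path, sep="\t", index_label="subject_id")


def write_annotation_tsv(ann: TranscriptAnnotation, path) -> None:
    out = ann.records.rename(columns={"transcript": "transcript_accession"})
    out.to_csv(path, sep="\t", index=False)


def write_phenotype_tsv(ph: LongitudinalPhenotypes, path) -> None:
    """Long-format table with the trait in its own lower-cased column and the
    other trait filled with zeros (single-trait simulation)."""
    d = ph.data
    out = pd.DataFrame(
        dict(
            subject_id=d["subject_id"],
            visit=d["visit"],
            sbp=d["value"] if ph.trait == "SBP" else 0.0,
            dbp=d["value"] if ph.trait == "DBP" else 0.0,
            age=d["age"],
            sex=d["sex"],
            smoke=d["smoke"],
            med=d["med"],
        )
    )
    out.to_csv(path, sep="\t", index=False)


def write_dataset(sim: SimulatedData, outdir) -> dict:
    """Write FAM/VCF/annotation/phenotype files; returns the path map."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = dict(
        fam=outdir / "sim.fam",
        vcf=outdir / "sim.vcf",
        annot=outdir / "sim_annotation.tsv",
        pheno=outdir / "sim_phenotypes.tsv",
    )
    write_fam(sim.ped, paths["fam"])
    write_vcf(sim.gm, paths["vcf"])
    write_annotation_tsv(sim.annotation, paths["annot"])
    write_phenotype_tsv(sim.phenotypes, paths["pheno"])
    return paths
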