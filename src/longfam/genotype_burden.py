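"""Genotype input, minor-allele frequencies, and rare-variant burden scores.

Rare variants (MAF < 5%) that are putatively functional are collapsed per mRNA
transcript into a burden score S_i = sum_j G_ij, the per-subject sum of
minor-allele dosages over the transcript's qualifying variants.  Transcripts
whose total rare allele frequency (sum of member MAFs) falls below a floor are
excluded; the burden score then enters the regression models as a regular
covariate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FUNCTIONAL_CATEGORIES",
    "GenotypeMatrix",
    "TranscriptAnnotation",
    "BurdenSet",
    "read_genotypes",
    "read_annotation",
    "compute_maf",
    "select_burden_variants",
    "build_burden_sets",
]

#: Functional categories that qualify a rare variant for the burden score.
FUNCTIONAL_CATEGORIES = frozenset(
    {
        "missense",
        "missense-near-splice",
        "splice-3",
        "splice-5",
        "stop-gained",
        "stop-lost",
        "stop-lost-near-splice",
    }
)


@dataclass
class GenotypeMatrix:
    """Subjects x variants minor-allele dosage matrix with variant metadata.

    ``dosage`` holds allele counts in [0, 2] (fractional dosages allowed,
    ``nan`` = missing).  ``variants`` has one row per variant with columns
    ``chrom, pos, ref, alt, flipped``; ``flipped`` records sites whose reported
    alternate allele was the major allele and whose dosages were reoriented.
    """

    subject_ids: list
    variant_ids: list
    dosage: np.ndarray
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.subject_ids), len(self.variant_ids)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.subject_ids)} subjects x {len(self.variant_ids)} variants"
            )
        with np.errstate(invalid="ignore"):
            bad = (self.dosage < 0) | (self.dosage > 2)
        if np.any(bad):
            raise ValueError("dosages must lie in [0, 2] or be missing (nan)")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    def variant_index(self, variant_ids) -> np.ndarray:
        lookup = {v: j for j, v in enumerate(self.variant_ids)}
        return np.asarray([lookup[v] for v in variant_ids], dtype=int)

    def subset_subjects(self, subject_ids) -> "GenotypeMatrix":
        lookup = {s: i for i, s in enumerate(self.subject_ids)}
        missing = [s for s in subject_ids if s not in lookup]
        if missing:
            raise KeyError(f"subjects absent from genotype matrix: {missing[:10]}")
        ix = [lookup[s] for s in subject_ids]
        return GenotypeMatrix(
            subject_ids=list(subject_ids),
            variant_ids=self.variant_ids,
            dosage=self.dosage[ix],
            variants=self.variants,
        )


@dataclass(frozen=True)
class TranscriptAnnotation:
    """Variant-to-transcript functional annotation.

    ``records`` columns: ``variant_id, transcript, category``.  Annotation is
    transcript-specific: the same variant may be e.g. missense for one
    transcript and intronic ("other") for another.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        req = ["variant_id", "transcript", "category"]
        if list(self.records.columns[:3]) != req:
            raise ValueError(f"annotation table must have columns {req}")
        if self.records.duplicated(subset=["variant_id", "transcript"]).any():
            raise ValueError("duplicate (variant_id, transcript) annotation pairs")


@dataclass
class BurdenSet:
    """A retained transcript with its member rare variants and burden scores."""

    transcript: str
    member_variants: list
    total_rare_allele_freq: float
    scores: pd.Series  # indexed by subject id


def read_annotation(path) -> TranscriptAnnotation:
    """Read a TSV with columns variant_id, transcript_accession/transcript, category."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    df = df.rename(columns={"transcript_accession": "transcript"})
    return TranscriptAnnotation(records=df[["variant_id", "transcript", "category"]])


def _orient_minor(dosage: np.ndarray, variants: pd.DataFrame) -> None:
    """Flip dosages in place so the counted allele is the minor one."""
    af = np.nanmean(dosage, axis=0) / 2.0
    flip = af > 0.5
    dosage[:, flip] = 2.0 - dosage[:, flip]
    variants["flipped"] = flip


def read_genotypes(path, fmt: str = "vcf") -> GenotypeMatrix:
    """Read genotypes from a VCF (GT or DS) or a dosage TSV.

    Minor-allele orientation is enforced: sites with alternate-allele frequency
    above 0.5 are flipped (dosage -> 2 - dosage) and flagged in
    ``variants['flipped']``.

    The dosage TSV layout is one header row of variant ids, then one row per
    subject: subject id followed by dosages.  Variant ids of the form
    ``chrom_pos`` are parsed into coordinates.
    """
    if fmt == "vcf":
        return _read_vcf(path)
    if fmt == "dosage-tsv":
        return _read_dosage_tsv(path)
    raise ValueError(f"unknown genotype format {fmt!r} (expected 'vcf' or 'dosage-tsv')")


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    subjects = list(vcf.samples)
    ids, rows, meta = [], [], []
    for rec_no, v in enumerate(vcf, start=1):
        vid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}_{v.POS}"
        try:
            ds = v.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            dose = np.asarray(ds, dtype=float).reshape(len(subjects))
        else:
            gts = v.genotypes
            if gts is None:
                raise ValueError(f"{path}: record {rec_no} ({vid}): no GT or DS field")
            dose = np.empty(len(subjects))
            for i, g in enumerate(gts):
                a = [x for x in g[:-1]]
                dose[i] = np.nan if any(x < 0 for x in a) else float(sum(a))
        with np.errstate(invalid="ignore"):
            if np.any((dose < 0) | (dose > 2)):
                raise ValueError(
                    f"{path}: record {rec_no} ({vid}): dosage outside [0, 2]"
                )
        ids.append(vid)
        rows.append(dose)
        meta.append(
            dict(
                chrom=v.CHROM,
                pos=int(v.POS),
                ref=v.REF,
                alt=v.ALT[0] if v.ALT else ".",
            )
        )
    dosage = np.asarray(rows).T if rows else np.empty((len(subjects), 0))
    variants = pd.DataFrame(meta, columns=["chrom", "pos", "ref", "alt"], index=ids)
    _orient_minor(dosage, variants)
    return GenotypeMatrix(
        subject_ids=subjects, variant_ids=ids, dosage=dosage, variants=variants
    )


def _read_dosage_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        dosage = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric dosage entry: {exc}") from exc
    ids = [str(c) for c in df.columns]
    chrom, pos = [], []
    for j, vid in enumerate(ids):
        parts = vid.rsplit("_", 1)
        if len(parts) == 2 and parts[1].isdigit():
            chrom.append(parts[0])
            pos.append(int(parts[1]))
        else:
            chrom.append("")
            pos.append(j + 1)
    variants = pd.DataFrame(
        dict(chrom=chrom, pos=pos, ref=".", alt="."), index=ids
    )
    _orient_minor(dosage, variants)
    return GenotypeMatrix(
        subject_ids=[str(s) for s in df.index],
        variant_ids=ids,
        dosage=dosage,
        variants=variants,
    )


def compute_maf(gm: GenotypeMatrix, subjects=None) -> pd.Series:
    """Per-variant minor allele frequency, folded to [0, 0.5].

    MAF is computed on the full analyzed sample by default; pass ``subjects``
    to restrict (e.g. to founders).  All-missing variants get ``nan`` and a
    logged flag; they are excluded downstream.
    """
    dosage = gm.dosage if subjects is None else gm.subset_subjects(subjects).dosage
    n_obs = np.sum(~np.isnan(dosage), axis=0)
    with np.errstate(invalid="ignore"):
        af = np.nansum(dosage, axis=0) / (2.0 * n_obs)
    af[n_obs == 0] = np.nan
    maf = np.minimum(af, 1.0 - af)
    n_bad = int(np.sum(n_obs == 0))
    if n_bad:
        logger.warning("%d variant(s) with all dosages missing; flagged nan", n_bad)
    return pd.Series(maf, index=gm.variant_ids, name="maf")


def select_burden_variants(
    gm: GenotypeMatrix,
    ann: TranscriptAnnotation,
    maf_cut: float = 0.05,
    maf: pd.Series | None = None,
) -> dict[str, list]:
    """Per-transcript lists of rare (MAF strictly below ``maf_cut``) functional variants.

    A variant qualifies for a transcript only if its category *for that
    transcript* is one of :data:`FUNCTIONAL_CATEGORIES`.  Annotation records
    that reference unknown variants are skipped with a logged count.
    """
    if maf is None:
        maf = compute_maf(gm)
    known = set(gm.variant_ids)
    rec = ann.records
    unknown = ~rec["variant_id"].isin(known)
    if unknown.any():
        logger.warning(
            "skipping %d annotation record(s) referencing unknown variants",
            int(unknown.sum()),
        )
        rec = rec[~unknown]
    out: dict[str, list] = {}
    for row in rec.itertuples():
        if row.category not in FUNCTIONAL_CATEGORIES:
            continue
        m = maf.get(row.variant_id)
        if m is None or np.isnan(m) or not (m < maf_cut):
            continue
        out.setdefault(row.transcript, []).append(row.variant_id)
    return out


def build_burden_sets(
    gm: GenotypeMatrix,
    selected: dict[str, list],
    min_total_freq: float = 0.01,
    maf: pd.Series | None = None,
    hard_call: bool = False,
) -> list[BurdenSet]:
    """Burden scores S_i = sum of member dosages, dropping low-frequency transcripts.

    Transcripts whose summed member MAF is below ``min_total_freq`` are
    excluded.  Missing dosages are mean-imputed per variant before summation.
    ``hard_call=True`` rounds fractional dosages to the nearest integer first.
    """
    if maf is None:
        maf = compute_maf(gm)
    sets: list[BurdenSet] = []
    n_dropped = 0
    for transcript in sorted(selected):
        variants = selected[transcript]
        if not variants:
            continue
        total = float(maf[variants].sum())
        if total < min_total_freq:
            n_dropped += 1
            continue
        cols = gm.variant_index(variants)
        block = gm.dosage[:, cols].copy()
        if hard_call:
            block = np.round(block)
        col_mean = np.nanmean(block, axis=0)
        nan_ix = np.where(np.isnan(block))
        block[nan_ix] = np.take(col_mean, nan_ix[1])
        scores = pd.Series(block.sum(axis=1), index=gm.subject_ids, name=transcript)
        sets.append(
            BurdenSet(
                transcript=transcript,
                member_variants=list(variants),
                total_rare_allele_freq=total,
                scores=scores,
            )
        )
    logger.info(
        "retained %d transcript(s); dropped %d below total rare allele frequency %g",
        len(sets),
        n_dropped,
        min_total_freq,
    )
    return sets
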