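"""Readers and writers for the pipeline's file formats.

Variant tables travel as a pinned TSV dialect (header-versioned) or as VCF
with per-sample AD/DP fields; gene sets as GMT; clonotype tables as
AIRR-style TSV; expression counts as genes-by-samples TSV with a sample
annotation TSV.  Every writer round-trips exactly through its reader.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .clonal import MutationPartition
from .repertoire import RepertoireSample
from .signatures import ExpressionMatrix, GeneSetCollection
from .simulate import ClonalTruth
from .union import VARIANT_COLUMNS, UnionMafMatrix

__all__ = [
    "read_variants", "write_variants",
    "read_gmt", "write_gmt",
    "read_repertoire", "write_repertoire",
    "read_counts", "write_counts",
    "write_union_matrix", "write_partition", "write_truth",
]

VARIANT_DIALECT_HEADER = "#pairedtumor-variants v1"
REPERTOIRE_COLUMNS = ["sample_id", "subject_id", "timepoint", "chain", "cdr3_aa", "count"]
TIMEPOINTS = ("pre", "post")


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


# ---------------------------------------------------------------------------
# variants


def _validate_variant_frame(df: pd.DataFrame, path) -> pd.DataFrame:
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    for col, kind in (("pos", int), ("ref_count", int), ("alt_count", int),
                      ("quality", float)):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            line = int(df.index[bad][0]) + 2  # header line + 1-based
            raise ParseError(f"{path}: malformed {col} value "
                             f"{df.loc[df.index[bad][0], col]!r} at line {line}")
        df[col] = converted.astype(kind)
    if (df["pos"] < 1).any():
        raise ParseError(f"{path}: positions must be 1-based (>= 1)")
    if ((df["ref_count"] < 0) | (df["alt_count"] < 0)).any():
        raise ParseError(f"{path}: negative read counts")
    bad_tp = ~df["timepoint"].isin(TIMEPOINTS)
    if bad_tp.any():
        raise ParseError(f"{path}: unknown timepoint {df.loc[bad_tp, 'timepoint'].iloc[0]!r} "
                         f"(expected one of {TIMEPOINTS})")
    if (df["ref"] == df["alt"]).any():
        raise ParseError(f"{path}: ref allele equals alt allele")
    return df[VARIANT_COLUMNS]


def read_variants(path, dialect: str = "tsv", *, subject_id: str | None = None,
                  sample_id: str | None = None, timepoint: str | None = None,
                  quality_field: str | None = None) -> pd.DataFrame:
    """Read a variant table into the pinned record layout.

    ``dialect="tsv"`` reads the package's own TSV dialect.  ``dialect="vcf"``
    reads a single-sample VCF via pysam (uncompressed or bgzipped), taking
    ref/alt read counts from the sample's AD field and caller quality from
    ``quality_field`` (an INFO key such as Strelka's QSS/QSI) or the QUAL
    column; the sample's subject/timepoint identity, which VCF does not
    carry, must be supplied.
    """
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        return _validate_variant_frame(df, path)
    if dialect == "vcf":
        return _read_vcf(path, subject_id=subject_id, sample_id=sample_id,
                         timepoint=timepoint, quality_field=quality_field)
    raise ValueError(f"unknown dialect: {dialect}")


def _read_vcf(path, *, subject_id, sample_id, timepoint, quality_field) -> pd.DataFrame:
    import pysam

    if subject_id is None or sample_id is None or timepoint is None:
        raise ValueError("VCF input requires subject_id, sample_id and timepoint")
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        vcf_samples = list(vcf.header.samples)
        if not vcf_samples:
            raise ParseError(f"{path}: VCF has no sample columns")
        col = vcf_samples[0]
        for rec in vcf:
            if not rec.alts:
                continue
            sample = rec.samples[col]
            ad = sample.get("AD")
            if ad is None or len(ad) < 2:
                raise ParseError(f"{path}: record {rec.chrom}:{rec.pos} lacks an AD field")
            if quality_field is not None:
                quality = float(rec.info.get(quality_field))
            else:
                quality = float(rec.qual) if rec.qual is not None else 0.0
            ref, alt = rec.ref, rec.alts[0]
            rows.append({
                "subject_id": subject_id, "sample_id": sample_id,
                "timepoint": timepoint, "chrom": rec.chrom, "pos": rec.pos,
                "ref": ref, "alt": alt,
                "ref_count": int(ad[0]), "alt_count": int(ad[1]),
                "quality": quality,
                "variant_class": "SNV" if len(ref) == 1 and len(alt) == 1 else "indel",
            })
    return _validate_variant_frame(pd.DataFrame(rows, columns=VARIANT_COLUMNS), path)


def write_variants(records: pd.DataFrame, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(VARIANT_DIALECT_HEADER + "\n")
        records[VARIANT_COLUMNS].to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene sets (GMT)


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: one set per line, tab-separated name, description, genes."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}: line {lineno} has fewer than 3 fields")
            name, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if name in sets:
                raise ParseError(f"{path}: duplicate gene set name {name!r} at line {lineno}")
            sets[name] = set(genes)
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")


# ---------------------------------------------------------------------------
# repertoires (AIRR-style TSV)


def read_repertoire(path) -> list[RepertoireSample]:
    df = pd.read_csv(path, sep="\t", dtype={"count": int})
    missing = [c for c in REPERTOIRE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    if (df["count"] < 1).any():
        raise ParseError(f"{path}: clonotype counts must be >= 1")
    samples = []
    for sample_id, grp in df.groupby("sample_id", sort=False):
        if grp["cdr3_aa"].duplicated().any():
            dup = grp.loc[grp["cdr3_aa"].duplicated(), "cdr3_aa"].iloc[0]
            raise ParseError(f"{path}: duplicate clonotype {dup!r} in sample {sample_id}")
        meta = grp.iloc[0]
        samples.append(RepertoireSample(
            sample_id=str(sample_id), subject_id=str(meta["subject_id"]),
            timepoint=str(meta["timepoint"]), chain=str(meta["chain"]),
            clonotypes=dict(zip(grp["cdr3_aa"], grp["count"].astype(int))),
        ))
    return samples


def write_repertoire(samples: list[RepertoireSample], path) -> None:
    rows = []
    for s in samples:
        for cdr3, count in sorted(s.clonotypes.items()):
            rows.append({"sample_id": s.sample_id, "subject_id": s.subject_id,
                         "timepoint": s.timepoint, "chain": s.chain,
                         "cdr3_aa": cdr3, "count": count})
    pd.DataFrame(rows, columns=REPERTOIRE_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# expression counts


def read_counts(path, annotations_path) -> ExpressionMatrix:
    counts = pd.read_csv(path, sep="\t", index_col=0)
    counts.index.name = "gene"
    if counts.index.has_duplicates:
        dup = counts.index[counts.index.duplicated()][0]
        raise ParseError(f"{path}: duplicate gene row {dup!r}")
    if (counts.to_numpy() < 0).any():
        raise ParseError(f"{path}: negative counts")
    annotations = pd.read_csv(annotations_path, sep="\t", index_col=0)
    return ExpressionMatrix(counts=counts, annotations=annotations)


def write_counts(m: ExpressionMatrix, counts_path, annotations_path) -> None:
    m.counts.to_csv(counts_path, sep="\t")
    m.annotations.to_csv(annotations_path, sep="\t")


# ---------------------------------------------------------------------------
# analysis outputs


def write_union_matrix(matrix: UnionMafMatrix, path, sidecar_path=None) -> None:
    """Union MAF matrix as TSV (loci rows, sample columns) + JSON provenance."""
    out = matrix.maf.copy()
    out.index = [f"{c}:{p}:{r}:{a}" for c, p, r, a in matrix.loci]
    out.index.name = "locus"
    out.to_csv(path, sep="\t", na_rep="NA")
    if sidecar_path is None:
        sidecar_path = Path(path).with_suffix(".provenance.json")
    with open(sidecar_path, "w") as fh:
        json.dump({"subject_id": matrix.subject_id,
                   "samples": matrix.samples,
                   "timepoints": matrix.timepoints,
                   **matrix.provenance}, fh, indent=2, sort_keys=True)


def write_partition(partition: MutationPartition, path) -> None:
    rows = []
    for locus, label in partition.labels.items():
        locus_id = ":".join(str(x) for x in locus)
        for s in partition.observed.columns:
            rows.append({"locus": locus_id, "sample_id": s,
                         "observed": bool(partition.observed.loc[locus, s]),
                         "label": label})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_truth(truths: list[ClonalTruth], path) -> None:
    """Simulator ground truth as a sidecar TSV keyed by mutation id."""
    rows = []
    for t in truths:
        fractions = {cid: (fpre, fpost) for cid, fpre, fpost in t.clones}
        for mut_id, clone in t.mutation_assignment.items():
            fpre, fpost = fractions[clone]
            rows.append({
                "subject_id": t.subject_id, "mutation_id": mut_id, "clone_id": clone,
                "clone_fraction_pre": fpre, "clone_fraction_post": fpost,
                "purity_pre": t.purity_pre, "purity_post": t.purity_post,
                "true_maf_pre": t.purity_pre * fpre / 2.0,
                "true_maf_post": t.purity_post * fpost / 2.0,
                "selection_strength": t.selection_strength,
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
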