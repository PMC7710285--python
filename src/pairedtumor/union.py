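"""Per-subject union-set mutant-allele-frequency matrices.

A somatic call set from one sample misses true mutations that fall just under
the caller's confidence threshold in that sample; comparing two samples on
their own call sets therefore inflates apparent differences.  The union-set
construction limits such false negatives: take every locus called with high
confidence in *any* of a subject's samples, then re-query the read evidence
at those loci in *all* samples, so a mutation called only pre-treatment still
contributes its (possibly low) post-treatment allele frequency.

Variant tables are pandas DataFrames with the pinned columns in
``VARIANT_COLUMNS`` (1-based VCF-style coordinates; loci keyed by
(chrom, pos, ref, alt) so multiallelic sites stay distinct).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "UnionMafMatrix",
    "select_high_confidence",
    "build_union_maf",
    "maf_scatter_summary",
    "copy_ratio_profile",
    "copy_ratio_concordance",
]

VARIANT_COLUMNS = [
    "subject_id", "sample_id", "timepoint", "chrom", "pos", "ref", "alt",
    "ref_count", "alt_count", "quality", "variant_class",
]

LOCUS_KEY = ["chrom", "pos", "ref", "alt"]


@dataclass
class UnionMafMatrix:
    """Loci x samples MAF matrix at the union of high-confidence loci.

    ``maf`` holds alt/(alt+ref) where depth > 0 and NaN where a locus has no
    read evidence in a sample ("missing", deliberately distinct from an
    observed MAF of 0).  ``high_conf_origin`` records in which sample(s) each
    locus was itself a high-confidence call.
    """

    subject_id: str
    loci: pd.MultiIndex            # (chrom, pos, ref, alt)
    samples: list[str]
    timepoints: dict[str, str]     # sample_id -> {pre, post}
    maf: pd.DataFrame
    depth: pd.DataFrame
    alt: pd.DataFrame
    high_conf_origin: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def sample_for(self, timepoint: str) -> str:
        hits = [s for s in self.samples if self.timepoints[s] == timepoint]
        if len(hits) != 1:
            raise ValueError(f"expected exactly one {timepoint} sample, found {len(hits)}")
        return hits[0]

    @property
    def n_loci(self) -> int:
        return len(self.loci)


def _require_single_subject(records: pd.DataFrame) -> str:
    subjects = records["subject_id"].unique()
    if len(subjects) != 1:
        raise ValueError(f"records span multiple subjects: {sorted(subjects)}")
    return str(subjects[0])


def select_high_confidence(records: pd.DataFrame, threshold: float = 30.0,
                           indel_threshold: float | None = None) -> pd.DataFrame:
    """Keep calls with caller quality strictly above the threshold.

    The inequality is strict (a call at exactly the threshold is excluded).
    SNVs and indels can carry separate thresholds; by default both are 30,
    the conventional high-confidence cut for Strelka's QSS_NT/QSI_NT scores.
    """
    _require_single_subject(records)
    if indel_threshold is None:
        indel_threshold = threshold
    cut = np.where(records["variant_class"] == "indel", indel_threshold, threshold)
    return records.loc[records["quality"].to_numpy() > cut].reset_index(drop=True)


def build_union_maf(all_records: pd.DataFrame, threshold: float = 30.0,
                    indel_threshold: float | None = None) -> UnionMafMatrix:
    """Construct the union-set MAF matrix for one subject.

    ``all_records`` must contain, for each sample, a row per locus with read
    evidence (``ref_count``/``alt_count``) whether or not the locus was
    called in that sample; the union loci are those whose quality exceeds
    the threshold in at least one sample.  A (locus, sample) pair without an
    evidence row — or with zero depth — is marked missing (NaN MAF), never
    silently zero.
    """
    subject = _require_single_subject(all_records)
    timepoints = (all_records.drop_duplicates("sample_id")
                  .set_index("sample_id")["timepoint"].to_dict())
    # canonical sample order (pre first, then id) makes the matrix invariant
    # to input record order
    samples = sorted(timepoints, key=lambda s: (timepoints[s] != "pre", s))
    if len(samples) < 2:
        raise ValueError("union construction requires >= 2 samples")

    high_conf = select_high_confidence(all_records, threshold, indel_threshold)
    if high_conf.empty:
        raise ValueError(f"no high-confidence calls for subject {subject}")
    union = (high_conf[LOCUS_KEY].drop_duplicates()
             .sort_values(LOCUS_KEY, kind="stable"))
    loci = pd.MultiIndex.from_frame(union)

    shape = (len(loci), len(samples))
    alt = pd.DataFrame(np.full(shape, np.nan), index=loci, columns=samples)
    depth = pd.DataFrame(np.full(shape, np.nan), index=loci, columns=samples)
    origin = pd.DataFrame(np.zeros(shape, dtype=bool), index=loci, columns=samples)

    for sample_id, grp in all_records.groupby("sample_id", sort=False):
        keyed = grp.set_index(LOCUS_KEY)
        if keyed.index.has_duplicates:
            raise ValueError(f"duplicate locus rows for sample {sample_id}")
        common = loci.intersection(keyed.index)
        alt.loc[common, sample_id] = keyed.loc[common, "alt_count"].to_numpy(dtype=float)
        depth.loc[common, sample_id] = (
            keyed.loc[common, "alt_count"] + keyed.loc[common, "ref_count"]
        ).to_numpy(dtype=float)
        cut = np.where(keyed.loc[common, "variant_class"] == "indel",
                       indel_threshold if indel_threshold is not None else threshold,
                       threshold)
        origin.loc[common, sample_id] = keyed.loc[common, "quality"].to_numpy() > cut

    depth = depth.fillna(0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        maf = alt.where(depth > 0) / depth.where(depth > 0)

    return UnionMafMatrix(
        subject_id=subject,
        loci=loci,
        samples=samples,
        timepoints={s: timepoints[s] for s in samples},
        maf=maf,
        depth=depth,
        alt=alt.where(depth > 0),
        high_conf_origin=origin,
        provenance={
            "threshold": threshold,
            "indel_threshold": indel_threshold if indel_threshold is not None else threshold,
            "maf_source": "caller-reported read counts (no re-pileup)",
            "n_union_loci": int(len(loci)),
        },
    )


def maf_scatter_summary(matrix: UnionMafMatrix, partition=None) -> pd.DataFrame:
    """Paired (pre_maf, post_maf, label) table for scatter display.

    One row per union locus with both samples' MAFs and the locus's
    private/shared label.  Requires exactly one pre and one post sample;
    with more samples, call per pair instead.
    """
    if len(matrix.samples) != 2:
        raise ValueError("maf_scatter_summary expects exactly one pre/post pair; "
                         "invoke per sample pair for multi-sample subjects")
    if partition is None:
        from .clonal import classify_private_shared
        partition = classify_private_shared(matrix)
    pre, post = matrix.sample_for("pre"), matrix.sample_for("post")
    table = pd.DataFrame({
        "pre_maf": matrix.maf[pre].to_numpy(),
        "post_maf": matrix.maf[post].to_numpy(),
        "label": partition.labels.reindex(matrix.loci).to_numpy(),
    }, index=matrix.loci)
    return table


def copy_ratio_profile(tumor_depths, normal_depths, bin_size: int = 1_000_000) -> pd.DataFrame:
    """Per-bin log2 copy ratio from binned read depths.

    ratio = log2((tumor_bin / tumor_total) / (normal_bin / normal_total));
    bins with zero normal depth are masked (NaN).  ``bin_size`` is recorded
    for the bin coordinates only.
    """
    t = np.asarray(tumor_depths, dtype=float)
    n = np.asarray(normal_depths, dtype=float)
    if t.shape != n.shape:
        raise ValueError("tumor and normal bins are not aligned")
    if t.sum() <= 0 or n.sum() <= 0:
        raise ValueError("total depth must be positive")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.log2((t / t.sum()) / (n / n.sum()))
    ratio[n == 0] = np.nan
    start = np.arange(t.size) * bin_size
    return pd.DataFrame({"bin_start": start, "bin_end": start + bin_size,
                         "log2_ratio": ratio})


def copy_ratio_concordance(pre_track: pd.DataFrame,
                           post_track: pd.DataFrame) -> tuple[float, bool]:
    """Pearson correlation of two log2-ratio tracks over shared finite bins.

    Returns (r, degenerate); the result is degenerate (r = NaN) when either
    track is constant over the comparable bins, e.g. two flat neutral tracks.
    """
    a = pre_track["log2_ratio"].to_numpy()
    b = post_track["log2_ratio"].to_numpy()
    if a.size != b.size:
        raise ValueError("tracks are not aligned")
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 2 or np.ptp(a[ok]) == 0 or np.ptp(b[ok]) == 0:
        return float("nan"), True
    r = float(np.corrcoef(a[ok], b[ok])[0, 1])
    return r, False
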