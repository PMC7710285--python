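"""Signature-level transcriptome comparison.

Raw gene counts are upper-quartile normalized, summarized per gene set either
as the mean log2(count + 1) over the set's genes or as a single-sample GSEA
(ssGSEA) enrichment score, and compared pre- vs post-treatment with a paired
t test per signature and Benjamini-Hochberg FDR control across signatures.

Gene-level differential expression is deliberately out of scope: the module
operates on signature scores only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import bh_fdr, paired_t

__all__ = [
    "ExpressionMatrix",
    "GeneSetCollection",
    "SignatureScoreMatrix",
    "upper_quartile_normalize",
    "signature_score",
    "ssgsea",
    "paired_signature_test",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples counts with per-sample annotations.

    ``counts`` rows are genes (unique labels), columns are sample ids;
    ``annotations`` is indexed by sample id with at least ``subject_id``
    and ``timepoint`` columns.
    """

    counts: pd.DataFrame
    annotations: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate gene labels")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        missing = set(self.counts.columns) - set(self.annotations.index)
        if missing:
            raise ValueError(f"samples without annotations: {sorted(missing)}")


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. parsed from a GMT file)."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"empty gene set: {name}")

    def intersect(self, genes) -> dict[str, set[str]]:
        universe = set(genes)
        return {name: s & universe for name, s in self.sets.items()}


@dataclass
class SignatureScoreMatrix:
    """Signatures x samples scores with the scoring method recorded."""

    scores: pd.DataFrame
    method: str

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.scores.to_numpy())):
            raise ValueError("non-finite signature scores")


def upper_quartile_normalize(m: ExpressionMatrix, target: float = 1000.0) -> ExpressionMatrix:
    """Scale each sample so the 75th percentile of its nonzero counts is ``target``.

    The percentile uses linear interpolation between order statistics of the
    nonzero counts.  Scale-invariant: multiplying a sample's counts by any
    positive constant leaves its normalized output unchanged.
    """
    scaled = {}
    for col in m.counts.columns:
        vals = m.counts[col].to_numpy(dtype=float)
        nonzero = vals[vals > 0]
        if nonzero.size == 0:
            raise ValueError(f"sample {col} has no nonzero counts")
        q75 = float(np.percentile(nonzero, 75))
        scaled[col] = vals * (target / q75)
    out = pd.DataFrame(scaled, index=m.counts.index)
    return ExpressionMatrix(counts=out, annotations=m.annotations)


def signature_score(m: ExpressionMatrix, sets: GeneSetCollection,
                    pseudocount: float = 1.0) -> SignatureScoreMatrix:
    """Mean log2(count + pseudocount) over each set's genes, per sample."""
    log2 = np.log2(m.counts.to_numpy(dtype=float) + pseudocount)
    log2_df = pd.DataFrame(log2, index=m.counts.index, columns=m.counts.columns)
    rows = {}
    for name, genes in sets.intersect(m.counts.index).items():
        if not genes:
            raise ValueError(f"gene set {name!r} shares no genes with the matrix")
        rows[name] = log2_df.loc[sorted(genes)].mean(axis=0)
    scores = pd.DataFrame(rows).T.loc[list(sets.sets)]
    scores.columns = m.counts.columns
    return SignatureScoreMatrix(scores=scores, method="mean_log2")


def _ssgsea_sample(expr: np.ndarray, set_mask: np.ndarray, alpha: float) -> float:
    """Enrichment score for one sample and one set.

    Genes are ranked by expression (rank N = highest); walking the list from
    the top, the in-set running sum climbs with weights rank^alpha while the
    out-set running sum climbs uniformly; the score is the sum of their
    differences over the whole list, so sets concentrated at the top of the
    ranking score positive.
    """
    n = expr.size
    # descending order with deterministic tie-break on gene index
    order = np.lexsort((np.arange(n), -expr))
    ranks = np.empty(n)
    ranks[order] = np.arange(n, 0, -1)  # position 1 (top) gets rank n
    in_set = set_mask[order]
    w = ranks[order] ** alpha
    w_in = np.where(in_set, w, 0.0)
    cum_in = np.cumsum(w_in) / w_in.sum()
    cum_out = np.cumsum(~in_set) / (n - in_set.sum())
    return float(np.sum(cum_in - cum_out))


def ssgsea(m: ExpressionMatrix, sets: GeneSetCollection, alpha: float = 0.25,
           normalize: bool = True) -> SignatureScoreMatrix:
    """Single-sample GSEA scores (weighted-ECDF running-sum method).

    Per sample and set, the enrichment score accumulates the difference
    between the rank-weighted in-set ECDF (weights rank^alpha) and the
    uniform out-set ECDF over the expression-ranked gene list.  With
    ``normalize``, all scores are divided by the overall score range across
    the matrix, as the method's common implementations do.
    """
    genes = m.counts.index
    masks = {}
    for name, genes_in in sets.intersect(genes).items():
        if len(genes_in) < 2:
            raise ValueError(f"gene set {name!r} has fewer than 2 genes in the matrix")
        if len(genes_in) >= len(genes):
            raise ValueError(f"gene set {name!r} covers every gene in the matrix")
        masks[name] = np.asarray(genes.isin(genes_in))

    expr = m.counts.to_numpy(dtype=float)
    scores = np.empty((len(masks), expr.shape[1]))
    for j in range(expr.shape[1]):
        for i, mask in enumerate(masks.values()):
            scores[i, j] = _ssgsea_sample(expr[:, j], mask, alpha)
    if normalize:
        rng_ = scores.max() - scores.min()
        if rng_ > 0:
            scores = scores / rng_
    df = pd.DataFrame(scores, index=list(masks), columns=m.counts.columns)
    return SignatureScoreMatrix(scores=df, method="ssgsea")


def paired_signature_test(scores: SignatureScoreMatrix,
                          annotations: pd.DataFrame) -> pd.DataFrame:
    """Paired pre/post t test per signature with BH FDR across signatures.

    ``annotations`` is indexed by sample id with ``subject_id`` and
    ``timepoint`` columns; subjects without exactly one pre and one post
    sample are excluded with a warning.  Returns a table with columns
    (signature, t, p, q, degenerate) sorted as the score matrix.
    """
    pre_cols, post_cols = [], []
    for subject, grp in annotations.groupby("subject_id", sort=True):
        pre = grp.index[grp["timepoint"] == "pre"]
        post = grp.index[grp["timepoint"] == "post"]
        if len(pre) != 1 or len(post) != 1:
            warnings.warn(f"subject {subject} lacks a complete pre/post pair; excluded",
                          stacklevel=2)
            continue
        if pre[0] in scores.scores.columns and post[0] in scores.scores.columns:
            pre_cols.append(pre[0])
            post_cols.append(post[0])
    if len(pre_cols) < 2:
        raise ValueError("paired signature test requires >= 2 complete pairs")

    rows = []
    for sig in scores.scores.index:
        res = paired_t(scores.scores.loc[sig, pre_cols].to_numpy(),
                       scores.scores.loc[sig, post_cols].to_numpy())
        rows.append({"signature": sig, "t": res.statistic, "p": res.p_value,
                     "degenerate": res.degenerate})
    table = pd.DataFrame(rows)
    table["q"] = bh_fdr(table["p"].to_numpy())
    return table[["signature", "t", "p", "q", "degenerate"]]
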