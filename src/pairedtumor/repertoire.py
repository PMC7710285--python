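"""Immune repertoire diversity and sharing analyses.

A repertoire sample is a clonotype -> count table for one specimen and one
receptor chain (TRB for T cells, IGH for B cells); clonotype identity is the
exact CDR3 amino-acid string.  Diversity is summarized with Shannon entropy,
compositional overlap between samples with the Morisita-Horn index, and
publicly shared clonotypes with a fractional-expression matrix.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import TestResult, paired_t

__all__ = [
    "RepertoireSample",
    "shannon_entropy",
    "morisita_horn",
    "sharing_matrix",
    "pairwise_morisita",
    "entropy_pre_post",
]


@dataclass
class RepertoireSample:
    """Clonotype counts for one sample and chain."""

    sample_id: str
    subject_id: str
    timepoint: str
    chain: str
    clonotypes: dict[str, int]

    def __post_init__(self) -> None:
        if any(c < 1 for c in self.clonotypes.values()):
            raise ValueError("clonotype counts must be >= 1")

    @property
    def total(self) -> int:
        return sum(self.clonotypes.values())


def shannon_entropy(sample: RepertoireSample, base: float = 2) -> float:
    """Shannon entropy H = -sum p_i log_base p_i of the clonotype frequencies.

    Base 2 (bits) by default; H is 0 for a monoclonal repertoire and
    log_base(k) for k equally abundant clonotypes.
    """
    counts = np.array(list(sample.clonotypes.values()), dtype=float)
    if counts.size == 0 or counts.sum() == 0:
        raise ValueError(f"empty repertoire: {sample.sample_id}")
    p = counts / counts.sum()
    return float(-(p * (np.log(p) / math.log(base))).sum())


def _union_counts(x: RepertoireSample, y: RepertoireSample) -> tuple[np.ndarray, np.ndarray]:
    keys = sorted(set(x.clonotypes) | set(y.clonotypes))
    xv = np.array([x.clonotypes.get(k, 0) for k in keys], dtype=float)
    yv = np.array([y.clonotypes.get(k, 0) for k in keys], dtype=float)
    return xv, yv


def morisita_horn(x: RepertoireSample, y: RepertoireSample) -> tuple[float, float]:
    """Morisita-Horn similarity and its complement (dissimilarity).

    similarity = 2 sum(x_i y_i) / ((sum x_i^2 / X^2 + sum y_i^2 / Y^2) X Y)
    over the union of clonotypes with zero fill; 1 for identical relative
    compositions, 0 for disjoint repertoires.  The complement is returned
    alongside because distance-oriented implementations (e.g. vegan's "horn"
    vegdist method) report 1 - similarity.
    """
    xv, yv = _union_counts(x, y)
    total_x, total_y = xv.sum(), yv.sum()
    if total_x == 0 or total_y == 0:
        raise ValueError("zero-total repertoire")
    num = 2.0 * float(np.dot(xv, yv))
    denom = ((xv ** 2).sum() / total_x ** 2 + (yv ** 2).sum() / total_y ** 2) * total_x * total_y
    similarity = float(min(1.0, num / denom))
    return similarity, 1.0 - similarity


def sharing_matrix(samples: list[RepertoireSample], public_min_samples: int = 2) -> pd.DataFrame:
    """Fractional expression of public clonotypes across samples.

    Rows are clonotypes present in at least ``public_min_samples`` samples;
    each entry is that clonotype's count divided by the sample's total
    clonotype counts (0 where absent).
    """
    if len(samples) < 2:
        raise ValueError("sharing_matrix requires >= 2 samples")
    presence: dict[str, int] = {}
    for s in samples:
        for k in s.clonotypes:
            presence[k] = presence.get(k, 0) + 1
    public = sorted(k for k, n in presence.items() if n >= public_min_samples)
    if not public:
        warnings.warn("no public clonotypes at the requested threshold", stacklevel=2)
    data = {
        s.sample_id: [s.clonotypes.get(k, 0) / s.total for k in public]
        for s in samples
    }
    return pd.DataFrame(data, index=pd.Index(public, name="cdr3_aa"))


def pairwise_morisita(samples: list[RepertoireSample]) -> pd.DataFrame:
    """Symmetric Morisita-Horn similarity matrix over all sample pairs."""
    if len(samples) < 2:
        raise ValueError("pairwise_morisita requires >= 2 samples")
    ids = [s.sample_id for s in samples]
    mat = np.eye(len(samples))
    for i in range(len(samples)):
        for j in range(i + 1, len(samples)):
            sim, _ = morisita_horn(samples[i], samples[j])
            mat[i, j] = mat[j, i] = sim
    return pd.DataFrame(mat, index=ids, columns=ids)


def entropy_pre_post(samples: list[RepertoireSample], chain: str = "TRB",
                     base: float = 2) -> tuple[pd.DataFrame, TestResult]:
    """Per-subject pre/post Shannon entropies with a paired t test.

    Subjects lacking one of the two timepoints for the requested chain are
    excluded with a warning.
    """
    by_subject: dict[str, dict[str, RepertoireSample]] = {}
    for s in samples:
        if s.chain != chain:
            continue
        by_subject.setdefault(s.subject_id, {})[s.timepoint] = s
    rows = []
    for subject in sorted(by_subject):
        pair = by_subject[subject]
        if "pre" not in pair or "post" not in pair:
            warnings.warn(f"subject {subject} lacks a pre/post pair for chain {chain}; excluded",
                          stacklevel=2)
            continue
        h_pre = shannon_entropy(pair["pre"], base=base)
        h_post = shannon_entropy(pair["post"], base=base)
        rows.append({"subject_id": subject, "H_pre": h_pre, "H_post": h_post,
                     "delta": h_post - h_pre})
    table = pd.DataFrame(rows, columns=["subject_id", "H_pre", "H_post", "delta"])
    if len(table) < 2:
        raise ValueError("paired entropy comparison requires >= 2 complete subjects")
    result = paired_t(table["H_pre"].to_numpy(), table["H_post"].to_numpy())
    return table, result
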