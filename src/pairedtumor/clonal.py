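"""Private/shared mutation decomposition and clonal-diversity statistics.

Given a subject's union-set MAF matrix, a mutation is *observed* in a sample
when it has alt-read evidence there (at least ``min_alt`` alt reads at
nonzero depth), *private* when observed in exactly one of the subject's
samples, and *shared* when observed in two or more.  The private fraction —
private mutations over the pair's union size — tracks clonal diversity: a
treatment that eliminates subclones converts their mutations into
pre-private loci and leaves the post sample with a smaller private fraction.

The Kolmogorov-Smirnov comparison of pre vs post MAF distributions is run in
two modes: over all union loci, and restricted to mutations with frequency
greater than zero in both samples.  The restriction removes the zero mass
contributed by private mutations, a control for sample-composition effects;
it does not remove a genuine tumor-purity difference, which rescales shared
MAFs too (see ``ks_pre_post``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy

from .stats import TestResult, ks_two_sample
from .union import UnionMafMatrix

__all__ = [
    "MutationPartition",
    "PairingClusterResult",
    "classify_private_shared",
    "mutation_count_delta",
    "ks_pre_post",
    "density_summary",
    "cluster_samples",
]


@dataclass
class MutationPartition:
    """Shared/private decomposition of one subject's union loci.

    ``labels`` maps each union locus to "shared", "private:<sample_id>", or
    "unobserved" (evidence present but below the observation threshold in
    every sample; such loci are excluded from ``union_size``).
    """

    subject_id: str
    observed: pd.DataFrame          # loci x samples bool
    labels: pd.Series               # per locus
    timepoints: dict[str, str]
    total_observed: dict[str, int]  # per sample
    private_observed: dict[str, int]
    union_size: int
    private_fraction: dict[str, float] = field(default_factory=dict)

    def fraction_for(self, timepoint: str) -> float:
        hits = [s for s, tp in self.timepoints.items() if tp == timepoint]
        if len(hits) != 1:
            raise ValueError(f"expected one {timepoint} sample")
        return self.private_fraction[hits[0]]


def classify_private_shared(matrix: UnionMafMatrix, min_alt: int = 1) -> MutationPartition:
    """Label each union locus shared or private.

    ``min_alt`` defaults to 1, implementing "frequency greater than zero":
    any alt evidence counts as observed.  A stricter threshold guards
    against sequencing noise at the cost of sensitivity.
    """
    if len(matrix.samples) < 2:
        raise ValueError("classification requires >= 2 samples")
    alt = matrix.alt
    observed = (alt >= min_alt) & (matrix.depth > 0)
    all_missing = (matrix.depth <= 0).all(axis=1)
    if all_missing.any():
        warnings.warn(f"{int(all_missing.sum())} union loci lack evidence in every sample; "
                      "excluded from the union size", stacklevel=2)
    n_obs = observed.sum(axis=1)

    labels = pd.Series("unobserved", index=matrix.loci, name="label")
    labels[n_obs >= 2] = "shared"
    for s in matrix.samples:
        only_here = (n_obs == 1) & observed[s]
        labels[only_here] = f"private:{s}"

    union_size = int((n_obs >= 1).sum())
    total = {s: int(observed[s].sum()) for s in matrix.samples}
    private = {s: int((labels == f"private:{s}").sum()) for s in matrix.samples}
    frac = {s: (private[s] / union_size if union_size else float("nan"))
            for s in matrix.samples}
    return MutationPartition(
        subject_id=matrix.subject_id,
        observed=observed,
        labels=labels,
        timepoints=dict(matrix.timepoints),
        total_observed=total,
        private_observed=private,
        union_size=union_size,
        private_fraction=frac,
    )


def mutation_count_delta(partitions: list[MutationPartition]) -> pd.DataFrame:
    """Per-subject observed mutation totals and their pre-to-post change."""
    rows = []
    for part in partitions:
        by_tp = {tp: s for s, tp in part.timepoints.items()}
        if "pre" not in by_tp or "post" not in by_tp:
            warnings.warn(f"subject {part.subject_id} is unpaired; skipped", stacklevel=2)
            continue
        pre_total = part.total_observed[by_tp["pre"]]
        post_total = part.total_observed[by_tp["post"]]
        rows.append({"subject_id": part.subject_id, "pre_total": pre_total,
                     "post_total": post_total, "delta": post_total - pre_total})
    return pd.DataFrame(rows, columns=["subject_id", "pre_total", "post_total", "delta"])


def ks_pre_post(matrix: UnionMafMatrix, mode: str = "all") -> TestResult:
    """KS test of pre vs post MAF distributions.

    mode="all" compares the full MAF vectors over union loci (missing
    entries dropped per sample); mode="shared_only" restricts both vectors
    to loci with MAF > 0 in both samples — the control that removes the
    private-mutation zero mass but not a purity rescaling of shared MAFs.
    """
    if mode not in ("all", "shared_only"):
        raise ValueError(f"unknown mode: {mode}")
    pre_s, post_s = matrix.sample_for("pre"), matrix.sample_for("post")
    pre = matrix.maf[pre_s]
    post = matrix.maf[post_s]
    if mode == "shared_only":
        keep = (pre > 0) & (post > 0)
        pre, post = pre[keep], post[keep]
    pre = pre.dropna().to_numpy()
    post = post.dropna().to_numpy()
    if pre.size < 2 or post.size < 2:
        return TestResult(float("nan"), float("nan"), pre.size, post.size,
                          f"ks_pre_post_{mode}", degenerate=True)
    res = ks_two_sample(pre, post)
    return TestResult(res.statistic, res.p_value, res.n1, res.n2,
                      f"ks_pre_post_{mode}")


def _kde_on_grid(values: np.ndarray, grid: np.ndarray) -> np.ndarray:
    # point-mass input (zero variance) gets a narrow Gaussian bump instead of
    # a singular KDE
    if np.ptp(values) == 0:
        return sps.norm.pdf(grid, loc=values[0], scale=0.02)
    return sps.gaussian_kde(values)(grid)


def density_summary(matrix: UnionMafMatrix, partition: MutationPartition | None = None,
                    grid_points: int = 256) -> dict[str, pd.DataFrame]:
    """MAF kernel densities and quantile-quantile pairs for display/export.

    Densities are evaluated on a [0, 1] grid per sample for the full MAF
    vector and for shared loci only; QQ pairs match pre/post quantiles at a
    common probability grid.  Vectors with fewer than 2 points are skipped.
    """
    if partition is None:
        partition = classify_private_shared(matrix)
    grid = np.linspace(0.0, 1.0, grid_points)
    shared_loci = partition.labels == "shared"

    dens_rows = []
    vectors: dict[tuple[str, str], np.ndarray] = {}
    for s in matrix.samples:
        col = matrix.maf[s]
        vectors[(s, "all")] = col.dropna().to_numpy()
        vectors[(s, "shared")] = col[shared_loci].dropna().to_numpy()
    for (s, subset), vals in vectors.items():
        if vals.size < 2:
            continue
        d = _kde_on_grid(vals, grid)
        dens_rows.append(pd.DataFrame({"sample_id": s, "subset": subset,
                                       "maf": grid, "density": d}))
    density = (pd.concat(dens_rows, ignore_index=True) if dens_rows
               else pd.DataFrame(columns=["sample_id", "subset", "maf", "density"]))

    probs = np.linspace(0.01, 0.99, 99)
    pre_s, post_s = matrix.sample_for("pre"), matrix.sample_for("post")
    qq_rows = []
    for subset in ("all", "shared"):
        pre_v, post_v = vectors[(pre_s, subset)], vectors[(post_s, subset)]
        if pre_v.size < 2 or post_v.size < 2:
            continue
        qq_rows.append(pd.DataFrame({
            "subset": subset, "prob": probs,
            "pre_quantile": np.quantile(pre_v, probs),
            "post_quantile": np.quantile(post_v, probs),
        }))
    qq = (pd.concat(qq_rows, ignore_index=True) if qq_rows
          else pd.DataFrame(columns=["subset", "prob", "pre_quantile", "post_quantile"]))
    return {"density": density, "qq": qq}


@dataclass
class PairingClusterResult:
    """Hierarchical clustering of all samples across subjects.

    ``pairing_score`` is the fraction of subjects whose pre and post samples
    are sister leaves in the tree (both merged directly with each other).
    """

    linkage: np.ndarray
    sample_ids: list[str]
    subjects: dict[str, str]        # sample_id -> subject_id
    pairing_score: float
    cophenetic: np.ndarray          # condensed distances
    newick: str


def _to_newick(node, labels: list[str]) -> str:
    if node.is_leaf():
        return labels[node.id]
    left = _to_newick(node.get_left(), labels)
    right = _to_newick(node.get_right(), labels)
    bl_left = node.dist - node.get_left().dist
    bl_right = node.dist - node.get_right().dist
    return f"({left}:{bl_left:.6g},{right}:{bl_right:.6g})"


def cluster_samples(matrices: list[UnionMafMatrix]) -> PairingClusterResult:
    """Cluster all samples of all subjects on the cross-subject locus union.

    Each sample's feature vector holds its subject's MAFs at that subject's
    union loci and 0 at every other subject's loci (absence of another
    tumor's mutation is a true zero); distances are Euclidean with complete
    linkage.  With paired designs, subject identity should dominate: pre and
    post samples of a subject share their truncal mutations and differ only
    in private loci, while different subjects share (almost) nothing.
    """
    if len(matrices) < 2:
        raise ValueError("cluster_samples requires >= 2 subjects")
    sample_ids: list[str] = []
    subjects: dict[str, str] = {}
    blocks = []
    for m in matrices:
        for s in m.samples:
            if s in subjects:
                raise ValueError(f"duplicate sample label: {s}")
            subjects[s] = m.subject_id
            sample_ids.append(s)
    n_samples = len(sample_ids)
    offset = 0
    col_of = {s: i for i, s in enumerate(sample_ids)}
    total_loci = sum(m.n_loci for m in matrices)
    feat = np.zeros((total_loci, n_samples))
    for m in matrices:
        vals = m.maf.fillna(0.0).to_numpy()
        for j, s in enumerate(m.samples):
            feat[offset:offset + m.n_loci, col_of[s]] = vals[:, j]
        offset += m.n_loci

    linkage = hierarchy.linkage(feat.T, method="complete", metric="euclidean")
    coph = hierarchy.cophenet(linkage)

    # sisters: merges whose two members are both original leaves
    sister_pairs = {frozenset((int(a), int(b)))
                    for a, b, _, _ in linkage if a < n_samples and b < n_samples}
    by_subject: dict[str, list[int]] = {}
    for s, subj in subjects.items():
        by_subject.setdefault(subj, []).append(col_of[s])
    paired = sum(1 for leaves in by_subject.values()
                 if len(leaves) == 2 and frozenset(leaves) in sister_pairs)
    score = paired / len(by_subject)

    tree = hierarchy.to_tree(linkage)
    newick = _to_newick(tree, sample_ids) + ";"
    return PairingClusterResult(
        linkage=linkage,
        sample_ids=sample_ids,
        subjects=subjects,
        pairing_score=score,
        cophenetic=coph,
        newick=newick,
    )
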