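"""Synthetic paired-tumor data with known clonal ground truth.

The generator emulates the study design the pipeline analyzes: for each
subject, a pre-treatment biopsy and a post-treatment resection of the same
tumor are exome-sequenced, somatic mutations are called against a germline
reference, and treatment may eliminate subclones ("selection") while private
mutations turn over between the two specimens.

Model
-----
A tumor has a truncal clone (id 0) carried by every tumor cell and
``n_subclones`` subclones occupying fractions of tumor cells.  Each mutation
belongs to one clone; under the diploid heterozygous model its true mutant
allele frequency in a specimen is

    MAF = purity * clone_fraction / 2

Read evidence is binomial at Poisson-distributed depth, and caller quality is
a noisy logistic function of alt-read support, so low-frequency mutations are
called with realistic unreliability while their read evidence remains
queryable.

Treatment effect: a fraction ``selection_strength`` of subclones is
eliminated in the post specimen (their niche regrows from truncal-only
cells; surviving subclones keep their cell fractions).  Independently, each
specimen carries specimen-private mutations at a configurable ``turnover``
rate; post-private mutations arise only in surviving subclones, so stronger
selection leaves fewer lineages to generate post-private novelty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .repertoire import RepertoireSample
from .signatures import ExpressionMatrix

__all__ = [
    "SimulationConfig",
    "ClonalTruth",
    "RepertoireSimConfig",
    "simulate_cohort",
    "simulate_repertoire",
    "simulate_expression",
    "simulate_binned_depths",
]

_BASES = np.array(list("ACGT"))
_AMINO = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

VARIANT_COLUMNS = [
    "subject_id", "sample_id", "timepoint", "chrom", "pos", "ref", "alt",
    "ref_count", "alt_count", "quality", "variant_class",
]


@dataclass(frozen=True)
class QualityModel:
    """Caller confidence as a noisy logistic in alt-read count.

    Defaults are scaled so ~8 supporting reads comfortably exceed the
    default high-confidence threshold of 30.
    """

    max_quality: float = 100.0
    midpoint: float = 5.0
    scale: float = 1.2
    noise_sd: float = 4.0

    def sample(self, alt_counts: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        base = self.max_quality / (1.0 + np.exp(-(alt_counts - self.midpoint) / self.scale))
        q = base + rng.normal(0.0, self.noise_sd, size=alt_counts.shape)
        return np.clip(q, 0.0, self.max_quality)


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level generator settings.

    Burden defaults reproduce the study's printed scale: an average of 190
    somatic mutations per tumor within a 100-240 range.
    """

    n_subjects: int = 5
    mutations_per_tumor_mean: int = 190
    mutations_per_tumor_range: tuple[int, int] = (100, 240)
    mutations_per_tumor_sd: float = 25.0
    n_subclones: int = 4
    truncal_fraction: float = 0.6
    subclonal_mass_range: tuple[float, float] = (0.6, 0.9)
    mean_depth: int = 100
    purity_range: tuple[float, float] = (0.4, 0.8)
    equal_purity: bool = False
    purity_pre: float | None = None   # explicit overrides for controlled experiments
    purity_post: float | None = None
    selection_strength: float = 0.5
    turnover: tuple[float, float] = (0.2, 0.2)  # (pre, post) private-mutation rates
    indel_fraction: float = 0.1
    quality_model: QualityModel = field(default_factory=QualityModel)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.mutations_per_tumor_range
        if not lo <= self.mutations_per_tumor_mean <= hi:
            raise ValueError("mutations_per_tumor_mean must lie within mutations_per_tumor_range")
        if not 0.0 <= self.selection_strength <= 1.0:
            raise ValueError("selection_strength must lie in [0, 1]")
        if not 0.0 < self.truncal_fraction < 1.0:
            raise ValueError("truncal_fraction must lie in (0, 1)")
        if self.subclonal_mass_range[1] > 1.0:
            raise ValueError("subclonal cell fractions cannot exceed 1 (would sum above the tumor)")
        if any(t < 0 for t in self.turnover):
            raise ValueError("turnover rates must be non-negative")


@dataclass
class ClonalTruth:
    """Ground truth for one simulated subject.

    ``clones`` lists (clone_id, pre_fraction, post_fraction) of tumor cells;
    the truncal clone (id 0) has fraction 1 at both timepoints.
    ``mutation_assignment`` maps mutation id ("chrom:pos:ref:alt") to the
    clone carrying it; ``presence`` records whether each mutation exists in
    the (pre, post) specimen — turnover-private mutations exist in only one
    even though their clone persists.
    """

    subject_id: str
    clones: list[tuple[int, float, float]]
    mutation_assignment: dict[str, int]
    purity_pre: float
    purity_post: float
    selection_strength: float
    presence: dict[str, tuple[bool, bool]] = field(default_factory=dict)

    def clone_fraction(self, clone_id: int, timepoint: str) -> float:
        for cid, fpre, fpost in self.clones:
            if cid == clone_id:
                return fpre if timepoint == "pre" else fpost
        raise KeyError(clone_id)

    def true_maf(self, mutation_id: str, timepoint: str) -> float:
        if self.presence:
            here = self.presence[mutation_id][0 if timepoint == "pre" else 1]
            if not here:
                return 0.0
        purity = self.purity_pre if timepoint == "pre" else self.purity_post
        clone = self.mutation_assignment[mutation_id]
        return purity * self.clone_fraction(clone, timepoint) / 2.0


def _truncated_normal_int(rng, mean, sd, lo, hi) -> int:
    while True:
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return int(round(x))


def _draw_loci(rng: np.random.Generator, n: int, subject_index: int, indel_fraction: float):
    """Unique genomic loci for one subject: chrom, pos, ref, alt, class."""
    chroms = np.array([f"chr{(i % 22) + 1}" for i in range(n)])
    # disjoint position blocks per subject keep mutation ids globally unique
    pos = 1_000_000 * (subject_index + 1) + rng.choice(np.arange(1, 500_000), size=n, replace=False)
    ref = rng.choice(_BASES, size=n)
    alt = np.array([rng.choice(_BASES[_BASES != r]) for r in ref])
    is_indel = rng.random(n) < indel_fraction
    vclass = np.where(is_indel, "indel", "SNV")
    alt = np.where(is_indel, np.char.add(alt, "A"), alt)
    return chroms, pos.astype(int), ref, alt, vclass


def _simulate_subject(config: SimulationConfig, subject_index: int,
                      rng: np.random.Generator) -> tuple[ClonalTruth, pd.DataFrame]:
    subject_id = f"S{subject_index + 1:02d}"
    n_target = _truncated_normal_int(
        rng, config.mutations_per_tumor_mean, config.mutations_per_tumor_sd,
        *config.mutations_per_tumor_range,
    )
    n_truncal = int(round(config.truncal_fraction * n_target))
    n_sub = max(n_target - n_truncal, config.n_subclones)

    # subclone cell fractions: moderately even split of the subclonal mass
    mass = rng.uniform(*config.subclonal_mass_range)
    weights = rng.dirichlet(np.full(config.n_subclones, 3.0))
    pre_fracs = mass * weights

    t_pre, t_post = config.turnover
    per_clone_base = np.bincount(
        rng.integers(0, config.n_subclones, size=n_sub), minlength=config.n_subclones
    )

    # selection: eliminate subclones uniformly at random; survivors keep
    # their cell fractions (the eliminated niche regrows from truncal-only
    # cells), so a mutation's detectability does not shift with selection
    n_elim = int(round(config.selection_strength * config.n_subclones))
    eliminated = set(rng.choice(config.n_subclones, size=n_elim, replace=False).tolist())
    post_fracs = pre_fracs.copy()
    post_fracs[list(eliminated)] = 0.0

    # mutation inventory: (clone, present_pre, present_post)
    clone_of: list[int] = []
    in_pre: list[bool] = []
    in_post: list[bool] = []
    for _ in range(n_truncal):
        clone_of.append(0)
        in_pre.append(True)
        in_post.append(True)
    for c in range(config.n_subclones):
        m = int(per_clone_base[c])
        alive_post = c not in eliminated
        for _ in range(m):  # shared-lineage mutations (present both, if clone survives)
            clone_of.append(c + 1)
            in_pre.append(True)
            in_post.append(alive_post)
        for _ in range(int(round(t_pre * m))):  # pre-specimen private
            clone_of.append(c + 1)
            in_pre.append(True)
            in_post.append(False)
        if alive_post:
            for _ in range(int(round(t_post * m))):  # post-specimen private
                clone_of.append(c + 1)
                in_pre.append(False)
                in_post.append(True)

    n_mut = len(clone_of)
    clone_arr = np.asarray(clone_of)
    chroms, pos, ref, alt, vclass = _draw_loci(rng, n_mut, subject_index, config.indel_fraction)
    mut_ids = [f"{c}:{p}:{r}:{a}" for c, p, r, a in zip(chroms, pos, ref, alt)]

    purity_pre = (config.purity_pre if config.purity_pre is not None
                  else rng.uniform(*config.purity_range))
    if config.purity_post is not None:
        purity_post = config.purity_post
    elif config.equal_purity:
        purity_post = purity_pre
    else:
        purity_post = rng.uniform(*config.purity_range)

    frac_lookup = np.concatenate([[1.0], pre_fracs]), np.concatenate([[1.0], post_fracs])
    present = {"pre": np.asarray(in_pre), "post": np.asarray(in_post)}
    purities = {"pre": purity_pre, "post": purity_post}

    frames = []
    for tp_index, tp in enumerate(("pre", "post")):
        fracs = frac_lookup[tp_index][clone_arr]
        maf_true = np.where(present[tp], purities[tp] * fracs / 2.0, 0.0)
        depth = rng.poisson(config.mean_depth, size=n_mut)
        alt_counts = rng.binomial(depth, np.clip(maf_true, 0.0, 1.0))
        quality = config.quality_model.sample(alt_counts, rng)
        frames.append(pd.DataFrame({
            "subject_id": subject_id,
            "sample_id": f"{subject_id}_{tp}",
            "timepoint": tp,
            "chrom": chroms,
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "ref_count": depth - alt_counts,
            "alt_count": alt_counts,
            "quality": np.round(quality, 2),
            "variant_class": vclass,
        }))

    truth = ClonalTruth(
        subject_id=subject_id,
        clones=[(0, 1.0, 1.0)] + [
            (c + 1, float(pre_fracs[c]), float(post_fracs[c]))
            for c in range(config.n_subclones)
        ],
        mutation_assignment=dict(zip(mut_ids, clone_arr.tolist())),
        purity_pre=float(purity_pre),
        purity_post=float(purity_post),
        selection_strength=config.selection_strength,
        presence=dict(zip(mut_ids, zip(in_pre, in_post))),
    )
    return truth, pd.concat(frames, ignore_index=True)


def simulate_cohort(config: SimulationConfig) -> tuple[list[ClonalTruth], pd.DataFrame]:
    """Simulate a paired pre/post cohort.

    Returns per-subject ground truth and one variant table containing, for
    every simulated mutation, a row per sample with read evidence and caller
    quality — i.e. both the call candidates and the re-query evidence the
    union-set construction needs.  Bit-reproducible given the config (which
    includes the seed); each subject consumes an independent substream.
    """
    ss = np.random.SeedSequence(config.seed)
    truths: list[ClonalTruth] = []
    frames: list[pd.DataFrame] = []
    for i, child in enumerate(ss.spawn(config.n_subjects)):
        truth, records = _simulate_subject(config, i, np.random.default_rng(child))
        truths.append(truth)
        frames.append(records)
    return truths, pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# immune repertoires


@dataclass(frozen=True)
class RepertoireSimConfig:
    """Power-law clonotype repertoire generator settings.

    ``dominance`` is the power-law exponent of the clone frequency spectrum
    (0 = uniform); ``shared_fraction`` of clonotype identities are common to
    all generated samples, the rest are sample-private.
    """

    n_clonotypes: int = 200
    dominance: float = 1.0
    shared_fraction: float = 0.3
    total_counts: int = 10_000
    chain: str = "TRB"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clonotypes < 1:
            raise ValueError("n_clonotypes must be >= 1")
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ValueError("shared_fraction must lie in [0, 1]")


def _random_cdr3(rng: np.random.Generator) -> str:
    length = int(rng.integers(8, 17))
    return "C" + "".join(rng.choice(_AMINO, size=length)) + "F"


def simulate_repertoire(config: RepertoireSimConfig, n_samples: int,
                        sample_ids: list[str] | None = None,
                        subject_ids: list[str] | None = None,
                        timepoints: list[str] | None = None) -> list[RepertoireSample]:
    """Draw clonotype count tables for ``n_samples`` samples.

    Clone frequencies follow p_i proportional to i^-dominance; counts are
    multinomial.  The first round(shared_fraction * n_clonotypes) clonotype
    identities are shared across samples; the remainder are unique to each
    sample, so shared_fraction controls compositional overlap.
    """
    rng = np.random.default_rng(config.seed)
    k = config.n_clonotypes
    freqs = np.arange(1, k + 1, dtype=float) ** (-config.dominance)
    freqs /= freqs.sum()
    n_shared = int(round(config.shared_fraction * k))
    # shared identities are spread over the abundance spectrum (not just the
    # dominant clones) but occupy the same ranks in every sample
    shared_ranks = set(rng.choice(k, size=n_shared, replace=False).tolist())
    shared_names = {r: _random_cdr3(rng) for r in sorted(shared_ranks)}

    samples = []
    for s in range(n_samples):
        names = [shared_names[i] if i in shared_ranks else _random_cdr3(rng)
                 for i in range(k)]
        counts = rng.multinomial(config.total_counts, freqs)
        clonotypes = {name: int(c) for name, c in zip(names, counts) if c > 0}
        samples.append(RepertoireSample(
            sample_id=sample_ids[s] if sample_ids else f"R{s + 1:02d}",
            subject_id=subject_ids[s] if subject_ids else f"S{s // 2 + 1:02d}",
            timepoint=timepoints[s] if timepoints else ("pre" if s % 2 == 0 else "post"),
            chain=config.chain,
            clonotypes=clonotypes,
        ))
    return samples


# ---------------------------------------------------------------------------
# expression counts


def simulate_expression(n_genes: int, n_pairs: int, signature_genes: set[str],
                        effect_size: float, seed: int, *,
                        dispersion: float = 0.1, base_log_mean: float = np.log(100.0),
                        base_log_sd: float = 1.0, subject_sd: float = 0.4,
                        ) -> tuple[ExpressionMatrix, dict]:
    """Negative-binomial counts for a paired pre/post design.

    Post-treatment samples shift the ``signature_genes`` by ``effect_size``
    on the log2 scale; a per-subject, per-gene lognormal effect induces the
    within-pair correlation a paired test exploits.  ``dispersion`` is the
    NB overdispersion (variance = m + dispersion * m^2); dispersion 0 means
    noise-free counts equal to their means.

    Returns the expression matrix plus a truth dict recording the perturbed
    genes and the applied effect.
    """
    rng = np.random.default_rng(seed)
    genes = [f"G{i + 1:05d}" for i in range(n_genes)]
    unknown = set(signature_genes) - set(genes)
    if unknown:
        raise ValueError(f"signature genes absent from the gene universe: {sorted(unknown)[:5]}")
    sig_mask = np.array([g in signature_genes for g in genes])

    base = np.exp(rng.normal(base_log_mean, base_log_sd, size=n_genes))
    sample_ids, subjects, timepoints, cols = [], [], [], []
    for s in range(n_pairs):
        subj_effect = np.exp(rng.normal(0.0, subject_sd, size=n_genes))
        for tp in ("pre", "post"):
            mean = base * subj_effect
            if tp == "post":
                mean = mean * np.where(sig_mask, 2.0 ** effect_size, 1.0)
            if dispersion > 0:
                lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
                counts = rng.poisson(lam).astype(float)
            else:
                counts = mean.copy()
            cols.append(counts)
            sample_ids.append(f"E{s + 1:02d}_{tp}")
            subjects.append(f"S{s + 1:02d}")
            timepoints.append(tp)

    counts_df = pd.DataFrame(np.column_stack(cols), index=pd.Index(genes, name="gene"),
                             columns=sample_ids)
    annotations = pd.DataFrame(
        {"subject_id": subjects, "timepoint": timepoints},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    truth = {"signature_genes": sorted(signature_genes), "effect_size": effect_size}
    return ExpressionMatrix(counts=counts_df, annotations=annotations), truth


# ---------------------------------------------------------------------------
# binned read depths for copy-ratio checks


def simulate_binned_depths(copy_state: np.ndarray, mean_reads_per_bin: float,
                           seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Poisson read counts per genomic bin for a tumor/normal pair.

    ``copy_state`` gives the tumor's absolute copy number per bin (2 =
    neutral); the matched normal is diploid everywhere.  Returns
    (tumor_depths, normal_depths).
    """
    rng = np.random.default_rng(seed)
    copy_state = np.asarray(copy_state, dtype=float)
    tumor = rng.poisson(mean_reads_per_bin * copy_state / 2.0)
    normal = rng.poisson(np.full_like(copy_state, mean_reads_per_bin))
    return tumor.astype(float), normal.astype(float)
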