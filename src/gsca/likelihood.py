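"""Haplotype-matching genotype likelihoods from read-pair SNP observations.

Each read-pair from a plant is scored at the panel SNPs it overlaps within a
gene set.  Given a reference panel of K genic haplotypes, the likelihood
that the plant's unordered diploid genic-genotype is [i, j] is a product of
per-read-pair mixture terms,

    U[i, j] = prod_r ( eps^h(r,i) / 2 + eps^h(r,j) / 2 ),

where h(r, k) counts sequence mismatches between read-pair r and haplotype
k, and eps absorbs sequencing/alignment error.  Matching sites contribute a
factor of 1 by default; ``bernoulli=True`` switches to the full
eps^h (1-eps)^(s-h) form (numerically indistinguishable at eps = 0.005).

Everything is computed in log space with per-read scaling so that arbitrary
mismatch counts cannot underflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .panel import HaplotypePanel

__all__ = [
    "ReadPairObservation",
    "MismatchProfile",
    "GenotypeLikelihoodTable",
    "DEFAULT_EPSILON",
    "mismatch_profile",
    "compute_U",
    "readpair_consistency",
    "compatible_genotypes",
    "ancestry_posteriors",
    "genotype_pairs",
]

DEFAULT_EPSILON = 0.005


@dataclass
class ReadPairObservation:
    """SNP calls from one read-pair (or single-end read): a bag of (snp_index, allele)."""

    plant_id: str
    set_id: str
    read_id: str
    snp_indices: np.ndarray  # column indices into the panel's SNP matrix
    alleles: np.ndarray  # observed allele codes, 0 = reference base, 1 = alternative

    def __post_init__(self) -> None:
        self.snp_indices = np.asarray(self.snp_indices, dtype=np.intp)
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.snp_indices.size == 0:
            raise ValueError("read-pair overlaps no retained SNPs; discard upstream")
        if self.snp_indices.size != self.alleles.size:
            raise ValueError("snp_indices and alleles length mismatch")


@dataclass
class MismatchProfile:
    """Mismatch counts h[r, k] and per-read overlapped-SNP counts s[r]."""

    h: np.ndarray
    s: np.ndarray


@dataclass
class GenotypeLikelihoodTable:
    """log U over unordered genotypes for one plant x gene set.

    ``loglik`` is the full symmetric (K, K) matrix of log U[i, j].  A table
    is flagged ``unknown`` when even the best genotype implies more than two
    mismatches per read-pair on average — the plant's reads are then treated
    as uninformative (flat likelihood) by downstream models.
    """

    plant_id: str
    set_id: str
    loglik: np.ndarray
    epsilon: float
    RP: int
    unknown: bool = False

    @property
    def K(self) -> int:
        return self.loglik.shape[0]

    def effective_loglik(self) -> np.ndarray:
        if self.unknown:
            return np.zeros_like(self.loglik)
        return self.loglik


def genotype_pairs(K: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/column indices of the K(K+1)/2 unordered genotypes (i <= j)."""
    return np.triu_indices(K)


def mismatch_profile(reads: list[ReadPairObservation], panel: HaplotypePanel) -> MismatchProfile:
    """h[r, k] = number of mismatches between read r and haplotype k."""
    if panel.K == 0:
        raise ValueError("empty haplotype panel")
    R = len(reads)
    h = np.zeros((R, panel.K), dtype=np.int64)
    s = np.zeros(R, dtype=np.int64)
    if R == 0:
        return MismatchProfile(h=h, s=s)
    cols = np.concatenate([r.snp_indices for r in reads])
    obs = np.concatenate([r.alleles for r in reads])
    lengths = np.array([r.snp_indices.size for r in reads])
    starts = np.concatenate([[0], np.cumsum(lengths)[:-1]])
    mism = panel.alleles[:, cols] != obs[None, :]  # (K, total calls)
    h[:] = np.add.reduceat(mism, starts, axis=1).T
    s[:] = lengths
    return MismatchProfile(h=h, s=s)


def loglik_from_mismatches(
    h: np.ndarray,
    s: np.ndarray,
    epsilon: float,
    bernoulli: bool = False,
) -> np.ndarray:
    """Sum per-read mixture terms into the (K, K) log U matrix."""
    R, K = h.shape
    if R == 0:
        return np.zeros((K, K))
    logf = h * np.log(epsilon)
    if bernoulli:
        logf = logf + (s[:, None] - h) * np.log1p(-epsilon)
    m = logf.max(axis=1)
    w = np.exp(logf - m[:, None])  # per-read scaling
    pair = 0.5 * (w[:, :, None] + w[:, None, :])
    return (np.log(pair) + m[:, None, None]).sum(axis=0)


def compute_U(
    reads: list[ReadPairObservation],
    panel: HaplotypePanel,
    epsilon: float = DEFAULT_EPSILON,
    bernoulli: bool = False,
    plant_id: str | None = None,
) -> GenotypeLikelihoodTable:
    """Genotype likelihood table for all read-pairs of one plant x gene set."""
    if not 0.0 < epsilon < 1.0:
        raise ValueError(f"epsilon must be in (0, 1), got {epsilon}")
    prof = mismatch_profile(reads, panel)
    loglik = loglik_from_mismatches(prof.h, prof.s, epsilon, bernoulli=bernoulli)
    RP = len(reads)
    if plant_id is None:
        plant_id = reads[0].plant_id if reads else "?"
    unknown = RP > 0 and float(loglik.max()) < RP * 2.0 * np.log(epsilon)
    return GenotypeLikelihoodTable(
        plant_id=plant_id,
        set_id=panel.set_id,
        loglik=loglik,
        epsilon=epsilon,
        RP=RP,
        unknown=unknown,
    )


def readpair_consistency(read: ReadPairObservation, panel: HaplotypePanel) -> bool:
    """True iff the read perfectly matches at least one genic haplotype."""
    prof = mismatch_profile([read], panel)
    return bool(prof.h.min() == 0)


def compatible_genotypes(
    table: GenotypeLikelihoodTable, fraction: float = 0.5
) -> set[tuple[int, int]]:
    """Genotypes whose likelihood is within ``fraction`` of the maximum.

    With no reads every genotype is compatible (the full K(K+1)/2 space).
    """
    iu = genotype_pairs(table.K)
    ll = table.effective_loglik()[iu]
    cut = ll.max() + np.log(fraction)
    keep = ll >= cut
    return {(int(i), int(j)) for i, j, k in zip(*iu, keep) if k}


def ancestry_posteriors(
    reads: list[ReadPairObservation],
    panel: HaplotypePanel,
    epsilon: float = DEFAULT_EPSILON,
    mode: str = "diploid",
) -> np.ndarray:
    """Posterior over genotypes under a uniform prior.

    ``mode="homozygous"`` restricts the genotype space to (k, k) — the RIL /
    ancestry-assignment setting where the plant is an inbred mosaic of
    founder haplotypes — and returns a length-K vector.  ``mode="diploid"``
    returns the posterior over the K(K+1)/2 unordered genotypes, in
    triu order.
    """
    table = compute_U(reads, panel, epsilon=epsilon, plant_id="_ancestry")
    if mode == "homozygous":
        ll = np.diag(table.loglik)
    elif mode == "diploid":
        ll = table.loglik[genotype_pairs(table.K)]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    w = np.exp(ll - ll.max())
    return w / w.sum()
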