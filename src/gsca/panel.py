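"""Reference haplotype panels: gene sets, distinct genic haplotypes, SNP thinning.

A "gene set" is a single gene or a cluster of overlapping / closely linked
(within 100 bp) genes treated as one non-recombining locus.  Within a gene
set, the sequenced reference lines collapse to K distinct *genic haplotypes*
with frequencies Q_k; every retained SNP is summarised by its indicator
vector delta (delta_k = 1 if haplotype k carries the reference base), so the
panel frequency of the reference base is p = sum_k delta_k * Q_k.

Coordinates are 0-based half-open internally; GFF3 conversion happens at the
I/O boundary (see :mod:`gsca.io`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "GeneModel",
    "GeneSet",
    "PanelSNP",
    "HaplotypePanel",
    "build_gene_sets",
    "extract_haplotypes",
    "thin_redundant_snps",
    "n_genotypes",
]


def n_genotypes(K: int) -> int:
    """Number of unordered diploid genic-genotypes for K haplotypes: K(K+1)/2."""
    return K * (K + 1) // 2


@dataclass(frozen=True)
class GeneModel:
    """One gene, 0-based half-open coordinates."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise ValueError(f"malformed coordinates for {self.gene_id}: [{self.start}, {self.end})")


@dataclass
class PanelSNP:
    """A biallelic panel SNP with its haplotype indicator vector.

    ``delta[k] == 1`` iff haplotype k carries the reference base; ``p_panel``
    is the reference-base frequency among panel haplotypes weighted by Q.
    """

    snp_id: str
    pos: int
    ref_base: str
    alt_base: str
    delta: np.ndarray
    p_panel: float


@dataclass
class GeneSet:
    set_id: str
    chrom: str
    start: int
    end: int
    members: list[str] = field(default_factory=list)
    snps: list[PanelSNP] = field(default_factory=list)


@dataclass
class HaplotypePanel:
    """K distinct genic haplotypes of one gene set.

    ``alleles`` is a (K, M) 0/1 matrix over the gene set's SNP columns with
    0 = reference base, 1 = alternative base.  ``Q`` are haplotype
    frequencies (multiplicity among panel lines / number of lines).
    """

    set_id: str
    alleles: np.ndarray
    Q: np.ndarray
    line_to_hap: dict[str, int] = field(default_factory=dict)
    snps: list[PanelSNP] = field(default_factory=list)

    @property
    def K(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_snps(self) -> int:
        return self.alleles.shape[1]

    def delta(self, snp_index: int) -> np.ndarray:
        """Indicator vector: 1 where a haplotype carries the reference base."""
        return (self.alleles[:, snp_index] == 0).astype(np.int8)

    def p_panel(self, snp_index: int) -> float:
        return float(self.delta(snp_index) @ self.Q)


def build_gene_sets(genes: list[GeneModel], gap: int = 100) -> list[GeneSet]:
    """Partition genes into gene sets by chaining overlaps and gaps <= ``gap`` bp.

    Two genes end up in the same set iff they are connected by a chain of
    pairwise overlaps or separations of at most ``gap`` base pairs
    (transitive closure).  Input order is irrelevant; genes with malformed
    coordinates are skipped with a warning.
    """
    ok: list[GeneModel] = []
    for g in genes:
        if g.start > g.end:  # unreachable with frozen dataclass validation, kept for raw tuples
            logger.warning("rejecting gene %s: start > end", g.gene_id)
            continue
        ok.append(g)

    by_chrom: dict[str, list[GeneModel]] = {}
    for g in sorted(ok, key=lambda g: (g.chrom, g.start, g.end, g.gene_id)):
        by_chrom.setdefault(g.chrom, []).append(g)

    sets: list[GeneSet] = []
    for chrom, gs in by_chrom.items():
        cur: list[GeneModel] = []
        cur_end = -1
        for g in gs:
            # half-open: separation in bp between [.., cur_end) and [g.start, ..)
            if cur and g.start - cur_end > gap:
                sets.append(_finish_set(chrom, cur, len(sets)))
                cur, cur_end = [], -1
            cur.append(g)
            cur_end = max(cur_end, g.end)
        if cur:
            sets.append(_finish_set(chrom, cur, len(sets)))
    return sets


def _finish_set(chrom: str, members: list[GeneModel], index: int) -> GeneSet:
    start = min(g.start for g in members)
    end = max(g.end for g in members)
    return GeneSet(
        set_id=f"gs{index:05d}",
        chrom=chrom,
        start=start,
        end=end,
        members=[g.gene_id for g in members],
    )


def extract_haplotypes(
    line_alleles: np.ndarray,
    line_ids: list[str] | None = None,
    set_id: str = "gs00000",
    snps: list[PanelSNP] | None = None,
) -> HaplotypePanel:
    """Collapse identical panel-line rows into distinct haplotypes.

    ``line_alleles`` is a (lines, SNPs) integer matrix; columns with more
    than two distinct values (non-biallelic after upstream calling) are
    dropped with a warning.  Haplotype frequency Q_k is the multiplicity of
    sequence k among the lines divided by the number of lines.
    """
    A = np.asarray(line_alleles)
    if A.ndim != 2:
        raise ValueError("line_alleles must be a 2-D matrix (lines x SNPs)")
    n_lines = A.shape[0]
    if n_lines == 0:
        raise ValueError("empty panel")
    if line_ids is None:
        line_ids = [f"line{i}" for i in range(n_lines)]

    keep = [j for j in range(A.shape[1]) if len(np.unique(A[:, j])) <= 2]
    if len(keep) < A.shape[1]:
        logger.warning(
            "dropping %d non-biallelic SNP column(s) in %s", A.shape[1] - len(keep), set_id
        )
    A = A[:, keep]
    kept_snps = [snps[j] for j in keep] if snps is not None else None

    # collapse identical rows, first occurrence fixes haplotype order
    seen: dict[bytes, int] = {}
    rows: list[np.ndarray] = []
    counts: list[int] = []
    line_to_hap: dict[str, int] = {}
    for i in range(n_lines):
        key = A[i].tobytes()
        if key not in seen:
            seen[key] = len(rows)
            rows.append(A[i])
            counts.append(0)
        k = seen[key]
        counts[k] += 1
        line_to_hap[line_ids[i]] = k

    alleles = np.vstack(rows).astype(np.int8)
    Q = np.asarray(counts, dtype=float) / n_lines
    panel = HaplotypePanel(set_id=set_id, alleles=alleles, Q=Q, line_to_hap=line_to_hap)
    if kept_snps is not None:
        for j, s in enumerate(kept_snps):
            s.delta = panel.delta(j)
            s.p_panel = panel.p_panel(j)
        panel.snps = kept_snps
    return panel


def thin_redundant_snps(
    panel: HaplotypePanel,
    snps: list[PanelSNP] | None = None,
    treat_complement_as_redundant: bool = True,
    drop_monomorphic: bool = True,
) -> list[PanelSNP]:
    """Keep one representative SNP per distinct haplotype bipartition.

    SNPs whose delta vectors are identical — or, by default, exact
    complements, since a flipped indicator induces the same bipartition of
    haplotypes and hence identical genotype likelihoods — are thinned to the
    5'-most representative.  SNPs monomorphic within the panel carry no
    frequency contrast and are dropped when ``drop_monomorphic``.
    """
    if snps is None:
        if not panel.snps:
            snps = [
                PanelSNP(f"snp{j}", j, "A", "T", panel.delta(j), panel.p_panel(j))
                for j in range(panel.n_snps)
            ]
        else:
            snps = panel.snps
    out: list[PanelSNP] = []
    seen: set[bytes] = set()
    for s in sorted(snps, key=lambda s: s.pos):
        d = np.asarray(s.delta, dtype=np.int8)
        if drop_monomorphic and (d.all() or not d.any()):
            continue
        key = d.tobytes()
        comp = (1 - d).tobytes()
        canon = min(key, comp) if treat_complement_as_redundant else key
        if canon in seen:
            continue
        seen.add(canon)
        out.append(s)
    return out
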