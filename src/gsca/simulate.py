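"""Synthetic experiments: panel, family structure, cohorts and read-pair data.

The generator emulates a two-year field design: year 1 samples reproductive
adults (cohort A) and a few greenhouse-grown progeny per mother; year 2 adds
the cohort of plants that germinated but failed to reproduce (L).  Maternal
genotypes are drawn Hardy-Weinberg from the reweighted haplotype
frequencies Q*(p_cohort); each offspring is selfed with the configured
probability, otherwise a sire haplotype is drawn from Q*(p_M); one maternal
haplotype is transmitted with probability 1/2.  Read-pairs are contiguous
SNP windows drawn from one of the plant's two haplotypes with per-base
error eps_sim — the structure of restriction-fragment (RAD/MSG) loci,
without simulating base-level sequence.

Under neutrality all cohort frequencies equal the panel frequency, so the
downstream likelihood-ratio tests should follow their asymptotic chi-square
null distribution; this is the calibration the test-suite checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .likelihood import ReadPairObservation
from .models import Family, SnpFamilyData
from .panel import HaplotypePanel

__all__ = [
    "SimulationConfig",
    "SimulatedYear",
    "SimulatedExperiment",
    "simulate_panel",
    "simulate_family",
    "simulate_readpairs",
    "simulate_year",
    "simulate_experiment",
]


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic experiment.

    Defaults mirror the field design the machinery targets: ~200 maternal
    families per cohort-year with 2-4 (default 3) progeny each, ~10%
    selfing, survival fraction 0.7 (fixing the L:A ratio), reads covering a
    median of ~6 SNPs, and mismatch rate eps = 0.005.
    """

    seed: int = 0
    K: int = 8
    n_snps_per_gene: int = 12
    n_families: int = 200  # cohort-A families per year
    n_failed: int | None = None  # cohort-L plants; default (1-alpha)/alpha * n_families
    offspring_per_family: int = 3
    selfing_rate: float = 0.10
    survival_fraction: float = 0.7
    cohort_freqs: dict[str, float] | None = None  # {"p_A","p_M","p_L"}; None = neutral
    coverage_mean: float = 10.0
    coverage_dispersion: float = 5.0  # negative-binomial shape
    snps_per_read: float = 6.0
    epsilon_sim: float = 0.005

    def __post_init__(self) -> None:
        for name in ("selfing_rate", "survival_fraction", "epsilon_sim"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.n_failed is None:
            a = self.survival_fraction
            self.n_failed = int(round(self.n_families * (1.0 - a) / a))


@dataclass
class SimulatedYear:
    """One year's families with full truth tables and read data.

    Plants are indexed 0..P-1 (mothers first, then offspring in family
    order).  ``reads_*`` hold all SNP calls concatenated; truth records the
    transmitted maternal and sire haplotypes per offspring.
    """

    year: int
    panel: HaplotypePanel
    focal_snp: int
    plant_geno: np.ndarray  # (P, 2) true haplotype indices
    mother_idx: np.ndarray  # (F,)
    is_A: np.ndarray  # (F,)
    off_plant: np.ndarray  # (F, Omax), -1 padded
    off_selfed: np.ndarray  # (F, Omax)
    off_maternal_hap: np.ndarray  # (F, Omax), -1 padded
    off_sire_hap: np.ndarray  # (F, Omax), -1 padded
    read_plant: np.ndarray  # (R,)
    read_lens: np.ndarray  # (R,)
    call_cols: np.ndarray  # concatenated SNP column indices
    call_obs: np.ndarray  # concatenated observed allele codes
    cohort_freqs: dict[str, float] = field(default_factory=dict)

    @property
    def n_plants(self) -> int:
        return self.plant_geno.shape[0]

    def plant_ids(self) -> list[str]:
        ids = [f"y{self.year}_m{f}" for f in range(self.mother_idx.size)]
        for f in range(self.off_plant.shape[0]):
            for o in range(self.off_plant.shape[1]):
                if self.off_plant[f, o] >= 0:
                    ids.append(f"y{self.year}_m{f}_o{o}")
        return ids

    def families(self) -> list[Family]:
        ids = self.plant_ids()
        fams = []
        for f in range(self.mother_idx.size):
            offspring = [
                (ids[self.off_plant[f, o]], "S" if self.off_selfed[f, o] else "O")
                for o in range(self.off_plant.shape[1])
                if self.off_plant[f, o] >= 0
            ]
            fams.append(
                Family(
                    family_id=f"y{self.year}_f{f}",
                    year=self.year,
                    maternal_plant=ids[f],
                    cohort="A" if self.is_A[f] else "L",
                    offspring=offspring,
                )
            )
        return fams

    def observations(self) -> list[ReadPairObservation]:
        ids = self.plant_ids()
        out = []
        start = 0
        for r, (p, ln) in enumerate(zip(self.read_plant, self.read_lens)):
            out.append(
                ReadPairObservation(
                    plant_id=ids[p],
                    set_id=self.panel.set_id,
                    read_id=f"y{self.year}_r{r}",
                    snp_indices=self.call_cols[start : start + ln],
                    alleles=self.call_obs[start : start + ln],
                )
            )
            start += ln
        return out

    def stacked_loglik(self, epsilon: float, bernoulli: bool = False) -> np.ndarray:
        """(P, K, K) log-U array for every plant, computed in one pass."""
        K = self.panel.K
        P = self.n_plants
        logU = np.zeros((P, K, K))
        if self.read_plant.size == 0:
            return logU
        starts = np.concatenate([[0], np.cumsum(self.read_lens)[:-1]])
        mism = self.panel.alleles[:, self.call_cols] != self.call_obs[None, :]
        h = np.add.reduceat(mism, starts, axis=1).T  # (R, K)
        logf = h * np.log(epsilon)
        if bernoulli:
            logf = logf + (self.read_lens[:, None] - h) * np.log1p(-epsilon)
        m = logf.max(axis=1)
        w = np.exp(logf - m[:, None])
        pair = np.log(0.5 * (w[:, :, None] + w[:, None, :])) + m[:, None, None]
        np.add.at(logU, self.read_plant, pair)
        return logU

    def snp_data(self, epsilon: float = 0.005) -> SnpFamilyData:
        """Bundle the year into a fitting-ready per-SNP dataset."""
        return SnpFamilyData.from_stacked(
            self.stacked_loglik(epsilon),
            self.mother_idx,
            self.is_A,
            self.off_plant,
            self.off_selfed,
            self.panel.Q,
            self.panel.delta(self.focal_snp),
        )

    def true_frequency(self, cohort: str) -> float:
        """Realized reference-allele frequency at the focal SNP in a cohort."""
        delta = self.panel.delta(self.focal_snp)
        if cohort == "A" or cohort == "L":
            mask = self.is_A if cohort == "A" else ~self.is_A
            g = self.plant_geno[self.mother_idx[mask]]
            return float(delta[g].mean())
        if cohort == "M":
            sires = self.off_sire_hap[(self.off_plant >= 0) & ~self.off_selfed]
            return float(delta[sires].mean())
        raise ValueError(f"unknown cohort {cohort!r}")


@dataclass
class SimulatedExperiment:
    config: SimulationConfig
    panel: HaplotypePanel
    year1: SimulatedYear
    year2: SimulatedYear


def simulate_panel(config: SimulationConfig, rng: np.random.Generator) -> HaplotypePanel:
    """K distinct haplotypes over random biallelic SNPs, uniform Q."""
    K, m = config.K, config.n_snps_per_gene
    if K < 2 or m < 1:
        raise ValueError("need K >= 2 haplotypes and >= 1 SNP")
    if K > 2**m:
        raise ValueError(f"cannot build {K} distinct haplotypes from {m} biallelic SNPs")
    for _ in range(1000):
        alleles = (rng.random((K, m)) < 0.5).astype(np.int8)
        # resample monomorphic columns
        for j in range(m):
            while alleles[:, j].min() == alleles[:, j].max():
                alleles[:, j] = (rng.random(K) < 0.5).astype(np.int8)
        if len({row.tobytes() for row in alleles}) == K:
            break
    else:  # pragma: no cover
        raise RuntimeError("failed to draw distinct haplotypes")
    return HaplotypePanel(
        set_id="sim_gs00000",
        alleles=alleles,
        Q=np.full(K, 1.0 / K),
        line_to_hap={f"line{k}": k for k in range(K)},
    )


def _pick_focal(panel: HaplotypePanel) -> int:
    """The SNP with panel frequency closest to 1/2 (ties to the 5'-most)."""
    p = np.array([panel.p_panel(j) for j in range(panel.n_snps)])
    return int(np.argmin(np.abs(p - 0.5)))


def _reweighted(panel: HaplotypePanel, focal: int, p_star: float | None) -> np.ndarray:
    from .models import reweight_frequencies

    if p_star is None:
        return panel.Q
    return reweight_frequencies(panel.Q, panel.delta(focal), panel.p_panel(focal), p_star)


def simulate_family(
    config: SimulationConfig,
    panel: HaplotypePanel,
    rng: np.random.Generator,
    focal_snp: int | None = None,
    cohort: str = "A",
    year: int = 2013,
    family_id: str = "f0",
) -> tuple[Family, dict]:
    """Draw a single family and its truth record (scalar mirror of the batch path)."""
    focal = _pick_focal(panel) if focal_snp is None else focal_snp
    freqs = config.cohort_freqs or {}
    p_mother = freqs.get("p_A" if cohort == "A" else "p_L")
    Qm = _reweighted(panel, focal, p_mother)
    Qsire = _reweighted(panel, focal, freqs.get("p_M"))
    mother = tuple(rng.choice(panel.K, size=2, p=Qm))
    offspring = []
    truth_off = []
    if cohort == "A":
        for o in range(config.offspring_per_family):
            selfed = rng.random() < config.selfing_rate
            mat = mother[rng.integers(2)]
            sire = mother[rng.integers(2)] if selfed else int(rng.choice(panel.K, p=Qsire))
            offspring.append((f"{family_id}_o{o}", "S" if selfed else "O"))
            truth_off.append({"maternal_hap": int(mat), "sire_hap": int(sire), "selfed": bool(selfed)})
    fam = Family(family_id, year, f"{family_id}_m", cohort, offspring)
    truth = {"mother_geno": (int(mother[0]), int(mother[1])), "offspring": truth_off}
    return fam, truth


def simulate_readpairs(
    plant_geno: np.ndarray,
    panel: HaplotypePanel,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Reads for all plants at once: (read_plant, read_lens, call_cols, call_obs).

    Per plant the read-pair count is negative binomial (configured mean and
    shape); each read is a contiguous SNP window from one of the plant's two
    haplotypes, each scored base flipped with probability eps_sim.
    """
    P = plant_geno.shape[0]
    m = panel.n_snps
    mean, k = config.coverage_mean, config.coverage_dispersion
    RP = rng.negative_binomial(k, k / (k + mean), size=P)
    read_plant = np.repeat(np.arange(P), RP)
    R = read_plant.size
    if R == 0:
        return read_plant, np.zeros(0, dtype=int), np.zeros(0, dtype=np.intp), np.zeros(0, dtype=np.int8)
    hap_choice = rng.integers(2, size=R)
    source = plant_geno[read_plant, hap_choice]
    lens = np.clip(1 + rng.poisson(max(config.snps_per_read - 1.0, 0.0), size=R), 1, m)
    starts = rng.integers(0, m - lens + 1)
    n_calls = int(lens.sum())
    ends = np.cumsum(lens)
    within = np.arange(n_calls) - np.repeat(ends - lens, lens)
    cols = (np.repeat(starts, lens) + within).astype(np.intp)
    obs = panel.alleles[np.repeat(source, lens), cols].copy()
    flips = rng.random(n_calls) < config.epsilon_sim
    obs[flips] = 1 - obs[flips]
    return read_plant, lens.astype(int), cols, obs


def simulate_year(
    config: SimulationConfig,
    panel: HaplotypePanel,
    rng: np.random.Generator,
    year: int,
    include_failed: bool = False,
    focal_snp: int | None = None,
) -> SimulatedYear:
    """One cohort-year: mothers (+ L plants), progeny, and their reads."""
    focal = _pick_focal(panel) if focal_snp is None else focal_snp
    freqs = dict(config.cohort_freqs or {})
    F_A = config.n_families
    F_L = config.n_failed if include_failed else 0
    F = F_A + F_L
    Omax = config.offspring_per_family

    Qa = _reweighted(panel, focal, freqs.get("p_A"))
    Ql = _reweighted(panel, focal, freqs.get("p_L"))
    Qs = _reweighted(panel, focal, freqs.get("p_M"))

    is_A = np.concatenate([np.ones(F_A, bool), np.zeros(F_L, bool)])
    mother_geno = np.empty((F, 2), dtype=np.intp)
    mother_geno[:F_A] = rng.choice(panel.K, size=(F_A, 2), p=Qa)
    if F_L:
        mother_geno[F_A:] = rng.choice(panel.K, size=(F_L, 2), p=Ql)

    off_plant = np.full((F, Omax), -1, dtype=np.intp)
    off_selfed = np.zeros((F, Omax), dtype=bool)
    off_mat = np.full((F, Omax), -1, dtype=np.intp)
    off_sire = np.full((F, Omax), -1, dtype=np.intp)

    selfed = rng.random((F_A, Omax)) < config.selfing_rate
    mat_pick = rng.integers(2, size=(F_A, Omax))
    mat_hap = mother_geno[np.arange(F_A)[:, None], mat_pick]
    self_pick = rng.integers(2, size=(F_A, Omax))
    self_sire = mother_geno[np.arange(F_A)[:, None], self_pick]
    out_sire = rng.choice(panel.K, size=(F_A, Omax), p=Qs)
    sire_hap = np.where(selfed, self_sire, out_sire)

    off_selfed[:F_A] = selfed
    off_mat[:F_A] = mat_hap
    off_sire[:F_A] = sire_hap
    off_plant[:F_A] = F + (np.arange(F_A * Omax)).reshape(F_A, Omax)

    plant_geno = np.concatenate(
        [mother_geno, np.stack([mat_hap.ravel(), sire_hap.ravel()], axis=1)]
    )
    mother_idx = np.arange(F, dtype=np.intp)

    read_plant, lens, cols, obs = simulate_readpairs(plant_geno, panel, config, rng)
    return SimulatedYear(
        year=year,
        panel=panel,
        focal_snp=focal,
        plant_geno=plant_geno,
        mother_idx=mother_idx,
        is_A=is_A,
        off_plant=off_plant,
        off_selfed=off_selfed,
        off_maternal_hap=off_mat,
        off_sire_hap=off_sire,
        read_plant=read_plant,
        read_lens=lens,
        call_cols=cols,
        call_obs=obs,
        cohort_freqs=freqs,
    )


def simulate_experiment(config: SimulationConfig) -> SimulatedExperiment:
    """Full two-year design: year 1 (A + progeny), year 2 (A, L, progeny)."""
    rng = np.random.default_rng(config.seed)
    panel = simulate_panel(config, rng)
    y1 = simulate_year(config, panel, rng, year=2013, include_failed=False)
    y2 = simulate_year(config, panel, rng, year=2014, include_failed=True)
    return SimulatedExperiment(config=config, panel=panel, year1=y1, year2=y2)
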