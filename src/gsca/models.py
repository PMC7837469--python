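"""Family-structured selection component likelihoods and LRT selection tests.

The data are families: a maternal field plant from cohort A (reproduced) or
L (failed to reproduce) plus, for A mothers, a sample of genotyped progeny,
each outcrossed or selfed.  At a focal SNP the K genic haplotypes split into
reference- and alternative-carrying classes, and a cohort's allele frequency
p* enters the likelihood through a proportional reweighting of the panel
haplotype frequencies:

    Q*_k = Q_k p*/p        (haplotype k carries the reference base)
    Q*_k = Q_k (1-p*)/(1-p)  otherwise,

where p is the panel frequency.  The likelihood of a family sums over
unordered maternal genotypes (Hardy-Weinberg prior under Q*(p_mother)),
multiplying the mother's genotype likelihood U by each offspring's
transmission term.  For an outcrossed offspring the sire-allele frequency
p_M enters linearly, V = p_M T1 + (1 - p_M) T2, with T1/T2 precomputable
coefficients; selfed offspring contribute 1/4 U_ii + 1/2 U_ij + 1/4 U_jj
and carry no information about p_M.

Model hierarchy (free cohort frequencies):

    2013:  H0: p_A = p_M = p          H1: p_A, p_M free
    2014:  H0: p_A = p_M = p_L = p    H1: p_A = p_M, p_L free
           H2: p_A = p_L, p_M free    H3: p_A, p_M, p_L free

Male selection is H1 vs H0 (2013) and H3 vs H1 (2014); viability selection
is H3 vs H2; the cross-year allele frequency change test constrains p_A of
year 1 to equal the pooled zygote frequency p_Z of year 2.  All contrasts
are 1-df likelihood-ratio tests; likelihoods are maximized with Powell's
method on logit-transformed frequencies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2

from .likelihood import GenotypeLikelihoodTable, genotype_pairs
from .panel import HaplotypePanel

logger = logging.getLogger(__name__)

__all__ = [
    "Family",
    "ModelSpec",
    "FitResult",
    "LRTResult",
    "ChangeTestResult",
    "SnpFamilyData",
    "MODELS_2013",
    "MODELS_2014",
    "reweight_frequencies",
    "maternal_prior",
    "offspring_lik_selfed",
    "offspring_coefficients",
    "family_loglik",
    "fit_model",
    "fit_year",
    "run_tests",
    "change_test",
    "selfing_rate",
]

P_FLOOR = 1e-6
PVAL_FLOOR = 1e-300


def selfing_rate(n_selfed: int, n_total: int) -> float:
    """Fraction of offspring classified as selfed (mating-system summary)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return n_selfed / n_total


@dataclass
class Family:
    """One maternal field plant and its genotyped offspring.

    ``cohort`` is 'A' (reproduced) or 'L' (failed to reproduce; no
    offspring).  Offspring are (plant_id, cross) with cross 'O' (outcrossed)
    or 'S' (selfed); missing cross-type is treated as outcrossed.
    """

    family_id: str
    year: int
    maternal_plant: str
    cohort: str
    offspring: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.cohort not in ("A", "L"):
            raise ValueError(f"cohort must be 'A' or 'L', got {self.cohort!r}")
        if self.cohort == "L" and self.offspring:
            raise ValueError("cohort-L families have no genotyped offspring")
        self.offspring = [(pid, c if c in ("O", "S") else "O") for pid, c in self.offspring]

    @property
    def O_y(self) -> int:
        return len(self.offspring)


@dataclass(frozen=True)
class ModelSpec:
    """A constraint pattern over cohort allele frequencies.

    ``roles`` maps each of 'A' (adult mothers), 'M' (successful male
    gametes), 'L' (failed plants) to the name of a free parameter or to a
    fixed float.
    """

    name: str
    free_params: tuple[str, ...]
    roles: dict[str, object]

    @property
    def n_free(self) -> int:
        return len(self.free_params)

    def frequencies(self, values: dict[str, float]) -> tuple[float, float, float]:
        out = []
        for role in ("A", "M", "L"):
            b = self.roles[role]
            out.append(values[b] if isinstance(b, str) else float(b))
        return tuple(out)


MODELS_2013: dict[str, ModelSpec] = {
    "H0": ModelSpec("H0", ("p",), {"A": "p", "M": "p", "L": "p"}),
    "H1": ModelSpec("H1", ("p_A", "p_M"), {"A": "p_A", "M": "p_M", "L": "p_A"}),
}

MODELS_2014: dict[str, ModelSpec] = {
    "H0": ModelSpec("H0", ("p",), {"A": "p", "M": "p", "L": "p"}),
    "H1": ModelSpec("H1", ("p_AM", "p_L"), {"A": "p_AM", "M": "p_AM", "L": "p_L"}),
    "H2": ModelSpec("H2", ("p_AL", "p_M"), {"A": "p_AL", "M": "p_M", "L": "p_AL"}),
    "H3": ModelSpec("H3", ("p_A", "p_M", "p_L"), {"A": "p_A", "M": "p_M", "L": "p_L"}),
}


@dataclass
class FitResult:
    spec: ModelSpec
    estimates: dict[str, float]
    lnL: float
    n_free: int
    converged: bool

    def frequency(self, role: str) -> float:
        b = self.spec.roles[role]
        return self.estimates[b] if isinstance(b, str) else float(b)


@dataclass
class LRTResult:
    statistic: float
    df: int
    p_value: float


@dataclass
class ChangeTestResult:
    lrt: LRTResult
    null_fit: FitResult
    alt_fit: FitResult
    p_A_year1: float
    p_Z_year2: float

    @property
    def observed_dp(self) -> float:
        return self.p_Z_year2 - self.p_A_year1


# ---------------------------------------------------------------------------
# elementary operations (reference forms; the fitter uses SnpFamilyData)
# ---------------------------------------------------------------------------


def reweight_frequencies(
    Q: np.ndarray, delta: np.ndarray, p: float, p_star: float
) -> np.ndarray:
    """Proportionally rescale haplotype frequencies to cohort frequency p*."""
    if not 0.0 < p < 1.0:
        raise ValueError("panel frequency p must be strictly inside (0, 1)")
    if not 0.0 <= p_star <= 1.0:
        raise ValueError("cohort frequency must lie in [0, 1]")
    Q = np.asarray(Q, dtype=float)
    delta = np.asarray(delta)
    return np.where(delta == 1, Q * p_star / p, Q * (1.0 - p_star) / (1.0 - p))


def maternal_prior(i: int, j: int, Qstar: np.ndarray) -> float:
    """Hardy-Weinberg prior of the unordered maternal genotype [i, j]."""
    if i == j:
        return float(Qstar[i] ** 2)
    return float(2.0 * Qstar[i] * Qstar[j])


def offspring_lik_selfed(U: np.ndarray, i: int, j: int) -> float:
    """Selfed-offspring likelihood: Mendelian mixture over the mother's gametes."""
    return 0.25 * U[i, i] + 0.5 * U[i, j] + 0.25 * U[j, j]


def offspring_coefficients(
    U: np.ndarray, i: int, j: int, Q: np.ndarray, delta: np.ndarray, p: float
) -> tuple[float, float]:
    """T1/T2 coefficients so that V(p_M) = p_M T1 + (1-p_M) T2.

    T1 sums sire haplotypes carrying the reference base (weights Q_v/p), T2
    the alternative class (weights Q_w/(1-p)); both fold in the 1/2 chance
    of either maternal allele being transmitted.  They depend only on the
    offspring's read data and the panel, so a likelihood search evaluates
    them once.
    """
    ref = delta == 1
    wR = np.where(ref, Q / p, 0.0)
    wA = np.where(~ref, Q / (1.0 - p), 0.0)
    half = 0.5 * (U[i, :] + U[j, :])
    return float(half @ wR), float(half @ wA)


def family_loglik(
    family: Family,
    params: dict[str, float],
    tables: dict[str, GenotypeLikelihoodTable],
    panel: HaplotypePanel,
    snp_index: int,
) -> float:
    """Reference (loop-based) log-likelihood of one family at one SNP.

    ``params`` supplies the mother-cohort frequency ('p_A' or 'p_L') and
    'p_M' for outcrossed offspring.  The vectorized :class:`SnpFamilyData`
    path is exactly equivalent; this form exists for clarity and testing.
    """
    K = panel.K
    Q, delta, p = panel.Q, panel.delta(snp_index), panel.p_panel(snp_index)
    p_mother = params["p_A"] if family.cohort == "A" else params["p_L"]
    p_M = params.get("p_M", p)
    Qstar_m = reweight_frequencies(Q, delta, p, p_mother)

    mt = tables.get(family.maternal_plant)
    logUm = mt.effective_loglik() if mt is not None else np.zeros((K, K))
    scale = logUm.max()
    Um = np.exp(logUm - scale)

    total = 0.0
    for i in range(K):
        for j in range(i, K):
            term = maternal_prior(i, j, Qstar_m) * Um[i, j]
            for pid, cross in family.offspring:
                ot = tables.get(pid)
                logUo = ot.effective_loglik() if ot is not None else np.zeros((K, K))
                c = logUo.max()
                Uo = np.exp(logUo - c)
                if cross == "S":
                    v = offspring_lik_selfed(Uo, i, j)
                else:
                    t1, t2 = offspring_coefficients(Uo, i, j, Q, delta, p)
                    v = p_M * t1 + (1.0 - p_M) * t2
                term *= v * np.exp(c)
            total += term
    return float(np.log(total) + scale)


# ---------------------------------------------------------------------------
# vectorized per-SNP data and model fitting
# ---------------------------------------------------------------------------


class SnpFamilyData:
    """Per-SNP precomputation over all families, ready for fast evaluation.

    Builds, per family, the maternal genotype log-likelihood over the
    K(K+1)/2 unordered genotypes, the (p_M-independent) selfed-offspring
    log term, and stacked T1/T2 coefficient arrays for outcrossed
    offspring, padded so all families share one array shape.
    """

    def __init__(
        self,
        families: list[Family],
        tables: dict[str, GenotypeLikelihoodTable],
        panel: HaplotypePanel,
        snp_index: int,
    ) -> None:
        K = panel.K
        iu_i, iu_j = genotype_pairs(K)
        self.panel = panel
        self.snp_index = snp_index
        self.families = families
        Q = panel.Q
        delta = panel.delta(snp_index)
        p = panel.p_panel(snp_index)
        if not 0.0 < p < 1.0:
            raise ValueError(f"SNP {snp_index} monomorphic in panel (p={p}); not testable")
        self.p = p
        self.aR = (delta[iu_i] + delta[iu_j]).astype(float)  # reference alleles per genotype
        mult = np.where(iu_i == iu_j, 1.0, 2.0)
        self.logprior0 = np.log(mult * Q[iu_i] * Q[iu_j])

        ref = delta == 1
        wR = np.where(ref, Q / p, 0.0)
        wA = np.where(~ref, Q / (1.0 - p), 0.0)

        F = len(families)
        G = iu_i.size
        Omax = max((sum(1 for _, c in f.offspring if c == "O") for f in families), default=0)
        self.is_A = np.array([f.cohort == "A" for f in families])
        self.logUm = np.zeros((F, G))
        self.logVself = np.zeros((F, G))
        self.T1 = np.ones((F, max(Omax, 1), G))
        self.T2 = np.ones((F, max(Omax, 1), G))
        self.logC = np.zeros(F)  # genotype-independent scale constants

        for y, fam in enumerate(families):
            mt = tables.get(fam.maternal_plant)
            if mt is not None:
                llm = mt.effective_loglik()
                c = llm.max()
                self.logUm[y] = llm[iu_i, iu_j] - c
                self.logC[y] += c
            o_out = 0
            for pid, cross in fam.offspring:
                ot = tables.get(pid)
                llo = ot.effective_loglik() if ot is not None else np.zeros((K, K))
                c = llo.max()
                Uo = np.exp(llo - c)
                self.logC[y] += c
                if cross == "S":
                    vs = (
                        0.25 * Uo[iu_i, iu_i] + 0.5 * Uo[iu_i, iu_j] + 0.25 * Uo[iu_j, iu_j]
                    )
                    with np.errstate(divide="ignore"):
                        self.logVself[y] += np.log(vs)
                else:
                    A1 = Uo @ wR
                    A2 = Uo @ wA
                    self.T1[y, o_out] = 0.5 * (A1[iu_i] + A1[iu_j])
                    self.T2[y, o_out] = 0.5 * (A2[iu_i] + A2[iu_j])
                    o_out += 1

    @classmethod
    def from_stacked(
        cls,
        logU: np.ndarray,
        mother_idx: np.ndarray,
        is_A: np.ndarray,
        off_plant: np.ndarray,
        off_selfed: np.ndarray,
        Q: np.ndarray,
        delta: np.ndarray,
    ) -> "SnpFamilyData":
        """Vectorized construction from a stacked (P, K, K) log-U array.

        ``off_plant`` is (F, Omax) with -1 padding for absent offspring;
        ``off_selfed`` marks selfed slots.  Used by the simulator, where all
        plants of an experiment share one array; exactly equivalent to the
        per-family constructor.
        """
        self = object.__new__(cls)
        P, K, _ = logU.shape
        iu_i, iu_j = genotype_pairs(K)
        G = iu_i.size
        p = float(delta @ Q)
        if not 0.0 < p < 1.0:
            raise ValueError(f"monomorphic focal SNP (p={p}); not testable")
        self.panel = None
        self.snp_index = -1
        self.families = None
        self.p = p
        self.aR = (delta[iu_i] + delta[iu_j]).astype(float)
        mult = np.where(iu_i == iu_j, 1.0, 2.0)
        self.logprior0 = np.log(mult * Q[iu_i] * Q[iu_j])

        ref = delta == 1
        wR = np.where(ref, Q / p, 0.0)
        wA = np.where(~ref, Q / (1.0 - p), 0.0)

        c_p = logU.max(axis=(1, 2))
        Uo = np.exp(logU - c_p[:, None, None])
        A1 = Uo @ wR  # (P, K)
        A2 = Uo @ wA

        F, Omax = off_plant.shape
        self.is_A = np.asarray(is_A, dtype=bool)
        self.logUm = logU[mother_idx][:, iu_i, iu_j] - c_p[mother_idx, None]
        self.logC = c_p[mother_idx].copy()

        Omax = max(Omax, 1)
        self.T1 = np.ones((F, Omax, G))
        self.T2 = np.ones((F, Omax, G))
        self.logVself = np.zeros((F, G))
        if off_plant.shape[1] > 0:
            exists = off_plant >= 0
            pid = np.where(exists, off_plant, 0)
            out_mask = exists & ~off_selfed
            T1_all = 0.5 * (A1[pid][:, :, iu_i] + A1[pid][:, :, iu_j])
            T2_all = 0.5 * (A2[pid][:, :, iu_i] + A2[pid][:, :, iu_j])
            self.T1[:, : off_plant.shape[1]] = np.where(out_mask[:, :, None], T1_all, 1.0)
            self.T2[:, : off_plant.shape[1]] = np.where(out_mask[:, :, None], T2_all, 1.0)
            self_mask = exists & off_selfed
            if self_mask.any():
                Vs = (
                    0.25 * Uo[pid][:, :, iu_i, iu_i]
                    + 0.5 * Uo[pid][:, :, iu_i, iu_j]
                    + 0.25 * Uo[pid][:, :, iu_j, iu_j]
                )
                with np.errstate(divide="ignore"):
                    logVs = np.where(self_mask[:, :, None], np.log(Vs), 0.0)
                self.logVself = logVs.sum(axis=1)
            self.logC += np.where(exists, c_p[pid], 0.0).sum(axis=1)
        return self

    def subset(self, mask: np.ndarray) -> "SnpFamilyData":
        """Restrict to a subset of families (e.g. an odd/even split half)."""
        sub = object.__new__(SnpFamilyData)
        sub.panel, sub.snp_index, sub.families = self.panel, self.snp_index, None
        sub.p, sub.aR, sub.logprior0 = self.p, self.aR, self.logprior0
        mask = np.asarray(mask)
        for name in ("is_A", "logUm", "logVself", "T1", "T2", "logC"):
            setattr(sub, name, getattr(self, name)[mask])
        return sub

    @property
    def n_families(self) -> int:
        return self.logUm.shape[0]

    def _logprior(self, p_star: float) -> np.ndarray:
        r = np.log(p_star / self.p)
        a = np.log((1.0 - p_star) / (1.0 - self.p))
        return self.logprior0 + self.aR * r + (2.0 - self.aR) * a

    def loglik(self, p_A: float, p_M: float, p_L: float | None = None) -> float:
        """Total log-likelihood at the given cohort frequencies."""
        p_A = float(np.clip(p_A, P_FLOOR, 1.0 - P_FLOOR))
        p_M = float(np.clip(p_M, P_FLOOR, 1.0 - P_FLOOR))
        prior_A = self._logprior(p_A)
        if self.is_A.all() or p_L is None:
            prior = np.broadcast_to(prior_A, self.logUm.shape)
        else:
            p_L = float(np.clip(p_L, P_FLOOR, 1.0 - P_FLOOR))
            prior = np.where(self.is_A[:, None], prior_A, self._logprior(p_L))
        with np.errstate(divide="ignore"):
            logVout = np.log(p_M * self.T1 + (1.0 - p_M) * self.T2).sum(axis=1)
        terms = prior + self.logUm + self.logVself + logVout
        m = terms.max(axis=1)
        ly = m + np.log(np.exp(terms - m[:, None]).sum(axis=1))
        return float(ly.sum() + self.logC.sum())


def _logit(x: np.ndarray) -> np.ndarray:
    return np.log(x / (1.0 - x))


def _expit(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def fit_model(
    data: SnpFamilyData,
    spec: ModelSpec,
    start: dict[str, float] | None = None,
    tol: float = 1e-9,
    fixed: dict[str, float] | None = None,
) -> FitResult:
    """Maximize the family likelihood under a model's constraint pattern.

    Powell's direction-set method on logit-transformed frequencies, started
    at the panel frequency, with restarts from 0.25 and 0.75 on failure.
    """

    def lnL_at(values: dict[str, float]) -> float:
        pA, pM, pL = spec.frequencies(values)
        return data.loglik(pA, pM, pL)

    if spec.n_free == 0:
        values = dict(fixed or {})
        return FitResult(spec, values, lnL_at(values), 0, True)

    names = spec.free_params

    def neg(theta: np.ndarray) -> float:
        vals = dict(zip(names, np.clip(_expit(theta), P_FLOOR, 1.0 - P_FLOOR)))
        if fixed:
            vals.update(fixed)
        return -lnL_at(vals)

    starts = [np.full(len(names), _logit(np.clip(data.p, 0.02, 0.98)))]
    if start:
        starts.insert(0, _logit(np.clip(np.array([start[n] for n in names]), 0.02, 0.98)))
    best = None
    converged = False
    for k, x0 in enumerate(starts + [np.full(len(names), _logit(0.25)), np.full(len(names), _logit(0.75))]):
        res = minimize(neg, x0, method="Powell", options={"ftol": tol, "xtol": 1e-7})
        if best is None or res.fun < best.fun - 1e-12:
            best = res
        if res.success:
            converged = True
        if converged and k >= len(starts) - 1:
            break
    est = dict(zip(names, np.clip(_expit(best.x), P_FLOOR, 1.0 - P_FLOOR)))
    if fixed:
        est.update(fixed)
    return FitResult(spec, {k: float(v) for k, v in est.items()}, -float(best.fun), len(names), converged)


def fit_year(data: SnpFamilyData, year: int) -> dict[str, FitResult]:
    """Fit the full model hierarchy for one year's data at one SNP."""
    models = MODELS_2013 if year == 2013 else MODELS_2014
    fits: dict[str, FitResult] = {}
    for name, spec in models.items():
        fits[name] = fit_model(data, spec)
    # nested models can never beat their generalization; nudge with warm starts if they do
    order = [("H0", "H1"), ("H0", "H2"), ("H1", "H3"), ("H2", "H3")]
    for con, gen in order:
        if con in fits and gen in fits and fits[gen].lnL < fits[con].lnL - 1e-9:
            warm = _warm_start(fits[con], models[gen])
            refit = fit_model(data, models[gen], start=warm)
            if refit.lnL > fits[gen].lnL:
                fits[gen] = refit
    return fits


def _warm_start(con_fit: FitResult, gen_spec: ModelSpec) -> dict[str, float]:
    start = {}
    for name in gen_spec.free_params:
        role = next((r for r, b in gen_spec.roles.items() if b == name), None)
        start[name] = con_fit.frequency(role) if role else 0.5
    return start


def lrt(general: FitResult, constrained: FitResult) -> LRTResult:
    stat = max(0.0, 2.0 * (general.lnL - constrained.lnL))
    df = general.n_free - constrained.n_free
    p = max(float(chi2.sf(stat, df)), PVAL_FLOOR)
    return LRTResult(stat, df, p)


def run_tests(fits: dict[str, FitResult], year: int) -> dict[str, LRTResult]:
    """Likelihood-ratio tests of the year's model hierarchy.

    2013: male selection = H1 vs H0.  2014: male selection = H3 vs H1,
    viability selection = H3 vs H2.  All are 1-df contrasts.
    """
    out: dict[str, LRTResult] = {}
    if year == 2013:
        out["male"] = lrt(fits["H1"], fits["H0"])
    else:
        out["male"] = lrt(fits["H3"], fits["H1"])
        out["viability"] = lrt(fits["H3"], fits["H2"])
    return out


def change_test(
    data_year1: SnpFamilyData,
    data_year2: SnpFamilyData,
    tol: float = 1e-9,
    year1_model: str = "H1",
) -> ChangeTestResult:
    """Cross-year allele frequency change test at one SNP.

    Null: p_A of year 1 equals the pooled zygote frequency p_Z of year 2
    (fitted H0-style from all year-2 cohorts).  Alternative: p_Z free,
    determined entirely by year-2 data.  The year-1 side fits H1 (p_A, p_M
    free) in both; ``year1_model="H0"`` collapses it to a single p.
    """
    use_h1 = year1_model == "H1"

    def joint_neg(theta: np.ndarray, null: bool) -> float:
        v = np.clip(_expit(theta), P_FLOOR, 1.0 - P_FLOOR)
        if null:
            if use_h1:
                p_share, p_M13 = v
            else:
                (p_share,) = v
                p_M13 = p_share
            return -(
                data_year1.loglik(p_share, p_M13)
                + data_year2.loglik(p_share, p_share, p_share)
            )
        if use_h1:
            p_A13, p_M13, p_Z = v
        else:
            p_A13, p_Z = v
            p_M13 = p_A13
        return -(
            data_year1.loglik(p_A13, p_M13) + data_year2.loglik(p_Z, p_Z, p_Z)
        )

    def optimize(n: int, null: bool):
        x0 = np.full(n, _logit(np.clip(data_year1.p, 0.02, 0.98)))
        best = minimize(lambda t: joint_neg(t, null), x0, method="Powell",
                        options={"ftol": tol, "xtol": 1e-7})
        for alt0 in (0.25, 0.75):
            if best.success:
                break
            best = minimize(lambda t: joint_neg(t, null), np.full(n, _logit(alt0)),
                            method="Powell", options={"ftol": tol, "xtol": 1e-7})
        return best

    n_null = 2 if use_h1 else 1
    res0 = optimize(n_null, null=True)
    res1 = optimize(n_null + 1, null=False)
    v0 = np.clip(_expit(np.atleast_1d(res0.x)), P_FLOOR, 1.0 - P_FLOOR)
    v1 = np.clip(_expit(np.atleast_1d(res1.x)), P_FLOOR, 1.0 - P_FLOOR)
    if use_h1:
        null_est = {"p_share": float(v0[0]), "p_M13": float(v0[1])}
        alt_est = {"p_A13": float(v1[0]), "p_M13": float(v1[1]), "p_Z14": float(v1[2])}
    else:
        null_est = {"p_share": float(v0[0])}
        alt_est = {"p_A13": float(v1[0]), "p_Z14": float(v1[1])}
    null_spec = ModelSpec("change_null", tuple(null_est), {"A": "p_share", "M": "p_share", "L": "p_share"})
    alt_spec = ModelSpec("change_alt", tuple(alt_est), {"A": "p_A13", "M": "p_M13" if use_h1 else "p_A13", "L": "p_Z14"})
    null_fit = FitResult(null_spec, null_est, -float(res0.fun), n_null, bool(res0.success))
    alt_fit = FitResult(alt_spec, alt_est, -float(res1.fun), n_null + 1, bool(res1.success))
    stat = max(0.0, 2.0 * (alt_fit.lnL - null_fit.lnL))
    p = max(float(chi2.sf(stat, 1)), PVAL_FLOOR)
    return ChangeTestResult(
        lrt=LRTResult(stat, 1, p),
        null_fit=null_fit,
        alt_fit=alt_fit,
        p_A_year1=alt_est["p_A13"],
        p_Z_year2=alt_est["p_Z14"],
    )
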