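"""Molecular summaries in windows around focal SNPs: S, pi, Tajima's D, Zns.

Windows are 100 bp of flanking sequence on each side of a focal SNP, with
the focal site itself excluded from S, pi and Tajima's D.  The panel of
phased reference sequences serves as the population sample.  Zns (the mean
squared allele-frequency correlation r^2 over all flanking site pairs)
summarizes haplotype structure; Z_focal restricts one member of each pair
to the focal SNP.  Balancing selection is expected to elevate all of these
relative to windows around SNPs with no evidence of selection.

pi uses the unbiased n/(n-1) sample correction; sites with more than two
alleles in the window sample are excluded throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "SequenceWindow",
    "WindowStats",
    "window_from_alignment",
    "window_stats",
    "r2",
    "tajimas_d",
    "contrast_windows",
    "control_set",
]

METRICS = ("S", "pi", "tajD", "zns", "z_focal")


@dataclass
class SequenceWindow:
    """Phased panel sequences around one focal SNP.

    ``flank`` is a (n, S) 0/1 matrix over the biallelic polymorphic flanking
    sites (focal excluded); ``focal`` the (n,) allele vector at the focal
    site itself.
    """

    focal_snp: str
    flank: np.ndarray
    focal: np.ndarray

    @property
    def n(self) -> int:
        return self.flank.shape[0]


@dataclass
class WindowStats:
    S: int
    pi: float
    tajD: float
    zns: float
    z_focal: float


def window_from_alignment(
    alignment: np.ndarray, focal_col: int, focal_id: str = "focal"
) -> SequenceWindow:
    """Extract a window from an (n, L) integer-coded alignment.

    Flanking columns that are monomorphic or carry more than two alleles in
    the sample are dropped; the remaining sites are recoded 0/1 (0 = the
    allele of the first sequence).
    """
    A = np.asarray(alignment)
    n, L = A.shape
    if n < 4:
        raise ValueError("need at least 4 sequences")
    cols = []
    for j in range(L):
        if j == focal_col:
            continue
        u = np.unique(A[:, j])
        if u.size == 2:
            cols.append((A[:, j] != A[0, j]).astype(np.int8))
    flank = np.column_stack(cols) if cols else np.zeros((n, 0), dtype=np.int8)
    focal = (A[:, focal_col] != A[0, focal_col]).astype(np.int8)
    return SequenceWindow(focal_snp=focal_id, flank=flank, focal=focal)


def r2(site_a: np.ndarray, site_b: np.ndarray) -> float:
    """Squared allele-frequency correlation between two biallelic sites.

    Computed from phased haplotype counts: r^2 = (p_AB - p_A p_B)^2 /
    (p_A(1-p_A) p_B(1-p_B)).  Undefined (ValueError) if a site is
    monomorphic in the sample.
    """
    a = np.asarray(site_a, dtype=float)
    b = np.asarray(site_b, dtype=float)
    pA, pB = a.mean(), b.mean()
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        raise ValueError("monomorphic site: r^2 undefined")
    pAB = (a * b).mean()
    return float((pAB - pA * pB) ** 2 / (pA * (1 - pA) * pB * (1 - pB)))


def tajimas_d(S: int, pi: float, n: int) -> float:
    """Tajima's D from the segregating-site count, mean pairwise diversity and n."""
    if S == 0:
        return float("nan")
    i = np.arange(1, n)
    a1 = (1.0 / i).sum()
    a2 = (1.0 / i**2).sum()
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    return float((pi - S / a1) / np.sqrt(var))


def window_stats(window: SequenceWindow) -> WindowStats:
    """All window summaries; undefined entries are NaN (S=0 -> no D, S<2 -> no Zns)."""
    flank = window.flank
    n, S = flank.shape
    freq = flank.mean(axis=0) if S else np.zeros(0)
    # unbiased mean pairwise differences, summed over sites
    pi = float((2.0 * freq * (1.0 - freq) * n / (n - 1)).sum())
    tajD = tajimas_d(S, pi, n)
    if S >= 2:
        vals = [r2(flank[:, a], flank[:, b]) for a in range(S) for b in range(a + 1, S)]
        zns = float(np.mean(vals))
    else:
        zns = float("nan")
    focal_poly = 0 < window.focal.mean() < 1
    if S >= 1 and focal_poly:
        z_focal = float(np.mean([r2(window.focal, flank[:, a]) for a in range(S)]))
    else:
        z_focal = float("nan")
    return WindowStats(S=S, pi=pi, tajD=tajD, zns=zns, z_focal=z_focal)


def contrast_windows(
    selected: list[WindowStats], control: list[WindowStats]
) -> dict[str, tuple[float, float]]:
    """One-way ANOVA per metric between selected-SNP and control windows.

    Missing (NaN) values are dropped per metric; a metric with fewer than
    two non-missing values in either group is skipped.
    """
    if not selected or not control:
        raise ValueError("both groups must be non-empty")
    out: dict[str, tuple[float, float]] = {}
    for metric in METRICS:
        a = np.array([getattr(w, metric) for w in selected], dtype=float)
        b = np.array([getattr(w, metric) for w in control], dtype=float)
        a, b = a[~np.isnan(a)], b[~np.isnan(b)]
        if a.size < 2 or b.size < 2:
            logger.warning("metric %s skipped: fewer than 2 non-missing values", metric)
            continue
        F, p = stats.f_oneway(a, b)
        out[metric] = (float(F), float(p))
    return out


def control_set(
    tested_snps: pd.DataFrame,
    n_control: int,
    seed: int,
    cutoff: float = 0.1,
    p_col: str = "p_value",
) -> pd.DataFrame:
    """Seeded sample of non-significant SNPs (p > cutoff), one per gene set."""
    eligible = tested_snps[tested_snps[p_col] > cutoff]
    eligible = eligible.sort_values([p_col, "pos"], kind="stable").groupby("set_id", sort=False).head(1)
    if len(eligible) == 0:
        logger.warning("no eligible control SNPs (all significant)")
        return eligible.reset_index(drop=True)
    if len(eligible) < n_control:
        logger.warning("only %d eligible control SNPs (< %d requested)", len(eligible), n_control)
        return eligible.reset_index(drop=True)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(eligible), size=n_control, replace=False)
    return eligible.iloc[np.sort(idx)].reset_index(drop=True)
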