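"""Population-genetic statistics on genotype panels.

Implements the estimators the synthesis pipeline reports:

* observed/expected/unbiased heterozygosity per sampling location;
* the Weir & Cockerham (1984) variance-components F_ST estimator (theta),
  per locus and multi-locus as a ratio of sums;
* the exact conditional Hardy–Weinberg test (enumeration of heterozygote
  counts given allele counts);
* Benjamini–Hochberg FDR adjustment (via statsmodels);
* a permutation Mantel test on Rousset-linearized F_ST, F_ST/(1-F_ST),
  against geographic distance (isolation by distance);
* Welch's unequal-variance t test (via scipy);
* upper-quantile outlier locus sets.

Negative theta values are reported as-is — the estimator is unbiased around
zero for undifferentiated samples and clamping would bias replicate screens.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .panel import MISSING, DistanceMatrix, GenotypePanel, PanelError

__all__ = [
    "HetSummary",
    "PerLocusFst",
    "PairwiseFstResult",
    "MantelResult",
    "heterozygosity",
    "wc_theta_per_locus",
    "wc_components",
    "pairwise_fst",
    "fst_matrix",
    "hwe_exact_test",
    "bh_fdr",
    "mantel_ibd",
    "welch_t",
    "upper_quantile_loci",
]


# ---------------------------------------------------------------------- results
@dataclass
class HetSummary:
    """Per-locus and mean heterozygosity for one sampling location."""

    location_code: str
    locus_ids: list[str]
    ho: np.ndarray          # observed het fraction per locus (NaN if no calls)
    he: np.ndarray          # expected het 1 - sum p_i^2
    uhe: np.ndarray         # unbiased He = He * 2n/(2n-1)
    n_called: np.ndarray
    n_zero_call_loci: int = 0

    @property
    def mean_ho(self) -> float:
        return float(np.nanmean(self.ho)) if np.isfinite(self.ho).any() else float("nan")

    @property
    def mean_he(self) -> float:
        return float(np.nanmean(self.he)) if np.isfinite(self.he).any() else float("nan")

    @property
    def mean_uhe(self) -> float:
        return float(np.nanmean(self.uhe)) if np.isfinite(self.uhe).any() else float("nan")


@dataclass(frozen=True)
class PerLocusFst:
    """Weir–Cockerham variance components and theta for one locus."""

    locus_id: str
    a: float   # among populations
    b: float   # among individuals within populations
    c: float   # within individuals
    theta: float | None  # None = UNDEFINED (a+b+c == 0)

    @property
    def defined(self) -> bool:
        return self.theta is not None


@dataclass
class PairwiseFstResult:
    """Multi-locus theta (ratio of sums over defined loci) for a sample pair."""

    pair: tuple[str, str]
    theta: float | None
    per_locus: list[PerLocusFst]

    @property
    def n_defined(self) -> int:
        return sum(1 for pl in self.per_locus if pl.defined)


@dataclass(frozen=True)
class MantelResult:
    r: float
    p: float
    n_permutations: int
    seed: int | None
    linearized: bool
    exact: bool = False
    alternative: str = "greater"


# ----------------------------------------------------------------- heterozygosity
def heterozygosity(panel: GenotypePanel, location_code: str) -> HetSummary:
    """Ho, He and unbiased He per locus for one sampling location.

    Ho = n_het / n_called; He = 1 - p^2 - q^2 = 2pq; uHe = He * 2n/(2n-1).
    Loci with zero calls are excluded from means and counted in the summary.
    """
    rows = panel.rows_for(location_code)
    if rows.size == 0:
        raise PanelError(f"unknown location {location_code!r}")
    sub = panel.dosages[rows, :]
    called = sub != MISSING
    n = called.sum(axis=0).astype(float)
    n_het = (sub == 1).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, np.where(called, sub, 0).sum(axis=0) / (2 * n), np.nan)
        ho = np.where(n > 0, n_het / n, np.nan)
        he = 2 * p * (1 - p)
        uhe = np.where(n > 0, he * (2 * n) / (2 * n - 1), np.nan)
    return HetSummary(
        location_code=location_code,
        locus_ids=panel.locus_ids,
        ho=ho,
        he=he,
        uhe=uhe,
        n_called=n.astype(int),
        n_zero_call_loci=int((n == 0).sum()),
    )


# --------------------------------------------------------- Weir–Cockerham theta
def wc_components(
    counts: Sequence[tuple[np.ndarray, np.ndarray, np.ndarray]],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Weir & Cockerham (1984) components a, b, c over loci.

    ``counts`` holds, per population, arrays of genotype counts
    (hom-designated, het, hom-other).  Populations with zero called
    individuals at a locus drop out of that locus' computation.  Entries where
    fewer than two populations remain, or where every remaining individual
    count is 1 (n_bar == 1), come back NaN in all three components.
    """
    if len(counts) < 2:
        raise PanelError("theta needs at least two populations")
    n2 = np.vstack([np.atleast_1d(np.asarray(c[0], float)) for c in counts])
    n1 = np.vstack([np.atleast_1d(np.asarray(c[1], float)) for c in counts])
    n0 = np.vstack([np.atleast_1d(np.asarray(c[2], float)) for c in counts])
    n = n2 + n1 + n0                       # individuals per pop per locus
    present = n > 0
    r = present.sum(axis=0).astype(float)  # populations observed per locus

    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(present, (2 * n2 + n1) / (2 * n), 0.0)
        h = np.where(present, n1 / n, 0.0)

        n_tot = n.sum(axis=0)
        nbar = n_tot / r
        nc = (n_tot - (n**2).sum(axis=0) / n_tot) / (r - 1)
        pbar = (n * p).sum(axis=0) / n_tot
        s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n * h).sum(axis=0) / n_tot

        inner = pbar * (1 - pbar) - ((r - 1) / r) * s2
        a = (nbar / nc) * (s2 - (inner - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (inner - ((2 * nbar - 1) / (4 * nbar)) * hbar)
        c = hbar / 2

    invalid = (r < 2) | (nbar <= 1) | ~np.isfinite(a)
    a = np.where(invalid, np.nan, a)
    b = np.where(invalid, np.nan, b)
    c = np.where(invalid, np.nan, c)
    return a, b, c


def wc_theta_per_locus(
    counts: Sequence[tuple[int, int, int]], locus_id: str = ""
) -> PerLocusFst:
    """Theta for one locus from per-population genotype counts.

    ``counts[i] = (hom-designated, het, hom-other)`` for population i.
    theta = a/(a+b+c), UNDEFINED when the denominator is zero (all
    populations monomorphic for the same allele).
    """
    arrs = [(np.array([c[0]]), np.array([c[1]]), np.array([c[2]])) for c in counts]
    a, b, c = wc_components(arrs)
    a_, b_, c_ = float(a[0]), float(b[0]), float(c[0])
    denom = a_ + b_ + c_
    if not math.isfinite(denom) or denom == 0.0:
        return PerLocusFst(locus_id, a_, b_, c_, None)
    return PerLocusFst(locus_id, a_, b_, c_, a_ / denom)


def _pair_fst(
    counts_a: tuple[np.ndarray, np.ndarray, np.ndarray],
    counts_b: tuple[np.ndarray, np.ndarray, np.ndarray],
    locus_ids: Sequence[str],
) -> PairwiseFstResult:
    a, b, c = wc_components([counts_a, counts_b])
    denom = a + b + c
    defined = np.isfinite(denom) & (denom != 0.0)
    per_locus = [
        PerLocusFst(
            lid,
            float(a[j]),
            float(b[j]),
            float(c[j]),
            float(a[j] / denom[j]) if defined[j] else None,
        )
        for j, lid in enumerate(locus_ids)
    ]
    if defined.any():
        theta = float(a[defined].sum() / denom[defined].sum())
    else:
        theta = None
    return PairwiseFstResult(pair=("", ""), theta=theta, per_locus=per_locus)


def pairwise_fst(panel: GenotypePanel) -> dict[tuple[str, str], PairwiseFstResult]:
    """Multi-locus WC theta between every pair of sampling locations.

    The multi-locus estimate is the ratio of summed components (sum a over
    sum a+b+c), not a mean of per-locus ratios; UNDEFINED loci are excluded
    from both sums.  A pair with no defined locus comes back with theta None.
    """
    locs = panel.locations
    if len(locs) < 2:
        raise PanelError("pairwise FST needs at least two locations")
    counts = panel.counts_by_location()
    out: dict[tuple[str, str], PairwiseFstResult] = {}
    for la, lb in itertools.combinations(locs, 2):
        res = _pair_fst(counts[la], counts[lb], panel.locus_ids)
        res.pair = (la, lb)
        out[(la, lb)] = res
    return out


def fst_matrix(results: Mapping[tuple[str, str], PairwiseFstResult]) -> tuple[tuple[str, ...], np.ndarray]:
    """Square symmetric multi-locus theta matrix (diagonal 0 by convention)."""
    labels: list[str] = []
    for a, b in results:
        for x in (a, b):
            if x not in labels:
                labels.append(x)
    m = np.zeros((len(labels), len(labels)))
    for (a, b), res in results.items():
        i, j = labels.index(a), labels.index(b)
        m[i, j] = m[j, i] = np.nan if res.theta is None else res.theta
    return tuple(labels), m


# ----------------------------------------------------------------- HWE exact test
@lru_cache(maxsize=65536)
def _hwe_tail(n: int, n_a: int, obs_het: int) -> float:
    """Exact conditional HWE p: mass of het counts no more probable than obs."""
    n_b = 2 * n - n_a
    rare = min(n_a, n_b)
    if rare == 0:
        return 1.0
    log_denom = gammaln(2 * n + 1) - gammaln(n_a + 1) - gammaln(n_b + 1)

    hets = np.arange(rare % 2, rare + 1, 2)
    homs_a = (n_a - hets) // 2
    homs_b = (n_b - hets) // 2
    logp = (
        gammaln(n + 1)
        - gammaln(homs_a + 1)
        - gammaln(hets + 1)
        - gammaln(homs_b + 1)
        + hets * math.log(2.0)
        - log_denom
    )
    probs = np.exp(logp)
    probs /= probs.sum()  # guard rounding; exact distribution sums to 1
    p_obs = probs[np.nonzero(hets == obs_het)[0][0]]
    return float(probs[probs <= p_obs * (1 + 1e-12)].sum())


def hwe_exact_test(n_hom_a: int, n_het: int, n_hom_b: int) -> float:
    """Exact conditional test of Hardy–Weinberg proportions.

    p = sum, over heterozygote counts whose conditional probability (given
    the allele counts) does not exceed that of the observed count, of that
    conditional distribution.  Monomorphic samples give p = 1 by convention.
    """
    n = n_hom_a + n_het + n_hom_b
    if n < 1 or min(n_hom_a, n_het, n_hom_b) < 0:
        raise ValueError("genotype counts must be nonnegative with n >= 1")
    n_a = 2 * n_hom_a + n_het
    return min(1.0, _hwe_tail(n, n_a, n_het))


# ------------------------------------------------------------------------- FDR
def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values with pi0 = 1)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ------------------------------------------------------------------ Mantel test
def _upper(m: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc @ yc) / math.sqrt((xc @ xc) * (yc @ yc)))


def mantel_ibd(
    fst: DistanceMatrix | np.ndarray,
    distances: DistanceMatrix | np.ndarray,
    n_permutations: int = 9999,
    seed: int | None = None,
    linearize: bool = True,
    alternative: str = "greater",
) -> MantelResult:
    """Mantel test of F_ST (optionally F_ST/(1-F_ST)) against distance.

    r is the Pearson correlation of the upper-triangle vectors; p comes from
    jointly permuting rows and columns of the distance matrix, with the +1
    correction (p is never exactly 0 and never below 1/(B+1)).  When the
    requested permutation count covers the full permutation group of the
    labels, the test switches to exhaustive enumeration (identity included),
    which the sampled +1-corrected p equals by construction.

    One-tailed 'greater' is the default because isolation by distance
    predicts a positive correlation; 'two-sided' is available.
    """
    if isinstance(fst, DistanceMatrix) and isinstance(distances, DistanceMatrix):
        if fst.labels != distances.labels:
            raise PanelError("FST and distance matrices must share labels and order")
    f = fst.values if isinstance(fst, DistanceMatrix) else np.asarray(fst, float)
    d = (
        distances.values
        if isinstance(distances, DistanceMatrix)
        else np.asarray(distances, float)
    )
    if f.shape != d.shape or f.shape[0] != f.shape[1]:
        raise PanelError("matrices must be square and of equal shape")
    n = f.shape[0]
    if n < 3:
        raise PanelError("Mantel test needs at least 3 labels")
    if linearize:
        if np.nanmax(_upper(f)) >= 1.0:
            raise ValueError("cannot linearize: F_ST >= 1 encountered")
        f = f / (1.0 - f)
    x = _upper(f)
    if np.isnan(x).any() or np.isnan(_upper(d)).any():
        raise PanelError("undefined entries in Mantel input matrices")
    y0 = _upper(d)
    if x.std() == 0 or y0.std() == 0:
        raise ValueError("degenerate Mantel input: zero variance in a matrix")

    r_obs = _pearson(x, y0)
    eps = 1e-12

    def extreme(r_perm: float) -> bool:
        if alternative == "greater":
            return r_perm >= r_obs - eps
        if alternative == "two-sided":
            return abs(r_perm) >= abs(r_obs) - eps
        raise ValueError(f"unknown alternative {alternative!r}")

    n_group = math.factorial(n)
    if n_permutations >= n_group - 1 and n <= 8:
        count = 0
        for perm in itertools.permutations(range(n)):
            dp = d[np.ix_(perm, perm)]
            if extreme(_pearson(x, _upper(dp))):
                count += 1
        return MantelResult(
            r=r_obs,
            p=count / n_group,
            n_permutations=n_group,
            seed=seed,
            linearized=linearize,
            exact=True,
            alternative=alternative,
        )

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        dp = d[np.ix_(perm, perm)]
        if extreme(_pearson(x, _upper(dp))):
            count += 1
    return MantelResult(
        r=r_obs,
        p=(1 + count) / (1 + n_permutations),
        n_permutations=n_permutations,
        seed=seed,
        linearized=linearize,
        exact=False,
        alternative=alternative,
    )


# --------------------------------------------------------------------- Welch t
def welch_t(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float, float]:
    """Welch's unequal-variance t test: (t, Satterthwaite df, two-sided p)."""
    a = np.asarray(list(group_a), float)
    b = np.asarray(list(group_b), float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            raise ValueError("Welch t undefined: zero variance and equal means")
    res = sps.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


# ----------------------------------------------------------- outlier quantiles
def upper_quantile_loci(
    per_locus_theta: Mapping[str, float | None], quantile: float = 0.95
) -> set[str]:
    """Loci at or above the empirical quantile of defined theta values.

    The quantile uses linear interpolation between order statistics and the
    cut is >=-inclusive, so complete ties return every locus.  Loci with
    UNDEFINED theta are excluded from the quantile population.
    """
    defined = {lid: t for lid, t in per_locus_theta.items() if t is not None}
    if not defined:
        raise ValueError("no defined theta values")
    cut = float(np.quantile(np.fromiter(defined.values(), float), quantile, method="linear"))
    return {lid for lid, t in defined.items() if t >= cut}
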