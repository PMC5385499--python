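"""Moment-based gene-flow and effective-population-size estimators.

Three classical single-timepoint estimators:

* ``nem_wright`` -- effective migrant number from F_ST.  The primary form
  is N_e m = (1/F_ST) - 1; the textbook island-model rearrangement
  N_e m = (1 - F_ST)/(4 F_ST) is available behind a flag since published
  analyses vary in which they quote.
* ``nem_private`` -- Barton & Slatkin's private-alleles method: the mean
  frequency of alleles observed in a single population, p(1), is related
  to N_e m through log-linear regressions calibrated by simulation at
  reference sample sizes 10, 25 and 50; coefficients are interpolated
  log-linearly to the data's mean sample size.
* ``ld_ne`` -- contemporary N_e from the mean squared allelic correlation
  (Burrows' composite measure over unordered genotypes) across all pairs
  of loci, with the Waples (2006) sample-size bias correction and the
  Waples & Do (2008) conversion to N_e.  Negative drift signal maps to an
  infinite estimate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

from .genodata import MISSING, GenotypeTable

# ln p(1) = a + b ln(Nem) regression coefficients at reference sample sizes
# (private-alleles calibration of Barton & Slatkin 1986)
_BS_COEFFS = {
    10: (-2.440, -0.505),
    25: (-2.949, -0.576),
    50: (-3.554, -0.612),
}


@dataclass
class GeneFlowEstimate:
    method: str
    nem: float  # may be math.inf
    inputs: dict


def nem_wright(fst: float, island_form: bool = False) -> GeneFlowEstimate:
    """Effective migrant number from F_ST.

    Default: N_e m = (1/F_ST) - 1.  With ``island_form=True``:
    N_e m = (1 - F_ST)/(4 F_ST).  F_ST <= 0 flags infinite gene flow.
    """
    if fst > 1:
        raise ValueError("F_ST cannot exceed 1")
    if fst <= 0:
        return GeneFlowEstimate("wright_fst", math.inf, {"fst": fst})
    nem = (1.0 - fst) / (4.0 * fst) if island_form else (1.0 / fst) - 1.0
    return GeneFlowEstimate(
        "wright_fst", nem, {"fst": fst, "island_form": island_form}
    )


def _bs_interp_coeffs(mean_n: float) -> tuple[float, float]:
    """Log-linear interpolation of the private-allele regression
    coefficients to an arbitrary mean sample size."""
    sizes = sorted(_BS_COEFFS)
    ln_n = math.log(mean_n)
    if mean_n <= sizes[0]:
        lo, hi = sizes[0], sizes[1]
    elif mean_n >= sizes[-1]:
        lo, hi = sizes[-2], sizes[-1]
    else:
        lo = max(s for s in sizes if s <= mean_n)
        hi = min(s for s in sizes if s >= mean_n)
        if lo == hi:
            return _BS_COEFFS[lo]
    (a0, b0), (a1, b1) = _BS_COEFFS[lo], _BS_COEFFS[hi]
    w = (ln_n - math.log(lo)) / (math.log(hi) - math.log(lo))
    return a0 + w * (a1 - a0), b0 + w * (b1 - b0)


def mean_private_allele_freq(table: GenotypeTable) -> tuple[float, float, int]:
    """Mean within-site frequency of private alleles, the mean per-site
    sample size (individuals), and the number of private alleles."""
    sites = table.site_ids()
    if len(sites) < 2:
        raise ValueError("need at least two sites")
    freqs = []
    n_scored = []
    for j in range(table.n_loci):
        seen: dict[int, list[str]] = {}
        for s in sites:
            for a in table.allele_counts(j, table.site_indices(s)):
                seen.setdefault(a, []).append(s)
        for a, where in seen.items():
            if len(where) == 1:
                s = where[0]
                f = table.allele_freqs(j, table.site_indices(s))[a]
                freqs.append(f)
    for s in sites:
        idx = table.site_indices(s)
        scored = (table.calls[idx, :, 0] != MISSING).sum(axis=0)
        n_scored.append(float(np.mean(scored)))
    return (
        float(np.mean(freqs)) if freqs else 0.0,
        float(np.mean(n_scored)),
        len(freqs),
    )


def nem_private(table: GenotypeTable) -> GeneFlowEstimate:
    """Barton-Slatkin private-alleles estimate of N_e m."""
    p1, mean_n, k = mean_private_allele_freq(table)
    if k == 0 or p1 <= 0:
        return GeneFlowEstimate(
            "private_alleles", math.inf, {"p1": p1, "mean_n": mean_n, "n_private": k}
        )
    a, b = _bs_interp_coeffs(mean_n)
    nem = math.exp((math.log(p1) - a) / b)
    return GeneFlowEstimate(
        "private_alleles", nem, {"p1": p1, "mean_n": mean_n, "n_private": k}
    )


# ---------------------------------------------------------------------------
# LD effective population size
# ---------------------------------------------------------------------------

@dataclass
class NeEstimate:
    ne: float  # math.inf when the drift signal is non-positive
    ci: tuple[float, float]
    r2_mean: float
    r2_expected: float
    r2_drift: float
    mean_n: float
    n_comparisons: int
    freq_cutoff: float


def _expected_r2(n: float) -> float:
    """E[r^2] under random mating for sample size n (Waples 2006)."""
    if n >= 30:
        return 1.0 / n + 3.19 / n**2
    return 0.0018 + 0.907 / n + 4.44 / n**2


def _ne_from_drift(r2d: float, n: float) -> float:
    """Waples & Do (2008) conversion of the drift component of r^2."""
    if r2d <= 0:
        return math.inf
    if n >= 30:
        disc = 1.0 / 9.0 - 2.76 * r2d
        if disc < 0:
            disc = 0.0
        return (1.0 / 3.0 + math.sqrt(disc)) / (2.0 * r2d)
    disc = 0.308**2 - 2.08 * r2d
    if disc < 0:
        disc = 0.0
    return (0.308 + math.sqrt(disc)) / (2.0 * r2d)


def ld_ne(calls: np.ndarray, freq_cutoff: float = 0.02) -> NeEstimate:
    """Contemporary N_e from linkage disequilibrium in one sample.

    ``calls``: (n_individuals, n_loci, 2) allele sizes with (0,0) missing.
    Alleles below ``freq_cutoff`` are excluded.  The statistic averages
    the squared Burrows composite correlation over every allele pair of
    every locus pair; the bias-corrected drift component is converted to
    N_e.  The CI is parametric (chi-square on the number of comparisons).
    """
    calls = np.asarray(calls)
    n_ind, n_loci, _ = calls.shape
    if n_ind < 10:
        warnings.warn(f"LD-Ne from only {n_ind} individuals is unreliable")

    # per-locus retained alleles and dosage matrices
    dosages: list[np.ndarray] = []  # (n_ind, k_alleles), nan where unscored
    for j in range(n_loci):
        col = calls[:, j, :]
        scored = col[:, 0] != MISSING
        genes = col[scored].ravel()
        if genes.size == 0:
            dosages.append(np.empty((n_ind, 0)))
            continue
        vals, cnts = np.unique(genes, return_counts=True)
        keep = vals[(cnts / cnts.sum()) >= freq_cutoff]
        if len(np.unique(genes)) < 2 or len(keep) < 1:
            dosages.append(np.empty((n_ind, 0)))
            continue
        d = np.full((n_ind, len(keep)), np.nan)
        for k, a in enumerate(keep):
            d[scored, k] = (col[scored] == a).sum(axis=1)
        dosages.append(d)

    usable = [j for j in range(n_loci) if dosages[j].shape[1] >= 1 and
              np.nanstd(dosages[j]) > 0]
    if len(usable) < 2:
        raise ValueError("need at least 2 usable polymorphic loci")

    r2_vals = []
    n_vals = []
    for j1, j2 in combinations(usable, 2):
        d1, d2 = dosages[j1], dosages[j2]
        both = ~np.isnan(d1[:, 0]) & ~np.isnan(d2[:, 0])
        n = int(both.sum())
        if n < 2:
            continue
        x_all, y_all = d1[both], d2[both]
        for k1 in range(x_all.shape[1]):
            x = x_all[:, k1]
            pa = x.mean() / 2.0
            if not 0 < pa < 1:
                continue
            for k2 in range(y_all.shape[1]):
                y = y_all[:, k2]
                pb = y.mean() / 2.0
                if not 0 < pb < 1:
                    continue
                delta = (n / (n - 1)) * (np.mean(x * y) / 2.0 - 2.0 * pa * pb)
                denom = pa * (1 - pa) * pb * (1 - pb)
                r2_vals.append(delta**2 / denom)
                n_vals.append(n)
    if not r2_vals:
        raise ValueError("no allele-pair comparisons available")

    r2_mean = float(np.mean(r2_vals))
    mean_n = float(np.mean(n_vals))
    exp_r2 = _expected_r2(mean_n)
    r2_drift = r2_mean - exp_r2
    ne = _ne_from_drift(r2_drift, mean_n)

    df = len(r2_vals)
    lo_r2 = r2_mean * df / stats.chi2.ppf(0.975, df)
    hi_r2 = r2_mean * df / stats.chi2.ppf(0.025, df)
    ci = (
        _ne_from_drift(hi_r2 - exp_r2, mean_n),
        _ne_from_drift(lo_r2 - exp_r2, mean_n),
    )
    ci = (min(ci), max(ci))
    return NeEstimate(ne, ci, r2_mean, exp_r2, r2_drift, mean_n, df, freq_cutoff)
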