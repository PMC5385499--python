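"""Per-site diversity statistics and exact Hardy-Weinberg testing.

Implements observed/unbiased expected heterozygosity, the exact HWE
probability test with Markov-chain Monte Carlo p-values, Weir & Cockerham's
inbreeding coefficient f (F_IS), rarefied allelic richness, private-allele
counts, Bonferroni adjustment over the full locus x site test family, and a
one-way ANOVA comparing diversity between fished and unfished groups of
sites.

The exact-test chain operates on the vector of 2n gene copies: swapping two
uniformly chosen gene positions is a symmetric proposal whose stationary
distribution over genotype tables is exactly the Levene conditional
distribution given the allele counts, so every proposal is accepted.  The
p-value is the chain-average probability of visiting a table no more
probable than the observed one, with a batch-means standard error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .genodata import MISSING, GenotypeTable


# ---------------------------------------------------------------------------
# heterozygosity
# ---------------------------------------------------------------------------

def heterozygosity(calls: np.ndarray) -> tuple[float, float]:
    """Observed and unbiased expected heterozygosity for one site x locus.

    ``calls`` is an (n, 2) array of allele sizes (missing rows excluded or
    coded (0,0)).  He carries the small-sample correction
    ``(2n/(2n-1)) * (1 - sum p_i^2)``.
    """
    calls = np.asarray(calls)
    scored = calls[calls[:, 0] != MISSING]
    n = len(scored)
    if n == 0:
        return (math.nan, math.nan)
    ho = float(np.mean(scored[:, 0] != scored[:, 1]))
    _, counts = np.unique(scored.ravel(), return_counts=True)
    p = counts / counts.sum()
    he = 1.0 - float(np.sum(p**2))
    if n > 0:
        he *= (2 * n) / (2 * n - 1)
    return ho, he


# ---------------------------------------------------------------------------
# exact HWE test
# ---------------------------------------------------------------------------

@dataclass
class HweResult:
    p_value: float
    se: float
    direction: str  # "deficit" | "excess"
    iterations: int
    dememorization: int


def _table_logprob_terms(pairs: np.ndarray) -> tuple[int, float]:
    """Heterozygote count and sum of log(genotype-cell factorials)."""
    het = int(np.sum(pairs[:, 0] != pairs[:, 1]))
    _, counts = np.unique(pairs, axis=0, return_counts=True)
    logfact = float(np.sum(gammaln(counts + 1)))
    return het, logfact


def exact_hwe(
    calls: np.ndarray,
    iterations: int = 10_000,
    dememorization: int = 1_000,
    seed: int | np.random.Generator = 0,
) -> HweResult:
    """Exact HWE probability test with a Markov-chain p-value.

    The test conditions on the observed allele counts; the p-value is the
    probability of genotype tables no more probable than the observed one
    under the Levene distribution.  Raises on monomorphic or n < 2 input.
    """
    calls = np.asarray(calls)
    scored = np.sort(calls[calls[:, 0] != MISSING], axis=1)
    n = len(scored)
    if n < 2:
        raise ValueError("need at least 2 scored individuals")
    if len(np.unique(scored.ravel())) < 2:
        raise ValueError("monomorphic locus: HWE test undefined")

    ho, he = heterozygosity(scored)
    direction = "deficit" if ho < he else "excess"

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    genes = scored.ravel().copy()  # 2n gene copies; pairs are (2i, 2i+1)
    m = len(genes)

    def rel_logprob(g: np.ndarray) -> float:
        pairs = np.sort(g.reshape(-1, 2), axis=1)
        het, logfact = _table_logprob_terms(pairs)
        return het * math.log(2.0) - logfact

    obs_lp = rel_logprob(genes)

    # vectorised swap schedule; recompute log-prob incrementally per step
    total = dememorization + iterations
    picks = rng.integers(0, m, size=(total, 2))
    cur_lp = obs_lp

    def pair_of(pos: int) -> tuple[int, int]:
        i = pos // 2
        a, b = genes[2 * i], genes[2 * i + 1]
        return (a, b) if a <= b else (b, a)

    from collections import Counter

    counts = Counter(tuple(p) for p in np.sort(genes.reshape(-1, 2), axis=1))
    het_count = sum(c for (a, b), c in counts.items() if a != b)
    logfact_sum = sum(gammaln(c + 1) for c in counts.values())

    hits = np.empty(iterations, dtype=np.float64)
    for t in range(total):
        p, q = picks[t]
        if p // 2 != q // 2 and genes[p] != genes[q]:
            old_i, old_j = pair_of(p), pair_of(q)
            genes[p], genes[q] = genes[q], genes[p]
            new_i, new_j = pair_of(p), pair_of(q)
            for old, new in ((old_i, new_i), (old_j, new_j)):
                if old == new:
                    continue
                c = counts[old]
                logfact_sum -= gammaln(c + 1) - gammaln(c)
                counts[old] = c - 1
                if counts[old] == 0:
                    del counts[old]
                c = counts.get(new, 0)
                logfact_sum += gammaln(c + 2) - gammaln(c + 1)
                counts[new] = c + 1
                het_count += int(new[0] != new[1]) - int(old[0] != old[1])
            cur_lp = het_count * math.log(2.0) - logfact_sum
        if t >= dememorization:
            hits[t - dememorization] = cur_lp <= obs_lp + 1e-9

    p_value = float(hits.mean())
    # batch-means SE to respect chain autocorrelation
    n_batch = 20
    usable = (iterations // n_batch) * n_batch
    batches = hits[:usable].reshape(n_batch, -1).mean(axis=1)
    se = float(batches.std(ddof=1) / math.sqrt(n_batch))
    return HweResult(p_value, se, direction, iterations, dememorization)


def hwe_enumeration_2allele(calls: np.ndarray) -> float:
    """Full-enumeration exact p-value for a biallelic locus.

    Sums the Levene probabilities of all heterozygote counts compatible
    with the observed allele counts that are no more probable than the
    observed configuration.  Serves as the closed-form reference for the
    Markov-chain test.
    """
    calls = np.asarray(calls)
    scored = np.sort(calls[calls[:, 0] != MISSING], axis=1)
    alleles = np.unique(scored.ravel())
    if len(alleles) != 2:
        raise ValueError("enumeration reference requires exactly 2 alleles")
    a = alleles[0]
    n = len(scored)
    n_a = int(np.sum(scored == a))
    n_b = 2 * n - n_a
    h_obs = int(np.sum(scored[:, 0] != scored[:, 1]))

    def logprob(h: int) -> float:
        naa = (n_a - h) // 2
        nbb = (n_b - h) // 2
        return (
            gammaln(n + 1)
            - gammaln(naa + 1)
            - gammaln(h + 1)
            - gammaln(nbb + 1)
            + h * math.log(2.0)
            + gammaln(n_a + 1)
            + gammaln(n_b + 1)
            - gammaln(2 * n + 1)
        )

    hs = [h for h in range(min(n_a, n_b) + 1) if (n_a - h) % 2 == 0]
    lps = {h: logprob(h) for h in hs}
    obs_lp = lps[h_obs]
    p = sum(math.exp(lp) for lp in lps.values() if lp <= obs_lp + 1e-12)
    return float(min(1.0, p))


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def bonferroni(p_values, alpha: float = 0.05) -> np.ndarray:
    """Bonferroni significance flags over one family of tests.

    The family is the full set of locus x site tests for a dataset; NaN
    entries (undefined tests) do not count toward the family size.
    """
    p = np.asarray(p_values, dtype=float)
    defined = ~np.isnan(p)
    k = int(defined.sum())
    if k == 0:
        raise ValueError("empty test family")
    flags = np.zeros(p.shape, dtype=bool)
    flags[defined] = p[defined] <= alpha / k
    return flags


# ---------------------------------------------------------------------------
# Weir & Cockerham inbreeding coefficient
# ---------------------------------------------------------------------------

def _fis_components(calls: np.ndarray) -> tuple[float, float]:
    """Within-population variance components (b, c) summed over alleles.

    Weir & Cockerham's (1984) single-population components: for each allele
    with sample frequency p and observed heterozygote frequency h involving
    that allele, b = (n/(n-1)) [p(1-p) - (2n-1)/(4n) h] and c = h/2.
    f = 1 - sum(c)/sum(b + c).
    """
    scored = np.asarray(calls)
    scored = scored[scored[:, 0] != MISSING]
    n = len(scored)
    if n < 2:
        return (math.nan, math.nan)
    alleles = np.unique(scored.ravel())
    b_sum = c_sum = 0.0
    for a in alleles:
        p = float(np.sum(scored == a)) / (2 * n)
        h = float(np.mean((scored[:, 0] == a) ^ (scored[:, 1] == a)))
        b_sum += (n / (n - 1)) * (p * (1 - p) - (2 * n - 1) / (4 * n) * h)
        c_sum += h / 2.0
    return b_sum, c_sum


def f_is(calls_by_locus: list[np.ndarray]) -> float:
    """Multi-locus Weir-Cockerham f for one site, combining components
    across loci by summation.  NaN when no variation anywhere."""
    b_tot = c_tot = 0.0
    any_ok = False
    for calls in calls_by_locus:
        b, c = _fis_components(calls)
        if math.isnan(b):
            continue
        b_tot += b
        c_tot += c
        any_ok = True
    if not any_ok or (b_tot + c_tot) == 0:
        return math.nan
    return 1.0 - c_tot / (b_tot + c_tot)


# ---------------------------------------------------------------------------
# allelic richness and private alleles
# ---------------------------------------------------------------------------

def allelic_richness(calls: np.ndarray, g: int) -> float:
    """Rarefied allelic richness: expected allele count in ``g`` genes.

    A_r(g) = sum_i [1 - C(2n - N_i, g) / C(2n, g)] over alleles with count
    N_i among the 2n sampled genes.  ``g`` must be between 2 and 2n.
    """
    if g < 2:
        raise ValueError("rarefaction size g must be >= 2")
    calls = np.asarray(calls)
    scored = calls[calls[:, 0] != MISSING]
    genes = scored.ravel()
    two_n = len(genes)
    if g > two_n:
        raise ValueError(f"g = {g} exceeds the {two_n} genes scored")
    _, counts = np.unique(genes, return_counts=True)

    def log_comb(n_, k_):
        return gammaln(n_ + 1) - gammaln(k_ + 1) - gammaln(n_ - k_ + 1)

    total = 0.0
    for n_i in counts:
        if two_n - n_i < g:
            total += 1.0
        else:
            total += 1.0 - math.exp(log_comb(two_n - n_i, g) - log_comb(two_n, g))
    return total


def private_alleles(table: GenotypeTable) -> pd.DataFrame:
    """Count alleles observed in exactly one site, per site.

    Returns one row per site with the private-allele count; the mean and
    standard error across sites are attached as DataFrame attrs.
    """
    sites = table.site_ids()
    if len(sites) < 2:
        import warnings

        warnings.warn("single site: every allele is trivially private")
    counts = {s: 0 for s in sites}
    for j in range(table.n_loci):
        present: dict[int, set[str]] = {}
        for s in sites:
            for a in table.allele_counts(j, table.site_indices(s)):
                present.setdefault(a, set()).add(s)
        for a, where in present.items():
            if len(where) == 1:
                counts[next(iter(where))] += 1
    df = pd.DataFrame({"site": sites, "private_alleles": [counts[s] for s in sites]})
    vals = df["private_alleles"].to_numpy(dtype=float)
    df.attrs["mean"] = float(vals.mean())
    df.attrs["se"] = float(vals.std(ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else math.nan
    return df


# ---------------------------------------------------------------------------
# fished vs unfished comparison
# ---------------------------------------------------------------------------

def compare_fished(values: pd.Series, fished: pd.Series) -> dict:
    """One-way fixed-effects ANOVA of a per-site diversity metric between
    fished and unfished groups.

    Returns group means +/- SE, F and p.  Identical groups give F = 0,
    p = 1.
    """
    v = np.asarray(values, dtype=float)
    f = np.asarray(fished, dtype=bool)
    g1, g0 = v[f], v[~f]
    if len(g1) < 2 or len(g0) < 2:
        raise ValueError("each group needs at least 2 sites")
    F, p = stats.f_oneway(g1, g0)
    if np.isnan(F):  # zero within-group variance with equal means
        F, p = 0.0, 1.0
    return {
        "mean_fished": float(g1.mean()),
        "se_fished": float(g1.std(ddof=1) / math.sqrt(len(g1))),
        "mean_unfished": float(g0.mean()),
        "se_unfished": float(g0.std(ddof=1) / math.sqrt(len(g0))),
        "F": float(F),
        "p": float(p),
        "n_fished": int(len(g1)),
        "n_unfished": int(len(g0)),
    }


# ---------------------------------------------------------------------------
# assembled summary
# ---------------------------------------------------------------------------

def diversity_summary(
    table: GenotypeTable,
    hwe_iterations: int = 10_000,
    hwe_dememorization: int = 1_000,
    seed: int = 0,
    rarefaction_g: int | None = None,
    alpha: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """Per site x locus diversity and HWE table plus per-site means.

    Returns ``{"by_locus": ..., "by_site": ...}``.  HWE p-values are
    Bonferroni-adjusted over the full locus x site family; undefined tests
    (monomorphic loci) are flagged NaN and excluded from the family size.
    """
    rng = np.random.default_rng(seed)
    sites = table.site_ids()
    rows = []
    for site in sites:
        idx = table.site_indices(site)
        for j, locus in enumerate(table.loci):
            calls = table.calls[idx, j, :]
            scored = calls[calls[:, 0] != MISSING]
            n = len(scored)
            na = len(np.unique(scored.ravel())) if n else 0
            ho, he = heterozygosity(calls)
            try:
                res = exact_hwe(calls, hwe_iterations, hwe_dememorization, rng)
                pval, pse, direction = res.p_value, res.se, res.direction
            except ValueError:
                pval, pse, direction = math.nan, math.nan, ""
            rows.append(
                {
                    "site": site,
                    "locus": locus,
                    "n": n,
                    "Na": na,
                    "Ho": ho,
                    "He": he,
                    "hwe_p": pval,
                    "hwe_p_se": pse,
                    "hwe_direction": direction,
                }
            )
    by_locus = pd.DataFrame(rows)
    by_locus["hwe_significant"] = bonferroni(by_locus["hwe_p"].to_numpy(), alpha)

    if rarefaction_g is None:
        min_genes = math.inf
        for site in sites:
            idx = table.site_indices(site)
            for j in range(table.n_loci):
                calls = table.calls[idx, j, :]
                genes = 2 * int(np.sum(calls[:, 0] != MISSING))
                if genes >= 2:
                    min_genes = min(min_genes, genes)
        rarefaction_g = int(min_genes) if math.isfinite(min_genes) else 2

    priv = private_alleles(table).set_index("site")["private_alleles"]
    site_rows = []
    for site in sites:
        idx = table.site_indices(site)
        sub = by_locus[by_locus["site"] == site]
        ar = np.mean(
            [
                allelic_richness(table.calls[idx, j, :], rarefaction_g)
                for j in range(table.n_loci)
                if 2 * np.sum(table.calls[idx, j, 0] != MISSING) >= rarefaction_g
            ]
        )
        site_rows.append(
            {
                "site": site,
                "n_mean": float(sub["n"].mean()),
                "Na_mean": float(sub["Na"].mean()),
                "Ho_mean": float(sub["Ho"].mean()),
                "He_mean": float(sub["He"].mean()),
                "A_r": float(ar),
                "rarefaction_g": rarefaction_g,
                "F_IS": f_is([table.calls[idx, j, :] for j in range(table.n_loci)]),
                "private_alleles": int(priv.loc[site]),
            }
        )
    return {"by_locus": by_locus, "by_site": pd.DataFrame(site_rows)}
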