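"""Independent reference implementations used only to check the package.

These deliberately use different computational routes from the library:
theta via a literal nested ANOVA on allele-indicator variables, G-statistics
by direct transcription of the defining formulas from tabulated
frequencies, and allelic richness by exhaustive enumeration of gene
subsamples.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

MISSING = 0


def theta_anova(calls_by_site: list[np.ndarray]) -> float:
    """Weir-Cockerham theta via nested ANOVA mean squares.

    For each allele, treat the indicator of that allele over gene copies as
    the response in a two-level nested design (populations / individuals /
    copies); theta = sum of between-population variance components over the
    sum of all components, pooling alleles and loci.  ``calls_by_site`` is
    a list (one per site) of (n_i, n_loci, 2) arrays.
    """
    n_loci = calls_by_site[0].shape[1]
    num = den = 0.0
    for l in range(n_loci):
        site_calls = []
        for site in calls_by_site:
            c = site[:, l, :]
            site_calls.append(c[c[:, 0] != MISSING])
        site_calls = [c for c in site_calls if len(c) > 0]
        r = len(site_calls)
        if r < 2:
            continue
        alleles = sorted(set(np.concatenate(site_calls).ravel().tolist()))
        if len(alleles) < 2:
            continue
        n_i = np.array([len(c) for c in site_calls], dtype=float)
        nbar = n_i.mean()
        nc = (n_i.sum() - (n_i**2).sum() / n_i.sum()) / (r - 1)
        for a in alleles:
            # y: indicator per gene copy, nested ind in pop
            ss_w = ss_i = ss_p = 0.0
            grand_sum = 0.0
            grand_n = 0.0
            pop_means = []
            for c in site_calls:
                y = (c == a).astype(float)  # (n_i, 2)
                ind_mean = y.mean(axis=1)
                ss_w += float(((y - ind_mean[:, None]) ** 2).sum())
                pop_mean = y.mean()
                ss_i += float(2 * ((ind_mean - pop_mean) ** 2).sum())
                pop_means.append((pop_mean, 2 * len(c)))
                grand_sum += y.sum()
                grand_n += y.size
            grand_mean = grand_sum / grand_n
            ss_p = sum(m_n * (m - grand_mean) ** 2 for m, m_n in pop_means)
            n_tot = n_i.sum()
            msw = ss_w / n_tot
            msi = ss_i / (n_tot - r)
            msp = ss_p / (r - 1)
            sw = msw
            si = (msi - msw) / 2.0
            sp = (msp - msi) / (2.0 * nc)
            num += sp
            den += sp + si + sw
    return num / den if den else math.nan


def gst_hedrick_direct(freqs: list[np.ndarray], n_i: np.ndarray, ho: np.ndarray) -> float:
    """Hedrick G'_ST at one locus, transcribed from the defining formulas.

    ``freqs``: per-site allele-frequency vectors over a common allele list;
    ``n_i``: per-site individuals scored; ``ho``: per-site observed
    heterozygote proportion.
    """
    k = len(freqs)
    ntilde = k / np.sum(1.0 / n_i)
    ho_bar = float(np.mean(ho))
    hs_plug = 1.0 - float(np.mean([np.sum(p**2) for p in freqs]))
    hs = (ntilde / (ntilde - 1)) * (hs_plug - ho_bar / (2 * ntilde))
    pbar = np.mean(freqs, axis=0)
    ht = 1.0 - float(np.sum(pbar**2)) + hs / (ntilde * k) - ho_bar / (2 * ntilde * k)
    gst = (ht - hs) / ht
    gst_max = (k - 1) * (1 - hs) / (k - 1 + hs)
    return gst / gst_max


def d_jost_direct(freqs: list[np.ndarray], n_i: np.ndarray, ho: np.ndarray) -> float:
    """Jost D at one locus from the defining formula."""
    k = len(freqs)
    ntilde = k / np.sum(1.0 / n_i)
    ho_bar = float(np.mean(ho))
    hs_plug = 1.0 - float(np.mean([np.sum(p**2) for p in freqs]))
    hs = (ntilde / (ntilde - 1)) * (hs_plug - ho_bar / (2 * ntilde))
    pbar = np.mean(freqs, axis=0)
    ht = 1.0 - float(np.sum(pbar**2)) + hs / (ntilde * k) - ho_bar / (2 * ntilde * k)
    return (k / (k - 1)) * (ht - hs) / (1 - hs)


def allelic_richness_exhaustive(genes: np.ndarray, g: int) -> float:
    """Mean allele count over all C(2n, g) gene subsamples (tiny inputs)."""
    genes = list(genes)
    total = 0
    count = 0
    for combo in itertools.combinations(range(len(genes)), g):
        total += len({genes[i] for i in combo})
        count += 1
    return total / count


def fis_textbook(calls: np.ndarray) -> float:
    """Single-population Weir-Cockerham f via the per-allele b, c formulas
    written out directly (loop transcription)."""
    calls = np.asarray(calls)
    scored = calls[calls[:, 0] != MISSING]
    n = len(scored)
    alleles = sorted(set(scored.ravel().tolist()))
    b_sum = c_sum = 0.0
    for a in alleles:
        count = sum(int(x == a) for row in scored for x in row)
        p = count / (2 * n)
        h = sum(1 for row in scored if (row[0] == a) != (row[1] == a)) / n
        b_sum += (n / (n - 1)) * (p * (1 - p) - (2 * n - 1) / (4 * n) * h)
        c_sum += h / 2
    if b_sum + c_sum == 0:
        return math.nan
    return 1 - c_sum / (b_sum + c_sum)
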