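"""Null-allele detection and dataset adjustment.

Microsatellite null alleles fail to amplify, so null/visible heterozygotes
are scored as visible homozygotes and null/null genotypes as missing data,
producing apparent heterozygote deficits.  The per-site null frequency is
estimated from excess homozygosity as r = (He - Ho) / (1 + He) (the Van
Oosterhout estimator); loci with consistent excess across sites are
flagged, and an adjusted dataset is produced in which the expected number
of masked heterozygotes is recoded as heterozygous for a synthetic null
allele labelled one repeat unit above the largest observed allele.

The exact recoding rule used by fragment-analysis software is not
documented at this granularity; the expected-count recoding with a seeded
deterministic choice of individuals implemented here is this package's own
reconstruction.  Downstream statistics should be run on both the raw and
the adjusted table for comparison.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .genodata import MISSING, GenotypeTable


def estimate_null_freq(calls: np.ndarray) -> float:
    """Van Oosterhout null-allele frequency estimate for one site x locus.

    r = (He - Ho) / (1 + He), with He = 1 - sum p_i^2 from the observed
    sample frequencies; negative estimates are truncated to 0.  NaN when
    the locus is monomorphic or unscored.
    """
    calls = np.asarray(calls)
    scored = calls[calls[:, 0] != MISSING]
    n = len(scored)
    if n == 0:
        return math.nan
    if n < 10:
        warnings.warn(f"null-frequency estimate from only {n} individuals")
    genes = scored.ravel()
    _, counts = np.unique(genes, return_counts=True)
    if len(counts) < 2:
        return math.nan
    p = counts / counts.sum()
    he = 1.0 - float(np.sum(p**2))
    ho = float(np.mean(scored[:, 0] != scored[:, 1]))
    return max(0.0, (he - ho) / (1.0 + he))


def null_freq_matrix(table: GenotypeTable) -> pd.DataFrame:
    """Site x locus matrix of estimated null frequencies."""
    sites = table.site_ids()
    data = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for j, locus in enumerate(table.loci):
            col = []
            for site in sites:
                idx = table.site_indices(site)
                col.append(estimate_null_freq(table.calls[idx, j, :]))
            data[locus] = col
    return pd.DataFrame(data, index=pd.Index(sites, name="site"))


def flag_null_loci(
    r_matrix: pd.DataFrame,
    threshold: float = 0.05,
    min_sites: int | None = None,
) -> pd.Series:
    """Flag loci whose estimated null frequency exceeds ``threshold`` at
    enough sites.

    ``min_sites`` defaults to a strict majority of the sites where the
    locus is polymorphic (NaN entries denote undefined estimates and do
    not count as polymorphic).
    """
    flags = {}
    for locus in r_matrix.columns:
        r = r_matrix[locus]
        n_poly = int(r.notna().sum())
        need = min_sites if min_sites is not None else (n_poly // 2 + 1)
        flags[locus] = bool((r > threshold).sum() >= need) if n_poly else False
    return pd.Series(flags, name="null_flag")


@dataclass
class NullAdjustment:
    r_matrix: pd.DataFrame
    flags: pd.Series
    adjusted: GenotypeTable
    null_label: dict[str, int]

    def report(self) -> pd.DataFrame:
        long = self.r_matrix.reset_index().melt(
            id_vars="site", var_name="locus", value_name="null_freq"
        )
        long["flagged"] = long["locus"].map(self.flags).astype(bool)
        return long


def apply_oosterhout(
    table: GenotypeTable,
    r_matrix: pd.DataFrame | None = None,
    flags: pd.Series | None = None,
    threshold: float = 0.05,
    min_sites: int | None = None,
    seed: int = 0,
) -> NullAdjustment:
    """Recode expected hidden null heterozygotes at flagged loci.

    At each flagged locus and site, every observed homozygote A/A is truly
    A/null with probability 2r / (q_A + 2r) where q_A is the visible-allele
    frequency rescaled by (1 - r).  The expected number of such genotypes
    is recoded (seeded deterministic choice among the homozygotes) as
    heterozygous A/null, with the null labelled one repeat unit above the
    locus's largest observed allele.  Unflagged loci are untouched.
    """
    if r_matrix is None:
        r_matrix = null_freq_matrix(table)
    if flags is None:
        flags = flag_null_loci(r_matrix, threshold, min_sites)
    rng = np.random.default_rng(seed)
    calls = table.calls.copy()
    null_label: dict[str, int] = {}

    for j, locus in enumerate(table.loci):
        if not flags.get(locus, False):
            continue
        unit = (table.repeat_units or {}).get(locus, 1)
        observed = table.calls[:, j, :]
        largest = int(observed.max())
        label = largest + unit
        while label in set(observed[observed != MISSING].ravel().tolist()):
            warnings.warn(
                f"synthetic null label {label} collides with an observed allele "
                f"at {locus}; shifting by one more repeat unit"
            )
            label += unit
        null_label[locus] = label
        for site in table.site_ids():
            r = float(r_matrix.loc[site, locus])
            if not (r > 0):
                continue
            idx = table.site_indices(site)
            site_calls = table.calls[idx, j, :]
            scored = site_calls[:, 0] != MISSING
            hom = scored & (site_calls[:, 0] == site_calls[:, 1])
            if not hom.any():
                continue
            genes = site_calls[scored].ravel()
            vals, cnts = np.unique(genes, return_counts=True)
            freq = dict(zip(vals.tolist(), (cnts / cnts.sum() * (1.0 - r)).tolist()))
            for allele in vals:
                carriers = idx[hom & (site_calls[:, 0] == allele)]
                q = freq[int(allele)]
                frac = 2 * r / (q + 2 * r) if (q + 2 * r) > 0 else 0.0
                k = int(round(frac * len(carriers)))
                if k == 0:
                    continue
                chosen = rng.choice(carriers, size=min(k, len(carriers)), replace=False)
                calls[chosen, j, 0] = allele
                calls[chosen, j, 1] = label
    adjusted = replace(table, calls=np.sort(calls, axis=2))
    return NullAdjustment(r_matrix=r_matrix, flags=flags, adjusted=adjusted, null_label=null_label)
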