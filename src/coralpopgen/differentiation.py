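"""Population differentiation statistics with permutation significance.

Covers Weir & Cockerham's theta (variance-components F_ST), Hedrick's
standardised G'_ST and Jost's D_EST (both from Nei-Chesser
sample-size-corrected heterozygosities), label-permutation p-values,
hierarchical AMOVA on allele-mismatch distances, principal coordinates
of a pairwise matrix, and the Mantel test of isolation by distance on
great-circle distances.

Raw (possibly slightly negative) estimates are stored; display flooring at
zero is left to the reporting layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genodata import MISSING, GenotypeTable

EARTH_RADIUS_KM = 6371.0


# ---------------------------------------------------------------------------
# integer-coded genotypes for fast recomputation under permutation
# ---------------------------------------------------------------------------

class CodedTable:
    """Per-locus integer allele codes (-1 = missing) for one table."""

    def __init__(self, table: GenotypeTable):
        self.n = table.n_individuals
        self.loci = list(table.loci)
        self.codes: list[np.ndarray] = []
        self.n_alleles: list[int] = []
        for j in range(table.n_loci):
            col = table.calls[:, j, :]
            alleles = np.unique(col[col != MISSING])
            lut = {a: i for i, a in enumerate(alleles.tolist())}
            coded = np.full(col.shape, -1, dtype=np.int64)
            for a, i in lut.items():
                coded[col == a] = i
            self.codes.append(coded)
            self.n_alleles.append(len(alleles))
        self.sites = np.asarray(table.sites, dtype=object)

    def labels_for(self, site_order: list[str]) -> np.ndarray:
        lut = {s: i for i, s in enumerate(site_order)}
        return np.array([lut[s] for s in self.sites], dtype=np.int64)


def _per_site_counts(codes: np.ndarray, labels: np.ndarray, n_groups: int, n_alleles: int):
    """Allele counts, per-allele heterozygote counts and sample sizes per group."""
    scored = codes[:, 0] >= 0
    g = labels[scored]
    c = codes[scored]
    counts = (
        np.bincount(g * n_alleles + c[:, 0], minlength=n_groups * n_alleles)
        + np.bincount(g * n_alleles + c[:, 1], minlength=n_groups * n_alleles)
    ).reshape(n_groups, n_alleles)
    het = c[:, 0] != c[:, 1]
    hcounts = (
        np.bincount(g[het] * n_alleles + c[het, 0], minlength=n_groups * n_alleles)
        + np.bincount(g[het] * n_alleles + c[het, 1], minlength=n_groups * n_alleles)
    ).reshape(n_groups, n_alleles)
    n_i = np.bincount(g, minlength=n_groups).astype(float)
    return counts.astype(float), hcounts.astype(float), n_i


def _wc_components(counts, hcounts, n_i):
    """Weir-Cockerham (1984) a, b, c summed over alleles at one locus."""
    use = n_i > 0
    counts, hcounts, n_i = counts[use], hcounts[use], n_i[use]
    r = len(n_i)
    if r < 2:
        return 0.0, 0.0, 0.0
    nbar = n_i.mean()
    if nbar <= 1:
        return 0.0, 0.0, 0.0
    nc = (r * nbar - np.sum(n_i**2) / (r * nbar)) / (r - 1)
    if nc <= 0:
        return 0.0, 0.0, 0.0
    p_i = counts / (2 * n_i[:, None])
    h_i = hcounts / n_i[:, None]
    pbar = np.sum(n_i[:, None] * p_i, axis=0) / (r * nbar)
    s2 = np.sum(n_i[:, None] * (p_i - pbar) ** 2, axis=0) / ((r - 1) * nbar)
    hbar = np.sum(n_i[:, None] * h_i, axis=0) / (r * nbar)
    inner = pbar * (1 - pbar) - (r - 1) / r * s2
    a = (nbar / nc) * (s2 - (inner - hbar / 4) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return float(a.sum()), float(b.sum()), float(c.sum())


def theta_wc_value(coded: CodedTable, labels: np.ndarray, n_groups: int) -> float:
    """Multi-locus theta = sum(a) / sum(a + b + c) over alleles and loci."""
    a_tot = d_tot = 0.0
    for codes, n_alleles in zip(coded.codes, coded.n_alleles):
        if n_alleles < 2:
            continue
        counts, hcounts, n_i = _per_site_counts(codes, labels, n_groups, n_alleles)
        a, b, c = _wc_components(counts, hcounts, n_i)
        a_tot += a
        d_tot += a + b + c
    if d_tot == 0:
        return math.nan
    return a_tot / d_tot


def _nei_chesser(counts, hcounts, n_i):
    """Sample-size-corrected Hs, Ht (Nei & Chesser 1983) and Ho at a locus."""
    use = n_i > 0
    counts, hcounts, n_i = counts[use], hcounts[use], n_i[use]
    k = len(n_i)
    if k < 2:
        return math.nan, math.nan, math.nan
    ntilde = k / np.sum(1.0 / n_i)  # harmonic mean sample size
    p_i = counts / (2 * n_i[:, None])
    ho = float(np.mean(np.sum(hcounts, axis=1) / (2 * n_i)))  # per-ind het rate
    hs_plug = 1.0 - float(np.mean(np.sum(p_i**2, axis=1)))
    hs = (ntilde / (ntilde - 1)) * (hs_plug - ho / (2 * ntilde))
    pbar = p_i.mean(axis=0)
    ht = 1.0 - float(np.sum(pbar**2)) + hs / (ntilde * k) - ho / (2 * ntilde * k)
    return hs, ht, ho


def gst_hedrick_value(coded: CodedTable, labels: np.ndarray, n_groups: int) -> float:
    """Multi-locus Hedrick G'_ST from locus-averaged Hs and Ht."""
    hs_list, ht_list = [], []
    for codes, n_alleles in zip(coded.codes, coded.n_alleles):
        if n_alleles < 1:
            continue
        counts, hcounts, n_i = _per_site_counts(codes, labels, n_groups, n_alleles)
        hs, ht, _ = _nei_chesser(counts, hcounts, n_i)
        if not math.isnan(hs):
            hs_list.append(hs)
            ht_list.append(ht)
    if not hs_list:
        return math.nan
    hs, ht = float(np.mean(hs_list)), float(np.mean(ht_list))
    if ht <= 0:
        return math.nan
    k = n_groups
    gst = (ht - hs) / ht
    gst_max = (k - 1) * (1 - hs) / (k - 1 + hs)
    if gst_max == 0:
        return math.nan
    return gst / gst_max


def d_jost_value(coded: CodedTable, labels: np.ndarray, n_groups: int) -> float:
    """Multi-locus Jost D: harmonic mean of per-locus D when all per-locus
    values are positive, otherwise their arithmetic mean (the harmonic mean
    is undefined at or below zero, which occurs under weak differentiation)."""
    ds = []
    k = n_groups
    for codes, n_alleles in zip(coded.codes, coded.n_alleles):
        if n_alleles < 1:
            continue
        counts, hcounts, n_i = _per_site_counts(codes, labels, n_groups, n_alleles)
        hs, ht, _ = _nei_chesser(counts, hcounts, n_i)
        if math.isnan(hs) or hs >= 1:
            continue
        ds.append((k / (k - 1)) * (ht - hs) / (1 - hs))
    if not ds:
        return math.nan
    ds = np.asarray(ds)
    if (ds > 0).all():
        return float(len(ds) / np.sum(1.0 / ds))
    return float(ds.mean())


_STAT_FUNCS = {
    "FST_WC": theta_wc_value,
    "GST_Hedrick_std": gst_hedrick_value,
    "D_Jost": d_jost_value,
}


@dataclass
class DifferentiationResult:
    statistic: str
    global_value: float
    global_p: float | None
    pairwise: pd.DataFrame | None
    pairwise_p: pd.DataFrame | None
    n_permutations: int
    seed: int | None


def permute_significance(
    stat_func,
    coded: CodedTable,
    labels: np.ndarray,
    n_groups: int,
    n_perm: int = 9_999,
    seed: int = 0,
) -> tuple[float, float]:
    """One-tailed permutation p-value for a differentiation statistic.

    Individuals are shuffled among groups holding group sizes fixed;
    p = (1 + #{permuted >= observed}) / (1 + n_perm).
    """
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    if n_groups < 2:
        raise ValueError("need at least two groups")
    rng = np.random.default_rng(seed)
    obs = stat_func(coded, labels, n_groups)
    if math.isnan(obs):
        return obs, math.nan
    exceed = 0
    work = labels.copy()
    for _ in range(n_perm):
        rng.shuffle(work)
        val = stat_func(coded, work, n_groups)
        if not math.isnan(val) and val >= obs - 1e-12:
            exceed += 1
    return obs, (1 + exceed) / (1 + n_perm)


def differentiation(
    table: GenotypeTable,
    statistic: str = "FST_WC",
    n_perm: int = 9_999,
    seed: int = 0,
    pairwise: bool = True,
) -> DifferentiationResult:
    """Global and pairwise differentiation with permutation p-values."""
    if statistic not in _STAT_FUNCS:
        raise ValueError(f"unknown statistic {statistic!r}")
    func = _STAT_FUNCS[statistic]
    coded = CodedTable(table)
    sites = table.site_ids()
    if len(sites) < 2:
        raise ValueError("need at least two sites")
    labels = coded.labels_for(sites)
    g_obs, g_p = permute_significance(func, coded, labels, len(sites), n_perm, seed)

    pw = pw_p = None
    if pairwise:
        pw = pd.DataFrame(0.0, index=sites, columns=sites)
        pw_p = pd.DataFrame(np.nan, index=sites, columns=sites)
        rng = np.random.default_rng(seed)
        for i in range(len(sites)):
            for j in range(i + 1, len(sites)):
                sub = np.flatnonzero(np.isin(labels, [i, j]))
                sub_tab = table.subset(sub)
                sub_coded = CodedTable(sub_tab)
                sub_labels = sub_coded.labels_for([sites[i], sites[j]])
                pair_seed = int(rng.integers(0, 2**31 - 1))
                val, p = permute_significance(
                    func, sub_coded, sub_labels, 2, n_perm, pair_seed
                )
                pw.iloc[i, j] = pw.iloc[j, i] = val
                pw_p.iloc[i, j] = pw_p.iloc[j, i] = p
    return DifferentiationResult(statistic, g_obs, g_p, pw, pw_p, n_perm, seed)


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

def allele_mismatch_matrix(table: GenotypeTable) -> np.ndarray:
    """Squared inter-individual distance = allele mismatches (0/1/2 per
    locus), summed over loci scored in both individuals."""
    n = table.n_individuals
    d2 = np.zeros((n, n))
    for j in range(table.n_loci):
        a = table.calls[:, j, :]
        scored = a[:, 0] != MISSING
        a1, a2 = a[:, 0], a[:, 1]
        eq_both = (a1[:, None] == a1[None, :]) & (a2[:, None] == a2[None, :])
        share = (
            (a1[:, None] == a1[None, :])
            | (a1[:, None] == a2[None, :])
            | (a2[:, None] == a1[None, :])
            | (a2[:, None] == a2[None, :])
        )
        mism = np.where(eq_both, 0, np.where(share, 1, 2)).astype(float)
        mism[~scored, :] = 0.0
        mism[:, ~scored] = 0.0
        d2 += mism
    np.fill_diagonal(d2, 0.0)
    return d2


def _amova_ss(d2: np.ndarray, ind_sites: np.ndarray, site_to_group: dict):
    """Sums of squares: total, among groups, among sites within groups,
    within sites -- from the squared-distance matrix."""
    n = len(ind_sites)
    tot = d2.sum() / (2 * n)
    ss_wp = 0.0
    sites = pd.unique(ind_sites)
    for s in sites:
        idx = np.flatnonzero(ind_sites == s)
        ss_wp += d2[np.ix_(idx, idx)].sum() / (2 * len(idx))
    ss_wg = 0.0
    ind_groups = np.array([site_to_group[s] for s in ind_sites], dtype=object)
    for g in pd.unique(ind_groups):
        idx = np.flatnonzero(ind_groups == g)
        ss_wg += d2[np.ix_(idx, idx)].sum() / (2 * len(idx))
    ss_ag = tot - ss_wg
    ss_ap = ss_wg - ss_wp
    return tot, ss_ag, ss_ap, ss_wp


@dataclass
class AmovaResult:
    sigma_among_groups: float
    sigma_among_sites: float
    sigma_within: float
    phi_ct: float
    phi_sc: float
    phi_st: float
    p_ct: float | None = None
    p_sc: float | None = None
    p_st: float | None = None
    df: tuple[int, int, int] = (0, 0, 0)

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "source": ["among_seamounts", "among_sites_within", "within_sites"],
                "df": list(self.df),
                "sigma2": [
                    self.sigma_among_groups,
                    self.sigma_among_sites,
                    self.sigma_within,
                ],
                "phi": [self.phi_ct, self.phi_sc, self.phi_st],
                "p": [self.p_ct, self.p_sc, self.p_st],
            }
        )


def _amova_components(d2, site_labels, group_of, site_order):
    site_labels = np.asarray(site_labels, dtype=object)
    n_p = np.array([np.sum(site_labels == s) for s in site_order], dtype=float)
    n_tot = int(n_p.sum())
    group_of_site = np.array([group_of[s] for s in site_order], dtype=object)
    groups = pd.unique(group_of_site)
    g = len(groups)
    p = len(site_order)
    tot, ss_ag, ss_ap, ss_wp = _amova_ss(d2, site_labels, dict(group_of))

    df_ag, df_ap, df_wp = g - 1, p - g, n_tot - p
    ms_wp = ss_wp / df_wp if df_wp else math.nan
    sigma_c = ms_wp

    Ng = {gr: n_p[group_of_site == gr].sum() for gr in groups}
    sum_sq_within = sum(
        (n_p[group_of_site == gr] ** 2).sum() / Ng[gr] for gr in groups
    )
    if df_ap > 0:
        n1 = (n_tot - sum_sq_within) / df_ap
        sigma_b = (ss_ap / df_ap - sigma_c) / n1 if n1 else math.nan
    else:
        sigma_b = 0.0  # one site per group: the within-group level is empty
    if df_ag > 0:
        n2 = (sum_sq_within - (n_p**2).sum() / n_tot) / df_ag
        n3 = (n_tot - sum(Ng[gr] ** 2 for gr in groups) / n_tot) / df_ag
        sb = 0.0 if math.isnan(sigma_b) else sigma_b
        sigma_a = (ss_ag / df_ag - sigma_c - n2 * sb) / n3 if n3 else math.nan
    else:
        sigma_a = math.nan
    return sigma_a, sigma_b, sigma_c, (df_ag, df_ap, df_wp)


def amova(
    table: GenotypeTable,
    group_of: dict[str, str],
    n_perm: int = 999,
    seed: int = 0,
) -> AmovaResult:
    """Two-level hierarchical AMOVA: sites nested in seamount groups.

    Permutation tests: Phi_CT permutes whole sites among groups, Phi_SC
    permutes individuals among sites within their group, Phi_ST permutes
    individuals among all sites.
    """
    site_order = table.site_ids()
    for s in site_order:
        if s not in group_of:
            raise ValueError(f"site {s} missing from the grouping")
    if len({group_of[s] for s in site_order}) < 2:
        raise ValueError("need at least two groups")
    d2 = allele_mismatch_matrix(table)
    labels = np.asarray(table.sites, dtype=object)

    sa, sb, sc, dfs = _amova_components(d2, labels, group_of, site_order)
    total = sa + sb + sc
    phi_ct = sa / total if total else math.nan
    phi_sc = sb / (sb + sc) if (sb + sc) and dfs[1] > 0 else math.nan
    phi_st = (sa + sb) / total if total else math.nan

    rng = np.random.default_rng(seed)

    def perm_p(observed, draw):
        if math.isnan(observed):
            return None
        exceed = 0
        for _ in range(n_perm):
            if draw() >= observed - 1e-12:
                exceed += 1
        return (1 + exceed) / (1 + n_perm)

    group_of_site = {s: group_of[s] for s in site_order}
    group_vals = [group_of_site[s] for s in site_order]

    def draw_ct():
        shuffled = list(group_vals)
        rng.shuffle(shuffled)
        g_map = dict(zip(site_order, shuffled))
        a, b, c, _ = _amova_components(d2, labels, g_map, site_order)
        t = a + b + c
        return a / t if t else -math.inf

    def draw_st():
        perm = rng.permutation(len(labels))
        a, b, c, _ = _amova_components(d2[np.ix_(perm, perm)], labels, group_of, site_order)
        t = a + b + c
        return (a + b) / t if t else -math.inf

    def draw_sc():
        new_labels = labels.copy()
        for gr in set(group_vals):
            gsites = [s for s in site_order if group_of_site[s] == gr]
            idx = np.flatnonzero(np.isin(labels, gsites))
            new_labels[idx] = new_labels[idx[rng.permutation(len(idx))]]
        a, b, c, _ = _amova_components(d2, new_labels, group_of, site_order)
        return b / (b + c) if (b + c) else -math.inf

    result = AmovaResult(sa, sb, sc, phi_ct, phi_sc, phi_st, df=dfs)
    result.p_ct = perm_p(phi_ct, draw_ct)
    result.p_sc = perm_p(phi_sc, draw_sc)
    result.p_st = perm_p(phi_st, draw_st)
    return result


# ---------------------------------------------------------------------------
# principal coordinates
# ---------------------------------------------------------------------------

def pcoa(matrix: pd.DataFrame | np.ndarray) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical PCoA (Gower double-centering of -D^2/2).

    Returns (coordinates, eigenvalue fractions) for the positive
    eigenvalues, axes ordered by decreasing eigenvalue; the first nonzero
    loading of each axis is made positive so the output is sign-stable.
    """
    if isinstance(matrix, pd.DataFrame):
        names = list(matrix.index)
        d = matrix.to_numpy(dtype=float)
    else:
        d = np.asarray(matrix, dtype=float)
        names = [f"s{i}" for i in range(len(d))]
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("PCoA requires a symmetric square matrix")
    n = len(d)
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > 1e-10
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    for k in range(coords.shape[1]):
        nz = np.flatnonzero(np.abs(coords[:, k]) > 1e-12)
        if nz.size and coords[nz[0], k] < 0:
            coords[:, k] = -coords[:, k]
    frac = evals[pos] / evals[pos].sum() if pos.any() else np.array([])
    cols = [f"axis{k+1}" for k in range(coords.shape[1])]
    return pd.DataFrame(coords, index=names, columns=cols), frac


# ---------------------------------------------------------------------------
# isolation by distance
# ---------------------------------------------------------------------------

def haversine_km(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance in km."""
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlmb = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlmb / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(math.sqrt(a))


@dataclass
class IbdResult:
    mantel_r: float
    r_squared: float
    p_value: float
    n_permutations: int
    distance_km: pd.DataFrame = field(repr=False, default=None)
    linearized: bool = False


def mantel_ibd(
    fst: pd.DataFrame,
    metadata: pd.DataFrame,
    n_perm: int = 9_999,
    seed: int = 0,
    linearize: bool = False,
) -> IbdResult:
    """Mantel test of pairwise F_ST against great-circle distance.

    One-tailed (positive association); p by jointly permuting rows and
    columns of the genetic matrix.  ``linearize`` optionally uses
    F_ST / (1 - F_ST).
    """
    sites = list(fst.index)
    if len(sites) < 4:
        raise ValueError("need at least 4 sites for a Mantel test")
    meta = metadata.set_index("site_id")
    missing = [s for s in sites if s not in meta.index]
    if missing:
        raise ValueError(f"no coordinates for sites: {missing}")
    n = len(sites)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = haversine_km(
                meta.loc[sites[i], "lat"],
                meta.loc[sites[i], "lon"],
                meta.loc[sites[j], "lat"],
                meta.loc[sites[j], "lon"],
            )
            dist[i, j] = dist[j, i] = d
    gen = fst.to_numpy(dtype=float).copy()
    if linearize:
        gen = gen / (1.0 - gen)
    iu = np.triu_indices(n, 1)
    x, y = dist[iu], gen[iu]

    def pearson(a, b):
        a = a - a.mean()
        b = b - b.mean()
        denom = math.sqrt((a**2).sum() * (b**2).sum())
        return float((a * b).sum() / denom) if denom else math.nan

    r_obs = pearson(x, y)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp = gen[np.ix_(perm, perm)][iu]
        if pearson(x, yp) >= r_obs - 1e-12:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    dist_df = pd.DataFrame(dist, index=sites, columns=sites)
    return IbdResult(r_obs, r_obs**2, p, n_perm, dist_df, linearize)
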