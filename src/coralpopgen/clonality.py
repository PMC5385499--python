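"""Clone detection and genotypic diversity.

Repeated multilocus genotypes (MLGs) in a sample of colonial or partially
clonal organisms may be clonemates or may be independent products of sexual
reproduction that happen to share a genotype.  This module partitions a
sample into MLGs (with a missing-data wildcard), computes the probability
P_gen of a genotype under random mating from the sample allele frequencies,
the probability P_sex that the observed number of copies arose through
independent sexual events, genotypic richness R = (G - 1)/(N - 1), and
condenses clones to one representative per site for gene-flow analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genodata import MISSING, GenotypeTable


@dataclass
class MlgRecord:
    """One multilocus genotype: its members, sites and sexual-origin odds."""

    mlg_id: int
    members: list[str]
    sites: list[str]
    n_copies: int
    p_gen: float | None = None
    p_sex: float | None = None
    unassessed: bool = False


@dataclass
class SiteGenotypicDiversity:
    site: str
    n: int
    g: int
    ng_ratio: float
    r: float | None  # None when N < 2


@dataclass
class CloneReport:
    """Partition of a sample into MLGs plus per-site genotypic diversity."""

    mlg_of: dict[str, int]
    mlgs: list[MlgRecord]
    per_site: list[SiteGenotypicDiversity] = field(default_factory=list)

    def mlg_table(self) -> pd.DataFrame:
        rows = []
        for m in self.mlgs:
            rows.append(
                {
                    "mlg_id": m.mlg_id,
                    "size": m.n_copies,
                    "sites": ";".join(m.sites),
                    "members": ";".join(m.members),
                    "p_gen": m.p_gen,
                    "p_sex": m.p_sex,
                    "unassessed": m.unassessed,
                }
            )
        return pd.DataFrame(rows)

    def site_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"site": s.site, "N": s.n, "Ng": s.g, "Ng_N": s.ng_ratio, "R": s.r}
                for s in self.per_site
            ]
        )


def _compatible(a: np.ndarray, b: np.ndarray) -> bool:
    """True when two call rows agree at every locus scored in both."""
    both = (a[:, 0] != MISSING) & (b[:, 0] != MISSING)
    return bool(np.all(a[both] == b[both]))


def find_mlgs(table: GenotypeTable, max_missing: int = 1) -> CloneReport:
    """Partition individuals into multilocus genotypes.

    Two individuals share an MLG iff they are identical at every locus
    scored in both AND each has at most ``max_missing`` missing loci
    (missing loci act as wildcards).  Matching is transitively closed.
    Individuals with more than ``max_missing`` missing loci are left as
    singletons flagged ``unassessed``.
    """
    if table.n_individuals == 0:
        raise ValueError("empty table")
    n = table.n_individuals
    n_missing = table.missing_mask().sum(axis=1)
    assessable = n_missing <= max_missing

    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    # group by complete-profile hash first to skip most pairs
    idx = np.flatnonzero(assessable)
    for ii, i in enumerate(idx):
        for j in idx[ii + 1 :]:
            if find(i) == find(j):
                continue
            if _compatible(table.calls[i], table.calls[j]):
                union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    mlg_of: dict[str, int] = {}
    mlgs: list[MlgRecord] = []
    for mlg_id, root in enumerate(sorted(groups)):
        members_idx = groups[root]
        members = [table.individuals[i] for i in members_idx]
        sites = sorted({str(table.sites[i]) for i in members_idx})
        for name in members:
            mlg_of[name] = mlg_id
        mlgs.append(
            MlgRecord(
                mlg_id=mlg_id,
                members=members,
                sites=sites,
                n_copies=len(members),
                unassessed=not assessable[members_idx[0]] and len(members_idx) == 1,
            )
        )
    report = CloneReport(mlg_of=mlg_of, mlgs=mlgs)
    report.per_site = _site_diversity(table, report)
    return report


def _site_diversity(table: GenotypeTable, report: CloneReport) -> list[SiteGenotypicDiversity]:
    out = []
    for site in table.site_ids():
        idx = table.site_indices(site)
        names = [table.individuals[i] for i in idx]
        n = len(names)
        g = len({report.mlg_of[name] for name in names})
        out.append(
            SiteGenotypicDiversity(
                site=site,
                n=n,
                g=g,
                ng_ratio=g / n,
                r=genotypic_richness(n, g),
            )
        )
    return out


def p_gen(genotype: np.ndarray, freqs: list[dict[int, float]]) -> float:
    """Probability of a multilocus genotype under random mating.

    ``genotype`` is an (n_loci, 2) array of allele sizes; ``freqs`` gives
    per-locus allele-frequency dicts from the (un-clone-corrected) sample
    where the genotype occurs.  Missing loci contribute a factor of 1.
    """
    genotype = np.asarray(genotype)
    p = 1.0
    for (a, b), f in zip(genotype, freqs):
        if a == MISSING:
            continue
        if a not in f or b not in f:
            raise ValueError(
                f"allele {a if a not in f else b} absent from the frequency table; "
                "frequencies must come from the same sample"
            )
        p *= f[a] ** 2 if a == b else 2.0 * f[a] * f[b]
    return p


def p_sex(pgen: float, n_copies: int, n: int) -> float:
    """Probability that >= ``n_copies`` copies of a genotype arose sexually.

    Given one observed copy, the remaining ``n - 1`` individuals each carry
    the genotype independently with probability ``pgen``; the tail
    probability of a Binomial(n - 1, pgen) at ``n_copies - 1`` follows.
    """
    if not 0.0 <= pgen <= 1.0:
        raise ValueError("pgen must be in [0, 1]")
    if not 2 <= n_copies <= n:
        raise ValueError("need 2 <= n_copies <= N")
    # sf(k) = P(X > k) = P(X >= k + 1)
    return float(stats.binom.sf(n_copies - 2, n - 1, pgen))


def genotypic_richness(n: int, g: int) -> float | None:
    """R = (G - 1)/(N - 1); 0 for a monoclonal sample, 1 for all-unique.

    Undefined (None) for N < 2.
    """
    if n < 2:
        return None
    if not 1 <= g <= n:
        raise ValueError("need 1 <= G <= N")
    return (g - 1) / (n - 1)


def annotate_psex(table: GenotypeTable, report: CloneReport) -> CloneReport:
    """Fill in P_gen and P_sex for every repeated MLG in the report.

    Allele frequencies are computed from the pooled, un-condensed sample of
    the site(s) where the MLG occurs.
    """
    for m in report.mlgs:
        if m.n_copies < 2:
            continue
        idx = np.flatnonzero(np.isin(table.sites, m.sites))
        freqs = [table.allele_freqs(j, idx) for j in range(table.n_loci)]
        # use the most complete member as the genotype template
        best = min(
            (table.individuals.index(name) for name in m.members),
            key=lambda i: int((table.calls[i, :, 0] == MISSING).sum()),
        )
        m.p_gen = p_gen(table.calls[best], freqs)
        m.p_sex = p_sex(m.p_gen, m.n_copies, len(idx))
    return report


def condense_clones(table: GenotypeTable, report: CloneReport) -> GenotypeTable:
    """Keep one representative (lowest individual id) per MLG per site.

    An MLG spanning several sites keeps one representative in each site, so
    site sample sizes after condensation equal the per-site unique-genotype
    counts.  Idempotent.
    """
    keep: list[int] = []
    chosen: dict[tuple[str, int], int] = {}
    for i, name in enumerate(table.individuals):
        key = (str(table.sites[i]), report.mlg_of[name])
        if key not in chosen or name < table.individuals[chosen[key]]:
            chosen[key] = i
    keep = sorted(chosen.values())
    return table.subset(np.array(keep, dtype=int))
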