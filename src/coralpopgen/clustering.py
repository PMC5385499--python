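"""Model-based assignment of individuals to K genetic clusters.

A Gibbs sampler for the admixture model with independent Dirichlet(1)
priors on per-cluster allele frequencies: each allele copy carries a
latent cluster assignment z sampled conditional on the cluster allele
frequencies P and the individual's ancestry vector q; P and q are then
re-sampled from their Dirichlet full conditionals, and the ancestry
concentration alpha is updated by a Metropolis step.  A no-admixture
variant assigns whole individuals to single clusters.

The independent-frequencies prior is a deliberate simplification of the
correlated-frequencies model used by the STRUCTURE program; the sampler is
validated by recovery of known groupings in simulated data rather than by
replicating any particular program's output.  L(K) is reported as the
posterior mean of the data log-likelihood; the number of clusters is
summarised both by L(K) and by the Evanno second-order statistic Delta-K,
and no single K is auto-selected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genodata import MISSING, GenotypeTable


@dataclass
class McmcSettings:
    burnin: int = 5_000
    iterations: int = 50_000
    seed: int = 0
    thin: int = 10
    alpha_init: float = 1.0
    alpha_proposal_sd: float = 0.25
    alpha_max: float = 10.0


@dataclass
class SingleRun:
    k: int
    q: np.ndarray  # (n_individuals, K) posterior-mean ancestry
    loglik_trace: np.ndarray
    mean_loglik: float
    seed: int
    model: str


@dataclass
class ClusterResult:
    k: int
    q_mean: pd.DataFrame
    site_means: pd.DataFrame
    logliks: list[float]
    mean_loglik: float
    sd_loglik: float
    runs: list[SingleRun] = field(repr=False, default_factory=list)


def _flatten(table: GenotypeTable):
    """Allele copies as flat arrays: individual index, locus index,
    per-locus allele code."""
    ind_idx, loc_idx, codes = [], [], []
    offsets = []
    n_codes = []
    for j in range(table.n_loci):
        col = table.calls[:, j, :]
        alleles = np.unique(col[col != MISSING])
        lut = {a: i for i, a in enumerate(alleles.tolist())}
        n_codes.append(len(alleles))
        for c in range(2):
            scored = col[:, c] != MISSING
            ind_idx.append(np.flatnonzero(scored))
            loc_idx.append(np.full(scored.sum(), j))
            codes.append(np.array([lut[a] for a in col[scored, c]], dtype=np.int64))
    return (
        np.concatenate(ind_idx),
        np.concatenate(loc_idx),
        np.concatenate(codes),
        n_codes,
    )


def fit_admixture(
    table: GenotypeTable,
    k: int,
    mcmc: McmcSettings | None = None,
    model: str = "admixture",
) -> SingleRun:
    """One MCMC run of the K-cluster admixture (or no-admixture) model.

    Returns the posterior-mean ancestry matrix Q and the data
    log-likelihood trace (recorded every ``thin`` iterations after
    burn-in).  Missing genotypes are skipped.
    """
    if mcmc is None:
        mcmc = McmcSettings()
    if k < 1:
        raise ValueError("K must be >= 1")
    if k > table.n_individuals:
        raise ValueError("K exceeds the number of individuals")
    if model not in ("admixture", "no_admixture"):
        raise ValueError(f"unknown model {model!r}")

    rng = np.random.default_rng(mcmc.seed)
    n = table.n_individuals
    ind, loc, code, n_codes = _flatten(table)
    n_obs = len(ind)
    n_loci = table.n_loci
    max_codes = max(n_codes) if n_codes else 1

    # flat index of (locus, allele-code) for frequency bookkeeping
    la = loc * max_codes + code

    alpha = mcmc.alpha_init
    q = np.full((n, k), 1.0 / k)
    freqs = rng.dirichlet(np.ones(max_codes), size=(k, n_loci))  # rows over codes
    z = rng.integers(0, k, size=n_obs)

    q_sum = np.zeros((n, k))
    ll_trace = []
    n_kept = 0

    total = mcmc.burnin + mcmc.iterations
    log_unif = None
    for it in range(total):
        # z | q, P
        p_obs = freqs[:, loc, code]  # (k, n_obs)
        if model == "admixture":
            w = q[ind].T * p_obs  # (k, n_obs)
            w_sum = w.sum(axis=0)
            u = rng.random(n_obs) * w_sum
            z = (np.cumsum(w, axis=0) < u).sum(axis=0)
        else:
            # whole-individual assignment: per-individual log-lik per cluster
            logp = np.log(np.maximum(p_obs, 1e-300))
            per_ind = np.zeros((k, n))
            for kk in range(k):
                per_ind[kk] = np.bincount(ind, weights=logp[kk], minlength=n)
            per_ind += np.log(np.maximum(q.T, 1e-300))
            per_ind -= per_ind.max(axis=0, keepdims=True)
            w = np.exp(per_ind)
            w_sum = w.sum(axis=0)
            u = rng.random(n) * w_sum
            zi = (np.cumsum(w, axis=0) < u).sum(axis=0)
            z = zi[ind]

        # P | z  (Dirichlet(1 + counts) per cluster x locus)
        for kk in range(k):
            sel = z == kk
            counts = np.bincount(la[sel], minlength=n_loci * max_codes).reshape(
                n_loci, max_codes
            )
            g = rng.gamma(counts + 1.0)
            freqs[kk] = g / g.sum(axis=1, keepdims=True)
        # mask codes that do not exist at a locus
        for j, nc in enumerate(n_codes):
            if nc < max_codes:
                freqs[:, j, nc:] = 0.0
                s = freqs[:, j, :nc].sum(axis=1, keepdims=True)
                freqs[:, j, :nc] /= np.maximum(s, 1e-300)

        # q | z
        if model == "admixture":
            counts_ik = np.zeros((n, k))
            for kk in range(k):
                counts_ik[:, kk] = np.bincount(ind[z == kk], minlength=n)
            g = rng.gamma(counts_ik + alpha)
            q = g / g.sum(axis=1, keepdims=True)
            # alpha | q by Metropolis (uniform prior on (0, alpha_max])
            prop = alpha + rng.normal(0.0, mcmc.alpha_proposal_sd)
            if 0 < prop <= mcmc.alpha_max:
                logq = np.log(np.maximum(q, 1e-300))

                def dir_ll(a):
                    return n * (math.lgamma(k * a) - k * math.lgamma(a)) + (
                        a - 1.0
                    ) * logq.sum()

                if math.log(rng.random()) < dir_ll(prop) - dir_ll(alpha):
                    alpha = prop
        else:
            counts_k = np.bincount(zi, minlength=k) if k > 1 else np.array([n])
            g = rng.gamma(counts_k + 1.0)
            pi = g / g.sum()
            q = np.tile(pi, (n, 1))

        if it >= mcmc.burnin and (it - mcmc.burnin) % mcmc.thin == 0:
            q_sum += q
            n_kept += 1
            mix = (q[ind].T * freqs[:, loc, code]).sum(axis=0)
            ll_trace.append(float(np.log(np.maximum(mix, 1e-300)).sum()))

    q_mean = q_sum / max(n_kept, 1)
    ll = np.asarray(ll_trace)
    return SingleRun(
        k=k,
        q=q_mean,
        loglik_trace=ll,
        mean_loglik=float(ll.mean()) if len(ll) else math.nan,
        seed=mcmc.seed,
        model=model,
    )


def align_runs(runs: list[SingleRun]) -> np.ndarray:
    """Average Q over replicates after greedy label alignment.

    Cluster columns of each run are matched to the first run by maximal
    column correlation (greedy, without replacement); invariant to any
    label permutation of the individual runs.
    """
    ref = runs[0].q
    k = ref.shape[1]
    total = np.zeros_like(ref)
    for run in runs:
        q = run.q
        perm = [-1] * k
        used = set()
        # greedy best-correlation matching
        cors = np.zeros((k, k))
        for a in range(k):
            for b in range(k):
                x, y = ref[:, a], q[:, b]
                sx, sy = x.std(), y.std()
                cors[a, b] = (
                    float(np.corrcoef(x, y)[0, 1]) if sx > 0 and sy > 0 else 0.0
                )
        for _ in range(k):
            a, b = np.unravel_index(np.argmax(cors), cors.shape)
            perm[a] = b
            cors[a, :] = -np.inf
            cors[:, b] = -np.inf
            used.add(b)
        total += q[:, perm]
    return total / len(runs)


def run_replicates(
    table: GenotypeTable,
    k: int,
    n_reps: int = 10,
    mcmc: McmcSettings | None = None,
    model: str = "admixture",
) -> ClusterResult:
    """Independent seeded replicate runs at one K, aligned and averaged."""
    if mcmc is None:
        mcmc = McmcSettings()
    seeds = np.random.SeedSequence(mcmc.seed).generate_state(n_reps) % (2**31 - 1)
    runs = []
    for s in seeds:
        settings = McmcSettings(
            burnin=mcmc.burnin,
            iterations=mcmc.iterations,
            seed=int(s),
            thin=mcmc.thin,
            alpha_init=mcmc.alpha_init,
            alpha_proposal_sd=mcmc.alpha_proposal_sd,
            alpha_max=mcmc.alpha_max,
        )
        runs.append(fit_admixture(table, k, settings, model))
    q_mean = align_runs(runs)
    qdf = pd.DataFrame(
        q_mean,
        index=table.individuals,
        columns=[f"cluster{c+1}" for c in range(k)],
    )
    qdf.insert(0, "site", list(table.sites))
    site_means = qdf.groupby("site", sort=False).mean(numeric_only=True)
    lls = [r.mean_loglik for r in runs]
    return ClusterResult(
        k=k,
        q_mean=qdf,
        site_means=site_means,
        logliks=lls,
        mean_loglik=float(np.mean(lls)),
        sd_loglik=float(np.std(lls, ddof=1)) if len(lls) > 1 else 0.0,
        runs=runs,
    )


def evanno_delta_k(results: dict[int, ClusterResult]) -> pd.DataFrame:
    """Evanno Delta-K table from replicate mean log-likelihoods per K.

    Delta-K(K) = |L(K+1) - 2 L(K) + L(K-1)| / sd(L(K)); defined only for
    interior K with positive replicate sd.  The returned frame carries the
    Delta-K argmax in ``attrs["delta_k_choice"]`` and the L(K) argmax in
    ``attrs["lk_choice"]``; selection between them is left to the analyst.
    """
    ks = sorted(results)
    rows = []
    for k in ks:
        res = results[k]
        dk = math.nan
        if k - 1 in results and k + 1 in results and res.sd_loglik > 0:
            dk = abs(
                results[k + 1].mean_loglik
                - 2 * res.mean_loglik
                + results[k - 1].mean_loglik
            ) / res.sd_loglik
        rows.append(
            {
                "K": k,
                "mean_LK": res.mean_loglik,
                "sd_LK": res.sd_loglik,
                "delta_K": dk,
            }
        )
    df = pd.DataFrame(rows)
    interior = df.dropna(subset=["delta_K"])
    df.attrs["delta_k_choice"] = (
        int(interior.loc[interior["delta_K"].idxmax(), "K"]) if len(interior) else None
    )
    df.attrs["lk_choice"] = int(df.loc[df["mean_LK"].idxmax(), "K"])
    return df


def export_structure(table: GenotypeTable, path) -> None:
    """Write genotypes in the two-rows-per-individual STRUCTURE format
    (-9 for missing) for users of the original program."""
    with open(path, "w") as fh:
        fh.write("\t".join(["id", "site"] + list(table.loci)) + "\n")
        site_code = {s: i + 1 for i, s in enumerate(table.site_ids())}
        for i, name in enumerate(table.individuals):
            for c in range(2):
                row = [name, str(site_code[table.sites[i]])]
                for j in range(table.n_loci):
                    a = int(table.calls[i, j, c])
                    row.append(str(a) if a != MISSING else "-9")
                fh.write("\t".join(row) + "\n")
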