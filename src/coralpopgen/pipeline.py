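"""Pipeline orchestration: run every analysis stage on one dataset.

Stage order: clone report (on the full sample) -> null-allele screen ->
per-variant (raw / null-adjusted) diversity + HWE, fished/unfished ANOVA,
clone condensation, differentiation (theta, G'_ST, Jost D) with
permutation tests, AMOVA, PCoA, Mantel isolation by distance, gene-flow
and N_e estimates, and model-based clustering with Evanno's Delta-K.  The
clone report is computed before the minimum-n inclusion filter; all
differentiation and gene-flow statistics are computed on the
clone-condensed, filtered table.

Every artefact is written as TSV (matrices in a dual-triangle layout with
theta below and Jost D above the diagonal, plus tidy long format) and a
machine-readable JSON manifest records all statistics, seeds and problem
sizes.  Identical configuration and seed give a byte-identical manifest.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clonality import annotate_psex, condense_clones, find_mlgs
from .clustering import McmcSettings, evanno_delta_k, run_replicates
from .differentiation import amova, differentiation, mantel_ibd, pcoa
from .diversity import compare_fished, diversity_summary
from .geneflow import ld_ne, nem_private, nem_wright
from .genodata import (
    GenotypeTable,
    filter_min_n,
    prune_metadata,
    read_genepop,
    read_site_metadata,
    write_genepop,
)
from .nulls import apply_oosterhout
from .simdata import preset_study, simulate


@dataclass
class RunConfig:
    genepop: str | None = None
    metadata: str | None = None
    preset: str | None = None
    preset_scale: float = 0.35
    outdir: str = "coralpop_out"
    min_n: int = 12
    permutations: int = 999
    hwe_iterations: int = 10_000
    k_range: tuple[int, int] = (1, 4)
    cluster_reps: int = 3
    mcmc_burnin: int = 500
    mcmc_iterations: int = 2_000
    seed: int = 0
    run_adjusted: bool = True
    run_clustering: bool = True
    pairwise: bool = True

    def __post_init__(self):
        if (self.genepop is None) == (self.preset is None):
            raise ValueError("provide exactly one of genepop or preset as input")


def _dual_triangle(lower: pd.DataFrame, upper: pd.DataFrame) -> pd.DataFrame:
    """Matrix with one statistic below and another above the diagonal."""
    sites = list(lower.index)
    out = pd.DataFrame("", index=sites, columns=sites)
    for i, si in enumerate(sites):
        for j, sj in enumerate(sites):
            if i == j:
                out.iloc[i, j] = "-"
            elif i > j:
                out.iloc[i, j] = f"{max(lower.iloc[i, j], 0.0):.3f}"
            else:
                out.iloc[i, j] = f"{max(upper.iloc[i, j], 0.0):.3f}"
    return out


def _jsonable(x):
    if isinstance(x, dict):
        return {str(k): _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, (np.floating, float)):
        x = float(x)
        if math.isnan(x):
            return None
        if math.isinf(x):
            return "Inf" if x > 0 else "-Inf"
        return x
    if isinstance(x, (np.integer, int)):
        return int(x)
    if isinstance(x, (np.bool_, bool)):
        return bool(x)
    return x


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis and write the report bundle.

    Returns the manifest dictionary (also written as manifest.json).
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": {},
    }

    # ---- load or simulate -------------------------------------------------
    if config.preset is not None:
        cfg = preset_study(config.preset, seed=config.seed, scale=config.preset_scale)
        table, meta, truth = simulate(cfg)
        write_genepop(table, out / "input.gen")
        meta.to_csv(out / "input_metadata.csv", index=False)
        truth.to_json(out / "sim_truth.json")
        manifest["input"] = {"preset": config.preset, "scale": config.preset_scale}
    else:
        meta = read_site_metadata(config.metadata) if config.metadata else None
        site_names = meta["site_id"].tolist() if meta is not None else None
        table = read_genepop(config.genepop, site_names=site_names)
        manifest["input"] = {"genepop": str(config.genepop)}
    manifest["input"]["n_individuals"] = table.n_individuals
    manifest["input"]["n_sites"] = len(table.site_ids())
    manifest["input"]["n_loci"] = table.n_loci

    # ---- clone report on the full, unfiltered sample ----------------------
    report = annotate_psex(table, find_mlgs(table))
    report.mlg_table().to_csv(out / "clone_mlgs.tsv", sep="\t", index=False)
    site_tab = report.site_table()
    site_tab.to_csv(out / "clone_sites.tsv", sep="\t", index=False)
    manifest["stages"]["clonality"] = {
        "n_mlgs": len(report.mlgs),
        "n_repeated": int(sum(m.n_copies > 1 for m in report.mlgs)),
        "mean_R": _jsonable(site_tab["R"].mean()),
        "per_site": _jsonable(site_tab.set_index("site")["R"].to_dict()),
    }

    # ---- null-allele screen ------------------------------------------------
    adj = apply_oosterhout(table, seed=int(rng.integers(2**31 - 1)))
    adj.report().to_csv(out / "null_report.tsv", sep="\t", index=False)
    flagged = [l for l, f in adj.flags.items() if f]
    manifest["stages"]["null_alleles"] = {
        "flagged_loci": flagged,
        "null_labels": _jsonable(adj.null_label),
    }
    variants = {"raw": table}
    if config.run_adjusted and flagged:
        variants["adjusted"] = adj.adjusted
        write_genepop(adj.adjusted, out / "input_adjusted.gen")

    for variant, vtable in variants.items():
        vman: dict = {}
        vdir = out / variant
        vdir.mkdir(exist_ok=True)
        filtered = filter_min_n(vtable, config.min_n)
        vman["sites_after_min_n"] = len(filtered.site_ids())

        # diversity + HWE
        div = diversity_summary(
            filtered,
            hwe_iterations=config.hwe_iterations,
            seed=int(rng.integers(2**31 - 1)),
        )
        div["by_locus"].to_csv(vdir / "diversity_by_locus.tsv", sep="\t", index=False)
        div["by_site"].to_csv(vdir / "diversity_by_site.tsv", sep="\t", index=False)
        defined = div["by_locus"]["hwe_p"].notna()
        vman["hwe"] = {
            "n_tests": int(defined.sum()),
            "n_significant_bonferroni": int(div["by_locus"]["hwe_significant"].sum()),
            "n_deficit": int(
                (
                    (div["by_locus"]["hwe_direction"] == "deficit")
                    & div["by_locus"]["hwe_significant"]
                ).sum()
            ),
        }

        # fished vs unfished ANOVA
        if meta is not None:
            msub = prune_metadata(meta, filtered).set_index("site_id")
            by_site = div["by_site"].set_index("site")
            fished = msub.loc[by_site.index, "fished"]
            anova_rows = []
            for metric in ("A_r", "He_mean"):
                try:
                    res = compare_fished(by_site[metric], fished)
                    res["metric"] = metric
                    anova_rows.append(res)
                except ValueError:
                    pass
            if anova_rows:
                pd.DataFrame(anova_rows).to_csv(
                    vdir / "fished_anova.tsv", sep="\t", index=False
                )
                vman["fished_anova"] = _jsonable(
                    {r["metric"]: {"F": r["F"], "p": r["p"]} for r in anova_rows}
                )

        # condense clones, then differentiation
        vreport = find_mlgs(filtered)
        condensed = condense_clones(filtered, vreport)
        write_genepop(condensed, vdir / "condensed.gen")
        diff_results = {}
        for stat in ("FST_WC", "GST_Hedrick_std", "D_Jost"):
            res = differentiation(
                condensed,
                statistic=stat,
                n_perm=config.permutations,
                seed=int(rng.integers(2**31 - 1)),
                pairwise=config.pairwise,
            )
            diff_results[stat] = res
            if res.pairwise is not None:
                res.pairwise.to_csv(vdir / f"pairwise_{stat}.tsv", sep="\t")
                res.pairwise_p.to_csv(vdir / f"pairwise_{stat}_p.tsv", sep="\t")
        if config.pairwise:
            _dual_triangle(
                diff_results["FST_WC"].pairwise, diff_results["D_Jost"].pairwise
            ).to_csv(vdir / "matrix_fst_jostd.tsv", sep="\t")
        vman["differentiation"] = {
            stat: {"global": _jsonable(r.global_value), "p": _jsonable(r.global_p)}
            for stat, r in diff_results.items()
        }

        # AMOVA by seamount
        if meta is not None:
            msub = prune_metadata(meta, condensed)
            group_of = dict(zip(msub["site_id"], msub["seamount"]))
            sites = condensed.site_ids()
            groups = {group_of[s] for s in sites}
            replicated = any(
                sum(group_of[s] == g for s in sites) > 1 for g in groups
            )
            if len(groups) >= 2 and replicated:
                am = amova(
                    condensed,
                    group_of,
                    n_perm=min(config.permutations, 499),
                    seed=int(rng.integers(2**31 - 1)),
                )
                am.table().to_csv(vdir / "amova.tsv", sep="\t", index=False)
                vman["amova"] = _jsonable(
                    {
                        "phi_ct": am.phi_ct,
                        "phi_sc": am.phi_sc,
                        "phi_st": am.phi_st,
                        "p_ct": am.p_ct,
                        "p_sc": am.p_sc,
                        "p_st": am.p_st,
                    }
                )

        # PCoA on pairwise theta
        if config.pairwise and len(condensed.site_ids()) >= 3:
            fst = diff_results["FST_WC"].pairwise.clip(lower=0.0)
            coords, frac = pcoa(fst)
            coords.to_csv(vdir / "pcoa_coordinates.tsv", sep="\t")
            vman["pcoa_eigen_fractions"] = _jsonable(list(frac[:3]))

        # Mantel IBD
        if (
            meta is not None
            and config.pairwise
            and len(condensed.site_ids()) >= 4
        ):
            ibd = mantel_ibd(
                diff_results["FST_WC"].pairwise,
                prune_metadata(meta, condensed),
                n_perm=config.permutations,
                seed=int(rng.integers(2**31 - 1)),
            )
            vman["mantel"] = _jsonable(
                {"r": ibd.mantel_r, "r2": ibd.r_squared, "p": ibd.p_value}
            )

        # gene flow + Ne
        gf = {}
        fst_global = diff_results["FST_WC"].global_value
        w = nem_wright(fst_global) if not math.isnan(fst_global) else None
        if w:
            gf["nem_wright"] = _jsonable(w.nem)
        pa = nem_private(condensed)
        gf["nem_private"] = _jsonable(pa.nem)
        gf["p1"] = _jsonable(pa.inputs["p1"])
        ne_rows = []
        for site in condensed.site_ids():
            idx = condensed.site_indices(site)
            try:
                ne = ld_ne(condensed.calls[idx])
                ne_rows.append(
                    {
                        "site": site,
                        "Ne": "Inf" if math.isinf(ne.ne) else round(ne.ne, 2),
                        "r2_mean": ne.r2_mean,
                        "ci_lo": "Inf" if math.isinf(ne.ci[0]) else round(ne.ci[0], 2),
                        "ci_hi": "Inf" if math.isinf(ne.ci[1]) else round(ne.ci[1], 2),
                    }
                )
            except ValueError:
                ne_rows.append({"site": site, "Ne": None})
        pd.DataFrame(ne_rows).to_csv(vdir / "ne_ld.tsv", sep="\t", index=False)
        finite = [r["Ne"] for r in ne_rows if isinstance(r["Ne"], float)]
        gf["ld_ne_sites_finite"] = len(finite)
        gf["ld_ne_sites_infinite"] = sum(1 for r in ne_rows if r["Ne"] == "Inf")
        vman["geneflow"] = gf
        pd.DataFrame([gf]).to_csv(vdir / "geneflow.tsv", sep="\t", index=False)

        # clustering
        if config.run_clustering:
            kmin, kmax = config.k_range
            results = {}
            base_seed = int(rng.integers(2**31 - 1))
            for k in range(kmin, kmax + 1):
                res = run_replicates(
                    condensed,
                    k,
                    n_reps=config.cluster_reps,
                    mcmc=McmcSettings(
                        burnin=config.mcmc_burnin,
                        iterations=config.mcmc_iterations,
                        seed=base_seed + k,
                        thin=10,
                    ),
                )
                results[k] = res
                res.q_mean.to_csv(vdir / f"q_matrix_K{k}.tsv", sep="\t")
            ev = evanno_delta_k(results)
            ev.to_csv(vdir / "evanno.tsv", sep="\t", index=False)
            vman["clustering"] = {
                "LK": _jsonable({int(k): results[k].mean_loglik for k in results}),
                "delta_k_choice": _jsonable(ev.attrs["delta_k_choice"]),
                "lk_choice": _jsonable(ev.attrs["lk_choice"]),
            }

        manifest["stages"][variant] = vman

    text = json.dumps(_jsonable(manifest), indent=1, sort_keys=True)
    (out / "manifest.json").write_text(text + "\n")
    return manifest


def make_fixtures(outdir: str, seed: int = 0, scale: float = 0.2) -> dict[str, Path]:
    """Write reduced-scale preset datasets (GenePop + metadata + truth)
    for test and demonstration use."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written = {}
    for preset in ("solenosmilia_like", "desmophyllum_like"):
        cfg = preset_study(preset, seed=seed, scale=scale)
        table, meta, truth = simulate(cfg)
        base = out / preset
        write_genepop(table, f"{base}.gen")
        meta.to_csv(f"{base}_metadata.csv", index=False)
        truth.to_json(f"{base}_truth.json")
        written[preset] = Path(f"{base}.gen")
    return written
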