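"""End-to-end orchestration of the three discovery analyses.

From one configuration (synthetic-generation blocks and/or file paths) the
pipeline runs: (1) the primary analysis — trio inheritance model
intersected with the tissue-correlated coexpression module; (2) the
secondary analysis — heat-diffusion subnetworks with permutation
significance, replicated by weighted burden testing in the singleton
cohort; (3) the catalog contrast — carrier counts in a known-gene list
compared between case and control trios by Fisher's exact test and
Monte-Carlo permutation, with a negative-control list.  Artifacts and a
run manifest are written per stage so every reported number is traceable.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, burden, coexpression, hotnet, io, stats, trio
from .simulate import (
    BurdenSet,
    CohortConfig,
    ConfigError,
    ExpressionModuleSpec,
    MafSpectrum,
    gene_names,
    simulate_expression_atlas,
    simulate_ppi_network,
    simulate_singleton_cohort,
    simulate_trio_cohort,
)

log = logging.getLogger(__name__)


class DataError(ValueError):
    """Raised when supplied input files are unusable."""


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, dict):
        return {str(k): _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    return x


def build_cohort_config(block: dict) -> CohortConfig:
    block = dict(block)
    if "maf_spectrum" in block and isinstance(block["maf_spectrum"], dict):
        block["maf_spectrum"] = MafSpectrum(**block["maf_spectrum"])
    if "burden_sets" in block:
        block["burden_sets"] = tuple(
            BurdenSet(**b) if isinstance(b, dict) else b for b in block["burden_sets"]
        )
    try:
        return CohortConfig(**block)
    except TypeError as e:
        raise ConfigError(str(e)) from e


def run_discovery(config: dict, outdir) -> dict:
    """Execute the full discovery flow; returns the report dict.

    ``config`` keys (all optional unless noted): ``seed``; ``cohort``
    (CohortConfig fields, or ``vcf``/``ped`` paths); ``coexpression``
    (atlas block); ``network`` (PPI block); ``thresholds``; ``gene_lists``
    (paths to known / negative-control / blacklist files).  Partial results
    are written as each stage completes; a stage failure raises StageError
    naming the stage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    thresholds = {
        "maf_max": 0.03,
        "depth_min": 8,
        "quality_min": 0.5,
        "network_maf_max": hotnet.NETWORK_MAF_MAX,
        "beta": hotnet.DEFAULT_BETA,
        "delta": None,
        "n_perm": 100,
        "alpha": 0.05,
        "n_pcs": 4,
        "mc_perm": 999,
    }
    thresholds.update(config.get("thresholds", {}))
    report: dict = {"seed": seed, "thresholds": _jsonable(thresholds)}
    manifest = {
        "package": "oligoheart",
        "version": __version__,
        "numpy": np.__version__,
        "seed": seed,
        "parameters": _jsonable(thresholds),
        "artifacts": [],
    }

    def _emit(name, producer):
        manifest["artifacts"].append({"file": name, "produced_by": producer})

    # ------------------------------------------------ stage: cohort
    stage = "trio_inheritance"
    try:
        cblock = dict(config.get("cohort", {}))
        if "vcf" in cblock:
            cohort = io.read_trio_vcf(cblock["vcf"], cblock["ped"])
            ccfg = None
        else:
            cblock.setdefault("seed", seed)
            ccfg = build_cohort_config(cblock)
            cohort = simulate_trio_cohort(ccfg)
            io.write_trio_vcf(cohort, outdir / "trios.vcf", outdir / "trios.ped")
            _emit("trios.vcf", "simulate_trio_cohort")
        blacklist = None
        gl = config.get("gene_lists", {})
        if gl.get("blacklist"):
            blacklist = trio.Blacklist.from_file(gl["blacklist"])

        case_calls = trio.cohort_to_calls(cohort, phenotype=2)
        ctrl_calls = trio.cohort_to_calls(cohort, phenotype=1)
        fkw = dict(
            maf_max=thresholds["maf_max"],
            depth_min=thresholds["depth_min"],
            quality_min=thresholds["quality_min"],
            blacklist=blacklist,
        )
        case_f = trio.filter_variants(case_calls, **fkw)
        ctrl_f = trio.filter_variants(ctrl_calls, **fkw)
        case_events = trio.classify_inheritance(case_f, cohort.trios)
        ctrl_events = trio.classify_inheritance(ctrl_f, cohort.trios)
        _, case_summary = trio.collate_by_gene(case_events)
        _, ctrl_summary = trio.collate_by_gene(ctrl_events)
        qc = trio.qc_statistics(case_calls)
        case_events.to_csv(outdir / "events_case.tsv", sep="\t", index=False)
        ctrl_events.to_csv(outdir / "events_control.tsv", sep="\t", index=False)
        _emit("events_case.tsv", "classify_inheritance")
        _emit("events_control.tsv", "classify_inheritance")
        with open(outdir / "qc.json", "w") as fh:
            json.dump(_jsonable(qc), fh, indent=1)
        _emit("qc.json", "qc_statistics")
        report["inheritance"] = {
            "case_summary": case_summary,
            "control_summary": ctrl_summary,
            "qc": _jsonable(qc),
        }
        if len(case_events) == 0 and len(ctrl_events) == 0:
            report["inheritance"]["note"] = "no qualifying events; downstream contrasts skipped"
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    universe = gene_names(max(1, -(-len(cohort.sites) // (ccfg.sites_per_gene if ccfg else 10))))
    universe = sorted(set(universe) | set(cohort.sites["gene"]))

    # ------------------------------------------------ stage: coexpression
    stage = "coexpression"
    try:
        xblock = dict(config.get("coexpression", {}))
        n_genes = int(xblock.get("n_genes", min(1500, len(universe))))
        n_tissues = int(xblock.get("n_tissues", 22))
        target_tissue = xblock.get("target_tissue", "AV_canal")
        tissue_list = [target_tissue] + [f"tissue{i:02d}" for i in range(2, n_tissues + 1)]
        module_genes = xblock.get("module_genes")
        if module_genes is None:
            module_genes = list(config.get("cohort", {}).get("planted_genes", ()))[:30]
        specs = []
        if module_genes:
            specs.append(
                ExpressionModuleSpec(
                    name="target", genes=tuple(module_genes), tissue=target_tissue,
                    strength=float(xblock.get("strength", 3.0)),
                )
            )
        counts, design, assignment = simulate_expression_atlas(
            n_genes=n_genes,
            n_tissues=n_tissues,
            module_spec=specs,
            seed=seed,
            libs_per_tissue=int(xblock.get("libs_per_tissue", 3)),
            tissue_names=tissue_list,
        )
        norm = coexpression.normalize_and_collapse(counts)
        modules, module_assignment = coexpression.build_modules(
            norm,
            soft_power=int(xblock.get("soft_power", 6)),
            min_module_size=int(xblock.get("min_module_size", 10)),
        )
        coexpression.module_tissue_correlation(modules, design)
        target_modules = [m for m in modules if m.best_tissue == target_tissue]
        target_module = target_modules[0] if target_modules else None
        module_assignment.to_csv(outdir / "modules.tsv", sep="\t")
        _emit("modules.tsv", "build_modules")
        hits = []
        enrich_p = None
        if target_module is not None:
            hits = coexpression.intersect_module_with_events(
                target_module, case_events, mode_filter="de_novo"
            )
            known = module_genes
            if known:
                k = len(set(known) & set(target_module.members))
                enrich_p = stats.hypergeom_upper(
                    k, len(known), len(target_module.members), len(norm)
                )
        report["coexpression"] = {
            "n_modules": len(modules),
            "target_module_size": len(target_module.members) if target_module else 0,
            "target_module_best_tissue": target_module.best_tissue if target_module else None,
            "de_novo_intersection": hits,
            "known_gene_enrichment_p": enrich_p,
        }
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    # ------------------------------------------------ stage: subnetworks
    stage = "hot_subnetworks"
    try:
        nblock = dict(config.get("network", {}))
        net_genes = sorted(set(cohort.sites["gene"]))
        n_nodes = int(nblock.get("n_nodes", min(800, len(net_genes))))
        planted = list(config.get("cohort", {}).get("planted_genes", ()))
        node_pool = sorted(set(planted) | set(net_genes[:n_nodes]))[:n_nodes]
        graph = simulate_ppi_network(
            n_nodes=len(node_pool),
            attachment=int(nblock.get("attachment", 3)),
            planted_module=[g for g in planted if g in node_pool],
            seed=seed,
            node_names=node_pool,
        )
        hot_calls = trio.filter_variants(
            case_calls, maf_max=thresholds["network_maf_max"],
            depth_min=thresholds["depth_min"], quality_min=thresholds["quality_min"],
            blacklist=blacklist,
        )
        hot_events = trio.classify_inheritance(hot_calls, cohort.trios)
        heat = hotnet.heat_from_events(hot_events)
        F, nodes = hotnet.diffusion_matrix(graph, thresholds["beta"])
        h = hotnet.heat_vector(heat, nodes)
        n_perm = int(nblock.get("n_perm", thresholds["n_perm"]))
        rng = np.random.default_rng(seed + 7001)
        perms = [hotnet.permute_network(graph, seed=int(rng.integers(2**31))) for _ in range(n_perm)]
        delta = thresholds["delta"]
        if delta is None:
            cand = hotnet.select_delta(perms[: min(n_perm, 20)], heat, thresholds["beta"],
                                       size_targets=(int(nblock.get("size_target", 8)),))
            delta = next(iter(cand.values())) or 0.0
        subs = hotnet.extract_subnetworks(F, h, delta, nodes)
        perm_subs = []
        for g in perms:
            Fp, nodesp = hotnet.diffusion_matrix(g, thresholds["beta"])
            hp = hotnet.heat_vector(heat, nodesp)
            perm_subs.append(hotnet.extract_subnetworks(Fp, hp, delta, nodesp))
        sig = hotnet.subnetwork_significance(subs, perm_subs)
        with open(outdir / "subnetworks.json", "w") as fh:
            json.dump(
                _jsonable(
                    {
                        "delta": delta,
                        "subnetworks": [{"members": s.members, "size": s.size} for s in subs],
                        "significance_by_size": sig,
                    }
                ),
                fh,
                indent=1,
            )
        _emit("subnetworks.json", "extract_subnetworks")
        report["subnetworks"] = {
            "delta": float(delta),
            "n_subnetworks": len(subs),
            "n_genes": len({g for s in subs for g in s.members}),
            "significance_by_size": _jsonable(sig),
        }
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    # ------------------------------------------------ stage: burden replication
    stage = "burden_replication"
    try:
        if ccfg is not None and (ccfg.n_singleton_cases + ccfg.n_singleton_controls) > 0:
            singles = simulate_singleton_cohort(ccfg)
            pcs = burden.genotype_pca(singles.G, k=int(thresholds["n_pcs"]))
            rows = []
            for s in subs:
                vmask = singles.variants["gene"].isin(s.members).to_numpy()
                vmask &= singles.variants["consequence"].isin(trio.PROTEIN_ALTERING).to_numpy()
                if vmask.sum() == 0:
                    continue
                res = burden.skat_linear_weighted(
                    singles.G[:, vmask], singles.y, X=pcs,
                    mafs=singles.variants["maf"].to_numpy()[vmask],
                )
                rows.append({"genes": ",".join(s.members), "n_variants": res.n_variants,
                             "Q": res.Q, "p": res.p_value})
            btab = pd.DataFrame(rows)
            if len(btab):
                thr, flags = burden.bonferroni_control(btab["p"].to_numpy(), thresholds["alpha"])
                btab["significant"] = flags
                _, inflation = burden.qq_diagnostics(btab["p"].to_numpy()) if len(btab) > 1 else (None, None)
            else:
                thr, inflation = None, None
            btab.to_csv(outdir / "burden.tsv", sep="\t", index=False)
            _emit("burden.tsv", "skat_linear_weighted")
            report["burden"] = {
                "n_sets_tested": int(len(btab)),
                "bonferroni_threshold": thr,
                "significant_sets": btab[btab["significant"]]["genes"].tolist() if len(btab) else [],
                "inflation_factor": inflation,
            }
        else:
            report["burden"] = {"note": "no singleton cohort configured; skipped"}
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    # ------------------------------------------------ stage: catalog contrast
    stage = "catalog_contrast"
    try:
        gl = config.get("gene_lists", {})
        known = io.read_gene_list(gl["known"]) if gl.get("known") else list(
            config.get("cohort", {}).get("planted_genes", ())
        )
        case_ids = cohort.trios[cohort.trios.phenotype == 2]["child"].tolist()
        ctrl_ids = cohort.trios[cohort.trios.phenotype == 1]["child"].tolist()
        case_inc = trio.incidence_matrix(case_events, case_ids, universe)
        ctrl_inc = trio.incidence_matrix(ctrl_events, ctrl_ids, universe)
        gidx = {g: i for i, g in enumerate(universe)}
        known_idx = [gidx[g] for g in known if g in gidx]
        if known_idx and len(case_events) + len(ctrl_events) > 0:
            table = stats.carrier_table(case_inc, ctrl_inc, known_idx)
            fisher_p = stats.fisher_exact(table, "one_tailed")
            mc = stats.montecarlo_geneset_p(
                case_inc, ctrl_inc, known_idx,
                n_perm=int(thresholds["mc_perm"]), seed=seed + 9001,
            )
            neg = gl.get("negative_control")
            neg_result = None
            if neg:
                neg_genes = io.read_gene_list(neg)
                neg_idx = [gidx[g] for g in neg_genes if g in gidx]
                ntab, np_ = stats.negative_control_contrast(case_inc, ctrl_inc, neg_idx, known_idx)
                neg_result = {"table": ntab, "p": np_}
            report["catalog"] = _jsonable(
                {
                    "carrier_table": table,
                    "fisher_one_tailed_p": fisher_p,
                    "montecarlo_p": mc.empirical_p,
                    "montecarlo_r": mc.r,
                    "montecarlo_n": mc.n,
                    "negative_control": neg_result,
                }
            )
        else:
            report["catalog"] = {"note": "no known-gene carriers or no events; test skipped"}
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    with open(outdir / "report.json", "w") as fh:
        json.dump(_jsonable(report), fh, indent=1)
    _emit("report.json", "run_discovery")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(_jsonable(manifest), fh, indent=1)
    return report
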