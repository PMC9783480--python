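"""End-to-end orchestration: ingest (or simulate) -> effect sizes ->
uncertainty -> multilevel fits -> permutation tests -> paired comparison ->
report, with a reproducibility manifest.

All randomness derives from one master seed via fixed per-stage offsets.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
import numpy as np
import pandas as pd

from . import __version__
from .datatypes import BootstrapConfig, PermutationConfig
from .effect_size import compute_effects, corpus_diagnostics
from .errors import PipelineError
from .io_ingest import (
    apply_inclusion_rules,
    read_primary_table,
    read_species_mapping,
    read_tree,
    resolve_species,
    write_effect_table,
    write_primary_table,
    write_reject_report,
    write_tree,
    TableDialect,
)
from .permutation import (
    paired_temp_diet_test,
    permutation_test_moderator,
    permutation_test_overall,
    standardize_slopes,
)
from .phylo_meta import fit_meta, phylo_correlation, subgroup_fits, variance_partition
from .synthetic import SimulationConfig, simulate_corpus
from .uncertainty import attach_uncertainty

# fixed per-stage seed offsets so stages stay decoupled
_STAGE_SEEDS = {"bootstrap": 11, "perm_overall": 23, "perm_moderator": 37,
                "paired": 53, "simulate": 71}


def _stage_seed(master: int, stage: str) -> int:
    ss = np.random.SeedSequence(entropy=master, spawn_key=(_STAGE_SEEDS[stage],))
    return int(ss.generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _fit_to_dict(fit) -> dict:
    d = {
        "mu_hat": fit.mu_hat, "se_mu": fit.se_mu,
        "beta_hat": fit.beta_hat, "se_beta": fit.se_beta,
        "sigma2_phylo": fit.sigma2_phylo, "sigma2_study": fit.sigma2_study,
        "sigma2_obs": fit.sigma2_obs, "z_stat": fit.z_stat,
        "p_param": fit.p_param, "p_perm": fit.p_perm,
        "phylo_var_share": fit.phylo_var_share, "n_effects": fit.n_effects,
        "converged": fit.converged, "loglik_reml": fit.loglik_reml,
        "moderator": fit.moderator,
    }
    d["variance_shares"] = variance_partition(fit)
    return d


@dataclass
class ReportBundle:
    output_dir: Path
    report: dict
    manifest: dict


def run_pipeline(config: dict) -> ReportBundle:
    """Run the full analysis from a config dict (see README for the schema).

    The config must contain either an ``inputs:`` section (primary_table,
    optional tree/mapping paths) or a ``simulate:`` section with
    :class:`SimulationConfig` fields.  Total and larval traits are analyzed
    as separate corpora throughout.
    """
    seed = int(config.get("seed", 0))
    out_dir = Path(config.get("output_dir", "dtmeta_out"))
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": seed,
        "config": config,
        "stage_seeds": {s: _stage_seed(seed, s) for s in _STAGE_SEEDS},
        "inputs": {},
        "counts": {},
    }

    # ------------------------------------------------------------------ ingest
    phylo = None
    mapping = None
    rejects = None
    if "simulate" in config:
        sim_conf = dict(config["simulate"])
        paired = sim_conf.pop("paired_diet", None)
        sim_conf.setdefault("seed", _stage_seed(seed, "simulate"))
        cfg = SimulationConfig(**sim_conf)
        diet_cfg = None
        if paired is not None:
            diet_over = dict(paired) if isinstance(paired, dict) else {}
            diet_conf = asdict(cfg)
            diet_conf.update(diet_over)
            diet_conf.update({"diet_mode": True,
                              "gradient_fold": diet_over.get("gradient_fold", 1.28),
                              "seed": cfg.seed + 1})
            diet_cfg = SimulationConfig(**diet_conf)
        corpus = simulate_corpus(cfg, paired_diet_cfg=diet_cfg)
        datasets = corpus.datasets
        phylo = corpus.tree
        write_primary_table(datasets, out_dir / "simulated_corpus.csv")
        write_tree(phylo, out_dir / "simulated_tree.nwk")
        (out_dir / "truth.json").write_text(json.dumps(corpus.truth, indent=2))
    elif "inputs" in config:
        inputs = config["inputs"]
        table_path = Path(inputs["primary_table"])
        dialect = TableDialect(**inputs.get("dialect", {}))
        ingest = read_primary_table(table_path, dialect)
        datasets = ingest.datasets
        rejects = ingest.rejects
        manifest["inputs"]["primary_table"] = {
            "path": str(table_path), "sha256": _sha256(table_path)}
        if "tree" in inputs:
            phylo = read_tree(inputs["tree"])
            manifest["inputs"]["tree"] = {
                "path": str(inputs["tree"]), "sha256": _sha256(Path(inputs["tree"]))}
        if "mapping" in inputs:
            mapping = read_species_mapping(inputs["mapping"])
            manifest["inputs"]["mapping"] = {
                "path": str(inputs["mapping"]), "sha256": _sha256(Path(inputs["mapping"]))}
    else:
        raise PipelineError("config needs an 'inputs' or 'simulate' section")

    if rejects is not None and len(rejects):
        write_reject_report(rejects, out_dir / "rejects.csv")
    manifest["counts"]["rows_rejected"] = 0 if rejects is None else int(len(rejects))
    manifest["counts"]["datasets_ingested"] = len(datasets)

    # --------------------------------------------------------------- inclusion
    incl = apply_inclusion_rules(datasets)
    manifest["counts"].update({
        "datasets_quantitative": len(incl.included),
        "datasets_qualitative_only": len(incl.qualitative_only),
        "datasets_excluded": len(incl.excluded),
    })

    # ------------------------------------------------------------ effect sizes
    effects, failures = compute_effects(incl.analyzable)
    manifest["counts"]["effects_computed"] = len(effects)
    manifest["counts"]["effects_failed"] = len(failures)
    boot_conf = config.get("bootstrap", {})
    boot_cfg = BootstrapConfig(
        n_reps=int(boot_conf.get("n_reps", 1000)),
        width_rule=boot_conf.get("width_rule", "sd_matched"),
        seed=_stage_seed(seed, "bootstrap"),
        degenerate_floor=float(boot_conf.get("degenerate_floor", 1e-8)),
    )
    quant_ids = {ds.dataset_id for ds in incl.included}
    attach_uncertainty(effects, incl.analyzable, boot_cfg)
    write_effect_table(effects, out_dir / "effects.csv")

    diagnostics = corpus_diagnostics(effects)
    report: dict = {"diagnostics": diagnostics, "fits": {}, "tests": {},
                    "effect_failures": failures}

    # ------------------------------------------------------- correlation matrix
    corr = None
    tip_by_species = None
    if phylo is not None:
        tip_by_species, unmapped, subs = resolve_species(
            [ds for ds in incl.included], mapping, phylo,
            strict=bool(config.get("strict_species", True)))
        manifest["counts"]["species_unmapped"] = len(unmapped)
        manifest["species_substitutions"] = subs
        tips = sorted(set(tip_by_species.values()))
        corr_tips = phylo_correlation(
            phylo, tips=tips,
            branch_rule=config.get("branch_rule", "grafen"))
        # re-key the matrix by data species name (congener tips stand in)
        import numpy as _np
        species = sorted(tip_by_species)
        idx = {t: i for i, t in enumerate(corr_tips.species)}
        ix = _np.array([idx[tip_by_species[sp]] for sp in species])
        from .datatypes import PhyloCorrelation
        m = corr_tips.matrix[_np.ix_(ix, ix)].copy()
        _np.fill_diagonal(m, 1.0)
        corr = PhyloCorrelation(tuple(species), m)

    # --------------------------------------------------------------- model fits
    run = config.get("run", {})
    perm_conf = config.get("permutation", {})
    n_perms = int(perm_conf.get("n_perms", 1000))
    recompute = bool(perm_conf.get("recompute_variances", False))
    temp_effects = [e for e in effects
                    if e.factor == "temperature" and e.boot_sd is not None]
    for trait in ("total", "larval"):
        sub = [e for e in temp_effects if e.trait == trait]
        if len(sub) < 2:
            continue
        sub_corr = corr.submatrix(sorted({e.species for e in sub})) if corr else None
        entry: dict = {}
        fit0 = fit_meta(sub, sub_corr)
        entry["overall"] = _fit_to_dict(fit0)
        if run.get("overall_permutation", True):
            sub_ds = [ds for ds in incl.included
                      if ds.trait == trait and ds.factor == "temperature"]
            res = permutation_test_overall(
                sub_ds, sub_corr,
                PermutationConfig(n_perms=n_perms,
                                  seed=_stage_seed(seed, "perm_overall")),
                boot_cfg=boot_cfg, recompute_variances=recompute)
            entry["overall"]["p_perm"] = res.p_perm
            pd.DataFrame({"z_null": res.null_z}).to_csv(
                out_dir / f"null_overall_{trait}.csv", index=False)
        if run.get("moderator", True):
            try:
                fit1 = fit_meta(sub, sub_corr, moderator="sdtd")
                entry["moderator"] = _fit_to_dict(fit1)
                if run.get("moderator_permutation", True):
                    res = permutation_test_moderator(
                        sub, sub_corr,
                        PermutationConfig(n_perms=n_perms,
                                          seed=_stage_seed(seed, "perm_moderator")))
                    entry["moderator"]["p_perm"] = res.p_perm
                    pd.DataFrame({"z_null": res.null_z}).to_csv(
                        out_dir / f"null_moderator_{trait}.csv", index=False)
            except Exception as exc:
                entry["moderator"] = {"error": str(exc)}
        if run.get("subgroups", True):
            table, _, skipped = subgroup_fits(sub, sub_corr)
            table.to_csv(out_dir / f"subgroups_{trait}.csv", index=False)
            entry["subgroups"] = {
                "table": table.to_dict(orient="records"),
                "skipped": [{"group": g, "reason": r} for g, r in skipped],
            }
        report["fits"][trait] = entry

    # ----------------------------------------------------- paired factor test
    if run.get("paired", False):
        pairs, skipped = standardize_slopes(
            [e for e in effects if e.boot_sd is not None],
            std_rule=config.get("std_rule", "none"))
        if len(pairs) >= 2:
            res = paired_temp_diet_test(
                pairs,
                PermutationConfig(n_perms=n_perms,
                                  seed=_stage_seed(seed, "paired")),
                exclusions=config.get("exclude_species", ()))
            res.table.to_csv(out_dir / "paired_table.csv", index=False)
            report["tests"]["paired_temp_diet"] = {
                "statistic": res.statistic, "p_perm": res.p_perm,
                "n_pairs": int(len(res.table)), "n_excluded": res.n_excluded,
                "n_skipped_species": len(skipped),
                "n_larger_temperature": int(
                    (res.table["larger_factor"] == "temperature").sum()),
            }
        else:
            report["tests"]["paired_temp_diet"] = {
                "error": "fewer than 2 species pairs available"}

    (out_dir / "report.json").write_text(
        json.dumps(report, indent=2, default=_json_default))
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=_json_default))
    return ReportBundle(output_dir=out_dir, report=report, manifest=manifest)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, float) and math.isnan(obj):
        return None
    raise TypeError(f"not JSON serializable: {type(obj)}")
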