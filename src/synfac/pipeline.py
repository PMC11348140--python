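"""End-to-end orchestration: simulate -> decompose -> group stats ->
factors -> associations -> transcriptomics (-> dynamics), with a single
validated configuration and a machine-readable report.

The configuration is one nested mapping (YAML or dict); unknown keys are
rejected up front so silent typos cannot change an analysis.  Every
stage writes its tables under ``out_dir`` and contributes a summary to
``report.json``.  Identical config + seed produces identical numeric
outputs.
"""
from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .errors import ConfigError
from .util import sym_to_vec

_DEFAULTS = {
    "out_dir": "synfac_out",
    "seed": 0,
    "simulate": {
        "n_cortical": 43,
        "n_subcortical": 7,
        "n_nc": 60,
        "n_scz": 60,
        "T": 240,
        "K": 3,
        "effect": 0.6,
        "n_sites": 3,
        "n_genes": 600,
        "n_planted": 60,
        "gene_noise_sd": 0.5,
        "sc_density": 0.1,
    },
    "phid": {"tau": 1},
    "groupdiff": {"covariates": ["age", "gender", "motion", "site"], "fdr_q": 0.05},
    "factors": {"K": 3, "scale": 10.0, "alpha": None, "eta": 0.01, "runs": 5,
                "max_iter": 100, "select_k": False, "k_grid": [2, 3, 4],
                "n_splits": 5},
    "associate": {"enabled": True},
    "genes": {"enabled": True, "n_top": 60, "n_bottom": 60, "n_surrogates": 200},
    "sa": {"n_surrogates": 200},
    "pmfm": {"enabled": False, "duration": 100.0, "burn_in": 30.0, "window": 12,
             "stride": 3, "generations": 16, "n_cortical": 30},
}


def _merge(defaults: dict, user: dict, path="") -> dict:
    out = {}
    for key, val in defaults.items():
        if key in user:
            uval = user[key]
            if isinstance(val, dict):
                if not isinstance(uval, dict):
                    raise ConfigError(f"config field '{path}{key}' must be a mapping")
                out[key] = _merge(val, uval, path=f"{path}{key}.")
            else:
                out[key] = uval
        else:
            out[key] = val
    unknown = set(user) - set(defaults)
    if unknown:
        raise ConfigError(
            f"unknown config field(s) {sorted(unknown)} at '{path or 'top level'}'"
        )
    return out


@dataclass
class RunConfig:
    settings: dict

    @classmethod
    def from_dict(cls, user: dict) -> "RunConfig":
        return cls(settings=_merge(_DEFAULTS, user or {}))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def __getitem__(self, key):
        return self.settings[key]


@dataclass
class RunReport:
    seed: int
    stages: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    wall_time_s: float = 0.0

    def to_json(self, path):
        payload = {
            "seed": self.seed,
            "stages": self.stages,
            "outputs": self.outputs,
            "warnings": self.warnings,
            "wall_time_s": self.wall_time_s,
        }
        Path(path).write_text(json.dumps(payload, indent=2, default=float))


def validate_inputs(paths: dict) -> list[str]:
    """Cross-check a data bundle: shapes, headers, region order, NaNs."""
    problems = []
    parc = None
    if "parcellation" in paths:
        try:
            parc = sio.read_parcellation(paths["parcellation"])
        except Exception as exc:  # noqa: BLE001 - report, don't raise
            problems.append(f"parcellation unreadable: {exc}")
    if parc is not None and "timeseries" in paths:
        for ts in sio.read_timeseries(paths["timeseries"]):
            if ts.n_regions != parc.n_regions:
                problems.append(
                    f"{ts.subject_id}: {ts.n_regions} regions vs parcellation "
                    f"{parc.n_regions}"
                )
            if not np.all(np.isfinite(ts.data)):
                problems.append(f"{ts.subject_id}: non-finite values")
    if parc is not None and "expression" in paths:
        expr = pd.read_csv(paths["expression"], sep="\t", index_col=0)
        if expr.shape[0] != parc.n_regions:
            problems.append(
                f"expression has {expr.shape[0]} regions vs parcellation "
                f"{parc.n_regions}"
            )
        if expr.isna().any().any():
            problems.append("expression contains missing values")
    if parc is not None and "sc" in paths:
        sc = sio.read_matrix(paths["sc"])
        if sc.shape[0] != parc.n_regions:
            problems.append(f"sc is {sc.shape[0]}x{sc.shape[1]} vs parcellation")
    return problems


def run_pipeline(config: RunConfig | dict) -> RunReport:
    from .association import clinical_correlations, glm_contrast, rsa_compare
    from .cohortstats import group_t_map, network_summary, regional_profile
    from .factors import (
        assign_subtype,
        factor_map,
        fit_lda,
        match_factors,
        prepare_documents,
        select_k,
        znormalize_to_controls,
    )
    from .infodynamics import functional_connectivity, pairwise_interaction_matrices
    from .synthdata import (
        make_parcellation,
        simulate_cohort,
        simulate_gene_expression,
        simulate_structural,
    )
    from .transcripto import (
        coexpression_factor_corr,
        coexpression_matrix,
        gene_factor_correlations,
        select_risk_genes,
        virtual_knockout,
    )

    if isinstance(config, dict):
        config = RunConfig.from_dict(config)
    cfg = config.settings
    t_start = time.time()
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    report = RunReport(seed=seed)

    # --- simulate -----------------------------------------------------
    sim = cfg["simulate"]
    parc = make_parcellation(sim["n_cortical"], sim["n_subcortical"], seed=seed)
    cohort, series, truth = simulate_cohort(
        parc, n_nc=sim["n_nc"], n_scz=sim["n_scz"], T=sim["T"], K=sim["K"],
        effect=sim["effect"], seed=seed + 1, n_sites=sim["n_sites"],
    )
    truth_maps = truth.factor_maps(parc.n_regions)
    expr, planted_genes = simulate_gene_expression(
        parc, n_genes=sim["n_genes"], factor_maps=truth_maps,
        n_planted=sim["n_planted"], noise_sd=sim["gene_noise_sd"], seed=seed + 2,
    )
    truth.risk_gene_index = planted_genes
    sc, myelin, gradient = simulate_structural(
        parc, density=sim["sc_density"], seed=seed + 3
    )
    sio.write_dataset(out / "data", cohort, series, parc, expr, sc, myelin,
                      gradient, truth)
    report.stages["simulate"] = {
        "n_subjects": len(cohort), "n_regions": parc.n_regions,
    }

    # --- pairwise information decomposition ---------------------------
    tau = int(cfg["phid"]["tau"])
    groups = cohort["group"].to_numpy()
    syn_mats, red_mats, fc_mats = [], [], []
    for ts in series:
        s, r = pairwise_interaction_matrices(ts, tau=tau)
        syn_mats.append(s)
        red_mats.append(r)
        fc_mats.append(functional_connectivity(ts))
    report.stages["phid"] = {"tau": tau, "n_pairs": len(sym_to_vec(syn_mats[0].values))}

    # --- group differences --------------------------------------------
    gd = cfg["groupdiff"]
    covs = cohort[gd["covariates"]]
    maps = {}
    for kind, mats in (("synergy", syn_mats), ("redundancy", red_mats), ("fc", fc_mats)):
        diff = group_t_map(mats, groups, covs)
        prof = regional_profile(diff)
        maps[kind] = {"diff": diff, "profile": prof}
        sio.write_matrix(out / f"tmap_{kind}.tsv", diff.t_values, parc.region_id)
        pd.DataFrame({"region_id": parc.region_id, "t_mean": prof}).to_csv(
            out / f"regional_profile_{kind}.tsv", sep="\t", index=False
        )
    net = network_summary(maps["synergy"]["profile"], np.asarray(parc.network))
    net.to_csv(out / "network_summary_synergy.tsv", sep="\t", index=False)
    report.stages["groupdiff"] = {
        kind: {"regional_t_mean": float(maps[kind]["profile"].mean())}
        for kind in maps
    }

    # --- latent factors ------------------------------------------------
    fc_cfg = cfg["factors"]
    is_scz = groups == "SCZ"
    z = znormalize_to_controls(
        [m for m, s in zip(syn_mats, is_scz) if s],
        [m for m, s in zip(syn_mats, is_scz) if not s],
    )
    docs = prepare_documents(z, scale=float(fc_cfg["scale"]))
    if fc_cfg["select_k"]:
        chosen_k, k_table = select_k(
            docs, K_grid=tuple(fc_cfg["k_grid"]), n_splits=fc_cfg["n_splits"],
            seed=seed + 4,
        )
        k_table.to_csv(out / "stability.tsv", sep="\t", index=False)
    else:
        chosen_k = int(fc_cfg["K"])
    models = [
        fit_lda(docs, K=chosen_k, alpha=fc_cfg["alpha"], eta=fc_cfg["eta"],
                seed=seed + 10 + r, max_iter=fc_cfg["max_iter"])
        for r in range(int(fc_cfg["runs"]))
    ]
    bounds = np.array([m.final_bound for m in models])
    model = models[int(np.argmax(bounds))]
    perm, match_r = match_factors(truth.factor_patterns, model.patterns)
    fmaps = np.stack([factor_map(model, k) for k in range(model.K)])
    subtypes, ties = assign_subtype(model.loadings)
    pd.DataFrame(model.patterns).to_csv(out / "patterns.tsv", sep="\t", index=False)
    pd.DataFrame(model.loadings).to_csv(out / "loadings.tsv", sep="\t", index=False)
    pd.DataFrame(fmaps.T, columns=[f"factor{k}" for k in range(model.K)]).to_csv(
        out / "factor_maps.tsv", sep="\t", index=False
    )
    report.stages["factors"] = {
        "K": chosen_k,
        "planted_match_r": [float(v) for v in match_r],
        "loading_match_r": [
            float(np.corrcoef(truth.loadings[:, k], model.loadings[:, perm[k]])[0, 1])
            for k in range(chosen_k)
        ],
    }

    # --- clinical associations -----------------------------------------
    if cfg["associate"]["enabled"]:
        scz = cohort[is_scz].reset_index(drop=True)
        raw_z = np.stack([sym_to_vec(m.z) for m in z])
        chars = scz[["age", "gender", "site", "PANSS_pos", "PANSS_neg", "PANSS_gen"]]
        rsa = rsa_compare(
            [m.loadings for m in models], raw_z, chars, run_bounds=bounds
        )
        rsa.to_csv(out / "rsa.tsv", sep="\t", index=False)
        clin = clinical_correlations(
            model.loadings,
            scz[["PANSS_pos", "PANSS_neg", "PANSS_gen"]],
            covariates=scz[["age", "gender", "motion"]],
            sites=scz["site"].to_numpy(),
        )
        clin.to_csv(out / "clinical_correlations.tsv", sep="\t", index=False)
        glm_rows = []
        for char in ("age", "motion"):
            y = scz[char].to_numpy(float)
            for H, lab in (([0, -1, 1], "f1_vs_f2"), ([0, 1, 0], "f1_vs_f3"),
                           ([0, 0, 1], "f2_vs_f3")):
                est, t, p = glm_contrast(y, model.loadings, H)
                glm_rows.append({"characteristic": char, "contrast": lab,
                                 "estimate": est, "t": t, "p": p})
        pd.DataFrame(glm_rows).to_csv(out / "glm_contrasts.tsv", sep="\t", index=False)
        overall = clin[clin["site"] == "overall"]
        report.stages["associate"] = {
            "overall_r": {
                f"factor{int(row.factor)}:{row.scale}": round(float(row.r), 4)
                for row in overall.itertuples()
            }
        }

    # --- transcriptomics ------------------------------------------------
    if cfg["genes"]["enabled"]:
        g = cfg["genes"]
        dist = parc.distance_matrix()
        union_all = []
        gene_summary = {}
        for k in range(model.K):
            rs = gene_factor_correlations(expr, fmaps[k])
            top, bottom, union = select_risk_genes(rs, g["n_top"], g["n_bottom"])
            union_all.extend(union)
            gene_summary[f"factor{k}"] = {"n_top": len(top), "n_bottom": len(bottom)}
            rs.to_csv(out / f"gene_factor_r_{k}.tsv", sep="\t")
        union_all = list(dict.fromkeys(union_all))
        (out / "risk_sets.txt").write_text("\n".join(union_all) + "\n")
        coexp = coexpression_matrix(expr[union_all])
        r0, p_sa = coexpression_factor_corr(
            coexp, fmaps[0], dist, n_surrogates=g["n_surrogates"], seed=seed + 5
        )
        gci = virtual_knockout(expr[union_all], fmaps[0])
        gci.to_csv(out / "gci.tsv", sep="\t")
        report.stages["genes"] = {
            "risk_union": len(union_all),
            "coexpr_factor0_r": float(r0),
            "coexpr_factor0_p_sa": float(p_sa),
            **gene_summary,
        }

    # --- dynamic mean-field fit -----------------------------------------
    if cfg["pmfm"]["enabled"]:
        from .dynamics import fcd as fcd_fn
        from .dynamics import optimize_pmfm, param_diff_factor_corr

        pm = cfg["pmfm"]
        dist = parc.distance_matrix()
        nc_mask = parc.is_cortical
        n_c = min(int(pm["n_cortical"]), int(nc_mask.sum()))
        idx = np.flatnonzero(nc_mask)[:n_c]
        sc_c = sc[np.ix_(idx, idx)]
        mye_c, grad_c = myelin[idx], gradient[idx]
        results = {}
        for gname in ("NC", "SCZ"):
            sel = [k for k, grp in enumerate(groups) if grp == gname][:10]
            fc_emp = np.mean(
                [np.corrcoef(series[k].data[:, idx].T) for k in sel], axis=0
            )
            params, res = optimize_pmfm(
                sc_c, mye_c, grad_c, fc_emp, None,
                duration=pm["duration"], burn_in=pm["burn_in"],
                window=pm["window"], stride=pm["stride"],
                max_generations=pm["generations"], seed=seed + 6,
            )
            results[gname] = {"params": params, "cost": res.f_best}
        from .dynamics import regional_params

        W_scz, I_scz, _ = regional_params(mye_c, grad_c, results["SCZ"]["params"])
        W_nc, I_nc, _ = regional_params(mye_c, grad_c, results["NC"]["params"])
        table = param_diff_factor_corr(
            {"W": W_scz, "I": I_scz}, {"W": W_nc, "I": I_nc},
            fmaps[:, idx], dist[np.ix_(idx, idx)],
            n_surrogates=cfg["sa"]["n_surrogates"], seed=seed + 7,
        )
        table.to_csv(out / "pmfm_factor_corr.tsv", sep="\t", index=False)
        report.stages["pmfm"] = {
            g: {"cost": float(results[g]["cost"])} for g in results
        }

    report.wall_time_s = time.time() - t_start
    report.outputs = {p.name: str(p) for p in sorted(out.glob("*.tsv"))}
    report.to_json(out / "report.json")
    return report
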