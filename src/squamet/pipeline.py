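"""End-to-end analysis: corrections -> scaling fits -> ANOVAs -> path analysis.

``run_all`` executes the full sequence on a trait table and tree and writes
a report bundle of five tables mirroring the analysis outputs: the
OLS/PGLS scaling comparison, the two factorial sequential ANOVAs
(temperature-corrected SMR against mass; mass-corrected SMR against inverse
thermal energy), the path-model CICc ranking, and the averaged best paths.
Tables are written as TSV at 3 decimals with a full-precision JSON sidecar,
plus a run log holding the resolved config, seed, and input checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dsep, mte, phylo_gls, trait_data

logger = logging.getLogger("squamet")


class PipelineError(RuntimeError):
    """A stage failure; the message names the stage."""


@dataclass
class AnalysisConfig:
    traits_path: str
    tree_path: str
    dag_config_path: str | None = None
    branch_length_policy: str = "as_is"  # "as_is" or "equal:<value>"
    lambda_policies: tuple = (0.0, 1.0, "ml")
    mte_fixed_b: float | None = None
    mte_fixed_E: float | None = None
    outdir: str = "squamet_out"
    seed: int = 0
    anova_lambda_policy: str | float = "ml"
    path_lambda_policy: str | float = "ml"
    # path analysis needs residual variation in SMR beyond (lnM, 1/kT);
    # exactly noise-free inputs make its claim regressions rank deficient
    include_paths: bool = True

    def __post_init__(self) -> None:
        if not self.lambda_policies:
            raise ValueError("at least one lambda policy is required")


@dataclass
class ReportBundle:
    scaling: pd.DataFrame
    anova_tsmr: pd.DataFrame
    anova_msmr: pd.DataFrame
    path_ranking: pd.DataFrame
    path_averaged: pd.DataFrame
    mte_fit: mte.MTEFit
    files: dict = field(default_factory=dict)


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _scaling_rows(y, x, name_y, name_x, V0, policies):
    """One fit per lambda policy for a simple regression y ~ x, with AIC
    deltas and an LRT of the ML-lambda fit against the lambda = 0 fit."""
    n = len(y)
    X = np.column_stack([np.ones(n), x])
    fits = {}
    for pol in policies:
        if pol == "ml":
            fit = phylo_gls.fit_lambda_ml(
                y, X, phylo_gls.PhyloCovariance(V0, list(range(n))),
                term_names=["intercept", name_x], response=name_y,
            )
        else:
            lam = float(pol)
            V = None if lam == 0.0 else phylo_gls.lambda_transform(V0, lam)
            fit = phylo_gls.gls_fit(
                y, X, V, term_names=["intercept", name_x], response=name_y, lambda_=lam
            )
        fits[pol] = fit
    lrt = None
    if "ml" in fits and 0.0 in fits:
        lrt = phylo_gls.likelihood_ratio_test(fits[0.0], fits["ml"])
    rows = []
    for pol, fit in fits.items():
        dof = fit.n - fit.p
        F = fit.tstat[1] ** 2
        rows.append(
            {
                "model": f"{name_y} ~ {name_x}",
                "lambda_policy": str(pol),
                "n": fit.n,
                "slope": fit.coef[1],
                "se": fit.se[1],
                "r2": fit.r2,
                "lambda": fit.lambda_ if fit.lambda_ is not None else np.nan,
                "lambda_lo": fit.lambda_ci[0] if fit.lambda_ci else np.nan,
                "lambda_hi": fit.lambda_ci[1] if fit.lambda_ci else np.nan,
                "aic": fit.aic,
                "lnL": fit.lnL,
                "F": F,
                "F_df1": 1,
                "F_df2": dof,
                "P": fit.pvalues[1],
                "lrt_vs_lambda0_p": lrt.p_value if (lrt and pol == "ml") else np.nan,
            }
        )
    return rows


def run_all(config: AnalysisConfig) -> ReportBundle:
    """Execute every stage and write the report bundle to config.outdir.

    Any stage failure raises :class:`PipelineError` naming the stage, and
    files written by earlier stages of the failed run are removed.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        return _run_all(config, outdir, written)
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(f"{getattr(exc, '_stage', 'pipeline')}: {exc}") from exc


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except Exception as exc:
                exc._stage = name
                raise

        return wrapped

    return deco


def _write_table(df: pd.DataFrame, path: Path, written: list[Path]) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.3f")
    sidecar = path.with_suffix(".json")
    sidecar.write_text(df.to_json(orient="records", indent=2) + "\n")
    written.extend([path, sidecar])


def _run_all(config: AnalysisConfig, outdir: Path, written: list[Path]) -> ReportBundle:
    # --- load ---
    load = _stage("load")(lambda: (
        trait_data.read_trait_table(config.traits_path),
        trait_data.read_newick(Path(config.tree_path).read_text()),
    ))
    table, tree = load()
    if config.branch_length_policy.startswith("equal"):
        value = 1.0
        if ":" in config.branch_length_policy:
            value = float(config.branch_length_policy.split(":", 1)[1])
        tree = trait_data.set_branch_lengths_equal(tree, value)
    elif config.branch_length_policy != "as_is":
        raise PipelineError(f"load: unknown branch_length_policy {config.branch_length_policy!r}")
    align = _stage("align")(trait_data.align)
    table, tree = align(table, tree, policy="prune")
    n = len(table)

    # --- MTE fit and corrections ---
    fit_stage = _stage("mte")(mte.fit_mte)
    mte_fit = fit_stage(table, fixed_b=config.mte_fixed_b, fixed_E=config.mte_fixed_E)
    corr = mte.correct(table, mte_fit)

    # --- scaling fits (OLS / fixed-lambda / ML-lambda PGLS) ---
    V0 = phylo_gls.vcv_from_tree(tree).matrix
    scaling = _stage("scaling")(
        lambda: pd.DataFrame(
            _scaling_rows(corr.t_smr, corr.ln_mass, "tSMR", "ln_mass", V0, config.lambda_policies)
            + _scaling_rows(corr.m_smr, corr.inv_kT, "mSMR", "inv_kT", V0, config.lambda_policies)
        )
    )()

    # --- factorial sequential ANOVAs ---
    data = pd.DataFrame(
        {
            "R": [1 if r.reproductive_mode == "viviparous" else 0 for r in table],
            "G": [1 if r.clade == "snake" else 0 for r in table],
            "ln_mass": corr.ln_mass,
            "inv_kT": corr.inv_kT,
            "t_smr": corr.t_smr,
            "m_smr": corr.m_smr,
            "ln_smr": corr.ln_smr,
        }
    )
    anova = _stage("anova")(phylo_gls.sequential_anova)
    terms_t = ["R", "G", "ln_mass", "R:G", "R:ln_mass", "G:ln_mass", "R:G:ln_mass"]
    terms_m = ["R", "G", "inv_kT", "R:G", "R:inv_kT", "G:inv_kT", "R:G:inv_kT"]
    pc = phylo_gls.PhyloCovariance(V0, table.species)
    anova_t = anova("t_smr", terms_t, data, pc, config.anova_lambda_policy)
    anova_m = anova("m_smr", terms_m, data, pc, config.anova_lambda_policy)

    # --- path analysis ---
    if config.dag_config_path:
        dags = dsep.parse_dag_config(Path(config.dag_config_path).read_text())
    else:
        dags = dsep.default_candidate_dags()
    path_data = pd.DataFrame(
        {
            "M": corr.ln_mass,
            "SMR": corr.ln_smr,
            "G": data["G"],
            "R": data["R"],
            "invkT": corr.inv_kT,
        }
    )
    if config.include_paths:
        paths_stage = _stage("paths")(dsep.run_path_analysis)
        ranked, averaged = paths_stage(
            dags, path_data, pc, lambda_policy=config.path_lambda_policy, seed=config.seed
        )
        ranking_df = dsep.ranking_frame(ranked)
        averaged_df = averaged.to_frame()
    else:
        ranking_df = pd.DataFrame(
            columns=["model", "k", "q", "C", "p", "CICc", "dCICc", "weight"]
        )
        averaged_df = pd.DataFrame(columns=["path", "coef", "lo95", "hi95"])

    # --- write bundle ---
    bundle = ReportBundle(
        scaling=scaling,
        anova_tsmr=anova_t.to_frame(),
        anova_msmr=anova_m.to_frame(),
        path_ranking=ranking_df,
        path_averaged=averaged_df,
        mte_fit=mte_fit,
    )
    tables = {
        "scaling.tsv": bundle.scaling,
        "anova_tsmr.tsv": bundle.anova_tsmr,
        "anova_msmr.tsv": bundle.anova_msmr,
        "path_ranking.tsv": bundle.path_ranking,
        "path_averaged.tsv": bundle.path_averaged,
    }
    for fname, df in tables.items():
        path = outdir / fname
        _write_table(df, path, written)
        bundle.files[fname] = path
    summary_path = outdir / "mte_fit.txt"
    summary_path.write_text(mte.fit_summary(mte_fit))
    written.append(summary_path)
    bundle.files["mte_fit.txt"] = summary_path
    log_path = outdir / "run_log.json"
    resolved = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(config).items()
        },
        "seed": config.seed,
        "n_species": n,
        "inputs": {
            "traits_sha256": _sha256(config.traits_path),
            "tree_sha256": _sha256(config.tree_path),
        },
        "anova_lambda": {"tSMR": anova_t.lambda_, "mSMR": anova_m.lambda_},
    }
    log_path.write_text(json.dumps(resolved, indent=2, sort_keys=True) + "\n")
    written.append(log_path)
    bundle.files["run_log.json"] = log_path
    return bundle
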