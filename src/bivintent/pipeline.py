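"""End-to-end orchestration: data -> factor scores -> models -> report tables.

Each stage writes its outputs under the run directory; ``run_pipeline`` is
what the ``bivintent run`` command calls and what the worked example in the
README executes on synthetic data.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import bbg, cumlogit, descriptives, factors, reporting
from .config import RunConfig
from .dataset import (
    RISK_ITEMS, TRUST_ITEMS, SurveyDataset, read_survey, write_table,
)
from .design import DEFAULT_REFERENCES, DesignSpec
from .simulate import SyntheticConfig, generate_survey


def derive_scores(ds: SurveyDataset, tercile_bounds=None):
    """Factor scores and categorical codings used as model covariates.

    Adds ``risk_score``/``trust_score`` (Thomson factor scores) and the
    categorical ``risk_cat``/``trust_cat``/``doubts_cat`` columns to a copy
    of the table; returns (table, factor models, codings).
    """
    tercile_bounds = tercile_bounds or {}
    df = ds.table.copy()
    models = {}
    codings = {}
    for name, items, labels in (
        ("risk", RISK_ITEMS, ("Low", "Medium", "High")),
        ("trust", TRUST_ITEMS, ("Low", "Medium", "High")),
    ):
        model = factors.fit_single_factor(df[items])
        score = factors.compute_scores(model, df[items])
        df[f"{name}_score"] = score
        coding, cats = factors.categorize_terciles(
            score, labels=labels, variable=f"{name}_cat",
            bounds=tuple(tercile_bounds[name]) if name in tercile_bounds else None,
        )
        df[f"{name}_cat"] = cats.astype(str)
        models[name] = model
        codings[f"{name}_cat"] = coding
    coding, cats = factors.categorize_doubts(df["vaccine_doubts"])
    df["doubts_cat"] = cats.astype(str)
    codings["doubts_cat"] = coding
    return df, models, codings


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write all artefacts under ``config.output_dir``."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.write_manifest(out)

    if config.input:
        ds = read_survey(config.input, schema=config.schema or None)
    else:
        ds = generate_survey(SyntheticConfig(n=config.synthetic_n, seed=config.seed))

    df, fmodels, codings = derive_scores(ds, config.tercile_bounds)

    # descriptive layer
    blocks = descriptives.table_one(
        df, group="doubts_cat",
        continuous=["age", "vaccine_intent", "cta_intent", "trust_score",
                    "trust_local", "self_efficacy", "conspiracy", "risk_score"],
        categorical=["gender", "education", "family_status", "job", "salary",
                     "flu_vaccine_2019", "covid_contact"],
        seed=config.seed,
    )
    write_table(descriptives.summaries_to_frame(blocks), out / "table1.csv")
    rho, pvals = descriptives.spearman_matrix(
        df, ["trust_score", "vaccine_doubts", "risk_score", "trust_local",
             "self_efficacy", "conspiracy"],
    )
    write_table(rho.reset_index(), out / "spearman_rho.csv")
    wstat, wp = descriptives.paired_wilcoxon(
        df["vaccine_intent"].to_numpy(), df["cta_intent"].to_numpy()
    )

    # joint intention model
    mcmc = bbg.MCMCConfig(
        iterations=config.mcmc_iterations, burnin=config.mcmc_burnin,
        seed=config.seed,
    )
    responses = ("vaccine_intent", "cta_intent")
    if config.run_selection:
        spec, trace = bbg.forward_select(
            config.bbg_covariates, df, responses=responses, config=mcmc
        )
        write_table(trace, out / "bbg_selection_trace.csv")
    else:
        spec = DesignSpec.shared(config.bbg_covariates)
    fit, draws, dic_value = bbg.fit_and_dic(spec, df, responses, mcmc)
    summary = bbg.summarize(draws, dic_value=dic_value)
    table2, footnotes = reporting.render_table2(
        summary, codings,
        references={k: v for k, v in DEFAULT_REFERENCES.items()
                    if k in spec.all_terms()},
    )
    write_table(summary.table, out / "bbg_posterior.csv")
    write_table(table2, out / "table2.csv")
    (out / "table2_footnotes.txt").write_text("\n".join(footnotes) + "\n")
    write_table(reporting.residual_qq(draws), out / "bbg_qq.csv")
    if "s(age)" in spec.all_terms():
        for block in ("mu1", "mu2", "rhogit"):
            write_table(
                bbg.spline_effect(draws, block, "age"),
                out / f"age_effect_{block}.csv",
            )

    # motivation model
    long = cumlogit.reshape_long(SurveyDataset(table=df))
    motiv_fit = cumlogit.fit_cumlogit(
        long, covariates=config.motivation_covariates,
        references=DEFAULT_REFERENCES,
    )
    or_table = cumlogit.odds_ratios(motiv_fit)
    write_table(reporting.render_table3(or_table), out / "table3.csv")

    # conspiracy model (fixed effects)
    consp_fit, consp_or = cumlogit.fit_conspiracy(
        df, covariates=config.conspiracy_covariates,
        references=DEFAULT_REFERENCES,
    )
    write_table(reporting.render_table3(consp_or), out / "conspiracy_or.csv")

    return {
        "dataset": ds,
        "table": df,
        "factor_models": fmodels,
        "codings": codings,
        "wilcoxon": (wstat, wp),
        "spearman": rho,
        "bbg_fit": fit,
        "bbg_draws": draws,
        "bbg_summary": summary,
        "dic": dic_value,
        "motivation_fit": motiv_fit,
        "motivation_or": or_table,
        "conspiracy_fit": consp_fit,
        "conspiracy_or": consp_or,
        "output_dir": out,
    }
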