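"""Umbrella pipeline: cohort -> reliability + comparison reports.

Given (or generating) a cohort of triplicate readings, the pipeline writes
per-site reliability reports, sex and age comparison tables, site-mean
rollups, and a provenance JSON (configuration echo, package and library
versions, seed) from which the run can be reproduced exactly.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .compare import GroupSummary
from .io import RunConfig, read_cohort, subject_site_means, write_cohort
from .normative import AGE_GROUP_NUMBERS, AGE_GROUPS, cohort_spec_from_normative
from .reliability import analyze_repeated
from .report import (
    age_comparison_table,
    reliability_table,
    rollup_report,
    sex_comparison_table,
    to_markdown,
)
from .synth import make_cohort, readings_matrix

log = logging.getLogger("cartizone")


def _site_key(side: str, region: str) -> str:
    return f"{side}_{region}"


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the bundle of output paths."""
    logging.basicConfig(
        level=config.log_level,
        format="%(levelname)s %(name)s %(message)s",
        stream=sys.stderr,
    )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.cohort_csv:
        log.info("stage=load cohort=%s", config.cohort_csv)
        cohort = read_cohort(config.cohort_csv)
    else:
        log.info("stage=simulate seed=%d sem_pct=%.2f",
                 config.seed, config.synth_sem_pct)
        spec = cohort_spec_from_normative(
            seed=config.seed,
            sem_pct=config.synth_sem_pct,
            between_subject_sd=config.synth_between_sd,
        )
        cohort = make_cohort(spec)
        write_cohort(cohort, out / "cohort.csv")

    sites = sorted(
        cohort[["side", "site"]].drop_duplicates()
        .itertuples(index=False, name=None)
    )

    # reliability per site
    rel_results = []
    for side, region in sites:
        mat = readings_matrix(cohort, side, region)
        rel_results.append(
            analyze_repeated(mat, site=_site_key(side, region),
                             alpha=config.alpha,
                             cv_variant=config.cv_variant)
        )
        log.info("stage=reliability site=%s seed=%d n=%d",
                 _site_key(side, region), config.seed, mat.shape[0])
    rel_df = reliability_table(rel_results)
    rel_df.to_csv(out / "reliability.csv", index=False)

    # subject-level means for comparisons
    subj = subject_site_means(cohort)

    sex_summaries, age_summaries, age_raw = {}, {}, {}
    site_mean_all: dict[str, float] = {}
    site_mean_by_sex: dict[str, dict[str, float]] = {"female": {}, "male": {}}
    for side, region in sites:
        key = _site_key(side, region)
        sub = subj[(subj.side == side) & (subj.site == region)]
        site_mean_all[key] = float(sub.thickness_mm.mean())
        sex_groups = {}
        for sex in ("female", "male"):
            vals = sub[sub.sex == sex].thickness_mm.to_numpy()
            if len(vals) >= 2:
                sex_groups[sex] = vals
                site_mean_by_sex[sex][key] = float(vals.mean())
        if len(sex_groups) == 2:
            sex_summaries[key] = GroupSummary.from_groups(sex_groups, site=key)
        groups = {}
        for g in AGE_GROUPS:
            vals = sub[sub.age_group == g].thickness_mm.to_numpy()
            if len(vals) >= 2:
                groups[AGE_GROUP_NUMBERS[g]] = vals
        if len(groups) >= 2:
            age_raw[key] = groups
            age_summaries[key] = GroupSummary.from_groups(groups, site=key)
        log.info("stage=compare site=%s seed=%d", key, config.seed)

    sex_df = sex_comparison_table(sex_summaries, variant=config.t_variant,
                                  tiers=config.sig_tiers)
    sex_df.to_csv(out / "comparison_sex.csv", index=False)
    age_df = age_comparison_table(age_summaries, raw_groups=age_raw,
                                  alpha=config.alpha, tiers=config.sig_tiers)
    age_df.to_csv(out / "comparison_age.csv", index=False)

    rollups = {
        "all": rollup_report(site_mean_all),
        "female": rollup_report(site_mean_by_sex["female"]),
        "male": rollup_report(site_mean_by_sex["male"]),
    }
    (out / "rollups.json").write_text(json.dumps(rollups, indent=2))

    report_md = "\n\n".join([
        "# Cartilage thickness report",
        "## Reliability\n" + to_markdown(rel_df),
        "## Sex comparison\n" + to_markdown(sex_df),
        "## Age-group comparison\n" + to_markdown(age_df),
        "## Rollups (mm)\n```json\n" + json.dumps(rollups, indent=2) + "\n```",
    ])
    (out / "report.md").write_text(report_md)

    provenance = {
        "package": "cartizone",
        "version": __version__,
        "seed": config.seed,
        "config": {**config.__dict__, "sig_tiers": list(config.sig_tiers)},
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    log.info("stage=done out=%s seed=%d", out, config.seed)
    return {
        "out_dir": str(out),
        "reliability": rel_results,
        "rollups": rollups,
        "sex_table": sex_df,
        "age_table": age_df,
    }
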