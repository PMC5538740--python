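"""End-to-end orchestration: from chronogram + occurrences to report tables.

``run_analysis`` produces, as pandas DataFrames written to CSV:

1. a richness table per island and period with percent changes and the
   μ = 0 contrast;
2. PD/MPD/MNTD per island × period × scope, with percent-change contrasts;
3. SES summaries (raw SES plus NRI/NTI) with the pooled mean ± 1.96·SE
   interval over islands and the paired t between periods;
4. temporal beta (per island, between periods) and spatial beta matrices
   (within periods) with SES values and Mantel tests against great-circle
   distance;
5. a JSON manifest recording inputs, seed and package version, so that two
   runs with the same seed and inputs are byte-identical.

Fixture mode (``contrast_richness_counts`` / ``contrast_metric_table``)
accepts pre-computed per-island tables — e.g. published richness counts or
PD/MPD/MNTD values — and runs only the contrast layer on them.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .alpha import TreeMetrics, alpha_diversity
from .beta import geo_distance_matrix, mantel, spatial_beta, temporal_beta
from .community import AssemblageSpec, OccurrenceMatrix, Period, Scope, assemble
from .nullses import pooled_interval, ses_profile
from .stats import ChangeSummary, change_summary, paired_t
from .treeio import Phylogeny

__all__ = [
    "PipelineConfig",
    "Report",
    "run_analysis",
    "write_report",
    "contrast_richness_counts",
    "contrast_metric_table",
]

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.6g"  # fixed CSV float format => byte-identical reruns


@dataclass
class PipelineConfig:
    n_rand: int = 999
    rng_seed: int = 0
    scopes: tuple[str, ...] = ("complete", "native_only")
    mantel_permutations: int = 999
    skip_missing: bool = False


@dataclass
class Report:
    """Bundle of result tables; ``tables`` maps name -> DataFrame."""

    tables: dict[str, pd.DataFrame]
    summaries: dict[str, object]
    manifest: dict


def _assemblages(
    matrix: OccurrenceMatrix, period: Period, scope: Scope
) -> dict[str, set[str]]:
    spec = AssemblageSpec(period, scope)
    return {i: assemble(matrix, i, spec) for i in matrix.island_names}


def run_analysis(
    tree: Phylogeny,
    matrix: OccurrenceMatrix,
    config: PipelineConfig | None = None,
) -> Report:
    """Run the full two-period phylogenetic diversity analysis."""
    config = config or PipelineConfig()
    tm = TreeMetrics(tree)
    islands = matrix.island_names
    tables: dict[str, pd.DataFrame] = {}
    summaries: dict[str, object] = {}

    # --- 1. richness ------------------------------------------------------
    logger.info("stage richness: %d islands, %d species", len(islands),
                len(matrix.species))
    pre = _assemblages(matrix, Period.PRE_EUROPEAN, Scope.COMPLETE)
    cur = _assemblages(matrix, Period.CURRENT, Scope.COMPLETE)
    cur_nat = _assemblages(matrix, Period.CURRENT, Scope.NATIVE_ONLY)
    cur_exo = _assemblages(matrix, Period.CURRENT, Scope.EXOTIC_ONLY)
    rich = pd.DataFrame(
        {
            "island": islands,
            "pre_complete": [len(pre[i]) for i in islands],
            "current_complete": [len(cur[i]) for i in islands],
            "current_native": [len(cur_nat[i]) for i in islands],
            "current_exotic": [len(cur_exo[i]) for i in islands],
        }
    )
    tables["richness"] = rich
    summaries["richness_change"] = contrast_richness_counts(rich)

    # --- 2. alpha diversity ----------------------------------------------
    logger.info("stage alpha: PD/MPD/MNTD per island x period x scope")
    rows = []
    period_scopes = [
        (Period.PRE_EUROPEAN, Scope.COMPLETE),
        (Period.CURRENT, Scope.COMPLETE),
        (Period.CURRENT, Scope.NATIVE_ONLY),
        (Period.CURRENT, Scope.EXOTIC_ONLY),
    ]
    for period, scope in period_scopes:
        for island in islands:
            taxa = assemble(matrix, island, AssemblageSpec(period, scope))
            if not taxa:
                logger.warning("alpha: empty assemblage %s/%s on %r; skipped",
                               period.value, scope.value, island)
                continue
            res = alpha_diversity(tm, taxa, skip_missing=config.skip_missing)
            rows.append(
                {
                    "island": island,
                    "period": period.value,
                    "scope": scope.value,
                    "pd": res.pd,
                    "mpd": res.mpd,
                    "mntd": res.mntd,
                    "n_species": res.n_species,
                    "n_matched": res.n_matched,
                }
            )
    alpha_df = pd.DataFrame(rows)
    tables["alpha"] = alpha_df
    summaries["alpha_change"] = contrast_metric_table(alpha_df)

    # --- 3. SES / NRI / NTI -----------------------------------------------
    logger.info("stage ses: %d randomizations", config.n_rand)
    seed_seq = np.random.SeedSequence(config.rng_seed)
    ses_seeds = seed_seq.spawn(len(period_scopes))
    ses_rows = []
    for (period, scope), sub_seed in zip(period_scopes, ses_seeds):
        groups = {
            i: assemble(matrix, i, AssemblageSpec(period, scope)) for i in islands
        }
        groups = {i: t for i, t in groups.items() if len(t) >= 2}
        if not groups:
            continue
        profile = ses_profile(
            tm,
            groups,
            n_rand=config.n_rand,
            rng_seed=np.random.default_rng(sub_seed),
        )
        for island, per_metric in profile.items():
            for metric, res in per_metric.items():
                ses_rows.append(
                    {
                        "island": island,
                        "period": period.value,
                        "scope": scope.value,
                        "metric": metric,
                        "observed": res.observed,
                        "null_mean": res.null_mean,
                        "null_sd": res.null_sd,
                        "ses": res.ses,
                        "nri_or_nti": res.nri_or_nti,
                        "classification": res.classification,
                        "degenerate": res.degenerate,
                    }
                )
    ses_df = pd.DataFrame(ses_rows)
    tables["ses"] = ses_df
    summaries["ses_pooled"] = _pooled_ses_summary(ses_df)
    summaries["ses_paired_t"] = _paired_ses_contrasts(ses_df)

    # --- 4. beta diversity --------------------------------------------------
    logger.info("stage beta: temporal and spatial 1 - PhyloSor")
    beta_seeds = seed_seq.spawn(4)[:]  # independent streams per beta block
    temporal = {}
    for scope in (Scope.COMPLETE, Scope.NATIVE_ONLY):
        temporal[scope.value] = temporal_beta(tm, matrix, scope)
    tables["temporal_beta"] = pd.DataFrame(
        [
            {
                "scope": scope,
                "island": isl,
                "one_minus_phylosor": val,
            }
            for scope, res in temporal.items()
            for isl, val in zip(res.islands, res.values)
        ]
    )
    summaries["temporal_beta"] = temporal

    geo = geo_distance_matrix(matrix.islands)
    spatial = {}
    mantel_results = {}
    spatial_specs = [
        ("pre_european_complete", AssemblageSpec(Period.PRE_EUROPEAN, Scope.COMPLETE)),
        ("current_complete", AssemblageSpec(Period.CURRENT, Scope.COMPLETE)),
        ("current_native", AssemblageSpec(Period.CURRENT, Scope.NATIVE_ONLY)),
    ]
    for (label, spec), bseed in zip(spatial_specs, beta_seeds):
        try:
            bm = spatial_beta(
                tm, matrix, spec, n_rand=config.n_rand,
                rng_seed=np.random.default_rng(bseed),
            )
        except ValueError as exc:
            logger.warning("spatial beta %s skipped: %s", label, exc)
            continue
        spatial[label] = bm
        mantel_results[label] = mantel(
            bm, geo, n_perm=config.mantel_permutations,
            rng_seed=np.random.default_rng(bseed.spawn(1)[0]),
        )
        df = pd.DataFrame(bm.values, index=bm.labels, columns=bm.labels)
        tables[f"beta_{label}"] = df
        if bm.ses_values is not None:
            tables[f"beta_ses_{label}"] = pd.DataFrame(
                bm.ses_values, index=bm.labels, columns=bm.labels
            )
    summaries["spatial_beta"] = spatial
    summaries["mantel"] = mantel_results
    tables["mantel"] = pd.DataFrame(
        [
            {"comparison": k, "r": v.r, "p": v.p, "n_perm": v.n_perm,
             "alternative": v.alternative}
            for k, v in mantel_results.items()
        ]
    )

    manifest = {
        "package": "islephylo",
        "version": __version__,
        "rng_seed": config.rng_seed,
        "n_rand": config.n_rand,
        "mantel_permutations": config.mantel_permutations,
        "n_islands": len(islands),
        "n_species": len(matrix.species),
        "n_tree_tips": tm.tree.n_tips if isinstance(tree, Phylogeny) else None,
    }
    return Report(tables, summaries, manifest)


def _pooled_ses_summary(ses_df: pd.DataFrame) -> pd.DataFrame:
    rows = []
    if ses_df.empty:
        return pd.DataFrame(rows)
    for (period, scope, metric), grp in ses_df.groupby(
        ["period", "scope", "metric"], sort=True
    ):
        vals = grp["ses"].dropna().tolist()
        if not vals:
            continue
        pooled = pooled_interval(vals)
        rows.append(
            {
                "period": period,
                "scope": scope,
                "metric": metric,
                "mean_ses": pooled.mean,
                "se": pooled.se,
                "lower": pooled.lower,
                "upper": pooled.upper,
                "n": pooled.n,
                "classification": pooled.classification,
            }
        )
    return pd.DataFrame(rows)


def _paired_ses_contrasts(ses_df: pd.DataFrame) -> pd.DataFrame:
    """Paired t of SES between periods, per metric, complete & native scopes."""
    rows = []
    if ses_df.empty:
        return pd.DataFrame(rows)
    for metric in sorted(ses_df["metric"].unique()):
        for scope_pair in (
            ("complete", "pre_european", "current", "complete"),
            ("native_only", "pre_european", "current", "native_only"),
        ):
            label, pre_period, cur_period, cur_scope = scope_pair
            pre = ses_df.query(
                "metric == @metric and period == @pre_period and scope == 'complete'"
            ).set_index("island")["ses"]
            cur = ses_df.query(
                "metric == @metric and period == @cur_period and scope == @cur_scope"
            ).set_index("island")["ses"]
            shared = [i for i in pre.index if i in cur.index
                      and pd.notna(pre[i]) and pd.notna(cur[i])]
            if len(shared) < 2:
                continue
            tt = paired_t(pre[shared].tolist(), cur[shared].tolist())
            rows.append(
                {
                    "metric": metric,
                    "contrast": label,
                    "n": len(shared),
                    "t": tt.t,
                    "p": tt.p,
                    "df": tt.df,
                    "degenerate": tt.degenerate,
                }
            )
    return pd.DataFrame(rows)


# -- fixture mode ----------------------------------------------------------


def contrast_richness_counts(table: pd.DataFrame) -> dict[str, ChangeSummary]:
    """Contrast layer on a richness table (fixture mode).

    ``table`` needs columns ``island, pre_complete, current_complete,
    current_native``.  Returns percent-change summaries for the complete
    flora (pre vs current) and for natives (pre vs surviving natives).
    """
    required = {"island", "pre_complete", "current_complete", "current_native"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"richness table missing columns: {sorted(missing)}")
    islands = table["island"].tolist()
    return {
        "complete": change_summary(
            islands, table["pre_complete"], table["current_complete"]
        ),
        "native": change_summary(
            islands, table["pre_complete"], table["current_native"]
        ),
    }


def contrast_metric_table(
    alpha_df: pd.DataFrame, metrics: Sequence[str] = ("pd", "mpd", "mntd")
) -> dict[str, dict[str, ChangeSummary]]:
    """Percent-change contrasts from a long-format alpha table (fixture mode).

    ``alpha_df`` needs columns ``island, period, scope`` plus the metric
    columns; rows for ``pre_european/complete`` are compared against
    ``current/complete`` and ``current/native_only``.
    """
    out: dict[str, dict[str, ChangeSummary]] = {}
    pre = alpha_df.query("period == 'pre_european' and scope == 'complete'")
    pre = pre.set_index("island")
    for label, query in (
        ("complete", "period == 'current' and scope == 'complete'"),
        ("native", "period == 'current' and scope == 'native_only'"),
    ):
        cur = alpha_df.query(query).set_index("island")
        shared = [i for i in pre.index if i in cur.index]
        if len(shared) < 2:
            continue
        out[label] = {}
        for metric in metrics:
            before = pre.loc[shared, metric]
            after = cur.loc[shared, metric]
            ok = before.notna() & after.notna()
            if ok.sum() < 2:
                continue
            out[label][metric] = change_summary(
                [i for i, keep in zip(shared, ok) if keep],
                before[ok], after[ok],
            )
    return out


def write_report(report: Report, out_dir) -> None:
    """Write every table as CSV plus the JSON manifest under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in report.tables.items():
        index = name.startswith("beta_")  # square matrices keep their labels
        df.to_csv(out / f"{name}.csv", index=index, float_format=_FLOAT_FMT)
    with open(out / "manifest.json", "w") as fh:
        json.dump(report.manifest, fh, indent=2, sort_keys=True)
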