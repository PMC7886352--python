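"""End-to-end orchestration: per-individual fits, cohort assembly, and
the cohort report consumed by the CLI."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cohort_report, fitting
from .celldynamics import leukocyte_trend, normalize_counts
from .excision_circles import QpcrMeasurement, replication_history, trec_content
from .io import count_series, enrichment_series
from .labelmodel import LYMPHOCYTE_SUBSETS, granulocyte_scale

logger = logging.getLogger("labelkin")

__all__ = ["IndividualFits", "fit_individual", "fit_cohort", "build_cohort_table",
           "make_report"]


@dataclass
class IndividualFits:
    individual: str
    body_water: fitting.FitResult
    subsets: dict[str, fitting.FitResult] = field(default_factory=dict)

    def rows(self) -> list[dict]:
        rows = self.body_water.param_rows(individual=self.individual,
                                          subset="body_water",
                                          n_components=np.nan)
        for subset, fit in self.subsets.items():
            rows += fit.param_rows(individual=self.individual, subset=subset,
                                   n_components=fit.n_components)
        return rows


def fit_individual(
    enr_df: pd.DataFrame,
    counts_df: pd.DataFrame,
    individual: str,
    tau: float = 42.0,
    seed: int = 0,
    n_boot: int = 0,
    n_starts: int = 12,
    subsets: tuple[str, ...] | None = None,
) -> IndividualFits:
    """Run the full estimation chain for one individual.

    Body-water and granulocyte enrichment are fit jointly; subset
    enrichment is scaled to the fitted granulocyte maximum and fit
    jointly with trend-normalized counts; 1 vs 2 kinetic components is
    decided by F-test; optional residual-bootstrap CIs.
    """
    urine = enrichment_series(enr_df, individual, "urine")
    gran = enrichment_series(enr_df, individual, "granulocytes")
    bw_fit = fitting.fit_body_water_and_granulocytes(
        urine, gran, tau=tau, n_starts=max(n_starts, 16), seed=seed
    )
    logger.info(
        "%s body-water fit: f=%.4f delta=%.3f M=%.4f converged=%s",
        individual, bw_fit.params["f"], bw_fit.params["delta"],
        bw_fit.scale_max, bw_fit.converged,
    )
    if n_boot:
        bw_fit = fitting.bootstrap_body_water(
            bw_fit, urine.times, gran.times, n_boot=n_boot, seed=seed
        )

    cs = count_series(counts_df, individual)
    trend = leukocyte_trend(cs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        normalize_counts(cs, trend)

    result = IndividualFits(individual, bw_fit)
    present = [
        s for s in (subsets or LYMPHOCYTE_SUBSETS)
        if ((enr_df["individual"] == individual)
            & (enr_df["compartment"] == s)).any() and s in cs.normalized
    ]
    for subset in present:
        scaled = granulocyte_scale(bw_fit, enrichment_series(enr_df, individual,
                                                             subset))
        counts = cs.normalized[subset]
        fit1 = fitting.fit_subset(scaled, counts, bw_fit, n_components=1,
                                  n_starts=n_starts, seed=seed)
        fit = fit1
        if len(scaled) >= 8:
            try:
                fit2 = fitting.fit_subset(scaled, counts, bw_fit, n_components=2,
                                          n_starts=max(n_starts, 16), seed=seed)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    if fitting.select_components(fit1, fit2) == 2:
                        fit = fit2
            except fitting.FitFailureError:
                pass
        if n_boot:
            fit = fitting.bootstrap_subset(fit, n_boot=n_boot, seed=seed)
        logger.info(
            "%s/%s: n_comp=%d p_avg=%.5f d=%.5f flags=%s",
            individual, subset, fit.n_components, fit.params["p_avg"],
            fit.params["d"], fit.flags,
        )
        result.subsets[subset] = fit
    return result


def fit_cohort(
    enr_df: pd.DataFrame,
    counts_df: pd.DataFrame,
    groups_df: pd.DataFrame,
    seed: int = 0,
    n_boot: int = 0,
    n_starts: int = 12,
    subsets: tuple[str, ...] | None = None,
) -> dict[str, IndividualFits]:
    """Fit every individual listed in the groups table."""
    fits = {}
    for i, row in enumerate(groups_df.itertuples()):
        fits[row.individual] = fit_individual(
            enr_df, counts_df, row.individual, tau=float(row.tau),
            seed=seed + 1000 * i, n_boot=n_boot, n_starts=n_starts,
            subsets=subsets,
        )
    return fits


def fits_to_frame(fits: dict[str, IndividualFits]) -> pd.DataFrame:
    rows = []
    for f in fits.values():
        rows += f.rows()
    return pd.DataFrame(rows)[
        ["individual", "subset", "n_components", "parameter", "estimate",
         "ci_low", "ci_high"]
    ]


def build_cohort_table(
    fits_df: pd.DataFrame,
    groups_df: pd.DataFrame,
    counts_df: pd.DataFrame | None = None,
    qpcr_df: pd.DataFrame | None = None,
    trec_df: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assemble the long-format cohort table (one value per individual,
    subset and quantity) from per-individual fit parameters and assays."""
    group_of = dict(zip(groups_df["individual"], groups_df["group"]))
    rows = []
    sel = fits_df[fits_df["subset"] != "body_water"]
    for (ind, subset), grp in sel.groupby(["individual", "subset"]):
        par = dict(zip(grp["parameter"], grp["estimate"]))
        rows.append((ind, group_of[ind], subset, "production_rate", par["p_avg"]))
        rows.append((ind, group_of[ind], subset, "loss_rate", par["d"]))
    if counts_df is not None:
        med = counts_df.groupby(["individual", "subset"])["subset_count_per_ml"].median()
        for (ind, subset), v in med.items():
            if ind in group_of:
                rows.append((ind, group_of[ind], subset, "count", float(v)))
    if trec_df is not None:
        for r in trec_df.itertuples():
            if r.individual in group_of:
                rows.append((
                    r.individual, group_of[r.individual], r.subset,
                    "trec_content",
                    trec_content(r.trec_copies, r.cell_equivalents).value,
                ))
    table = pd.DataFrame(
        rows, columns=["individual", "group", "subset", "quantity", "value"]
    )
    return cohort_report.validate_cohort_table(table)


def krec_divisions(qpcr_df: pd.DataFrame) -> pd.DataFrame:
    """Replication history per individual from the KREC qPCR table."""
    def measurement(grp, control):
        cts = dict(zip(grp["target"], grp["ct_mean"]))
        return QpcrMeasurement(
            ct_signal_joint=cts.get("signal"),
            ct_coding_joint=cts.get("coding"),
            ct_albumin=cts.get("albumin"),
            is_control_line=control,
        )

    ctrl_rows = qpcr_df[qpcr_df["control_flag"].astype(bool)]
    if ctrl_rows.empty:
        raise ValueError("qPCR table lacks the control-line measurements")
    control = measurement(ctrl_rows, True)
    rows = []
    for ind, grp in qpcr_df[~qpcr_df["control_flag"].astype(bool)].groupby(
            "individual"):
        div = replication_history(measurement(grp, False), control)
        rows.append((ind, div.value, div.flagged))
    return pd.DataFrame(rows, columns=["individual", "divisions", "flagged"])


def make_report(
    table: pd.DataFrame,
    quantities: tuple[str, ...] = ("production_rate", "loss_rate"),
) -> tuple[pd.DataFrame, str]:
    """Fold changes and Mann-Whitney comparisons per subset/quantity.

    Returns the summary frame and a Markdown rendering.
    """
    rows = []
    for quantity in quantities:
        for subset in sorted(table.loc[table["quantity"] == quantity,
                                       "subset"].unique()):
            sub = table[(table["subset"] == subset) & (table["quantity"] == quantity)]
            med = sub.groupby("group")["value"].median()
            try:
                fold = cohort_report.median_fold_change(table, subset, quantity)
                cmp_ = cohort_report.compare_groups(table, subset, quantity)
                rows.append({
                    "subset": subset,
                    "quantity": quantity,
                    "median_patient": med.get("patient", np.nan),
                    "median_control": med.get("healthy_control", np.nan),
                    "fold_change": fold.value,
                    "fold_presented": fold.presented,
                    "test": cmp_.test,
                    "p_value": cmp_.p_value,
                })
            except ValueError as exc:
                logger.warning("report: skipping %s/%s: %s", subset, quantity, exc)
    summary = pd.DataFrame(rows)
    lines = ["# Cohort report", ""]
    for quantity in quantities:
        part = summary[summary["quantity"] == quantity]
        if part.empty:
            continue
        lines += [f"## {quantity}", "",
                  "| subset | patients | controls | fold | p |",
                  "|---|---|---|---|---|"]
        for r in part.itertuples():
            lines.append(
                f"| {r.subset} | {r.median_patient:.3g} | {r.median_control:.3g} "
                f"| {r.fold_change:.2f} | {r.p_value:.3g} |"
            )
        lines.append("")
    return summary, "\n".join(lines)
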