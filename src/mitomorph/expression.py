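"""qPCR relative quantification by the 2^-ΔΔCt method with triplicate QC.

Technical triplicates are screened with an SD rule before any averaging: a
triplicate whose sample standard deviation exceeds 0.5 cycles has the single
replicate whose removal minimizes the remaining pair's SD dropped; if the
best pair still exceeds the limit the whole triplicate is excluded.  Every
decision is recorded in a QC log.  Reference-gene triplicates pass through
the same rule.

Fold changes assume perfect amplification efficiency (doubling per cycle):
ΔCt = mean Ct(target) - mean Ct(reference) within one biological sample,
ΔΔCt = ΔCt(treated) - mean ΔCt(control), fold = 2^-ΔΔCt.  ΔΔCt is computed
per biological replicate and then summarized, so a fold-change dispersion
across replicates is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("mitomorph")

__all__ = ["TriplicateQC", "qc_triplicate", "qc_table", "ddct_fold_change"]

SD_LIMIT = 0.5


@dataclass(frozen=True)
class TriplicateQC:
    """Outcome of the SD rule on one triplicate."""

    kept: tuple[float, ...]
    removed: tuple[float, ...]
    excluded: bool
    sd_before: float
    sd_after: float


def qc_triplicate(cts, sd_limit: float = SD_LIMIT) -> TriplicateQC:
    """Apply the SD > limit outlier rule to three Ct values.

    If the triplicate SD is within the limit all three are kept.  Otherwise
    the single replicate whose removal minimizes the remaining pair's SD is
    dropped; if that pair still exceeds the limit, the triplicate is excluded
    (kept is empty).  This is the most conservative reading of an "outliers
    removed" rule that always keeps at least two replicates.
    """
    x = np.asarray(cts, dtype=float)
    if x.shape != (3,):
        raise ValueError("a triplicate has exactly 3 Ct values")
    sd0 = float(np.std(x, ddof=1))
    if sd0 <= sd_limit:
        return TriplicateQC(tuple(x), (), False, sd0, sd0)
    pair_sds = [float(np.std(np.delete(x, i), ddof=1)) for i in range(3)]
    i = int(np.argmin(pair_sds))
    if pair_sds[i] <= sd_limit:
        return TriplicateQC(tuple(np.delete(x, i)), (float(x[i]),), False, sd0, pair_sds[i])
    return TriplicateQC((), tuple(x), True, sd0, pair_sds[i])


def qc_table(
    table: pd.DataFrame, sd_limit: float = SD_LIMIT
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the SD rule over every gene x sample triplicate of a long table.

    ``table`` has columns (gene, sample, condition, replicate, ct).  Returns
    ``(clean, log)``: ``clean`` keeps one row per gene/sample with the
    post-QC mean Ct and replicate count (excluded triplicates are absent);
    ``log`` records every triplicate's SDs and decision.
    """
    required = {"gene", "sample", "condition", "ct"}
    if missing := required - set(table.columns):
        raise ValueError(f"Ct table lacks columns: {sorted(missing)}")
    clean_rows, log_rows = [], []
    for (gene, sample, cond), grp in table.groupby(
        ["gene", "sample", "condition"], sort=True
    ):
        cts = grp["ct"].to_numpy()
        if len(cts) != 3:
            raise ValueError(f"{gene}/{sample}: expected a triplicate, got {len(cts)}")
        qc = qc_triplicate(cts, sd_limit)
        log_rows.append(
            {
                "gene": gene,
                "sample": sample,
                "condition": cond,
                "sd_before": qc.sd_before,
                "sd_after": qc.sd_after,
                "n_removed": len(qc.removed),
                "excluded": qc.excluded,
            }
        )
        if qc.excluded:
            logger.warning(
                "qPCR QC: %s/%s excluded (SD %.3f, best pair %.3f > %.2f)",
                gene, sample, qc.sd_before, qc.sd_after, sd_limit,
            )
            continue
        if qc.removed:
            logger.info(
                "qPCR QC: %s/%s dropped replicate %.3f (SD %.3f -> %.3f)",
                gene, sample, qc.removed[0], qc.sd_before, qc.sd_after,
            )
        clean_rows.append(
            {
                "gene": gene,
                "sample": sample,
                "condition": cond,
                "mean_ct": float(np.mean(qc.kept)),
                "replicates_used": len(qc.kept),
            }
        )
    return pd.DataFrame(clean_rows), pd.DataFrame(log_rows)


def ddct_fold_change(
    table: pd.DataFrame,
    reference_gene: str,
    control_condition: str,
    sd_limit: float = SD_LIMIT,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """2^-ΔΔCt fold changes from a long-format triplicate Ct table.

    Returns ``(folds, qc_log)``.  ``folds`` has one row per target gene x
    condition with columns delta_ct (mean over samples), ddct, fold_change
    (2^-ddct of the mean), fold_sem (SEM of per-sample fold changes, NaN for
    a single sample) and replicates_used (biological samples contributing).
    The control condition appears with ddct = 0 and fold 1 by construction.
    Samples whose target or reference triplicate was excluded by QC are
    flagged missing and skipped; a gene with no usable control sample raises.
    """
    clean, log = qc_table(table, sd_limit)
    if reference_gene not in set(clean["gene"]):
        raise ValueError(f"reference gene {reference_gene!r} absent after QC")
    ref = clean[clean["gene"] == reference_gene].set_index("sample")["mean_ct"]
    rows = []
    targets = [g for g in clean["gene"].unique() if g != reference_gene]
    for gene in targets:
        sub = clean[clean["gene"] == gene]
        # per-biological-sample ΔCt; samples lacking a reference value drop out
        dct = {
            s: mc - ref[s]
            for s, mc in zip(sub["sample"], sub["mean_ct"])
            if s in ref.index
        }
        per_cond: dict[str, list[float]] = {}
        for (_, r) in sub.iterrows():
            if r["sample"] in dct:
                per_cond.setdefault(r["condition"], []).append(dct[r["sample"]])
        if control_condition not in per_cond or not per_cond[control_condition]:
            raise ValueError(f"gene {gene!r}: no usable control samples")
        dct_control = float(np.mean(per_cond[control_condition]))
        for cond, vals in per_cond.items():
            ddcts = np.asarray(vals) - dct_control
            folds = 2.0 ** (-ddcts)
            rows.append(
                {
                    "gene": gene,
                    "condition": cond,
                    "delta_ct": float(np.mean(vals)),
                    "ddct": float(np.mean(ddcts)),
                    "fold_change": float(2.0 ** (-np.mean(ddcts))),
                    "fold_sem": float(np.std(folds, ddof=1) / np.sqrt(len(folds)))
                    if len(folds) > 1
                    else float("nan"),
                    "replicates_used": len(vals),
                }
            )
    return pd.DataFrame(rows), log
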