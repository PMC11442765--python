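"""Digestion-efficiency control and sample / smMIP level filters.

Unmethylated lambda phage DNA is spiked into every sample; after a complete
MSRE digest no lambda CpG-target molecules should survive, so the ratio of
lambda CpG to lambda reference counts - relative to the same ratio in
undigested control samples - measures the percentage of non-digested DNA.
Samples exceeding the 5% non-digestion threshold, or sequenced below the
minimum depth, are removed; CpG smMIPs with no counts in any sample are
dropped as dead probes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import CATEGORY_CPG, CountMatrix

#: sample-level defaults
DIGESTION_THRESHOLD_PCT = 5.0
MIN_COUNTS_PER_SAMPLE = 5000


def _lambda_ratio(counts: CountMatrix, sample_id: str) -> float:
    cpg = counts.counts.loc[sample_id, counts.lambda_cpg_ids].sum()
    ref = counts.counts.loc[sample_id, counts.lambda_ref_ids].sum()
    if ref == 0:
        raise ValueError(f"sample {sample_id}: lambda reference counts sum to zero")
    return float(cpg) / float(ref)


def digestion_percentage(
    counts: CountMatrix, sample_id: str, undigested_ids: list[str] | None = None
) -> float:
    """Percentage of non-digested DNA in a sample.

    100 x (lambda CpG / lambda reference count ratio of the sample) divided
    by the mean of the same ratio over the undigested control samples.
    """
    if not counts.lambda_cpg_ids or not counts.lambda_ref_ids:
        raise ValueError("panel has no lambda control smMIPs; digestion QC impossible")
    if undigested_ids is None:
        undigested_ids = counts.undigested_samples
    if not undigested_ids:
        raise ValueError("no undigested control samples available")
    control_mean = float(np.mean([_lambda_ratio(counts, u) for u in undigested_ids]))
    if control_mean == 0:
        raise ValueError("undigested controls have zero lambda CpG signal")
    return 100.0 * _lambda_ratio(counts, sample_id) / control_mean


@dataclass
class QcReport:
    """Per-sample QC table and the dropped-smMIP list.

    ``per_sample`` columns: total_counts, non_digestion_pct (NaN when not
    computable), pass_depth, pass_digestion, removed, removal_reason.
    """

    per_sample: pd.DataFrame
    dropped_smmips: pd.DataFrame
    threshold_pct: float
    min_counts: int

    @property
    def removed_samples(self) -> list[str]:
        return list(self.per_sample.index[self.per_sample["removed"]])

    def to_tsv(self, path) -> None:
        self.per_sample.rename_axis("sample_id").to_csv(path, sep="\t")

    def to_dict(self) -> dict:
        return {
            "threshold_pct": self.threshold_pct,
            "min_counts": self.min_counts,
            "removed_samples": {
                sid: self.per_sample.loc[sid, "removal_reason"]
                for sid in self.removed_samples
            },
            "dropped_smmips": self.dropped_smmips["smmip_id"].tolist()
            if len(self.dropped_smmips)
            else [],
        }


def apply_sample_qc(
    counts: CountMatrix,
    threshold_pct: float = DIGESTION_THRESHOLD_PCT,
    min_counts: int = MIN_COUNTS_PER_SAMPLE,
) -> tuple[CountMatrix, QcReport]:
    """Remove under-sequenced and under-digested samples.

    Depth first: samples (digested or control) below ``min_counts`` total
    are removed; the undigested-control mean for the digestion statistic is
    then taken over controls passing depth.  A digested sample is removed
    when its non-digestion percentage strictly exceeds ``threshold_pct``
    (a sample at exactly the threshold is retained).
    """
    totals = counts.counts.sum(axis=1)
    pass_depth = totals >= min_counts

    surviving_controls = [u for u in counts.undigested_samples if pass_depth[u]]
    pct = pd.Series(np.nan, index=counts.counts.index)
    for sid in counts.counts.index:
        if pass_depth[sid] and surviving_controls:
            pct[sid] = digestion_percentage(counts, sid, surviving_controls)

    pass_digestion = pct.le(threshold_pct) | ~counts.sample_meta["digested"].astype(bool)
    removed = {}
    for sid in counts.counts.index:
        if not pass_depth[sid]:
            removed[sid] = f"total counts {int(totals[sid])} < {min_counts}"
        elif counts.sample_meta.loc[sid, "digested"] and pct[sid] > threshold_pct:
            removed[sid] = f"non-digestion {pct[sid]:.1f}% > {threshold_pct}%"

    report = QcReport(
        per_sample=pd.DataFrame(
            {
                "total_counts": totals.astype(np.int64),
                "non_digestion_pct": pct,
                "pass_depth": pass_depth,
                "pass_digestion": pct.le(threshold_pct),
                "removed": pd.Series(
                    [sid in removed for sid in counts.counts.index], index=counts.counts.index
                ),
                "removal_reason": pd.Series(
                    [removed.get(sid, "") for sid in counts.counts.index],
                    index=counts.counts.index,
                ),
            }
        ),
        dropped_smmips=pd.DataFrame(columns=["smmip_id", "reason"]),
        threshold_pct=threshold_pct,
        min_counts=min_counts,
    )
    keep = [sid for sid in counts.counts.index if sid not in removed]
    return counts.subset(samples=keep), report


def drop_dead_smmips(counts: CountMatrix) -> tuple[CountMatrix, pd.DataFrame]:
    """Drop CpG smMIPs with zero counts in every sample.

    Reference and lambda smMIPs are never removed here; an all-zero
    reference smMIP is only flagged (it would otherwise silently shrink the
    normalization denominator).
    """
    col_sums = counts.counts.sum(axis=0)
    meta = counts.smmip_meta.loc[counts.counts.columns]
    dead = col_sums == 0
    is_cpg = meta["category"] == CATEGORY_CPG
    dropped = [
        {"smmip_id": pid, "reason": "no counts in any sample"}
        for pid in counts.counts.columns[dead & is_cpg]
    ]
    flagged = [
        {"smmip_id": pid, "reason": "all-zero non-CpG smMIP (kept, flagged)"}
        for pid in counts.counts.columns[dead & ~is_cpg]
    ]
    keep = [pid for pid in counts.counts.columns if not (dead[pid] and is_cpg[pid])]
    table = pd.DataFrame(dropped + flagged, columns=["smmip_id", "reason"])
    return counts.subset(smmips=keep), table
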