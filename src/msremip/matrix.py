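"""Count-matrix container shared across the pipeline.

A :class:`CountMatrix` holds deduplicated molecule counts (samples x smMIPs)
together with the sample metadata (tissue, condition, digested flag) and the
per-smMIP metadata (target, tile, category) needed by QC, normalization and
classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: smMIP / target categories.
CATEGORY_CPG = "cpg"
CATEGORY_REF_NO_SITE = "ref_no_site"
CATEGORY_REF_NO_CPG = "ref_no_cpg"
CATEGORY_LAMBDA_CPG = "lambda_cpg"
CATEGORY_LAMBDA_REF = "lambda_ref"

CATEGORIES = (
    CATEGORY_CPG,
    CATEGORY_REF_NO_SITE,
    CATEGORY_REF_NO_CPG,
    CATEGORY_LAMBDA_CPG,
    CATEGORY_LAMBDA_REF,
)

#: Human reference categories used for normalization.
REFERENCE_CATEGORIES = (CATEGORY_REF_NO_SITE, CATEGORY_REF_NO_CPG)

CONDITIONS = ("tumor", "normal", "blood")


@dataclass
class CountMatrix:
    """Samples x smMIPs integer count table with metadata.

    Parameters
    ----------
    counts
        DataFrame indexed by sample id, columns are smMIP ids, values are
        non-negative integers (deduplicated molecule counts).
    sample_meta
        DataFrame indexed by sample id with columns ``tissue``, ``condition``
        (tumor / normal / blood) and ``digested`` (bool).
    smmip_meta
        DataFrame indexed by smMIP id with columns ``target_id``, ``tile``
        and ``category``.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame
    smmip_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.counts.index.equals(self.sample_meta.index):
            missing = set(self.counts.index) ^ set(self.sample_meta.index)
            raise ValueError(f"sample metadata does not match counts: {sorted(missing)}")
        unknown = set(self.counts.columns) - set(self.smmip_meta.index)
        if unknown:
            raise ValueError(f"count columns absent from smMIP metadata: {sorted(unknown)}")
        bad = set(self.smmip_meta["category"]) - set(CATEGORIES)
        if bad:
            raise ValueError(f"unknown smMIP categories: {sorted(bad)}")
        vals = self.counts.to_numpy()
        if vals.size and (not np.issubdtype(vals.dtype, np.integer) and not np.allclose(vals, np.round(vals))):
            raise ValueError("counts must be integer-valued")
        if vals.size and (vals < 0).any():
            raise ValueError("counts must be non-negative")

    # -- convenient id sets ------------------------------------------------
    def ids_by_category(self, *categories: str) -> list[str]:
        meta = self.smmip_meta.loc[self.counts.columns]
        return list(meta.index[meta["category"].isin(categories)])

    @property
    def cpg_ids(self) -> list[str]:
        return self.ids_by_category(CATEGORY_CPG)

    @property
    def reference_ids(self) -> list[str]:
        return self.ids_by_category(*REFERENCE_CATEGORIES)

    @property
    def lambda_cpg_ids(self) -> list[str]:
        return self.ids_by_category(CATEGORY_LAMBDA_CPG)

    @property
    def lambda_ref_ids(self) -> list[str]:
        return self.ids_by_category(CATEGORY_LAMBDA_REF)

    @property
    def digested_samples(self) -> list[str]:
        return list(self.sample_meta.index[self.sample_meta["digested"].astype(bool)])

    @property
    def undigested_samples(self) -> list[str]:
        return list(self.sample_meta.index[~self.sample_meta["digested"].astype(bool)])

    def subset(self, samples=None, smmips=None) -> "CountMatrix":
        samples = list(samples) if samples is not None else list(self.counts.index)
        smmips = list(smmips) if smmips is not None else list(self.counts.columns)
        return CountMatrix(
            counts=self.counts.loc[samples, smmips].copy(),
            sample_meta=self.sample_meta.loc[samples].copy(),
            smmip_meta=self.smmip_meta.copy(),
        )

    # -- I/O ---------------------------------------------------------------
    def to_tsv(self, counts_path: str | Path, sample_meta_path: str | Path | None = None) -> None:
        """Write counts as a TSV with smMIPs as rows and samples as columns."""
        self.counts.T.rename_axis("smmip_id").to_csv(counts_path, sep="\t")
        if sample_meta_path is not None:
            self.sample_meta.rename_axis("sample_id").to_csv(sample_meta_path, sep="\t")

    @classmethod
    def from_tsv(
        cls,
        counts_path: str | Path,
        sample_meta_path: str | Path,
        smmip_meta: pd.DataFrame,
    ) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0).T
        counts.index.name = "sample_id"
        meta = pd.read_csv(sample_meta_path, sep="\t", index_col=0)
        meta["digested"] = meta["digested"].astype(bool)
        return cls(counts=counts.loc[meta.index], sample_meta=meta, smmip_meta=smmip_meta)
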