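"""Relative expression from qPCR cycle thresholds (2^-ddCt).

Each sample's target Ct is normalized against the geometric mean of the
reference-gene quantities — on the exponential scale ``2**-Ct`` the geometric
mean of reference quantities corresponds exactly to the arithmetic mean of
reference Ct values, so dCt = Ct_gene - mean(Ct_refs).  Fold changes between
treated and vehicle samples paired by biological replicate follow as
``efficiency**-ddCt`` with the amplification efficiency fixed at 2 by default.
Default reference genes are UBC, GAPDH and TBP; a single reference gene is the
degenerate case of the same formula.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

DEFAULT_REFERENCE_GENES = ("UBC", "GAPDH", "TBP")

REQUIRED_COLUMNS = (
    "sample",
    "treatment",
    "biological_replicate",
    "gene",
    "technical_replicate",
    "ct",
)


class CtTableError(ValueError):
    """Raised when a Ct table violates its contract."""


@dataclass
class CtTable:
    """Long-format table of qPCR cycle thresholds.

    One row per (sample, gene, technical replicate).  Every sample must carry
    Ct values for all reference genes; Ct values must be finite and positive.
    """

    data: pd.DataFrame
    reference_genes: tuple[str, ...] = DEFAULT_REFERENCE_GENES

    def __post_init__(self) -> None:
        df = self.data
        missing_cols = set(REQUIRED_COLUMNS) - set(df.columns)
        if missing_cols:
            raise CtTableError(f"Ct table missing columns: {sorted(missing_cols)}")
        ct = df["ct"].to_numpy(dtype=float)
        if not np.all(np.isfinite(ct)) or np.any(ct <= 0):
            raise CtTableError("Ct values must be finite and > 0")
        self.reference_genes = tuple(self.reference_genes)
        by_sample = df.groupby("sample")["gene"].apply(set)
        for sample, genes in by_sample.items():
            for ref in self.reference_genes:
                if ref not in genes:
                    raise CtTableError(
                        f"sample {sample!r} lacks reference gene {ref!r}"
                    )

    def filter_max_ct(self, ct_max: float = 38.0) -> "CtTable":
        """Optional pre-filter dropping target genes with mean Ct above *ct_max*.

        Reference genes are never dropped.  Filtering happens on the Ct scale
        before normalization.
        """
        mean_ct = self.data.groupby("gene")["ct"].mean()
        keep = set(mean_ct[mean_ct < ct_max].index) | set(self.reference_genes)
        return CtTable(self.data[self.data["gene"].isin(keep)].copy(), self.reference_genes)


def delta_ct(table: CtTable) -> pd.DataFrame:
    """Per-sample dCt for every target gene.

    Technical replicates are averaged on the Ct scale first.  dCt is the
    gene's mean Ct minus the arithmetic mean of the reference-gene mean Cts
    (the log2 of the geometric mean of reference quantities).  Reference
    genes themselves are excluded from the output.

    Returns a DataFrame with columns sample, treatment, biological_replicate,
    gene, delta_ct.
    """
    df = table.data
    per_gene = (
        df.groupby(["sample", "treatment", "biological_replicate", "gene"], sort=False)["ct"]
        .mean()
        .reset_index()
    )
    rows = []
    for (sample, treatment, rep), grp in per_gene.groupby(
        ["sample", "treatment", "biological_replicate"], sort=False
    ):
        cts = dict(zip(grp["gene"], grp["ct"]))
        for ref in table.reference_genes:
            if ref not in cts:
                raise CtTableError(f"sample {sample!r} lacks reference gene {ref!r}")
        ref_mean = float(np.mean([cts[r] for r in table.reference_genes]))
        for gene, ct in cts.items():
            if gene in table.reference_genes:
                continue
            rows.append(
                {
                    "sample": sample,
                    "treatment": treatment,
                    "biological_replicate": rep,
                    "gene": gene,
                    "delta_ct": ct - ref_mean,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class ExpressionResult:
    """Fold changes per gene x treatment, with per-pair detail.

    ``pairs`` holds one row per (gene, treatment, biological replicate) with
    ddCt and fold change; ``summary`` aggregates to mean fold change and its
    standard deviation across replicate pairs.
    """

    pairs: pd.DataFrame
    summary: pd.DataFrame
    vehicle_label: str
    efficiency: float = 2.0

    def to_rows(self) -> list[dict]:
        return self.summary.to_dict("records")


def fold_changes(
    dct: pd.DataFrame,
    vehicle_label: str = "vehicle",
    efficiency: float = 2.0,
) -> ExpressionResult:
    """2^-ddCt fold changes of each treatment vs vehicle, paired by replicate.

    ddCt = dCt(treated) - dCt(vehicle) within each biological replicate;
    the fold change is ``efficiency**-ddCt``.  Every treated replicate must
    have a vehicle partner.  Downstream significance testing is delegated to
    :func:`colonyprofiler.stats.paired_expression_test` on the paired values.
    """
    if efficiency <= 1:
        raise ValueError(f"amplification efficiency must be > 1, got {efficiency}")
    if vehicle_label not in set(dct["treatment"]):
        raise CtTableError(f"no vehicle group {vehicle_label!r} in dCt table")
    veh = dct[dct["treatment"] == vehicle_label]
    veh_lookup = {
        (r.gene, r.biological_replicate): r.delta_ct for r in veh.itertuples()
    }
    rows = []
    for r in dct[dct["treatment"] != vehicle_label].itertuples():
        key = (r.gene, r.biological_replicate)
        if key not in veh_lookup:
            raise CtTableError(
                f"treated replicate {r.biological_replicate!r} of gene {r.gene!r} "
                f"has no vehicle partner"
            )
        ddct = r.delta_ct - veh_lookup[key]
        rows.append(
            {
                "gene": r.gene,
                "treatment": r.treatment,
                "biological_replicate": r.biological_replicate,
                "delta_delta_ct": ddct,
                "fold_change": float(efficiency ** (-ddct)),
            }
        )
    pairs = pd.DataFrame(rows)
    if pairs.empty:
        raise CtTableError("fold_changes: no non-vehicle treatment present")
    summary = (
        pairs.groupby(["gene", "treatment"], sort=False)["fold_change"]
        .agg(mean_fold_change="mean", sd_fold_change="std", n_pairs="count")
        .reset_index()
    )
    return ExpressionResult(
        pairs=pairs, summary=summary, vehicle_label=vehicle_label, efficiency=efficiency
    )
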