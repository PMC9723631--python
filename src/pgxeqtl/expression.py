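"""Gene-count normalization, filtering, and drug-vs-vehicle DEG calling.

The expression container holds one genes-by-samples raw count matrix per
drug condition (vehicle, agonist, modulator, agonist+modulator) over the
same gene and sample index. Normalization is log2-CPM; differential
expression between two conditions is a paired test on per-sample log-CPM
differences, since every cell line is its own control across conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import stats

CONDITIONS = ("vehicle", "cortisol", "c297", "cortisol_c297")


@dataclass
class DrugExpressionSet:
    """Raw counts per condition with a shared gene/sample index."""

    counts: dict[str, pd.DataFrame]  # condition -> genes x samples

    def __post_init__(self) -> None:
        if not self.counts:
            raise ValueError("need at least one condition")
        ref = next(iter(self.counts.values()))
        for cond, df in self.counts.items():
            if not df.index.equals(ref.index) or not df.columns.equals(ref.columns):
                raise ValueError(
                    f"condition {cond!r} has a different gene/sample index"
                )
            values = df.to_numpy()
            if (values < 0).any():
                raise ValueError(f"negative counts in condition {cond!r}")

    @property
    def genes(self) -> pd.Index:
        return next(iter(self.counts.values())).index

    @property
    def samples(self) -> pd.Index:
        return next(iter(self.counts.values())).columns

    @property
    def conditions(self) -> list[str]:
        return list(self.counts)

    def subset_genes(self, gene_ids) -> "DrugExpressionSet":
        gene_ids = list(gene_ids)
        return DrugExpressionSet(
            {cond: df.loc[gene_ids] for cond, df in self.counts.items()}
        )


@dataclass(frozen=True)
class DegRecord:
    gene_id: str
    contrast: tuple[str, str]
    log2_fc: float
    p: float
    q: float
    is_deg: bool


def filter_genes(
    expr: DrugExpressionSet, min_count: int = 32, min_samples: float = 0.5
) -> list[str]:
    """Genes with raw count >= min_count in at least ceil(min_samples * n)
    samples in at least one condition.

    Idempotent: re-filtering the kept subset keeps it unchanged.
    """
    n = len(expr.samples)
    needed = int(np.ceil(min_samples * n))
    keep = np.zeros(len(expr.genes), dtype=bool)
    for df in expr.counts.values():
        keep |= ((df.to_numpy() >= min_count).sum(axis=1) >= needed)
    return list(expr.genes[keep])


def normalize(expr: DrugExpressionSet, pseudo: float = 0.5) -> dict[str, pd.DataFrame]:
    """log2-CPM per condition (each sample/condition is one library)."""
    out = {}
    for cond, df in expr.counts.items():
        out[cond] = pd.DataFrame(
            stats.log_cpm(df.to_numpy(), pseudo=pseudo),
            index=df.index,
            columns=df.columns,
        )
    return out


def differential_expression(
    expr: DrugExpressionSet,
    contrast: tuple[str, str],
    alpha: float = 0.05,
    pseudo: float = 0.5,
) -> pd.DataFrame:
    """Paired per-gene test of log-CPM between two conditions.

    ``contrast = (reference, treatment)``; log2FC > 0 means higher in the
    treatment. Samples are paired by column; genes with zero variance in
    the paired differences get p = 1.

    Returns a DataFrame (gene_id, log2_fc, p, q, is_deg).
    """
    ref_cond, trt_cond = contrast
    norm = normalize(expr, pseudo=pseudo)
    diffs = norm[trt_cond].to_numpy() - norm[ref_cond].to_numpy()
    n = diffs.shape[1]
    if n < 3:
        raise stats.NotTestable("paired DEG test needs >= 3 sample pairs")
    mean = diffs.mean(axis=1)
    sd = diffs.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(np.abs(t), df=n - 1)
    p[sd == 0] = 1.0
    q = stats.bh_fdr(p)
    return pd.DataFrame(
        {
            "gene_id": expr.genes,
            "log2_fc": mean,
            "p": p,
            "q": q,
            "is_deg": q < alpha,
        }
    ).reset_index(drop=True)
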