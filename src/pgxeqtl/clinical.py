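"""LD expansion and GWAS/PheWAS catalog overlap of discovered SNPs.

One-hop LD expansion only: proxies of identified SNPs at r2 above a
threshold, never transitive chains. Catalog rows are taken at the
significance their source database assigned (an optional boolean
``significant`` column or a p ceiling filters them).
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def ld_expand(
    snp_ids: list[str], ld: pd.DataFrame, r2_min: float = 0.8
) -> dict[str, dict[str, float]]:
    """Per input SNP, its LD partners with r2 > r2_min plus itself.

    The LD table is symmetrized at load. Returns
    {snp_id: {partner_id: r2, snp_id: 1.0}}; monotone in r2_min (a lower
    threshold yields a superset).
    """
    sym = pd.concat(
        [ld, ld.rename(columns={"snp_a": "snp_b", "snp_b": "snp_a"})],
        ignore_index=True,
    )
    sym = sym[sym["r2"] > r2_min]
    partners = {
        a: dict(zip(grp["snp_b"], grp["r2"]))
        for a, grp in sym.groupby("snp_a")
    }
    return {sid: {sid: 1.0, **partners.get(sid, {})} for sid in snp_ids}


def catalog_overlap(
    snp_ids: list[str],
    proxies: dict[str, dict[str, float]],
    catalog: pd.DataFrame,
    max_p: float | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Catalog hits for SNPs and their proxies, plus a summary.

    A hit through a proxy is annotated with ``proxy_of`` and the proxy r2.
    Rows with a boolean ``significant`` column must be True; ``max_p``
    additionally caps the catalog p column when present.

    Returns (hits frame, summary dict with fraction of input SNPs having
    >= 1 hit and per-phenotype counts).
    """
    cat = catalog
    if "significant" in cat.columns:
        cat = cat[cat["significant"].astype(bool)]
    if max_p is not None and "p" in cat.columns:
        cat = cat[cat["p"] <= max_p]
    by_snp = {sid: grp for sid, grp in cat.groupby("snp_id")}

    rows = []
    snps_with_hit = set()
    for sid in snp_ids:
        for partner, r2 in sorted(proxies.get(sid, {sid: 1.0}).items()):
            grp = by_snp.get(partner)
            if grp is None:
                continue
            for _, hit in grp.iterrows():
                is_proxy = partner != sid
                rows.append(
                    (sid, hit["phenotype"], hit.get("source", "gwas"),
                     partner if is_proxy else "", r2 if is_proxy else np.nan)
                )
                snps_with_hit.add(sid)
    hits = pd.DataFrame(
        rows, columns=["snp_id", "phenotype", "source", "proxy_of", "proxy_r2"]
    )
    summary = {
        "n_snps": len(snp_ids),
        "n_with_hit": len(snps_with_hit),
        "fraction_with_hit": (len(snps_with_hit) / len(snp_ids)) if snp_ids else 0.0,
        "by_phenotype": hits.groupby("phenotype")["snp_id"].nunique().to_dict()
        if not hits.empty
        else {},
    }
    return hits, summary
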