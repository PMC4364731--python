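"""Gene-set fold enrichment per tool combination, and cross-disease LD
overlap of the prioritized variants.

Enrichment follows the fold statistic (m/n)/(M/N) with a Fisher exact
p-value: n is the number of distinct gene symbols near the variants
passing every tool in a combination, M the disease gene-set size, m
their overlap, and N the genome background (30,000 genes by default).
Significance is annotated at p <= 0.01; no multiple-testing correction
is applied.
"""

from __future__ import annotations

from itertools import combinations
from typing import Mapping, Optional, Sequence

import pandas as pd

from cisprior.annotation_concordance import CutoffFlags
from cisprior.core_io import GeneMap, GeneSetCollection, PipelineConfig
from cisprior.stats_tests import fisher_exact_two_sided, fold_enrichment

__all__ = [
    "TOOL_LABELS",
    "all_tool_combos",
    "genes_for_combo",
    "enrichment_sweep",
    "pooled_gene_set",
    "cross_disease_overlap",
]

TOOL_LABELS = ("CADD", "GWAVA", "RegDB")

_FLAG_ATTR = {"CADD": "pass_cadd", "GWAVA": "pass_gwava", "RegDB": "pass_regdb"}


def all_tool_combos() -> list[frozenset[str]]:
    """The 7 non-empty subsets of the three tools, singletons first."""
    out = []
    for k in (1, 2, 3):
        for combo in combinations(TOOL_LABELS, k):
            out.append(frozenset(combo))
    return out


def combo_label(combo: frozenset[str]) -> str:
    return "+".join(t for t in TOOL_LABELS if t in combo)


def genes_for_combo(
    flags: Sequence[CutoffFlags],
    combo: frozenset[str],
    gene_map: GeneMap,
) -> frozenset[str]:
    """Distinct gene symbols near variants passing every tool in ``combo``.

    A symbol appearing next to several passing variants counts once;
    variants with no mapped genes contribute nothing.
    """
    if not combo or not combo <= set(TOOL_LABELS):
        raise ValueError(f"combo must be a non-empty subset of {TOOL_LABELS}")
    attrs = [_FLAG_ATTR[t] for t in combo]
    genes: set[str] = set()
    for f in flags:
        if all(getattr(f, a) for a in attrs):
            genes.update(gene_map.genes_for(f.rsid))
    return frozenset(genes)


def pooled_gene_set(gene_sets: GeneSetCollection, names: Sequence[str]) -> frozenset[str]:
    """Union of several disease sets with duplicates removed (for pooled
    multi-disease references)."""
    pooled: set[str] = set()
    for name in names:
        pooled |= gene_sets.sets[name]
    return frozenset(pooled)


def enrichment_sweep(
    flags: Sequence[CutoffFlags],
    gene_map: GeneMap,
    gene_sets: GeneSetCollection,
    config: Optional[PipelineConfig] = None,
    pooled: Optional[Mapping[str, Sequence[str]]] = None,
) -> pd.DataFrame:
    """Fold enrichment and Fisher p for every tool combination x gene set.

    ``pooled`` optionally adds union reference sets, e.g.
    ``{"IMD4": ["AS", "CeD", "Ps", "T1D"]}``. A combination prioritizing
    zero genes yields a row with fold and p set to NA rather than being
    dropped. The ``significant`` column marks p <= 0.01.
    """
    cfg = config or PipelineConfig()
    N = cfg.background_N
    disease_sets: dict[str, frozenset[str]] = dict(gene_sets.sets)
    for name, members in (pooled or {}).items():
        disease_sets[name] = pooled_gene_set(gene_sets, members)
    rows = []
    for disease, dset in disease_sets.items():
        M = len(dset)
        for combo in all_tool_combos():
            genes = genes_for_combo(flags, combo, gene_map)
            n = len(genes)
            m = len(genes & dset)
            if n == 0:
                fold = p = None
            else:
                fold = fold_enrichment(m, n, M, N)
                p = fisher_exact_two_sided(m, n, M, N)
            rows.append(
                {
                    "disease": disease,
                    "tools": combo_label(combo),
                    "m": m,
                    "n": n,
                    "M": M,
                    "N": N,
                    "fold": fold,
                    "p_value": p,
                    "significant": (p is not None and p <= 0.01),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["disease", "tools", "m", "n", "M", "N", "fold", "p_value", "significant"],
    )


def cross_disease_overlap(
    prioritized: Sequence[str],
    disease_ld_tables: Mapping[str, pd.DataFrame],
    r2_min: float = 0.8,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """LD overlap between prioritized variants and other diseases' leads.

    Each disease table has columns lead_rsid, proxy_rsid, r2 (strong-LD
    expansions of that disease's lead GWAS SNPs). A prioritized variant
    matches a disease lead if it appears in the lead's strong-LD set
    (r2 >= r2_min), or if it *is* a lead for that disease (self-match,
    r² = 1). Duplicate table rows are collapsed keeping the larger r².

    Returns (cells, summary): ``cells`` holds one row per prioritized
    variant x disease with the matches rendered ``lead (r2); ...`` or
    ``-``; ``summary`` gives per-disease counts of covered prioritized
    variants and distinct matching leads.
    """
    prioritized = list(dict.fromkeys(prioritized))
    cell_rows = []
    summary_rows = []
    for disease in disease_ld_tables:
        df = disease_ld_tables[disease]
        best: dict[tuple[str, str], float] = {}
        lead_ids: set[str] = set()
        for row in df.itertuples(index=False):
            lead, proxy, r2 = str(row.lead_rsid), str(row.proxy_rsid), float(row.r2)
            lead_ids.add(lead)
            if lead == proxy:
                continue
            key = (proxy, lead)
            if r2 >= r2_min and (key not in best or r2 > best[key]):
                best[key] = r2
        covered = 0
        matched_leads: set[str] = set()
        for rsid in prioritized:
            matches = sorted(
                ((lead, r2) for (proxy, lead), r2 in best.items() if proxy == rsid),
                key=lambda t: (-t[1], t[0]),
            )
            if rsid in lead_ids:
                matches.insert(0, (rsid, 1.0))
            # a lead may surface both as a self-match and via an explicit row
            dedup: dict[str, float] = {}
            for lead, r2 in matches:
                if lead not in dedup or r2 > dedup[lead]:
                    dedup[lead] = r2
            matches = sorted(dedup.items(), key=lambda t: (-t[1], t[0]))
            if matches:
                covered += 1
                matched_leads.update(lead for lead, _ in matches)
            cell_rows.append(
                {
                    "prioritized_rsid": rsid,
                    "disease": disease,
                    "matches": "; ".join(f"{l} ({r2:g})" for l, r2 in matches) or "-",
                    "n_matches": len(matches),
                }
            )
        summary_rows.append(
            {
                "disease": disease,
                "covered_prioritized": covered,
                "distinct_leads": len(matched_leads),
            }
        )
    cells = pd.DataFrame(
        cell_rows, columns=["prioritized_rsid", "disease", "matches", "n_matches"]
    )
    summary = pd.DataFrame(
        summary_rows, columns=["disease", "covered_prioritized", "distinct_leads"]
    )
    return cells, summary
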