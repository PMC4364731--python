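"""Classifier-cutoff concordance: pass flags, Venn partition, and the
triple-concordant prioritized set.

Each variant in the universe is tested against three inclusive cutoffs —
deleteriousness score >= cadd_cut, functional score >= gwava_cut, and
regulatory category major <= regdb_cut_major. A missing score fails its
own cutoff only (so indels without a functional score can still pass the
other two), and a no-data regulatory category fails the category cutoff.
Variants passing all three are the prioritized set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from cisprior.core_io import (
    AnnotationRecord,
    GeneMap,
    PipelineConfig,
    ValidationError,
)
from cisprior.ld_expansion import Locus
from cisprior.stats_tests import RankSumResult, wilcoxon_rank_sum

__all__ = [
    "CutoffFlags",
    "VennPartition",
    "apply_cutoffs",
    "venn_partition",
    "prioritize_concordant",
    "compare_lead_vs_ld",
]

VENN_REGIONS = ("C", "G", "R", "CG", "CR", "GR", "CGR")


@dataclass(frozen=True)
class CutoffFlags:
    rsid: str
    pass_cadd: bool
    pass_gwava: bool
    pass_regdb: bool

    @property
    def region(self) -> str:
        """Exclusive Venn region label, or 'none'."""
        label = (
            ("C" if self.pass_cadd else "")
            + ("G" if self.pass_gwava else "")
            + ("R" if self.pass_regdb else "")
        )
        return label or "none"


@dataclass
class VennPartition:
    """Exclusive region membership for the three classifier pass-sets.

    ``regions`` maps each of C, G, R, CG, CR, GR, CGR (and 'none') to the
    set of rsids falling exactly there; ``union`` is every rsid passing
    at least one cutoff. ``pairwise_inclusive`` gives the full (not
    region-exclusive) two-way intersections, since summaries in the
    field are written both ways.
    """

    regions: dict[str, frozenset[str]]
    union: frozenset[str]
    pairwise_inclusive: dict[str, frozenset[str]]

    @property
    def counts(self) -> dict[str, int]:
        out = {r: len(self.regions[r]) for r in VENN_REGIONS}
        out["none"] = len(self.regions["none"])
        out["union"] = len(self.union)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"region": r, "count": len(self.regions[r])}
            for r in (*VENN_REGIONS, "none")
        ]
        rows.append({"region": "union", "count": len(self.union)})
        for name, members in self.pairwise_inclusive.items():
            rows.append({"region": f"{name}_inclusive", "count": len(members)})
        return pd.DataFrame(rows, columns=["region", "count"])


def apply_cutoffs(
    annotations: Sequence[AnnotationRecord],
    config: Optional[PipelineConfig] = None,
    universe: Optional[Sequence[str]] = None,
) -> list[CutoffFlags]:
    """Evaluate the three inclusive cutoffs for every variant.

    If ``universe`` is given, variants absent from the annotation table
    are retained with all-failing flags (they were scored by nobody, but
    they are still part of the study) and the output follows the
    universe order.
    """
    cfg = config or PipelineConfig()
    by_rsid = {a.rsid: a for a in annotations}
    rsids = list(universe) if universe is not None else [a.rsid for a in annotations]
    flags = []
    for rsid in rsids:
        a = by_rsid.get(rsid)
        if a is None:
            flags.append(CutoffFlags(rsid, False, False, False))
            continue
        pass_cadd = a.cadd_like is not None and a.cadd_like >= cfg.cadd_cut
        pass_gwava = a.gwava_like is not None and a.gwava_like >= cfg.gwava_cut
        pass_regdb = (
            a.regdb_cat is not None
            and not a.regdb_cat.is_no_data
            and a.regdb_cat.major <= cfg.regdb_cut_major
        )
        flags.append(CutoffFlags(rsid, pass_cadd, pass_gwava, pass_regdb))
    return flags


def venn_partition(flags: Sequence[CutoffFlags]) -> VennPartition:
    """Partition flagged variants into the seven exclusive Venn regions."""
    seen = set()
    for f in flags:
        if f.rsid in seen:
            raise ValidationError(f"duplicate rsid in flags: {f.rsid}")
        seen.add(f.rsid)
    regions: dict[str, set[str]] = {r: set() for r in (*VENN_REGIONS, "none")}
    for f in flags:
        regions[f.region].add(f.rsid)
    union = frozenset().union(*(regions[r] for r in VENN_REGIONS))
    c_all = {f.rsid for f in flags if f.pass_cadd}
    g_all = {f.rsid for f in flags if f.pass_gwava}
    r_all = {f.rsid for f in flags if f.pass_regdb}
    pairwise = {
        "CG": frozenset(c_all & g_all),
        "CR": frozenset(c_all & r_all),
        "GR": frozenset(g_all & r_all),
    }
    return VennPartition(
        regions={k: frozenset(v) for k, v in regions.items()},
        union=union,
        pairwise_inclusive=pairwise,
    )


def prioritize_concordant(
    flags: Sequence[CutoffFlags],
    loci: Sequence[Locus],
    gene_map: Optional[GeneMap] = None,
    annotations: Optional[Sequence[AnnotationRecord]] = None,
) -> pd.DataFrame:
    """Extract the triple-concordant variants as a prioritized table.

    One row per (variant, containing locus): rsid, lead_rsid, r2 to that
    lead, the three scores, and comma-joined gene symbols. A prioritized
    variant that belongs to no locus is an error. Output is sorted by
    rsid then lead for row-order invariance; the distinct-lead count is
    available from the ``lead_rsid`` column.
    """
    gene_map = gene_map or GeneMap()
    annot = {a.rsid: a for a in (annotations or [])}
    concordant = sorted(
        f.rsid for f in flags if f.pass_cadd and f.pass_gwava and f.pass_regdb
    )
    rows = []
    for rsid in concordant:
        hits = [(l.lead_rsid, l.member_r2[rsid]) for l in loci if rsid in l.member_r2]
        if not hits:
            raise ValidationError(f"prioritized variant {rsid} absent from every locus")
        a = annot.get(rsid)
        genes = gene_map.genes_for(rsid)
        for lead, r2 in sorted(hits):
            rows.append(
                {
                    "rsid": rsid,
                    "lead_rsid": lead,
                    "r2": r2,
                    "cadd": a.cadd_like if a else None,
                    "gwava": a.gwava_like if a else None,
                    "regdb": a.regdb_cat.token if a and a.regdb_cat else "ND",
                    "genes": ",".join(genes) if genes else "-",
                }
            )
    return pd.DataFrame(
        rows, columns=["rsid", "lead_rsid", "r2", "cadd", "gwava", "regdb", "genes"]
    )


def compare_lead_vs_ld(
    annotations: Sequence[AnnotationRecord],
    roles: Mapping[str, str],
    score_field: str = "cadd_like",
) -> tuple[RankSumResult, float, float]:
    """Rank-sum comparison of a score between lead SNPs and their proxies.

    Returns the two-sided test result plus the two group medians
    (lead, proxy). Variants with a missing score are dropped; an empty
    group is an error.
    """
    lead_scores, proxy_scores = [], []
    for a in annotations:
        v = getattr(a, score_field)
        if v is None:
            continue
        role = roles.get(a.rsid)
        if role == "lead":
            lead_scores.append(v)
        elif role == "proxy":
            proxy_scores.append(v)
    if not lead_scores or not proxy_scores:
        raise ValidationError("both lead and proxy groups need >= 1 non-missing score")
    result = wilcoxon_rank_sum(lead_scores, proxy_scores)
    med = lambda v: float(pd.Series(v).median())
    return result, med(lead_scores), med(proxy_scores)
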