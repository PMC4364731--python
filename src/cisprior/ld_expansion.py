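"""Expand lead SNPs into loci of strong-LD proxies.

A locus is a lead SNP plus every proxy whose r² with the lead is at or
above the threshold (0.8 by default, inclusive). The union of all loci —
each shared variant counted once, but tagged with every locus it belongs
to — is the variant universe the annotation stages operate on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from cisprior.core_io import LDPair, ValidationError, VariantRecord

__all__ = ["Locus", "expand_loci", "variant_universe", "locus_summary"]


@dataclass
class Locus:
    """One lead SNP and its strong-LD members (the lead itself has r² = 1)."""

    lead_rsid: str
    member_r2: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.member_r2.setdefault(self.lead_rsid, 1.0)

    @property
    def members(self) -> frozenset[str]:
        return frozenset(self.member_r2)

    @property
    def size(self) -> int:
        return len(self.member_r2)

    @property
    def is_singleton(self) -> bool:
        return self.size == 1


def expand_loci(
    leads: Sequence[VariantRecord],
    ld_pairs: Iterable[LDPair],
    r2_min: float = 0.8,
) -> list[Locus]:
    """Build one locus per lead, keeping proxies with r² >= ``r2_min``.

    Every LD pair must reference a known lead; unknown leads are reported
    together in a single error. A lead with no qualifying proxies yields
    a singleton locus. The result is independent of input row order
    (members are keyed by rsid; a duplicated pair keeps the larger r²).
    """
    known = {v.rsid for v in leads}
    unknown = sorted({p.lead_rsid for p in ld_pairs if p.lead_rsid not in known})
    if unknown:
        raise ValidationError(f"LD pairs reference unknown lead SNP(s): {unknown}")
    loci = {v.rsid: Locus(v.rsid) for v in leads}
    for p in ld_pairs:
        if p.r2 >= r2_min:
            locus = loci[p.lead_rsid]
            prev = locus.member_r2.get(p.proxy_rsid)
            if prev is None or p.r2 > prev:
                locus.member_r2[p.proxy_rsid] = p.r2
    return [loci[v.rsid] for v in leads]


def variant_universe(
    loci: Sequence[Locus],
    variant_classes: Optional[Mapping[str, str]] = None,
) -> tuple[list[VariantRecord], dict[str, list[str]]]:
    """Merge loci into the de-duplicated variant universe.

    Returns the variant records (role ``lead`` if the rsid is any locus
    lead, else ``proxy``) and a mapping rsid -> list of lead rsids of
    every locus containing it. A proxy shared by two loci appears once;
    a lead that is its own proxy keeps role ``lead``.
    """
    leads = {l.lead_rsid for l in loci}
    membership: dict[str, list[str]] = {}
    for locus in loci:
        for rsid in locus.member_r2:
            membership.setdefault(rsid, []).append(locus.lead_rsid)
    classes = variant_classes or {}
    records = [
        VariantRecord(
            rsid=rsid,
            var_class=classes.get(rsid, "SNP"),
            role="lead" if rsid in leads else "proxy",
        )
        for rsid in membership
    ]
    return records, membership


def locus_summary(
    loci: Sequence[Locus],
    variant_classes: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Per-locus member counts and variant-class tallies.

    Columns: lead_rsid, n_members, n_proxies, n_snp, n_insertion,
    n_deletion (class tallies cover proxies only; unknown classes count
    as SNP).
    """
    classes = variant_classes or {}
    rows = []
    for locus in loci:
        tally = {"SNP": 0, "insertion": 0, "deletion": 0}
        for rsid in locus.member_r2:
            if rsid == locus.lead_rsid:
                continue
            tally[classes.get(rsid, "SNP")] += 1
        rows.append(
            {
                "lead_rsid": locus.lead_rsid,
                "n_members": locus.size,
                "n_proxies": locus.size - 1,
                "n_snp": tally["SNP"],
                "n_insertion": tally["insertion"],
                "n_deletion": tally["deletion"],
            }
        )
    return pd.DataFrame(
        rows,
        columns=["lead_rsid", "n_members", "n_proxies", "n_snp", "n_insertion", "n_deletion"],
    )
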