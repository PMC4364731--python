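"""Bundled reference tables.

Two small published summary tables ship with the package as plain TSV:
the 18 triple-concordant prioritized SNPs of the inflammatory bowel
disease (IBD) GWAS-locus study this pipeline reimplements (rsid, locus
lead, r², the three annotation scores, nearby HGNC symbols), and the
strong-LD overlap of those SNPs with lead GWAS SNPs of six
immune-mediated diseases. They serve as ready-made worked-example
inputs and as regression anchors for the concordance and overlap
stages.
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd

from cisprior.core_io import (
    AnnotationRecord,
    GeneMap,
    LDPair,
    VariantRecord,
    parse_reg_category,
)

__all__ = [
    "IMD_DISEASES",
    "load_disease_ld_tables",
    "load_prioritized_snps",
    "prioritized_input_bundle",
]

IMD_DISEASES = ("AS", "CeD", "IBD", "Ps", "RA", "T1D")


def _data(name: str):
    return files("cisprior").joinpath("data", name)


def load_prioritized_snps() -> pd.DataFrame:
    """The published table of 18 prioritized putative regulatory SNPs."""
    with _data("ibd_prioritized_snps.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"chrom": str})


def prioritized_input_bundle():
    """Re-shape the prioritized-SNP table into pipeline inputs.

    Returns (leads, ld_pairs, annotations, gene_map). Lead coordinates
    are placeholders (the table records only the prioritized variants'
    positions); no downstream computation reads them.
    """
    df = load_prioritized_snps()
    leads: dict[str, VariantRecord] = {}
    ld_pairs: list[LDPair] = []
    annotations: list[AnnotationRecord] = []
    mapping: dict[str, tuple[str, ...]] = {}
    for row in df.itertuples(index=False):
        if row.lead_rsid not in leads:
            leads[row.lead_rsid] = VariantRecord(
                rsid=row.lead_rsid, chrom=str(row.chrom), pos=int(row.pos), role="lead"
            )
        if row.rsid != row.lead_rsid:
            ld_pairs.append(LDPair(row.lead_rsid, row.rsid, float(row.r2)))
        annotations.append(
            AnnotationRecord(
                rsid=row.rsid,
                cadd_like=float(row.cadd),
                gwava_like=float(row.gwava),
                regdb_cat=parse_reg_category(str(row.regdb)),
            )
        )
        genes = () if row.genes == "-" else tuple(row.genes.split(","))
        mapping[row.rsid] = genes
    return list(leads.values()), ld_pairs, annotations, GeneMap(mapping)


def load_disease_ld_tables() -> dict[str, pd.DataFrame]:
    """Per-disease strong-LD tables for the six immune-mediated diseases.

    Diseases with no published match (T1D) get an empty table, so
    overlap summaries cover all six.
    """
    with _data("imd_ld_overlap.tsv").open() as fh:
        long = pd.read_csv(fh, sep="\t")
    tables: dict[str, pd.DataFrame] = {}
    for disease in IMD_DISEASES:
        sub = long[long["disease"] == disease][["lead_rsid", "proxy_rsid", "r2"]]
        tables[disease] = sub.reset_index(drop=True)
    return tables
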