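"""Synthetic input bundles with planted ground truth.

The generator emulates the structure of a post-GWAS annotation study:
lead SNPs expanded into strong-LD loci, three annotation scores driven
by a single latent functional indicator (so that triple-concordance is
informative rather than coincidental), selection statistics with valid
ranges, a variant-to-gene map, and a disease gene set whose overlap with
the prioritized genes is planted to yield a chosen fold enrichment.

Default sizes mirror the study conditions this pipeline targets: 152
loci averaging ~30 strong-LD candidate proxies each (~94% SNPs, ~4.4%
deletions, ~1.6% insertions among proxies), a background deleteriousness
score with mean ~3.5, a functional score with background mean ~0.2, and
a regulatory-category table with a large no-data mass. r² values are
drawn, never computed from genotypes.

All randomness flows through one seeded generator; identical seeds give
byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from cisprior.annotation_concordance import apply_cutoffs
from cisprior.core_io import GeneMap, GeneSetCollection, PipelineConfig
from cisprior.enrichment_eval import genes_for_combo
from cisprior.ld_expansion import expand_loci, variant_universe
from cisprior.core_io import AnnotationRecord, LDPair, SelectionRecord, VariantRecord
from cisprior.core_io import parse_reg_category

__all__ = ["CohortSpec", "CohortBundle", "PlantedTruth", "generate_cohort", "generate_disease_sets", "write_gmt"]

# regulatory-category sampling tables conditioned on the latent indicator;
# background keeps a heavy no-data mass, functional variants concentrate
# in categories 1-2
REGDB_BACKGROUND = {
    "ND": 0.41, "6": 0.17, "5": 0.17, "4": 0.17,
    "3a": 0.01, "3b": 0.005,
    "2a": 0.01, "2b": 0.012, "2c": 0.01,
    "1a": 0.0005, "1b": 0.002, "1c": 0.0005, "1d": 0.0005, "1e": 0.0005, "1f": 0.029,
}
REGDB_FUNCTIONAL = {
    "ND": 0.15, "6": 0.03, "5": 0.04, "4": 0.08,
    "3a": 0.05, "3b": 0.025,
    "2a": 0.10, "2b": 0.15, "2c": 0.05,
    "1a": 0.01, "1b": 0.05, "1c": 0.005, "1d": 0.005, "1e": 0.005, "1f": 0.25,
}


@dataclass
class CohortSpec:
    """Parameters of one synthetic cohort.

    Score laws: the deleteriousness score is Gamma(shape, scale) in the
    background and location-shifted Gamma for functional variants; the
    functional score is Beta(1.5, 6) background versus Beta(6, 2)
    functional (indels have no functional score, as in real retrievals);
    regulatory categories come from the two categorical tables above.
    """

    n_loci: int = 152
    proxies_per_locus_mean: float = 30.0
    r2_low: float = 0.5
    r2_high: float = 1.0
    functional_fraction: float = 0.03
    # variant-class mix among proxies
    p_deletion: float = 0.044
    p_insertion: float = 0.016
    # deleteriousness score (C-score analogue)
    cadd_bg_shape: float = 1.2
    cadd_bg_scale: float = 2.9
    cadd_fn_shift: float = 8.0
    cadd_fn_shape: float = 2.0
    cadd_fn_scale: float = 3.0
    # functional score (0-1)
    gwava_bg: tuple[float, float] = (1.5, 6.0)
    gwava_fn: tuple[float, float] = (6.0, 2.0)
    # selection statistics (leads only)
    nr_range: tuple[float, float] = (1.0, 6.0)
    rs_mean: float = 0.2
    rs_sd: float = 1.5
    p_fully_conserved: float = 0.125
    td_mean: float = 1.8
    td_sd: float = 1.2
    td_range: tuple[float, float] = (-2.5, 4.0)
    p_missing_popstats: float = 0.026
    # gene map
    max_genes_per_locus: int = 4
    p_gene_kept: float = 0.7
    # planted enrichment
    planted_fold: float = 25.0
    disease_set_size: int = 300
    background_N: int = 30000
    seed: int = 0

    def validate(self) -> None:
        if self.n_loci <= 0:
            raise ValueError("n_loci must be positive")
        for name in ("functional_fraction", "p_deletion", "p_insertion",
                     "p_fully_conserved", "p_missing_popstats", "p_gene_kept"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if not (0.0 <= self.r2_low <= self.r2_high <= 1.0):
            raise ValueError("need 0 <= r2_low <= r2_high <= 1")
        if self.planted_fold < 0 or self.disease_set_size <= 0 or self.background_N <= 0:
            raise ValueError("planted_fold must be >= 0 and set sizes positive")
        if self.disease_set_size > self.background_N:
            raise ValueError("disease_set_size cannot exceed background_N")


@dataclass
class PlantedTruth:
    """Ground truth recorded at generation time."""

    functional: dict[str, bool]
    prioritized_genes: frozenset[str]
    disease_overlap: int            # m* actually planted
    planted_fold: float
    disease_set_size: int
    background_N: int


@dataclass
class CohortBundle:
    """In-memory cohort: typed records plus the planted truth."""

    leads: list[VariantRecord]
    ld_pairs: list[LDPair]
    annotations: list[AnnotationRecord]
    selection: list[SelectionRecord]
    gene_map: GeneMap
    gene_sets: GeneSetCollection
    truth: PlantedTruth
    variant_classes: dict[str, str] = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> Path:
        """Write the six input tables plus truth.tsv."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "leads.tsv", "w") as fh:
            fh.write("rsid\tchrom\tpos\tvar_class\n")
            for v in self.leads:
                fh.write(f"{v.rsid}\t{v.chrom}\t{v.pos}\t{v.var_class}\n")
        with open(out / "ld.tsv", "w") as fh:
            fh.write("lead_rsid\tproxy_rsid\tr2\n")
            for p in self.ld_pairs:
                fh.write(f"{p.lead_rsid}\t{p.proxy_rsid}\t{p.r2:g}\n")
        with open(out / "annot.tsv", "w") as fh:
            fh.write("rsid\tcadd\tgwava\tregdb\n")
            for a in self.annotations:
                gw = "NA" if a.gwava_like is None else f"{a.gwava_like:g}"
                cat = "ND" if a.regdb_cat is None or a.regdb_cat.is_no_data else a.regdb_cat.token
                fh.write(f"{a.rsid}\t{a.cadd_like:g}\t{gw}\t{cat}\n")
        with open(out / "selection.tsv", "w") as fh:
            fh.write("rsid\trs\tnr\ttd\tdaf\tddaf\n")
            for s in self.selection:
                td = "NA" if s.td is None else f"{s.td:g}"
                daf = "NA" if s.daf is None else f"{s.daf:g}"
                ddaf = "NA" if s.delta_daf is None else f"{s.delta_daf:g}"
                fh.write(f"{s.rsid}\t{s.rs_score:g}\t{s.nr_score:g}\t{td}\t{daf}\t{ddaf}\n")
        with open(out / "genemap.tsv", "w") as fh:
            fh.write("rsid\tgenes\n")
            for rsid, genes in self.gene_map.mapping.items():
                fh.write(f"{rsid}\t{','.join(genes) if genes else '-'}\n")
        write_gmt(self.gene_sets, out / "genesets.gmt")
        with open(out / "truth.tsv", "w") as fh:
            fh.write("rsid\tfunctional\n")
            for rsid, fn in self.truth.functional.items():
                fh.write(f"{rsid}\t{int(fn)}\n")
        return out


def write_gmt(gene_sets: GeneSetCollection, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name, genes in gene_sets.sets.items():
            fh.write("\t".join([name, "synthetic"] + sorted(genes)) + "\n")
    return path


def _sample_regdb(rng: np.random.Generator, table: dict[str, float], size: int) -> list[str]:
    toks = list(table)
    probs = np.asarray([table[t] for t in toks])
    probs = probs / probs.sum()
    return list(rng.choice(toks, size=size, p=probs))


def generate_cohort(spec: CohortSpec, out_dir: str | Path | None = None) -> CohortBundle:
    """Generate a full input bundle from ``spec``.

    The planted disease gene set is built against the genes of the
    variants that actually pass all three default cutoffs; when no
    variant is triple-concordant (e.g. functional_fraction = 0) the set
    is pure filler with zero overlap. Raises before writing anything if
    the requested fold is infeasible for the realized margins.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    counter = 0

    def next_rsid() -> str:
        nonlocal counter
        counter += 1
        return f"rsS{counter:06d}"

    leads: list[VariantRecord] = []
    ld_pairs: list[LDPair] = []
    classes: dict[str, str] = {}
    locus_members: dict[str, list[str]] = {}
    for _ in range(spec.n_loci):
        lead_id = next_rsid()
        chrom = str(rng.integers(1, 23))
        pos = int(rng.integers(10_000, 50_000_000))
        leads.append(VariantRecord(lead_id, chrom, pos, var_class="SNP", role="lead"))
        classes[lead_id] = "SNP"
        members = [lead_id]
        n_prox = int(rng.poisson(spec.proxies_per_locus_mean))
        if n_prox:
            r2s = rng.uniform(spec.r2_low, spec.r2_high, size=n_prox).round(3)
            u = rng.uniform(size=n_prox)
            for j in range(n_prox):
                pid = next_rsid()
                vclass = (
                    "deletion" if u[j] < spec.p_deletion
                    else "insertion" if u[j] < spec.p_deletion + spec.p_insertion
                    else "SNP"
                )
                classes[pid] = vclass
                ld_pairs.append(LDPair(lead_id, pid, float(r2s[j])))
                members.append(pid)
        locus_members[lead_id] = members

    all_rsids = [r for members in locus_members.values() for r in members]
    functional = dict(
        zip(all_rsids, rng.uniform(size=len(all_rsids)) < spec.functional_fraction)
    )

    # annotation scores driven by the shared latent indicator
    annotations: list[AnnotationRecord] = []
    fn_mask = np.asarray([functional[r] for r in all_rsids])
    n_all = len(all_rsids)
    cadd = rng.gamma(spec.cadd_bg_shape, spec.cadd_bg_scale, size=n_all)
    cadd_fn = spec.cadd_fn_shift + rng.gamma(spec.cadd_fn_shape, spec.cadd_fn_scale, size=n_all)
    cadd = np.where(fn_mask, cadd_fn, cadd).round(3)
    gwava = rng.beta(*spec.gwava_bg, size=n_all)
    gwava_fn = rng.beta(*spec.gwava_fn, size=n_all)
    gwava = np.where(fn_mask, gwava_fn, gwava).round(3)
    regdb_bg = _sample_regdb(rng, REGDB_BACKGROUND, n_all)
    regdb_fn = _sample_regdb(rng, REGDB_FUNCTIONAL, n_all)
    for i, rsid in enumerate(all_rsids):
        tok = regdb_fn[i] if fn_mask[i] else regdb_bg[i]
        annotations.append(
            AnnotationRecord(
                rsid=rsid,
                cadd_like=float(cadd[i]),
                gwava_like=None if classes[rsid] != "SNP" else float(gwava[i]),
                regdb_cat=parse_reg_category(tok),
            )
        )

    # selection statistics for the leads
    selection: list[SelectionRecord] = []
    for v in leads:
        nr = round(float(rng.uniform(*spec.nr_range)), 3)
        if rng.uniform() < spec.p_fully_conserved:
            rs = nr
        else:
            rs = round(float(min(rng.normal(spec.rs_mean, spec.rs_sd), nr)), 3)
        if rng.uniform() < spec.p_missing_popstats:
            td = daf = ddaf = None
        else:
            td = round(float(np.clip(rng.normal(spec.td_mean, spec.td_sd), *spec.td_range)), 3)
            daf = round(float(rng.beta(2, 2)), 3)
            ddaf = round(float(np.clip(daf - rng.beta(2, 2), -1, 1)), 3)
        selection.append(SelectionRecord(v.rsid, rs, nr, td, daf, ddaf))

    # gene map: each locus owns up to max_genes_per_locus symbols; each
    # member variant keeps each locus gene independently
    gene_counter = 0
    mapping: dict[str, tuple[str, ...]] = {}
    for lead_id, members in locus_members.items():
        k = int(rng.integers(0, spec.max_genes_per_locus + 1))
        locus_genes = []
        for _ in range(k):
            gene_counter += 1
            locus_genes.append(f"SYNG{gene_counter:05d}")
        for rsid in members:
            kept = tuple(g for g in locus_genes if rng.uniform() < spec.p_gene_kept)
            mapping[rsid] = kept
    gene_map = GeneMap(mapping)

    # planted disease set against the realized triple-concordant genes of
    # the strong-LD universe (the set the pipeline itself prioritizes)
    cfg = PipelineConfig()
    universe, _ = variant_universe(expand_loci(leads, ld_pairs, cfg.r2_min))
    flags = apply_cutoffs(annotations, cfg, universe=[v.rsid for v in universe])
    prioritized_genes = genes_for_combo(flags, frozenset({"CADD", "GWAVA", "RegDB"}), gene_map)
    gene_sets, m_star = _plant_disease_set(
        prioritized_genes,
        spec.planted_fold,
        spec.disease_set_size,
        spec.background_N,
        rng,
    )
    truth = PlantedTruth(
        functional=functional,
        prioritized_genes=prioritized_genes,
        disease_overlap=m_star,
        planted_fold=spec.planted_fold,
        disease_set_size=spec.disease_set_size,
        background_N=spec.background_N,
    )
    bundle = CohortBundle(
        leads=leads,
        ld_pairs=ld_pairs,
        annotations=annotations,
        selection=selection,
        gene_map=gene_map,
        gene_sets=gene_sets,
        truth=truth,
        variant_classes=classes,
    )
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle


def _plant_disease_set(
    prioritized_genes: frozenset[str],
    fold: float,
    M: int,
    N: int,
    rng: np.random.Generator,
    name: str = "PLANTED",
) -> tuple[GeneSetCollection, int]:
    n = len(prioritized_genes)
    m_star = int(round(fold * n * M / N)) if n else 0
    if m_star > min(n, M):
        raise ValueError(
            f"infeasible planted fold {fold}: m*={m_star} exceeds min(n={n}, M={M})"
        )
    overlap = sorted(rng.choice(sorted(prioritized_genes), size=m_star, replace=False)) if m_star else []
    fillers = [f"SYNF{i:05d}" for i in range(1, M - m_star + 1)]
    genes = frozenset(overlap) | frozenset(fillers)
    return GeneSetCollection({name: frozenset(genes)}, background_size=N), m_star


def generate_disease_sets(
    prioritized_genes: Sequence[str] | frozenset[str],
    planted_fold: float,
    M: int,
    N: int = 30000,
    seed: int | np.random.Generator = 0,
    name: str = "PLANTED",
) -> GeneSetCollection:
    """Build a disease gene set of size ``M`` whose overlap with the
    prioritized genes is m* = round(fold * n * M / N).

    Filler symbols are disjoint from the cohort namespace. Raises if the
    required overlap exceeds min(n, M).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    genes = frozenset(prioritized_genes)
    if not genes:
        raise ValueError("prioritized gene list is empty; nothing to plant against")
    sets, _ = _plant_disease_set(genes, planted_fold, M, N, rng, name=name)
    return sets
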