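"""Domain types, table schemas, and readers/writers for the pipeline.

All tables are plain tab-separated text. Positions are 1-based (GRCh37
convention) everywhere inside the package; conversion to 0-based half-open
intervals happens only at BED export. Missing values may be written as
``NA``, ``.`` or an empty field — the three encodings are equivalent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "AnnotationRecord",
    "GeneMap",
    "GeneSetCollection",
    "InputBundle",
    "LDPair",
    "PipelineConfig",
    "RegCategory",
    "RegCategoryParseError",
    "SchemaError",
    "SelectionRecord",
    "ValidationError",
    "VariantRecord",
    "parse_reg_category",
    "read_annotations",
    "read_disease_ld_dir",
    "read_gene_map",
    "read_gene_sets",
    "read_ld_pairs",
    "read_leads",
    "read_selection",
    "read_tables",
    "write_prioritized",
]

MISSING_TOKENS = {"", "NA", ".", "nan", "NaN"}

VAR_CLASSES = ("SNP", "insertion", "deletion")


class SchemaError(ValueError):
    """A required column is absent or a file does not match its schema."""


class ValidationError(ValueError):
    """A field value violates a documented invariant."""


class RegCategoryParseError(ValueError):
    """A regulatory-category token is not one of the recognised forms."""


# ---------------------------------------------------------------------------
# regulatory category (ordinal, RegulomeDB-style)
# ---------------------------------------------------------------------------

#: The 14 informative category tokens in increasing order of rank
#: (decreasing regulatory evidence). Major 7 means "no data" and sits
#: outside the ranked scale.
REG_CATEGORY_ORDER = (
    "1a", "1b", "1c", "1d", "1e", "1f",
    "2a", "2b", "2c",
    "3a", "3b",
    "4", "5", "6",
)

_RANK = {tok: i + 1 for i, tok in enumerate(REG_CATEGORY_ORDER)}

_VALID_MINORS = {1: "abcdef", 2: "abc", 3: "ab"}


@dataclass(frozen=True, order=False)
class RegCategory:
    """Ordinal regulatory-evidence class.

    Categories run 1a (strongest evidence: eQTL + TF binding + matched
    motif + DNase footprint + DNase peak) through 6 (minimal evidence);
    major category 7 encodes "no annotation data". Minor letters exist
    only for majors 1–3.
    """

    major: int
    minor: Optional[str] = None

    def __post_init__(self) -> None:
        if self.major == 7:
            if self.minor is not None:
                raise ValidationError("no-data category carries no minor letter")
            return
        if self.major in _VALID_MINORS:
            if self.minor is None or self.minor not in _VALID_MINORS[self.major]:
                raise ValidationError(
                    f"category {self.major} requires a minor letter in "
                    f"'{_VALID_MINORS[self.major]}', got {self.minor!r}"
                )
        elif self.major in (4, 5, 6):
            if self.minor is not None:
                raise ValidationError(f"category {self.major} carries no minor letter")
        else:
            raise ValidationError(f"major category must be 1..7, got {self.major}")

    @property
    def is_no_data(self) -> bool:
        return self.major == 7

    @property
    def rank(self) -> Optional[int]:
        """Position in the 1a < 1b < ... < 6 total order; None for no-data."""
        if self.is_no_data:
            return None
        return _RANK[self.token]

    @property
    def token(self) -> str:
        if self.is_no_data:
            return "7"
        return f"{self.major}{self.minor or ''}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.token


NO_DATA = RegCategory(7)


def parse_reg_category(token: str, row: Optional[int] = None) -> RegCategory:
    """Parse a category token such as ``"1f"``, ``"4"`` or ``"7"``.

    ``"7"``, ``"ND"`` and ``"."`` all map to the no-data category. Any
    other token outside the 14 valid forms raises
    :class:`RegCategoryParseError` naming the token (and row, if given).
    """
    tok = token.strip()
    where = f" (row {row})" if row is not None else ""
    if not tok:
        raise RegCategoryParseError(f"empty regulatory-category token{where}")
    if tok in ("7", "ND", "."):
        return NO_DATA
    if tok in _RANK:
        major = int(tok[0])
        minor = tok[1:] or None
        return RegCategory(major, minor)
    raise RegCategoryParseError(f"malformed regulatory-category token {tok!r}{where}")


# ---------------------------------------------------------------------------
# record types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariantRecord:
    """One variant: identifiers, coordinates, class and lead/proxy role."""

    rsid: str
    chrom: str = ""
    pos: int = 1
    ref_alt: Optional[str] = None
    var_class: str = "SNP"
    role: str = "proxy"

    def __post_init__(self) -> None:
        if not self.rsid:
            raise ValidationError("rsid must be non-empty")
        if self.pos < 1:
            raise ValidationError(f"{self.rsid}: pos must be >= 1, got {self.pos}")
        if self.var_class not in VAR_CLASSES:
            raise ValidationError(
                f"{self.rsid}: var_class must be one of {VAR_CLASSES}, got {self.var_class!r}"
            )
        if self.role not in ("lead", "proxy"):
            raise ValidationError(f"{self.rsid}: role must be 'lead' or 'proxy'")


@dataclass(frozen=True)
class LDPair:
    """A (lead, proxy, r²) edge. Self-pairs are implied with r² = 1, never stored."""

    lead_rsid: str
    proxy_rsid: str
    r2: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.r2 <= 1.0):
            raise ValidationError(
                f"{self.lead_rsid}-{self.proxy_rsid}: r2 must be in [0,1], got {self.r2}"
            )
        if self.lead_rsid == self.proxy_rsid:
            raise ValidationError(f"self LD pair stored for {self.lead_rsid}")


@dataclass(frozen=True)
class AnnotationRecord:
    """Per-variant annotation scores from the three classifiers.

    ``cadd_like`` is a scaled deleteriousness score (C-score analogue,
    >= 0, unbounded above); ``gwava_like`` a functional-impact score in
    [0,1] (missing for indels in real retrievals); ``regdb_cat`` the
    ordinal regulatory category.
    """

    rsid: str
    cadd_like: Optional[float] = None
    gwava_like: Optional[float] = None
    regdb_cat: Optional[RegCategory] = None

    def __post_init__(self) -> None:
        if not self.rsid:
            raise ValidationError("rsid must be non-empty")
        if self.cadd_like is not None and self.cadd_like < 0:
            raise ValidationError(f"{self.rsid}: cadd_like must be >= 0, got {self.cadd_like}")
        if self.gwava_like is not None and not (0.0 <= self.gwava_like <= 1.0):
            raise ValidationError(
                f"{self.rsid}: gwava_like must be in [0,1], got {self.gwava_like}"
            )


@dataclass(frozen=True)
class SelectionRecord:
    """Selection statistics for one variant.

    rs_score: rejected substitutions (neutral rate minus observed);
    nr_score: neutral rate (> 0); td: Tajima's D; daf: derived allele
    frequency in the focal population; delta_daf: DAF difference versus
    all other populations. td/daf/delta_daf may be missing.
    """

    rsid: str
    rs_score: float
    nr_score: float
    td: Optional[float] = None
    daf: Optional[float] = None
    delta_daf: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.rsid:
            raise ValidationError("rsid must be non-empty")
        if self.nr_score <= 0:
            raise ValidationError(f"{self.rsid}: nr_score must be > 0, got {self.nr_score}")
        if self.rs_score > self.nr_score + 1e-9:
            raise ValidationError(
                f"{self.rsid}: rs_score ({self.rs_score}) cannot exceed nr_score ({self.nr_score})"
            )
        if self.daf is not None and not (0.0 <= self.daf <= 1.0):
            raise ValidationError(f"{self.rsid}: daf must be in [0,1], got {self.daf}")
        if self.delta_daf is not None and not (-1.0 <= self.delta_daf <= 1.0):
            raise ValidationError(
                f"{self.rsid}: delta_daf must be in [-1,1], got {self.delta_daf}"
            )


@dataclass
class GeneSetCollection:
    """Disease-name -> gene-symbol sets, plus the genome background size."""

    sets: dict[str, frozenset[str]]
    background_size: int = 30000

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValidationError(f"gene set {name!r} is empty")
        if self.background_size <= 0:
            raise ValidationError("background_size must be positive")


@dataclass
class GeneMap:
    """rsid -> list of gene symbols (possibly empty; '-' rows parse to [])."""

    mapping: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def genes_for(self, rsid: str) -> tuple[str, ...]:
        return self.mapping.get(rsid, ())


@dataclass
class PipelineConfig:
    """Every threshold the pipeline applies, with the published defaults."""

    r2_min: float = 0.8
    cadd_cut: float = 10.0      # inclusive
    gwava_cut: float = 0.4      # inclusive
    regdb_cut_major: int = 2    # inclusive: category major <= 2 passes
    rs_strong: float = 2.0      # RS >= rs_strong => strong negative selection
    td_strong: float = 2.0      # TD > td_strong => balancing selection
    daf_high: float = 0.8       # DAF >= daf_high => high derived frequency
    background_N: int = 30000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, float) and not math.isfinite(v):
                raise ValidationError(f"config field {f.name} must be finite")
        if not (0.0 < self.r2_min <= 1.0):
            raise ValidationError(f"r2_min must be in (0,1], got {self.r2_min}")
        if self.background_N <= 0:
            raise ValidationError("background_N must be positive")

    def replace(self, **kw) -> "PipelineConfig":
        return replace(self, **kw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class InputBundle:
    """Everything a pipeline run reads, already validated."""

    variants: list[VariantRecord]
    ld_pairs: list[LDPair]
    annotations: list[AnnotationRecord]
    selection: list[SelectionRecord]
    gene_map: GeneMap
    gene_sets: Optional[GeneSetCollection] = None


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment="#")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    return df


def _opt_float(tok: str) -> Optional[float]:
    tok = tok.strip()
    if tok in MISSING_TOKENS:
        return None
    return float(tok)


def read_leads(path: str | Path) -> list[VariantRecord]:
    """Read a lead-SNP table (columns: rsid, chrom, pos [, var_class])."""
    df = _read_tsv(path, ["rsid", "chrom", "pos"])
    has_class = "var_class" in df.columns
    out = []
    for row in df.itertuples(index=False):
        out.append(
            VariantRecord(
                rsid=row.rsid.strip(),
                chrom=str(row.chrom).strip(),
                pos=int(row.pos),
                var_class=row.var_class.strip() if has_class else "SNP",
                role="lead",
            )
        )
    return out


def read_ld_pairs(path: str | Path) -> list[LDPair]:
    """Read an LD table (columns: lead_rsid, proxy_rsid, r2). Self rows are dropped."""
    df = _read_tsv(path, ["lead_rsid", "proxy_rsid", "r2"])
    out = []
    for row in df.itertuples(index=False):
        lead, proxy = row.lead_rsid.strip(), row.proxy_rsid.strip()
        if lead == proxy:
            # self-association is implicit (r² = 1); storing it is harmless noise
            continue
        out.append(LDPair(lead, proxy, float(row.r2)))
    return out


def read_annotations(path: str | Path) -> list[AnnotationRecord]:
    """Read an annotation table (columns: rsid, cadd, gwava, regdb).

    An rsID may appear on several rows (multi-allelic sites get one
    deleteriousness score per substitution). Duplicates collapse to a
    single record keeping the maximum cadd score, the maximum non-missing
    gwava score, and the best-ranked (strongest-evidence) non-missing
    regulatory category — a risk-maximal policy.
    """
    df = _read_tsv(path, ["rsid", "cadd", "gwava", "regdb"])
    grouped: dict[str, dict] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        rsid = row.rsid.strip()
        cadd = _opt_float(row.cadd)
        gwava = _opt_float(row.gwava)
        tok = row.regdb.strip()
        cat = None if tok in MISSING_TOKENS else parse_reg_category(tok, row=i + 2)
        slot = grouped.setdefault(rsid, {"cadd": None, "gwava": None, "cat": None})
        if cadd is not None and (slot["cadd"] is None or cadd > slot["cadd"]):
            slot["cadd"] = cadd
        if gwava is not None and (slot["gwava"] is None or gwava > slot["gwava"]):
            slot["gwava"] = gwava
        if cat is not None and not cat.is_no_data:
            if slot["cat"] is None or slot["cat"].is_no_data or cat.rank < slot["cat"].rank:
                slot["cat"] = cat
        elif cat is not None and slot["cat"] is None:
            slot["cat"] = cat
    return [
        AnnotationRecord(rsid, s["cadd"], s["gwava"], s["cat"])
        for rsid, s in grouped.items()
    ]


def read_selection(path: str | Path) -> list[SelectionRecord]:
    """Read a selection-statistics table (columns: rsid, rs, nr, td, daf, ddaf)."""
    df = _read_tsv(path, ["rsid", "rs", "nr", "td", "daf", "ddaf"])
    out = []
    for row in df.itertuples(index=False):
        out.append(
            SelectionRecord(
                rsid=row.rsid.strip(),
                rs_score=float(row.rs),
                nr_score=float(row.nr),
                td=_opt_float(row.td),
                daf=_opt_float(row.daf),
                delta_daf=_opt_float(row.ddaf),
            )
        )
    return out


def read_gene_map(path: str | Path) -> GeneMap:
    """Read an rsid -> comma-separated gene-symbol table. '-' means no genes."""
    df = _read_tsv(path, ["rsid", "genes"])
    mapping: dict[str, tuple[str, ...]] = {}
    for row in df.itertuples(index=False):
        raw = row.genes.strip()
        if raw in MISSING_TOKENS or raw == "-":
            genes: tuple[str, ...] = ()
        else:
            genes = tuple(g.strip() for g in raw.split(",") if g.strip())
        mapping[row.rsid.strip()] = genes
    return GeneMap(mapping)


def read_gene_sets(path: str | Path, background_size: int = 30000) -> GeneSetCollection:
    """Read disease gene sets from a standard GMT file (name, description, genes...)."""
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise SchemaError(f"{path}:{lineno}: GMT line needs name, description, >=1 gene")
            name = parts[0].strip()
            genes = frozenset(g.strip() for g in parts[2:] if g.strip())
            if not genes:
                raise SchemaError(f"{path}:{lineno}: gene set {name!r} has no genes")
            sets[name] = genes
    return GeneSetCollection(sets, background_size)


def read_disease_ld_dir(directory: str | Path) -> dict[str, pd.DataFrame]:
    """Read one LD table per reference disease from ``<disease>.tsv`` files.

    Unlike :func:`read_ld_pairs`, self rows (lead == proxy) are retained:
    they declare that the SNP is itself a lead for that disease.
    """
    tables = {}
    for p in sorted(Path(directory).glob("*.tsv")):
        df = _read_tsv(p, ["lead_rsid", "proxy_rsid", "r2"])
        df = df.assign(r2=df["r2"].astype(float))
        tables[p.stem] = df
    return tables


def read_tables(
    leads_path: str | Path,
    ld_path: str | Path,
    annot_path: str | Path,
    selection_path: str | Path | None = None,
    genemap_path: str | Path | None = None,
    genesets_path: str | Path | None = None,
    config: Optional[PipelineConfig] = None,
) -> InputBundle:
    """Read and validate a full input bundle."""
    config = config or PipelineConfig()
    return InputBundle(
        variants=read_leads(leads_path),
        ld_pairs=read_ld_pairs(ld_path),
        annotations=read_annotations(annot_path),
        selection=read_selection(selection_path) if selection_path else [],
        gene_map=read_gene_map(genemap_path) if genemap_path else GeneMap(),
        gene_sets=(
            read_gene_sets(genesets_path, config.background_N) if genesets_path else None
        ),
    )


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

PRIORITIZED_COLUMNS = [
    "rsid", "chrom", "pos", "lead_rsid", "r2", "cadd", "gwava", "regdb", "genes",
]


def _fmt(v) -> str:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return "NA"
    if isinstance(v, RegCategory):
        return v.token
    if isinstance(v, float):
        return f"{v:g}"
    return str(v)


def write_prioritized(
    records: Iterable[Mapping],
    path: str | Path,
    format: str = "tsv",
) -> Path:
    """Write prioritized variants as TSV (default), BED, or minimal VCF.

    Each record is a mapping with the :data:`PRIORITIZED_COLUMNS` keys;
    ``genes`` may be a sequence of symbols. BED converts the 1-based
    position to a 0-based half-open interval; an empty record list yields
    a header-only file.
    """
    path = Path(path)
    rows = list(records)
    if format == "tsv":
        with open(path, "w") as fh:
            fh.write("\t".join(PRIORITIZED_COLUMNS) + "\n")
            for r in rows:
                vals = []
                for c in PRIORITIZED_COLUMNS:
                    v = r.get(c)
                    if c == "genes" and not isinstance(v, str):
                        v = ",".join(v) if v else "-"
                    vals.append(_fmt(v))
                fh.write("\t".join(vals) + "\n")
    elif format == "bed":
        with open(path, "w") as fh:
            for r in rows:
                pos = int(r["pos"])
                fh.write(f"{r['chrom']}\t{pos - 1}\t{pos}\t{r['rsid']}\n")
    elif format == "vcf":
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##INFO=<ID=LEAD,Number=1,Type=String,Description="Lead SNP of the locus">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            for r in rows:
                ref_alt = r.get("ref_alt") or "N\tN"
                if isinstance(ref_alt, str) and "\t" not in ref_alt:
                    ref_alt = ref_alt.replace("/", "\t")
                info = f"LEAD={r.get('lead_rsid', '.')}"
                fh.write(
                    f"{r['chrom']}\t{r['pos']}\t{r['rsid']}\t{ref_alt}\t.\tPASS\t{info}\n"
                )
    else:
        raise ValueError(f"unknown format {format!r}")
    return path
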