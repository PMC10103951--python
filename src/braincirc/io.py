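"""Readers and writers for every external format the pipeline touches.

All genomic intervals are 0-based half-open internally (BED-native).
GTF input (1-based closed) is converted on read: exon [s, e] -> [s-1, e).
Writers emit a deterministic column order and row sort so that runs with
identical inputs are byte-identical.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import gffutils
import numpy as np
import pandas as pd

#: Default mapping from cell type to cell group: pyramidal neurons from the
#: temporal (TCPY) and motor (MCPY) cortex are pooled as PY; peripheral blood
#: mononuclear cells and fibroblasts as non-neuronal (NN).
DEFAULT_GROUP_MAP = {"DA": "DA", "TCPY": "PY", "MCPY": "PY", "PBMC": "NN", "FB": "NN"}

#: Deterministic group order used for tie-breaking throughout.
GROUP_ORDER = ("DA", "PY", "NN")

CIRC_CLASSES = ("exonic", "ciRNA")

BED12_COLUMNS = [
    "chrom", "start", "end", "name", "score", "strand",
    "thickStart", "thickEnd", "itemRgb", "blockCount", "blockSizes",
    "blockStarts", "circType", "geneName", "readNumber",
]


class ParseError(ValueError):
    """Malformed input line; message names the offending line number."""


class ValidationError(ValueError):
    """Structurally parseable input violating a domain invariant."""


# ---------------------------------------------------------------------------
# CircRecord
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CircRecord:
    """One back-spliced circular RNA.

    ``exon_blocks`` are (genomic_start, size) pairs, sorted, non-overlapping,
    tiling the circle boundaries: the first block starts at ``start`` and the
    last block ends at ``end``.  ``circ_class`` is ``exonic`` for exon-derived
    circles and ``ciRNA`` for circular intronic RNAs, which by definition
    consist of a single block spanning the whole interval.
    """

    chrom: str
    start: int
    end: int
    strand: str
    circ_class: str
    host_gene: str
    exon_blocks: tuple[tuple[int, int], ...]
    bsj_reads_total: int
    extra: tuple[str, ...] = field(default=())

    @property
    def circ_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}|{self.strand}"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval [{self.start}, {self.end}) for {self.chrom}"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"invalid strand {self.strand!r}")
        if self.circ_class not in CIRC_CLASSES:
            raise ValidationError(f"invalid circ_class {self.circ_class!r}")
        if self.bsj_reads_total < 0:
            raise ValidationError("bsj_reads_total must be non-negative")
        if not self.exon_blocks:
            raise ValidationError("at least one exon block required")
        prev_end = None
        for bs, size in self.exon_blocks:
            if size <= 0:
                raise ValidationError("block sizes must be positive")
            if bs < self.start or bs + size > self.end:
                raise ValidationError(
                    f"block [{bs}, {bs + size}) outside [{self.start}, {self.end})"
                )
            if prev_end is not None and bs < prev_end:
                raise ValidationError("blocks must be sorted and non-overlapping")
            prev_end = bs + size
        if self.exon_blocks[0][0] != self.start:
            raise ValidationError("first block must start at circle start")
        last_start, last_size = self.exon_blocks[-1]
        if last_start + last_size != self.end:
            raise ValidationError("last block must end at circle end")
        if self.circ_class == "ciRNA" and (
            len(self.exon_blocks) != 1
            or self.exon_blocks[0] != (self.start, self.end - self.start)
        ):
            raise ValidationError("ciRNA must be a single block spanning the interval")


_CIRC_CLASS_ALIASES = {"exonic": "exonic", "circRNA": "exonic", "ciRNA": "ciRNA"}


def _parse_circ_line(fields: list[str], lineno: int) -> CircRecord:
    if len(fields) < 15:
        raise ParseError(f"line {lineno}: expected >=15 tab-separated columns, got {len(fields)}")
    try:
        chrom = fields[0]
        start, end = int(fields[1]), int(fields[2])
        strand = fields[5]
        n_blocks = int(fields[9])
        sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
        offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
        circ_type = fields[12]
        gene = fields[13]
        reads = int(fields[14])
    except ValueError as exc:
        raise ParseError(f"line {lineno}: {exc}") from None
    if len(sizes) != n_blocks or len(offsets) != n_blocks:
        raise ParseError(
            f"line {lineno}: blockCount {n_blocks} does not match block lists"
        )
    if circ_type not in _CIRC_CLASS_ALIASES:
        raise ParseError(f"line {lineno}: unknown circType {circ_type!r}")
    try:
        return CircRecord(
            chrom=chrom,
            start=start,
            end=end,
            strand=strand,
            circ_class=_CIRC_CLASS_ALIASES[circ_type],
            host_gene=gene,
            exon_blocks=tuple((start + off, size) for off, size in zip(offsets, sizes)),
            bsj_reads_total=reads,
            extra=tuple(fields[15:]),
        )
    except ValidationError as exc:
        raise ValidationError(f"line {lineno}: {exc}") from None


def read_circ_bed(path) -> list[CircRecord]:
    """Read circRNA calls in the BED12+ dialect of the upstream caller.

    Standard BED12 columns followed by circType, geneName, readNumber; any
    further columns are preserved as opaque annotations.  Block offsets are
    converted to genomic coordinates and records sorted by (chrom, start, end).
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            records.append(_parse_circ_line(line.split("\t"), lineno))
    records.sort(key=lambda r: (r.chrom, r.start, r.end, r.strand))
    return records


def write_circ_bed(records: list[CircRecord], path) -> None:
    """Write records in the same BED12+ dialect, sorted canonically."""
    recs = sorted(records, key=lambda r: (r.chrom, r.start, r.end, r.strand))
    class_out = {"exonic": "exonic", "ciRNA": "ciRNA"}
    with open(path, "w") as fh:
        for r in recs:
            sizes = ",".join(str(s) for _, s in r.exon_blocks)
            offs = ",".join(str(bs - r.start) for bs, _ in r.exon_blocks)
            fields = [
                r.chrom, str(r.start), str(r.end), r.circ_id, "0", r.strand,
                str(r.start), str(r.end), "0", str(len(r.exon_blocks)),
                sizes, offs, class_out[r.circ_class], r.host_gene,
                str(r.bsj_reads_total), *r.extra,
            ]
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Count matrices
# ---------------------------------------------------------------------------

def read_count_matrix(path) -> pd.DataFrame:
    """Read a circRNA x sample matrix of non-negative integer counts (TSV)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate row ids: {dups}")
    if df.columns.has_duplicates:
        raise ValidationError("duplicate sample ids in header")
    if df.isna().any().any():
        raise ValidationError("missing cells in count matrix")
    for col in df.columns:
        if not pd.api.types.is_integer_dtype(df[col]):
            raise ValidationError(f"non-integer counts in column {col!r}")
    if (df.to_numpy() < 0).any():
        raise ValidationError("negative counts")
    df.index.name = "circ_id"
    return df


def write_count_matrix(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out.index.name = "circ_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

SAMPLE_COLUMNS = [
    "sample_id", "cell_type", "group", "condition", "sex", "age", "pmi",
    "rin", "library_size", "rnase_status", "pair_id",
]


def validate_sample_table(samples: pd.DataFrame) -> pd.DataFrame:
    if samples["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample_ids")
    if (samples["library_size"] <= 0).any():
        raise ValidationError("library_size must be positive")
    bad = set(samples["rnase_status"]) - {"treated", "mock", "none"}
    if bad:
        raise ValidationError(f"invalid rnase_status values: {sorted(bad)}")
    treated = samples[samples["rnase_status"] == "treated"]
    mock = samples[samples["rnase_status"] == "mock"]
    mock_ids = mock["pair_id"].value_counts()
    for pid in treated["pair_id"]:
        if mock_ids.get(pid, 0) != 1:
            raise ValidationError(
                f"treated sample pair_id {pid!r} must match exactly one mock sample"
            )
    return samples


def read_sample_table(path, group_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read per-sample metadata; derive the cell group from cell type.

    The group column, if absent, is derived through ``group_map`` (default:
    TCPY/MCPY -> PY, PBMC/FB -> NN, DA -> DA).
    """
    samples = pd.read_csv(path, sep="\t", dtype={"pair_id": str}, keep_default_na=False)
    missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns and c != "group"]
    if missing:
        raise ValidationError(f"sample table missing columns: {missing}")
    if "group" not in samples.columns:
        gmap = dict(DEFAULT_GROUP_MAP if group_map is None else group_map)
        unknown = set(samples["cell_type"]) - set(gmap)
        if unknown:
            raise ValidationError(f"cell types without group mapping: {sorted(unknown)}")
        samples["group"] = samples["cell_type"].map(gmap)
    return validate_sample_table(samples[SAMPLE_COLUMNS].copy())


def write_sample_table(samples: pd.DataFrame, path) -> None:
    samples[SAMPLE_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene models (GTF)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """Exon structure of one gene: per-transcript sorted exon interval lists."""

    gene_id: str
    chrom: str
    strand: str
    transcripts: dict[str, tuple[tuple[int, int], ...]]
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        for tx, exons in self.transcripts.items():
            prev_end = None
            for s, e in exons:
                if s >= e:
                    raise ValidationError(f"{self.gene_id}/{tx}: empty exon [{s}, {e})")
                if prev_end is not None and s < prev_end:
                    raise ValidationError(
                        f"{self.gene_id}/{tx}: exons must be sorted, non-overlapping"
                    )
                prev_end = e

    def max_exon_count(self) -> int:
        return max(len(ex) for ex in self.transcripts.values())

    def all_exons(self) -> set[tuple[int, int]]:
        return {iv for exons in self.transcripts.values() for iv in exons}


def gtf_to_bed_interval(start_1based: int, end_closed: int) -> tuple[int, int]:
    """Convert a GTF 1-based closed interval [s, e] to 0-based half-open [s-1, e)."""
    return start_1based - 1, end_closed


def read_gtf(path) -> dict[str, GeneModel]:
    """Read exon models from a GTF file into 0-based half-open coordinates."""
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    per_gene: dict[str, dict] = {}
    for ex in db.features_of_type("exon"):
        gene_id = ex.attributes["gene_id"][0]
        tx_id = ex.attributes["transcript_id"][0]
        biotype = ex.attributes.get("gene_biotype", ["protein_coding"])[0]
        g = per_gene.setdefault(
            gene_id,
            {"chrom": ex.seqid, "strand": ex.strand, "biotype": biotype, "tx": {}},
        )
        g["tx"].setdefault(tx_id, []).append(gtf_to_bed_interval(ex.start, ex.end))
    models = {}
    for gene_id, g in sorted(per_gene.items()):
        transcripts = {
            tx: tuple(sorted(exons)) for tx, exons in sorted(g["tx"].items())
        }
        models[gene_id] = GeneModel(
            gene_id=gene_id, chrom=g["chrom"], strand=g["strand"],
            transcripts=transcripts, biotype=g["biotype"],
        )
    return models


def write_gtf(models: dict[str, GeneModel], path) -> None:
    """Emit exon lines (1-based closed, per GTF) in deterministic order."""
    with open(path, "w") as fh:
        for gene_id in sorted(models):
            m = models[gene_id]
            for tx_id in sorted(m.transcripts):
                for s, e in m.transcripts[tx_id]:
                    attrs = (
                        f'gene_id "{gene_id}"; transcript_id "{tx_id}"; '
                        f'gene_biotype "{m.biotype}";'
                    )
                    fh.write(
                        "\t".join(
                            [m.chrom, "braincirc", "exon", str(s + 1), str(e),
                             ".", m.strand, ".", attrs]
                        )
                        + "\n"
                    )


# ---------------------------------------------------------------------------
# Gene sets (GMT) and disease-gene associations
# ---------------------------------------------------------------------------

def read_gmt(path) -> dict[str, tuple[str, tuple[str, ...]]]:
    """Read a GMT file: set_id -> (description, deduplicated member tuple)."""
    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"line {lineno}: GMT requires set_id, description and >=1 member"
                )
            set_id, desc = fields[0], fields[1]
            members = tuple(dict.fromkeys(g for g in fields[2:] if g))
            if not members:
                raise ParseError(f"line {lineno}: gene set {set_id!r} has no members")
            sets[set_id] = (desc, members)
    return sets


def write_gmt(sets: dict[str, tuple[str, tuple[str, ...]]], path) -> None:
    with open(path, "w") as fh:
        for set_id in sorted(sets):
            desc, members = sets[set_id]
            fh.write("\t".join([set_id, desc, *members]) + "\n")


GDA_COLUMNS = ["gene_id", "disease_id", "disease_name", "gda_score", "mesh_classes"]


def read_gda(path, score_threshold: float = 0.1) -> pd.DataFrame:
    """Read a disease-gene association table, keeping rows with score strictly
    above ``score_threshold``.  ``mesh_classes`` is a ``|``-separated list,
    parsed into frozensets."""
    df = pd.read_csv(path, sep="\t", dtype={"mesh_classes": str}, keep_default_na=False)
    missing = [c for c in GDA_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"GDA table missing columns: {missing}")
    if len(df):
        scores = df["gda_score"].astype(float)
        if ((scores < 0) | (scores > 1)).any():
            raise ValidationError("gda_score outside [0, 1]")
        df = df[scores > score_threshold].copy()
    df["mesh_classes"] = [
        frozenset(x.split("|")) - {""} for x in df["mesh_classes"].astype(str)
    ]
    return df[GDA_COLUMNS].reset_index(drop=True)


def read_snp_table(path) -> pd.DataFrame:
    """Read a SNP position table: columns chrom, position (0-based), snp_id."""
    df = pd.read_csv(path, sep="\t")
    for col in ("chrom", "position", "snp_id"):
        if col not in df.columns:
            raise ValidationError(f"SNP table missing column {col!r}")
    if (df["position"] < 0).any():
        raise ValidationError("negative SNP position")
    return df


def read_fpkm_table(path) -> pd.DataFrame:
    """Read a gene x sample FPKM matrix (TSV, float cells allowed)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise ValidationError("duplicate gene ids in FPKM table")
    if df.isna().any().any():
        raise ValidationError("missing cells in FPKM table")
    if (df.to_numpy() < 0).any():
        raise ValidationError("negative FPKM values")
    df.index.name = "gene_id"
    return df


def write_fpkm_table(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.6g")
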