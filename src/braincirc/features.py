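"""Genomic characterization of circRNAs against annotation and interval tracks.

Covers the biogenesis-associated features of back-spliced exons: circularized
exon lengths, flanking intron lengths, repeat-element content of flanking
introns, RNA-binding-protein (eCLIP) peak overlap, circles-per-gene versus
exon count, and GWAS SNP proximity.  All intervals are 0-based half-open; a
peak touching a query end-to-start does not overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .io import CircRecord, GeneModel, ValidationError
from .ranktest import RankTestResult, mann_whitney


class BoundaryError(ValidationError):
    """circRNA boundary does not coincide with an annotated exon border."""


@dataclass
class IntervalTrack:
    """Named collection of genomic intervals, indexed per chromosome."""

    name: str
    trees: dict[str, IntervalTree] = field(default_factory=dict)

    @classmethod
    def from_intervals(cls, name: str, intervals) -> "IntervalTrack":
        track = cls(name=name)
        for chrom, start, end in intervals:
            if start >= end:
                raise ValidationError(f"empty interval [{start}, {end}) on {chrom}")
            track.trees.setdefault(chrom, IntervalTree()).addi(start, end)
        return track

    @classmethod
    def from_bed(cls, name: str, path) -> "IntervalTrack":
        intervals = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ValidationError(f"line {lineno}: BED needs >= 3 columns")
                intervals.append((fields[0], int(fields[1]), int(fields[2])))
        return cls.from_intervals(name, intervals)


def overlap_count(query: tuple[str, int, int], track: IntervalTrack) -> int:
    """Number of track intervals with non-empty half-open intersection."""
    chrom, start, end = query
    if start >= end:
        raise ValidationError(f"empty query interval [{start}, {end})")
    tree = track.trees.get(chrom)
    return 0 if tree is None else len(tree.overlap(start, end))


# ---------------------------------------------------------------------------
# Flanking introns
# ---------------------------------------------------------------------------

def _matching_transcript(
    circ: CircRecord, model: GeneModel
) -> tuple[str, tuple[tuple[int, int], ...], int] | None:
    """Transcript whose exon chain contains the circle's blocks as a
    contiguous run; ambiguity resolved by longest transcript (then id)."""
    block_ivs = tuple((s, s + size) for s, size in circ.exon_blocks)
    candidates = []
    for tx_id, exons in model.transcripts.items():
        try:
            i = exons.index(block_ivs[0])
        except ValueError:
            continue
        if exons[i : i + len(block_ivs)] == block_ivs:
            length = sum(e - s for s, e in exons)
            candidates.append((length, tx_id, exons, i))
    if not candidates:
        return None
    candidates.sort(key=lambda c: (-c[0], c[1]))
    _, tx_id, exons, i = candidates[0]
    return tx_id, exons, i


def flanking_introns(
    circ: CircRecord, model: GeneModel, strict: bool = False
) -> tuple[tuple[int, int] | None, tuple[int, int] | None]:
    """Introns flanking the circularized exon run, as (start, end) intervals.

    The genomic-left intron is the gap between the preceding exon and the
    circle start; genomic-right analogous.  On the minus strand the labels
    swap so that "upstream" is upstream in transcript orientation.  ``None``
    at a transcript terminus.  Strict mode demands the circle boundaries be
    annotated exon borders (blocks matching a contiguous exon run).
    """
    if circ.host_gene != model.gene_id:
        raise ValidationError(
            f"circ host gene {circ.host_gene!r} does not match model {model.gene_id!r}"
        )
    match = _matching_transcript(circ, model)
    if match is not None:
        _, exons, i = match
        j = i + len(circ.exon_blocks) - 1
        left = (exons[i - 1][1], circ.start) if i > 0 else None
        right = (circ.end, exons[j + 1][0]) if j + 1 < len(exons) else None
    else:
        if strict:
            raise BoundaryError(
                f"{circ.circ_id}: boundaries are not annotated exon borders"
            )
        # fall back to the longest transcript's nearest exon edges
        tx_id = min(
            model.transcripts,
            key=lambda t: (-sum(e - s for s, e in model.transcripts[t]), t),
        )
        exons = model.transcripts[tx_id]
        start_in_exon = any(s < circ.start < e for s, e in exons)
        end_in_exon = any(s < circ.end < e for s, e in exons)
        prev_ends = [e for _, e in exons if e <= circ.start]
        next_starts = [s for s, _ in exons if s >= circ.end]
        left = (
            (max(prev_ends), circ.start)
            if not start_in_exon and prev_ends and max(prev_ends) < circ.start
            else None
        )
        right = (
            (circ.end, min(next_starts))
            if not end_in_exon and next_starts and min(next_starts) > circ.end
            else None
        )
    if circ.strand == "-":
        return right, left
    return left, right


def noncircularized_exons(
    circs: list[CircRecord], models: dict[str, GeneModel]
) -> list[tuple[str, int, int]]:
    """Background exon set: annotated exons of circRNA-producing genes that
    are not part of any circle's block."""
    used: dict[str, set[tuple[int, int]]] = {}
    for c in circs:
        used.setdefault(c.host_gene, set()).update(
            (s, s + size) for s, size in c.exon_blocks
        )
    out = []
    for gene, blocks in sorted(used.items()):
        model = models.get(gene)
        if model is None:
            continue
        for iv in sorted(model.all_exons() - blocks):
            out.append((model.chrom, iv[0], iv[1]))
    return out


def feature_summary(
    circs: list[CircRecord],
    models: dict[str, GeneModel],
    repeats: IntervalTrack | None = None,
    eclip: IntervalTrack | None = None,
    strict: bool = False,
) -> pd.DataFrame:
    """Per-circRNA feature table: exon lengths, flanking intron lengths,
    repeat counts per flanking intron, and eCLIP peak overlaps with the
    circularized exons."""
    rows = []
    for c in circs:
        model = models.get(c.host_gene)
        if model is None:
            raise ValidationError(f"host gene {c.host_gene!r} absent from annotation")
        up, down = flanking_introns(c, model, strict=strict)
        exon_lengths = [size for _, size in c.exon_blocks]
        row = {
            "circ_id": c.circ_id,
            "host_gene": c.host_gene,
            "circ_class": c.circ_class,
            "n_blocks": len(c.exon_blocks),
            "mean_exon_length": float(np.mean(exon_lengths)),
            "total_exon_length": int(np.sum(exon_lengths)),
            "upstream_intron_length": up[1] - up[0] if up else np.nan,
            "downstream_intron_length": down[1] - down[0] if down else np.nan,
        }
        if repeats is not None:
            row["upstream_repeats"] = (
                overlap_count((c.chrom, *up), repeats) if up else np.nan
            )
            row["downstream_repeats"] = (
                overlap_count((c.chrom, *down), repeats) if down else np.nan
            )
        if eclip is not None:
            row["eclip_peaks"] = sum(
                overlap_count((c.chrom, s, s + size), eclip)
                for s, size in c.exon_blocks
            )
        rows.append(row)
    return pd.DataFrame(rows)


def compare_feature(group_a, group_b) -> tuple[RankTestResult, float, float]:
    """Two-sided rank test plus group medians for one feature."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise ValidationError("both feature groups must be non-empty")
    return mann_whitney(a, b), float(np.median(a)), float(np.median(b))


# ---------------------------------------------------------------------------
# Circles per gene vs exon count
# ---------------------------------------------------------------------------

def circ_per_gene_vs_exons(
    circs: list[CircRecord], models: dict[str, GeneModel]
) -> tuple[pd.DataFrame, float, bool]:
    """Per-gene (circle count, max exon count) with their Pearson r.

    Returns (table, r, degenerate) where degenerate flags a zero-variance
    input for which r is reported as 0.
    """
    if len(models) < 3:
        raise ValidationError("need at least 3 genes")
    n_circ = pd.Series(0, index=sorted(models))
    for c in circs:
        if c.host_gene in n_circ.index:
            n_circ[c.host_gene] += 1
    table = pd.DataFrame(
        {
            "gene_id": sorted(models),
            "n_circ": [int(n_circ[g]) for g in sorted(models)],
            "n_exons": [models[g].max_exon_count() for g in sorted(models)],
        }
    )
    if table["n_circ"].nunique() == 1 or table["n_exons"].nunique() == 1:
        return table, 0.0, True
    r = stats.pearsonr(table["n_circ"], table["n_exons"]).statistic
    return table, float(r), False


# ---------------------------------------------------------------------------
# SNP proximity
# ---------------------------------------------------------------------------

def snp_proximity_fraction(
    snps: pd.DataFrame, circs: list[CircRecord], window: int = 1_000_000
) -> float:
    """Fraction of SNPs within ``window`` bp of (or inside) any circRNA.

    Distance is measured to the interval edge: 0 inside the half-open
    interval, otherwise the gap to the nearest covered base.
    """
    if window < 0:
        raise ValidationError("window must be >= 0")
    if len(snps) == 0:
        raise ValidationError("empty SNP table")
    if not circs:
        return 0.0
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for c in circs:
        by_chrom.setdefault(c.chrom, []).append((c.start, c.end))
    hits = 0
    for chrom, sub in snps.groupby("chrom"):
        ivs = by_chrom.get(chrom)
        if not ivs:
            continue
        starts = np.array([s for s, _ in ivs])
        ends = np.array([e for _, e in ivs])
        pos = sub["position"].to_numpy()
        # distance of each SNP to each interval; 0 when inside
        left = starts[None, :] - pos[:, None]
        right = pos[:, None] - (ends[None, :] - 1)
        dist = np.maximum(np.maximum(left, right), 0)
        hits += int((dist.min(axis=1) <= window).sum())
    return hits / len(snps)


def proportion_percent(numerator: int, denominator: int, decimals: int = 1) -> float:
    """Coverage percentage, e.g. GWAS genes producing circRNAs."""
    if denominator <= 0:
        raise ValidationError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ValidationError("numerator must lie in [0, denominator]")
    return round(100.0 * numerator / denominator, decimals)
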