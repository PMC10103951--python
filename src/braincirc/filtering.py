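"""Two-stage circRNA filtering: expression support, then RNase-R validation.

RNase R digests linear RNAs but spares covalently closed circles, so a genuine
circle should be enriched in a treated library relative to its mock-treated
pair.  Validation requires, within at least one treated/mock pair, (i) a raw
treated read count at or above ``min_treated_reads`` and (ii) a library-size-
scaled (reads-per-million) treated/mock fold at or above ``min_fold``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .io import ValidationError


def filter_expressed(counts: pd.DataFrame, min_total_reads: int = 2) -> set[str]:
    """circRNAs whose total read support across all samples meets the floor."""
    totals = counts.sum(axis=1)
    return set(totals.index[totals >= min_total_reads])


@dataclass(frozen=True)
class PairEvidence:
    pair_id: str
    treated_reads: int
    mock_reads: int
    fold_enrichment: float  # per-million scaled; inf when mock is fully digested


@dataclass(frozen=True)
class ValidationResult:
    circ_id: str
    expressed: bool
    pairs: tuple[PairEvidence, ...]
    validated: bool


def _pairing(pair_meta: pd.DataFrame) -> list[tuple[str, str, str, float, float]]:
    """(pair_id, treated_sample, mock_sample, treated_lib, mock_lib) tuples."""
    treated = pair_meta[pair_meta["rnase_status"] == "treated"]
    mock = pair_meta[pair_meta["rnase_status"] == "mock"].set_index("pair_id")
    if mock.index.has_duplicates:
        dup = mock.index[mock.index.duplicated()][0]
        raise ValidationError(f"multiple mock samples for pair_id {dup!r}")
    out = []
    for _, row in treated.iterrows():
        pid = row["pair_id"]
        if pid not in mock.index:
            raise ValidationError(f"treated sample with unmatched pair_id {pid!r}")
        m = mock.loc[pid]
        out.append(
            (pid, row["sample_id"], m["sample_id"],
             float(row["library_size"]), float(m["library_size"]))
        )
    return out


def rnase_validate(
    counts: pd.DataFrame,
    pair_meta: pd.DataFrame,
    min_treated_reads: int = 20,
    min_fold: float = 2.0,
    min_total_reads: int = 2,
) -> dict[str, ValidationResult]:
    """Evaluate the RNase-R validation filter for every circRNA.

    The read floor applies to raw treated reads; the fold is computed on
    per-million-scaled counts.  A circle with treated reads but a fully
    digested (zero-count) mock gets fold +inf and passes the fold test;
    zero treated reads give fold 0.  Validation requires both criteria within
    the same pair, in at least one pair, and expression support overall.
    """
    pairs = _pairing(pair_meta)
    if not pairs:
        raise ValidationError("no treated/mock pairs in metadata")
    expressed = filter_expressed(counts, min_total_reads)
    results: dict[str, ValidationResult] = {}
    for circ_id, row in counts.iterrows():
        evidence = []
        passed = False
        for pid, t_sample, m_sample, t_lib, m_lib in pairs:
            t, m = int(row[t_sample]), int(row[m_sample])
            t_rpm = t / t_lib * 1e6
            m_rpm = m / m_lib * 1e6
            if t == 0:
                fold = 0.0
            elif m == 0:
                fold = math.inf
            else:
                fold = t_rpm / m_rpm
            evidence.append(PairEvidence(pid, t, m, fold))
            if t >= min_treated_reads and fold >= min_fold:
                passed = True
        is_expr = circ_id in expressed
        results[circ_id] = ValidationResult(
            circ_id=circ_id,
            expressed=is_expr,
            pairs=tuple(evidence),
            validated=bool(passed and is_expr),
        )
    return results


def validated_set(results: dict[str, ValidationResult]) -> set[str]:
    return {cid for cid, r in results.items() if r.validated}


def validation_rate(validated_counts: int, candidate_counts: int) -> float:
    """Percentage of candidates surviving validation, to one decimal."""
    if candidate_counts <= 0:
        raise ValueError("candidate_counts must be positive")
    if not 0 <= validated_counts <= candidate_counts:
        raise ValueError("validated_counts must be within [0, candidates]")
    return round(100.0 * validated_counts / candidate_counts, 1)


def results_table(results: dict[str, ValidationResult]) -> pd.DataFrame:
    """Flatten ValidationResults into a per-circ TSV-ready table."""
    rows = []
    for cid in sorted(results):
        r = results[cid]
        best = max((p.fold_enrichment for p in r.pairs), default=0.0)
        rows.append(
            {
                "circ_id": cid,
                "expressed": int(r.expressed),
                "n_pairs": len(r.pairs),
                "max_fold_enrichment": best,
                "max_treated_reads": max((p.treated_reads for p in r.pairs), default=0),
                "validated": int(r.validated),
            }
        )
    return pd.DataFrame(rows)
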