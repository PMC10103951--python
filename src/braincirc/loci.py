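"""Host-locus architecture of cell-type-specific circRNAs, and
circular-to-linear expression ratios.

A locus is *exclusive* to a group when every specific circRNA it produces is
assigned to that one group; a *super-host* locus tailors distinct specific
circRNA isoforms to two or more groups (e.g. via alternative back-splicing).
The circular-to-linear ratio relates BSJ read abundance to the linear
(spliced + unspliced) reads spanning the same donor and acceptor sites.
"""

from __future__ import annotations

import pandas as pd

from .io import ValidationError
from .ranktest import RankTestResult, mann_whitney

ARCHITECTURES = ("exclusive", "super-host", "none")


def classify_loci(spec: pd.DataFrame, host_map: dict[str, str]) -> pd.DataFrame:
    """Per-gene architecture from a specificity table.

    Returns one row per host gene with per-group specific-circRNA counts and
    the architecture label: ``exclusive-<G>`` when all its specific circles
    belong to group G, ``super-host`` for >= 2 distinct groups, ``none``
    otherwise.
    """
    hits = spec[spec["is_specific"]]
    if hits["transcript_id"].duplicated().any():
        dup = hits["transcript_id"][hits["transcript_id"].duplicated()].iloc[0]
        raise ValidationError(f"circRNA {dup!r} specific to more than one group")
    groups = [g for g in spec["group"].unique()]
    genes = sorted(set(host_map.values()))
    counts: dict[str, dict[str, int]] = {g: {grp: 0 for grp in groups} for g in genes}
    for _, row in hits.iterrows():
        gene = host_map.get(row["transcript_id"])
        if gene is None:
            raise ValidationError(
                f"specific circRNA {row['transcript_id']!r} has no host gene"
            )
        counts.setdefault(gene, {grp: 0 for grp in groups})[row["group"]] += 1
    rows = []
    for gene in sorted(counts):
        per_group = counts[gene]
        active = [g for g, n in per_group.items() if n > 0]
        if len(active) == 0:
            arch = "none"
        elif len(active) == 1:
            arch = f"exclusive-{active[0]}"
        else:
            arch = "super-host"
        rows.append(
            {"gene_id": gene, **{f"n_specific_{g}": per_group[g] for g in groups},
             "architecture": arch}
        )
    return pd.DataFrame(rows)


def architecture_summary(locus_table: pd.DataFrame) -> pd.Series:
    return locus_table["architecture"].value_counts()


def circ_linear_ratio(
    circ_reads: float,
    donor_linear: float,
    acceptor_linear: float,
    pseudocount: float = 1.0,
) -> float:
    """circ / (mean(donor, acceptor) + pseudocount).

    The pseudocount bounds the ratio and keeps it defined when the linear
    cognate is fully absent at both junctions.
    """
    if min(circ_reads, donor_linear, acceptor_linear) < 0:
        raise ValidationError("read counts must be non-negative")
    return circ_reads / ((donor_linear + acceptor_linear) / 2 + pseudocount)


def ratios_by_group(
    bsj_counts: pd.DataFrame,
    linear_counts: dict[str, pd.DataFrame],
    samples: pd.DataFrame,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per circRNA per group: ratio from counts summed over the group's samples."""
    rows = []
    for group, sub in samples.groupby("group", sort=True):
        ids = [s for s in sub["sample_id"] if s in bsj_counts.columns]
        if not ids:
            continue
        circ = bsj_counts[ids].sum(axis=1)
        donor = linear_counts["donor"][ids].sum(axis=1)
        acceptor = linear_counts["acceptor"][ids].sum(axis=1)
        for cid in bsj_counts.index:
            rows.append(
                {
                    "circ_id": cid,
                    "group": group,
                    "circ_reads": int(circ[cid]),
                    "linear_donor_reads": int(donor[cid]),
                    "linear_acceptor_reads": int(acceptor[cid]),
                    "ratio": circ_linear_ratio(
                        circ[cid], donor[cid], acceptor[cid], pseudocount
                    ),
                }
            )
    return pd.DataFrame(rows)


def compare_ratio_groups(
    ratios: pd.Series, group_labels: pd.Series, group_a: str, group_b: str
) -> RankTestResult:
    """Two-sided Mann-Whitney U of ratios between two label sets (e.g.
    neurons vs non-neuronal cells); exact enumeration at small n."""
    a = ratios[group_labels == group_a]
    b = ratios[group_labels == group_b]
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("both groups must be non-empty")
    return mann_whitney(a.to_numpy(), b.to_numpy())
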