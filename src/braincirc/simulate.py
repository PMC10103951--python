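"""Seeded synthetic datasets with the statistical structure the analysis assumes.

The generator emulates a laser-capture brain RNA-seq circRNA study: a gene
annotation in which the number of circles per gene grows with its exon count,
back-splice-junction (BSJ) counts that are negative-binomially distributed with
designed cell-group specificity, paired RNase-R treated/mock libraries in which
true circles are enriched and linear artifacts depleted, linear cognate
junction counts with a neuron-versus-non-neuron circular-to-linear shift, and a
case/control cohort with a designed disease effect on a fraction of host genes.

Determinism: every stage derives its own child generator from the master seed,
so each ``simulate_*`` function is bitwise reproducible in isolation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CircRecord, GeneModel, GROUP_ORDER

_STAGE = {"annotation": 1, "counts": 2, "rnase": 3, "disease": 4, "reference": 5}


@dataclass(frozen=True)
class DiseaseConfig:
    """Case/control contrast design (prodromal cases vs healthy controls)."""

    frac_affected_genes: float = 0.1
    log2_fold: float = -1.0
    n_case: int = 27
    n_control: int = 59


@dataclass(frozen=True)
class SimConfig:
    n_genes: int = 500
    exons_per_gene_range: tuple[int, int] = (2, 20)
    n_circ_per_gene_range: tuple[int, int] = (0, 8)
    samples_per_group: dict = field(
        default_factory=lambda: {"DA": 20, "PY": 20, "NN": 7}
    )
    frac_specific: dict = field(
        default_factory=lambda: {"DA": 0.15, "PY": 0.15, "NN": 0.15}
    )
    specific_fold: float = 20.0
    baseline_mean_bsj: float = 20.0
    nb_dispersion: float = 0.1
    library_size_range: tuple[int, int] = (5_000_000, 20_000_000)
    rnase_pairs: int = 6
    rnase_enrich_true: float = 5.0
    rnase_deplete_artifact: float = 0.1
    frac_artifact: float = 0.2
    cirna_per_intron_prob: float = 0.05
    linear_baseline_mean: float = 40.0
    neuron_linear_factor: float = 1 / 3
    disease: DiseaseConfig = field(default_factory=DiseaseConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_artifact", "cirna_per_intron_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for g, f in self.frac_specific.items():
            if not 0 <= f <= 1:
                raise ValueError(f"frac_specific[{g}] must be in [0, 1]")
        if sum(self.frac_specific.values()) > 1:
            raise ValueError("frac_specific values must sum to <= 1")
        for name in ("specific_fold", "rnase_enrich_true", "rnase_deplete_artifact",
                     "baseline_mean_bsj", "linear_baseline_mean",
                     "neuron_linear_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.exons_per_gene_range[0] < 1:
            raise ValueError("exons_per_gene_range lower bound must be >= 1")
        if not 0 <= self.disease.frac_affected_genes <= 1:
            raise ValueError("frac_affected_genes must be in [0, 1]")


@dataclass
class SimTruth:
    """Oracle labels recorded at generation time for recovery tests."""

    is_true_circle: dict[str, bool] = field(default_factory=dict)
    designed_specific_group: dict[str, str | None] = field(default_factory=dict)
    designed_disease_lfc: dict[str, float] = field(default_factory=dict)


def _rng(config: SimConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), _STAGE[stage]])


def _nb_draw(rng: np.random.Generator, mean, dispersion: float):
    """NB(mean mu, variance mu + alpha mu^2); Poisson in the alpha -> 0 limit."""
    mean = np.asarray(mean, dtype=float)
    if dispersion < 1e-8:
        return rng.poisson(mean)
    size_param = 1.0 / dispersion
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p)


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def simulate_annotation(
    config: SimConfig,
) -> tuple[dict[str, GeneModel], list[CircRecord], SimTruth]:
    """Draw gene models and candidate circRNAs.

    Each exonic circle's blocks are a contiguous run of its host gene's exons;
    the expected number of circles per gene is proportional to the exon count,
    so the circles-per-gene vs exon-count correlation holds by construction.
    Circular intronic RNAs (ciRNAs) are drawn per intron as single-block
    records.  A ``frac_artifact`` share of all candidates is labelled a linear
    artifact in the truth table.
    """
    rng = _rng(config, "annotation")
    lo_e, hi_e = config.exons_per_gene_range
    lo_c, hi_c = config.n_circ_per_gene_range
    mean_exons = (lo_e + hi_e) / 2
    # expected circles per gene ~ exons/mean_exons * midpoint of the circ range
    circ_rate = (lo_c + hi_c) / 2 / mean_exons

    models: dict[str, GeneModel] = {}
    records: list[CircRecord] = []
    truth = SimTruth()
    pos = 10_000
    chrom_idx = 1
    for gi in range(config.n_genes):
        if gi and gi % 50 == 0:
            chrom_idx += 1
            pos = 10_000
        gene_id = f"G{gi:05d}"
        chrom = f"chr{chrom_idx}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(lo_e, hi_e + 1))
        exons = []
        cur = pos
        for _ in range(n_exons):
            size = int(rng.integers(80, 400))
            exons.append((cur, cur + size))
            cur += size + int(rng.integers(200, 5000))
        pos = cur + int(rng.integers(10_000, 50_000))
        models[gene_id] = GeneModel(
            gene_id=gene_id, chrom=chrom, strand=strand,
            transcripts={f"{gene_id}.t1": tuple(exons)},
        )

        n_circ = int(np.clip(rng.poisson(circ_rate * n_exons), lo_c, hi_c))
        seen: set[tuple[int, int]] = set()
        for _ in range(n_circ):
            i = int(rng.integers(0, n_exons))
            j = int(rng.integers(i, n_exons))
            if (i, j) in seen:
                continue
            seen.add((i, j))
            blocks = tuple((s, e - s) for s, e in exons[i : j + 1])
            rec = CircRecord(
                chrom=chrom, start=exons[i][0], end=exons[j][1], strand=strand,
                circ_class="exonic", host_gene=gene_id, exon_blocks=blocks,
                bsj_reads_total=0,
            )
            records.append(rec)
            truth.is_true_circle[rec.circ_id] = bool(
                rng.random() >= config.frac_artifact
            )
        # intron-lariat-derived ciRNA candidates
        for (s1, e1), (s2, _e2) in zip(exons[:-1], exons[1:]):
            if rng.random() < config.cirna_per_intron_prob:
                rec = CircRecord(
                    chrom=chrom, start=e1, end=s2, strand=strand,
                    circ_class="ciRNA", host_gene=gene_id,
                    exon_blocks=((e1, s2 - e1),), bsj_reads_total=0,
                )
                records.append(rec)
                truth.is_true_circle[rec.circ_id] = bool(
                    rng.random() >= config.frac_artifact
                )

    groups = list(config.frac_specific)
    probs = [config.frac_specific[g] for g in groups]
    probs.append(1 - sum(probs))
    for rec in records:
        if truth.is_true_circle[rec.circ_id]:
            choice = rng.choice(len(groups) + 1, p=probs)
            truth.designed_specific_group[rec.circ_id] = (
                groups[choice] if choice < len(groups) else None
            )
        else:
            truth.designed_specific_group[rec.circ_id] = None
    records.sort(key=lambda r: (r.chrom, r.start, r.end, r.strand))
    return models, records, truth


# ---------------------------------------------------------------------------
# Expression counts
# ---------------------------------------------------------------------------

_REFERENCE_DEPTH = 1e7  # library size at which baseline_mean_bsj is the NB mean


def _make_samples(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    cell_types = {"DA": ["DA"], "PY": ["TCPY"], "NN": ["PBMC", "FB"]}
    for g in GROUP_ORDER:
        n = config.samples_per_group.get(g, 0)
        for i in range(n):
            ct = cell_types[g][i % len(cell_types[g])]
            rows.append(
                {
                    "sample_id": f"{g}_{i:03d}",
                    "cell_type": ct,
                    "group": g,
                    "condition": "HC",
                    "sex": "M" if rng.random() < 0.5 else "F",
                    "age": float(np.round(rng.normal(75, 8), 1)),
                    "pmi": float(np.round(rng.exponential(5) + 1, 1)),
                    "rin": float(np.round(rng.uniform(6, 9), 1)),
                    "library_size": int(rng.integers(*config.library_size_range)),
                    "rnase_status": "none",
                    "pair_id": "",
                }
            )
    return pd.DataFrame(rows)


def expected_mean(config: SimConfig, library_size: int, specific: bool) -> float:
    """NB mean for one circle in one sample under the design."""
    fold = config.specific_fold if specific else 1.0
    return config.baseline_mean_bsj * fold * library_size / _REFERENCE_DEPTH


def simulate_counts(
    models: dict[str, GeneModel],
    records: list[CircRecord],
    truth: SimTruth,
    config: SimConfig,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame], pd.DataFrame, pd.DataFrame]:
    """Draw BSJ counts, linear cognate junction counts, samples and FPKM.

    Returns ``(bsj_counts, {"donor": ..., "acceptor": ...}, samples, fpkm)``.
    BSJ counts are NB with mean ``baseline * specific_fold`` in the designed
    group (baseline elsewhere), scaled by library size.  Linear junction
    counts are drawn independently with neuron libraries' linear means shrunk
    by ``neuron_linear_factor``, producing the designed neuron-elevated
    circular-to-linear ratio.  FPKM profiles are flat across groups: the
    linear transcripts carry no cell-type specificity by design.
    """
    rng = _rng(config, "counts")
    samples = _make_samples(config, rng)
    circ_ids = [r.circ_id for r in records]
    lib = samples["library_size"].to_numpy(float)
    group = samples["group"].to_numpy()

    spec_group = np.array(
        [truth.designed_specific_group.get(cid) or "" for cid in circ_ids]
    )
    fold = np.where(spec_group[:, None] == group[None, :], config.specific_fold, 1.0)
    mu = config.baseline_mean_bsj * fold * (lib[None, :] / _REFERENCE_DEPTH)
    counts = _nb_draw(rng, mu, config.nb_dispersion)
    bsj = pd.DataFrame(counts, index=pd.Index(circ_ids, name="circ_id"),
                       columns=samples["sample_id"])

    neuron = np.isin(group, ["DA", "PY"])
    lin_scale = np.where(neuron, config.neuron_linear_factor, 1.0)
    lin_mu = config.linear_baseline_mean * lin_scale[None, :] * (
        lib[None, :] / _REFERENCE_DEPTH
    )
    linear = {
        side: pd.DataFrame(
            _nb_draw(rng, np.broadcast_to(lin_mu, mu.shape), config.nb_dispersion),
            index=pd.Index(circ_ids, name="circ_id"), columns=samples["sample_id"],
        )
        for side in ("donor", "acceptor")
    }

    gene_ids = sorted(models)
    base_fpkm = rng.lognormal(mean=2.0, sigma=1.0, size=len(gene_ids))
    fpkm_vals = base_fpkm[:, None] * rng.lognormal(0, 0.2, (len(gene_ids), len(samples)))
    fpkm = pd.DataFrame(np.round(fpkm_vals, 4),
                        index=pd.Index(gene_ids, name="gene_id"),
                        columns=samples["sample_id"])
    return bsj, linear, samples, fpkm


# ---------------------------------------------------------------------------
# RNase-R pairs
# ---------------------------------------------------------------------------

def simulate_rnase_pairs(
    records: list[CircRecord], truth: SimTruth, config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw paired RNase-R treated and mock libraries.

    Enrichment acts on expected counts before NB sampling: a true circle's
    treated mean is ``mock mean x rnase_enrich_true``; a linear artifact's is
    ``mock mean x rnase_deplete_artifact``.  Treated and mock library sizes
    are drawn independently.  Returns ``(counts, pair_meta)`` where counts has
    one treated and one mock column per pair.
    """
    if config.rnase_pairs < 1:
        raise ValueError("at least one RNase-R pair required")
    rng = _rng(config, "rnase")
    circ_ids = [r.circ_id for r in records]
    is_true = np.array([truth.is_true_circle[cid] for cid in circ_ids])
    enrich = np.where(is_true, config.rnase_enrich_true, config.rnase_deplete_artifact)

    cols, data, meta = [], [], []
    for p in range(config.rnase_pairs):
        pair_id = f"RP{p + 1}"
        lib_mock = int(rng.integers(*config.library_size_range))
        lib_treat = int(rng.integers(*config.library_size_range))
        mu_mock = config.baseline_mean_bsj * lib_mock / _REFERENCE_DEPTH
        mu_treat = (
            config.baseline_mean_bsj * enrich * lib_treat / _REFERENCE_DEPTH
        )
        for status, lib, mu in (
            ("treated", lib_treat, mu_treat),
            ("mock", lib_mock, np.full(len(circ_ids), mu_mock)),
        ):
            sid = f"{pair_id}_{status}"
            cols.append(sid)
            data.append(_nb_draw(rng, mu, config.nb_dispersion))
            meta.append(
                {
                    "sample_id": sid, "cell_type": "DA", "group": "DA",
                    "condition": "HC", "sex": "M", "age": 75.0, "pmi": 3.0,
                    "rin": 7.5, "library_size": lib, "rnase_status": status,
                    "pair_id": pair_id,
                }
            )
    counts = pd.DataFrame(
        np.column_stack(data), index=pd.Index(circ_ids, name="circ_id"), columns=cols
    )
    return counts, pd.DataFrame(meta)


# ---------------------------------------------------------------------------
# Disease cohort
# ---------------------------------------------------------------------------

def simulate_disease_effect(
    records: list[CircRecord], truth: SimTruth, config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Draw a case/control cohort with a designed effect on a gene subset.

    A ``frac_affected_genes`` share of host genes gets its case-group expected
    counts scaled by ``2**log2_fold`` (all circles of an affected gene move
    together, matching gene-level aggregation downstream).  Covariates (sex,
    age, PMI, RIN) are drawn independently of condition so that Wald-test
    calibration is testable.  The truth table gains per-gene designed LFCs.
    """
    d = config.disease
    if d.n_case < 2 or d.n_control < 2:
        raise ValueError("need at least two case and two control samples")
    rng = _rng(config, "disease")
    genes = sorted({r.host_gene for r in records})
    affected = rng.random(len(genes)) < d.frac_affected_genes
    truth = SimTruth(
        is_true_circle=dict(truth.is_true_circle),
        designed_specific_group=dict(truth.designed_specific_group),
        designed_disease_lfc={
            g: (d.log2_fold if a else 0.0) for g, a in zip(genes, affected)
        },
    )

    n = d.n_case + d.n_control
    condition = np.array(["ILB"] * d.n_case + ["HC"] * d.n_control)
    samples = pd.DataFrame(
        {
            "sample_id": [f"DIS_{i:03d}" for i in range(n)],
            "cell_type": "DA",
            "group": "DA",
            "condition": condition,
            "sex": np.where(rng.random(n) < 0.5, "M", "F"),
            "age": np.round(rng.normal(75, 8, n), 1),
            "pmi": np.round(rng.exponential(5, n) + 1, 1),
            "rin": np.round(rng.uniform(6, 9, n), 1),
            "library_size": rng.integers(*config.library_size_range, n),
            "rnase_status": "none",
            "pair_id": "",
        }
    )

    circ_ids = [r.circ_id for r in records]
    gene_lfc = np.array([truth.designed_disease_lfc[r.host_gene] for r in records])
    lib = samples["library_size"].to_numpy(float)
    case = (condition == "ILB").astype(float)
    fold = 2.0 ** (gene_lfc[:, None] * case[None, :])
    mu = config.baseline_mean_bsj * fold * (lib[None, :] / _REFERENCE_DEPTH)
    counts = pd.DataFrame(
        _nb_draw(rng, mu, config.nb_dispersion),
        index=pd.Index(circ_ids, name="circ_id"),
        columns=samples["sample_id"],
    )
    return counts, samples, truth


# ---------------------------------------------------------------------------
# Reference tables (gene sets, disease-gene associations, SNP positions)
# ---------------------------------------------------------------------------

def simulate_reference_tables(
    models: dict[str, GeneModel],
    records: list[CircRecord],
    truth: SimTruth,
    config: SimConfig,
    n_random_sets: int = 15,
    n_snps: int = 200,
) -> tuple[dict, pd.DataFrame, pd.DataFrame]:
    """Companion annotation resources with designed signal.

    Gene sets: one set per cell group built from the host genes of that
    group's designed-specific circles (enriched by construction) plus random
    background sets.  Disease table: one brain disorder per group with the
    same construction, plus random non-brain diseases.  SNPs: half placed
    inside or near simulated circles, half far away on the same chromosomes.
    Returns ``(gene_sets, gda_table, snp_table)``.
    """
    rng = _rng(config, "reference")
    genes = sorted(models)
    host_by_group: dict[str, set] = {}
    for r in records:
        g = truth.designed_specific_group.get(r.circ_id)
        if g:
            host_by_group.setdefault(g, set()).add(r.host_gene)

    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    for g in sorted(host_by_group):
        members = sorted(host_by_group[g])
        if members:
            sets[f"SYN_SPECIFIC_{g}"] = (f"designed {g}-specific host genes",
                                         tuple(members))
    for i in range(n_random_sets):
        size = int(rng.integers(5, max(6, len(genes) // 4)))
        members = sorted(rng.choice(genes, size=min(size, len(genes)), replace=False))
        sets[f"RANDOM_{i:02d}"] = ("random background set", tuple(members))

    gda_rows = []
    for g in sorted(host_by_group):
        for gene in sorted(host_by_group[g]):
            gda_rows.append(
                {"gene_id": gene, "disease_id": f"DIS_{g}",
                 "disease_name": f"synthetic {g} disorder", "gda_score": 0.5,
                 "mesh_classes": "C10"}
            )
    for i in range(3):
        size = int(rng.integers(5, max(6, len(genes) // 5)))
        for gene in rng.choice(genes, size=min(size, len(genes)), replace=False):
            gda_rows.append(
                {"gene_id": gene, "disease_id": f"DIS_OTHER_{i}",
                 "disease_name": f"synthetic non-brain disease {i}",
                 "gda_score": 0.5, "mesh_classes": "C04"}
            )
    gda = pd.DataFrame(
        gda_rows,
        columns=["gene_id", "disease_id", "disease_name", "gda_score",
                 "mesh_classes"],
    )

    snp_rows = []
    if records:
        for i in range(n_snps):
            rec = records[int(rng.integers(len(records)))]
            if i % 2 == 0:  # near: within the proximity window of a circle
                pos = int(rec.start + rng.integers(-500_000, 500_000))
            else:  # far: several Mb beyond the circle
                pos = int(rec.end + 5_000_000 + rng.integers(0, 5_000_000))
            snp_rows.append(
                {"chrom": rec.chrom, "position": max(pos, 0), "snp_id": f"rs{i}"}
            )
    snps = pd.DataFrame(snp_rows, columns=["chrom", "position", "snp_id"])
    return sets, gda, snps


# ---------------------------------------------------------------------------
# Convenience bundle
# ---------------------------------------------------------------------------

def simulate_dataset(config: SimConfig) -> dict:
    """Run all stages; returns a dict with every artefact plus the truth."""
    models, records, truth = simulate_annotation(config)
    bsj, linear, samples, fpkm = simulate_counts(models, records, truth, config)
    rnase_counts, rnase_meta = simulate_rnase_pairs(records, truth, config)
    dis_counts, dis_samples, truth = simulate_disease_effect(records, truth, config)
    gene_sets, gda, snps = simulate_reference_tables(models, records, truth, config)
    totals = bsj.sum(axis=1)
    records = [
        dataclasses.replace(r, bsj_reads_total=int(totals[r.circ_id]))
        for r in records
    ]
    return {
        "models": models,
        "records": records,
        "truth": truth,
        "bsj_counts": bsj,
        "linear_counts": linear,
        "samples": samples,
        "fpkm": fpkm,
        "rnase_counts": rnase_counts,
        "rnase_meta": rnase_meta,
        "disease_counts": dis_counts,
        "disease_samples": dis_samples,
        "gene_sets": gene_sets,
        "gda": gda,
        "snps": snps,
    }


def truth_tables(truth: SimTruth) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Truth as two DataFrames (per-circle, per-gene) for TSV export."""
    circ = pd.DataFrame(
        {
            "circ_id": sorted(truth.is_true_circle),
        }
    )
    circ["is_true_circle"] = [int(truth.is_true_circle[c]) for c in circ["circ_id"]]
    circ["designed_specific_group"] = [
        truth.designed_specific_group.get(c) or "" for c in circ["circ_id"]
    ]
    gene = pd.DataFrame(
        {
            "gene_id": sorted(truth.designed_disease_lfc),
        }
    )
    gene["designed_disease_lfc"] = [
        truth.designed_disease_lfc[g] for g in gene["gene_id"]
    ]
    return circ, gene
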