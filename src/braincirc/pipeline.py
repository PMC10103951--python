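"""End-to-end orchestration: config, stage ordering, reporting.

Stages run in dependency order (filter -> specificity -> loci -> features ->
enrich -> diffexp); each emits deterministic TSVs whose header comment records
the tool version, a hash of the effective config, and the seed, so re-running
with identical inputs is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, diffexp, enrichment, features, filtering, io, loci, specificity

log = logging.getLogger("braincirc")

STAGES = ("filter", "specificity", "loci", "features", "enrich", "diffexp")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, outdir: Path, cause: Exception):
        super().__init__(f"stage {stage!r} failed ({cause}); partial outputs in {outdir}")
        self.stage = stage
        self.outdir = outdir


@dataclass
class PipelineConfig:
    # input paths (empty string = not provided; stages needing them are skipped)
    circ_bed: str = ""
    bsj_counts: str = ""
    linear_donor: str = ""
    linear_acceptor: str = ""
    samples: str = ""
    rnase_counts: str = ""
    rnase_samples: str = ""
    gtf: str = ""
    gmt: str = ""
    gda: str = ""
    snps: str = ""
    fpkm: str = ""
    disease_counts: str = ""
    disease_samples: str = ""
    repeats_bed: str = ""
    eclip_bed: str = ""
    # thresholds
    min_total_reads: int = 2
    min_treated_reads: int = 20
    min_fold: float = 2.0
    s_threshold: float = 0.5
    gda_threshold: float = 0.1
    jaccard_threshold: float = 0.7
    snp_window: int = 1_000_000
    pseudocount: float = 1.0
    contrast: tuple[str, str] = ("ILB", "HC")
    group_map: dict = field(default_factory=lambda: dict(io.DEFAULT_GROUP_MAP))
    seed: int = 0
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})

    def __post_init__(self) -> None:
        if self.min_total_reads < 0 or self.min_treated_reads < 0:
            raise ValueError("read thresholds must be non-negative")
        if self.min_fold < 1:
            raise ValueError("min_fold must be >= 1")
        if not 0 <= self.s_threshold <= 1:
            raise ValueError("s_threshold must be in [0, 1]")
        if not 0 <= self.gda_threshold <= 1:
            raise ValueError("gda_threshold must be in [0, 1]")
        if not 0 <= self.jaccard_threshold <= 1:
            raise ValueError("jaccard_threshold must be in [0, 1]")
        if self.snp_window < 0:
            raise ValueError("snp_window must be >= 0")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "contrast" in raw:
            raw["contrast"] = tuple(raw["contrast"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["contrast"] = list(d["contrast"])
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def _write(df: pd.DataFrame, path: Path, config: PipelineConfig, index: bool) -> None:
    with open(path, "w") as fh:
        fh.write(
            f"# braincirc {__version__} config_hash={config.config_hash()} "
            f"seed={config.seed}\n"
        )
        df.to_csv(fh, sep="\t", index=index)


def read_stage_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def _required_inputs(config: PipelineConfig) -> list[str]:
    need = []
    if config.stages.get("filter"):
        need += [config.bsj_counts]
        if config.rnase_counts or config.rnase_samples:
            need += [config.rnase_counts, config.rnase_samples]
    if config.stages.get("specificity"):
        need += [config.bsj_counts, config.samples]
    if config.stages.get("loci"):
        need += [config.bsj_counts, config.samples, config.circ_bed,
                 config.linear_donor, config.linear_acceptor]
    if config.stages.get("features"):
        need += [config.circ_bed, config.gtf]
    if config.stages.get("enrich"):
        need += [config.circ_bed, config.gtf, config.gmt]
    if config.stages.get("diffexp"):
        need += [config.circ_bed, config.disease_counts, config.disease_samples]
    return [p for p in dict.fromkeys(need) if p]


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute the enabled stages; returns the summary dict.

    Inputs referenced by enabled stages are checked before any stage runs.
    Each stage writes its table(s) under ``outdir``; a stage failure aborts
    with the stage name and the partial-output location.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    missing = [p for p in _required_inputs(config) if not Path(p).exists()]
    if missing:
        raise FileNotFoundError(f"missing input files: {missing}")
    log.info("config hash %s, seed %d", config.config_hash(), config.seed)

    summary: dict = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages_run": [],
    }
    state: dict = {}

    records = None
    if config.circ_bed:
        records = io.read_circ_bed(config.circ_bed)
        state["host_map"] = {r.circ_id: r.host_gene for r in records}
        summary["n_candidates"] = len(records)

    stage_inputs = {
        "filter": [config.bsj_counts],
        "specificity": [config.bsj_counts, config.samples],
        "loci": [config.bsj_counts, config.samples,
                 config.linear_donor, config.linear_acceptor],
        "features": [config.circ_bed, config.gtf],
        "enrich": [config.circ_bed, config.gtf, config.gmt],
        "diffexp": [config.circ_bed, config.disease_counts,
                    config.disease_samples],
    }
    for stage in STAGES:
        if not config.stages.get(stage, False):
            continue
        if not all(stage_inputs[stage]):
            log.info("stage %s skipped: inputs not configured", stage)
            summary.setdefault("stages_skipped", []).append(stage)
            continue
        try:
            _run_stage(stage, config, outdir, state, summary, records)
        except Exception as exc:  # noqa: BLE001 - abort with stage context
            raise PipelineError(stage, outdir, exc) from exc
        summary["stages_run"].append(stage)
        log.info("stage %s done", stage)

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def _run_stage(stage, config, outdir, state, summary, records) -> None:
    if stage == "filter":
        counts = io.read_count_matrix(config.bsj_counts)
        expressed = filtering.filter_expressed(counts, config.min_total_reads)
        summary["n_expressed"] = len(expressed)
        validated = expressed
        if config.rnase_counts:
            rnase_counts = io.read_count_matrix(config.rnase_counts)
            rnase_meta = io.read_sample_table(config.rnase_samples, config.group_map)
            results = filtering.rnase_validate(
                rnase_counts, rnase_meta,
                min_treated_reads=config.min_treated_reads,
                min_fold=config.min_fold,
                min_total_reads=config.min_total_reads,
            )
            validated = filtering.validated_set(results) & expressed
            _write(filtering.results_table(results), outdir / "validation.tsv",
                   config, index=False)
        summary["n_validated"] = len(validated)
        if len(counts):
            summary["validation_rate_pct"] = filtering.validation_rate(
                len(validated), len(counts)
            )
        if records is not None:
            by_class: dict[str, list] = {"exonic": [], "ciRNA": []}
            for r in records:
                by_class[r.circ_class].append(r.circ_id)
            for cls, ids in by_class.items():
                cand = [c for c in ids if c in counts.index]
                if cand:
                    summary[f"validation_rate_{cls}_pct"] = filtering.validation_rate(
                        sum(c in validated for c in cand), len(cand)
                    )
        state["validated"] = validated
        state["counts"] = counts

    elif stage == "specificity":
        counts = state.get("counts")
        if counts is None:
            counts = io.read_count_matrix(config.bsj_counts)
        samples = io.read_sample_table(config.samples, config.group_map)
        keep = sorted(state.get("validated", set(counts.index)) & set(counts.index))
        counts = counts.loc[keep]
        rpm = specificity.rpm_normalize(
            counts, samples.set_index("sample_id")["library_size"]
        )
        state["counts"] = counts
        spec = specificity.classify_specific(rpm, samples, config.s_threshold)
        _write(spec, outdir / "specificity_circ.tsv", config, index=False)
        assigned = specificity.specific_assignments(spec)
        summary["n_specific_per_group"] = (
            assigned.value_counts().sort_index().to_dict()
        )
        state["spec_circ"] = spec
        state["samples"] = samples
        if config.fpkm:
            fpkm = io.read_fpkm_table(config.fpkm)
            spec_lin = specificity.classify_specific(
                fpkm, samples, config.s_threshold
            )
            _write(spec_lin, outdir / "specificity_linear.tsv", config, index=False)
            pairs, stat, p, excluded = specificity.compare_circ_vs_linear(
                spec, spec_lin, state["host_map"]
            )
            _write(pairs, outdir / "circ_vs_linear.tsv", config, index=False)
            summary["circ_vs_linear"] = {
                "median_delta_s": float(pairs["delta_s"].median()),
                "p": p,
                "n_pairs": len(pairs),
                "n_excluded": excluded,
            }

    elif stage == "loci":
        spec = state["spec_circ"]
        locus_table = loci.classify_loci(spec, state["host_map"])
        _write(locus_table, outdir / "locus_architecture.tsv", config, index=False)
        arch = loci.architecture_summary(locus_table)
        summary["locus_architecture"] = arch.to_dict()
        summary["n_super_host"] = int(arch.get("super-host", 0))
        linear = {
            "donor": io.read_count_matrix(config.linear_donor),
            "acceptor": io.read_count_matrix(config.linear_acceptor),
        }
        counts = state["counts"].loc[spec["transcript_id"].unique()]
        ratios = loci.ratios_by_group(
            counts, linear, state["samples"], config.pseudocount
        )
        _write(ratios, outdir / "circ_linear_ratios.tsv", config, index=False)
        neuron = ratios["group"].isin(["DA", "PY"]).map({True: "neuron", False: "NN"})
        res = loci.compare_ratio_groups(ratios["ratio"], neuron, "neuron", "NN")
        summary["ratio_neuron_vs_nonneuron"] = {
            "U": res.statistic, "p": res.pvalue, "method": res.method,
        }

    elif stage == "features":
        models = io.read_gtf(config.gtf)
        state["models"] = models
        repeats = (
            features.IntervalTrack.from_bed("repeats", config.repeats_bed)
            if config.repeats_bed else None
        )
        eclip = (
            features.IntervalTrack.from_bed("eclip", config.eclip_bed)
            if config.eclip_bed else None
        )
        table = features.feature_summary(records, models, repeats, eclip)
        _write(table, outdir / "feature_summary.tsv", config, index=False)
        per_gene, r, degenerate = features.circ_per_gene_vs_exons(records, models)
        _write(per_gene, outdir / "circ_per_gene.tsv", config, index=False)
        summary["circ_per_gene_vs_exons_r"] = r
        if config.snps:
            snps = io.read_snp_table(config.snps)
            frac = features.snp_proximity_fraction(snps, records, config.snp_window)
            summary["snp_proximity_fraction"] = frac

    elif stage == "enrich":
        models = state.get("models") or io.read_gtf(config.gtf)
        universe = set(models)
        spec = state.get("spec_circ")
        host_map = state["host_map"]
        if spec is not None:
            assigned = specificity.specific_assignments(spec)
            query_by_group = {
                g: {host_map[c] for c in assigned.index[assigned == g]} & universe
                for g in sorted(assigned.unique())
            }
        else:
            query_by_group = {"all": {host_map[r.circ_id] for r in records} & universe}
        sets = io.read_gmt(config.gmt)
        frames = []
        for g, query in query_by_group.items():
            if not query:
                continue
            rows = enrichment.fisher_enrich(query, sets, universe)
            if rows.empty:
                continue
            rows = enrichment.slim_terms(rows, config.jaccard_threshold)
            rows.insert(0, "group", g)
            frames.append(rows.drop(columns=["members"]))
        if frames:
            go_table = pd.concat(frames, ignore_index=True)
            _write(go_table, outdir / "go_enrichment.tsv", config, index=False)
            summary["n_enriched_terms_q05"] = int((go_table["q"] < 0.05).sum())
        if config.gda:
            gda = io.read_gda(config.gda, config.gda_threshold)
            coding = {g for g, m in models.items() if m.biotype == "protein_coding"}
            host_by_group = {
                g: q & coding for g, q in query_by_group.items()
            }
            dis = enrichment.disease_enrich(host_by_group, gda, coding, brain_only=False)
            if not dis.empty:
                _write(dis, outdir / "disease_enrichment.tsv", config, index=False)
                summary["n_disease_q05"] = int((dis["q"] < 0.05).sum())

    elif stage == "diffexp":
        dcounts = io.read_count_matrix(config.disease_counts)
        dsamples = io.read_sample_table(config.disease_samples, config.group_map)
        gene_counts = diffexp.aggregate_to_gene(dcounts, state["host_map"])
        de = diffexp.nb_wald(gene_counts, dsamples, contrast=config.contrast)
        _write(de.reset_index(), outdir / "diffexp.tsv", config, index=False)
        _write(
            volcano := diffexp.volcano_table(de).reset_index(),
            outdir / "volcano.tsv", config, index=False,
        )
        ok = de["p"].notna()
        summary["n_de_genes_q05"] = int((de.loc[ok, "q"] < 0.05).sum())
        summary["n_genes_tested"] = int(ok.sum())
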