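"""Stage orchestration: simulate -> promoters -> scan -> diffexp -> enrich ->
targets -> network, with a structured configuration object, key=value logging
and deterministic, seed-stamped outputs.

The stages communicate through files in ``out_dir`` using the package's
standard formats, so any stage can be rerun in isolation; rerunning with the
same config and seed is byte-identical for the deterministic stages. The
functions here are the interface (no shell entry point); see examples/ for
narrative usage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .formats import (
    read_fasta, write_fasta, read_pwm, write_pwm,
    read_expression_table, write_expression_table, write_bed,
)
from .intervals import GenomicInterval
from .promoters import (
    load_annotation, write_annotation, refine_core_promoter,
    promoter_search_region, GCZScoreScorer, CorePromoter,
)
from .motifs import pwm_from_counts, scan_region, select_top_k, site_counts_per_mirna, MotifHit
from .expression import differential_expression, select_regulated
from .enrichment import rank_order_probes, enrichment_curve
from .seeds import MatureMiRNA, find_seed_sites, sites_table
from .network import build_network, find_feedback_loops, export_network
from .simulate import SyntheticStudyConfig, generate_study

logger = logging.getLogger(__name__)

STAGES = ("simulate", "promoters", "scan", "diffexp", "enrich", "targets", "network", "all")


@dataclass
class PipelineConfig:
    """All pipeline inputs and the study's stated constants.

    Every constant is overridable and defaults to the published value:
    200-bp core window, 15-kb flank, top-500 pooled sites, fold-change
    threshold 2, p threshold 0.05, 300-probe enrichment window at step 1.
    """

    out_dir: str = "pipeline_out"
    genome_path: str | None = None
    annotation_path: str | None = None
    pwm_path: str | None = None
    expression_path: str | None = None
    utr_path: str | None = None
    mirna_path: str | None = None
    tf_id: str = "YY1"
    core_window: int = 200
    flank: int = 15_000
    top_k: int = 500
    scan_threshold: float = 0.0  # bits; sub-background windows never reach the top K here
    fc_threshold: float = 2.0
    p_threshold: float = 0.05
    enrich_window: int = 300
    enrich_step: int = 1
    n_perm: int = 1000
    rng_seed: int = 0
    one_based_inclusive: bool = False
    min_site_type: str = "7mer"
    numerator_condition: str = "DM3"
    denominator_condition: str = "GM"
    sort: str = "p"  # report order: "p" = (p asc, FC desc), "fc" = FC desc
    ordering: str = "rank_product"  # enrichment ranking statistic

    def validate(self) -> None:
        bad = []
        for key in ("core_window", "flank", "top_k", "enrich_window", "enrich_step", "n_perm"):
            if getattr(self, key) <= 0 and not (key == "flank" and self.flank == 0):
                bad.append(key)
        if self.fc_threshold < 0:
            bad.append("fc_threshold")
        if not 0.0 <= self.p_threshold <= 1.0:
            bad.append("p_threshold")
        if self.sort not in ("p", "fc"):
            bad.append("sort")
        if self.ordering not in ("rank_product", "fold_change"):
            bad.append("ordering")
        if bad:
            raise ValueError(f"invalid config value(s) for: {', '.join(sorted(bad))}")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        return cls(**json.loads(text))

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]

    def path(self, key: str, stage: str) -> Path:
        value = getattr(self, key)
        if value is None:
            raise FileNotFoundError(f"stage {stage!r} requires config key {key!r} (not set)")
        p = Path(value)
        if not p.exists():
            raise FileNotFoundError(f"stage {stage!r}: {key} file {p} does not exist")
        return p


def _log(stage: str, **kv) -> None:
    logger.info("stage=%s " + " ".join(f"{k}={v}" for k, v in kv.items()), stage)


def _out(config: PipelineConfig, name: str) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out / name


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(config: PipelineConfig, synthetic: SyntheticStudyConfig | None):
    syn = synthetic or SyntheticStudyConfig(rng_seed=config.rng_seed)
    study = generate_study(syn, tf_id=config.tf_id)
    paths = {
        "genome_path": _out(config, "genome.fa"),
        "annotation_path": _out(config, "annotation.tsv"),
        "pwm_path": _out(config, "matrices.transfac"),
        "expression_path": _out(config, "expression.tsv"),
        "utr_path": _out(config, "utrs.fa"),
        "mirna_path": _out(config, "mirnas.fa"),
    }
    write_fasta(study.genome, paths["genome_path"])
    write_annotation(study.annotation, paths["annotation_path"])
    write_pwm([study.pwm_record], paths["pwm_path"])
    write_expression_table(study.expression, paths["expression_path"])
    write_fasta({g: u for g, u in study.utrs.items()}, paths["utr_path"])
    write_fasta({m: s.sequence.replace("U", "T") for m, s in study.mirna_seqs.items()},
                paths["mirna_path"])
    study.site_truth.to_csv(_out(config, "truth_sites.tsv"), sep="\t", index=False)
    study.expression_truth.to_csv(_out(config, "truth_expression.tsv"), sep="\t")
    study.utr_truth.to_csv(_out(config, "truth_utr_sites.tsv"), sep="\t", index=False)
    sidecar = {
        "seed": syn.rng_seed,
        "config": syn.to_dict(),
        "pipeline_config_hash": config.config_hash(),
        "version": __version__,
    }
    _out(config, "provenance.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    for key, p in paths.items():
        setattr(config, key, str(p))
    _log("simulate", seed=syn.rng_seed, n_mirnas=syn.n_mirnas, n_targets=len(study.target_mirnas))
    return {"study": study, **{k: str(v) for k, v in paths.items()}}


def _stage_promoters(config: PipelineConfig):
    genome = read_fasta(config.path("genome_path", "promoters"))
    annotation = load_annotation(
        config.path("annotation_path", "promoters"),
        one_based_inclusive=config.one_based_inclusive,
    )
    scorer = GCZScoreScorer.from_genome(genome, config.core_window)
    cores, regions = [], []
    for t in annotation.transcripts:
        core = refine_core_promoter(t, genome, config.core_window, scorer)
        cores.append(core)
        chrom_len = genome[t.promoter.chrom].length
        regions.append(promoter_search_region(core, config.flank, chrom_len))
    core_rows = pd.DataFrame(
        {
            "pri_id": [c.transcript for c in cores],
            "chrom": [c.window.chrom for c in cores],
            "core_start": [c.window.start for c in cores],
            "core_end": [c.window.end for c in cores],
            "strand": [c.window.strand for c in cores],
            "core_score": [c.core_score for c in cores],
            "truncated": [c.truncated for c in cores],
            "region_start": [r.start for r in regions],
            "region_end": [r.end for r in regions],
        }
    )
    core_rows.to_csv(_out(config, "core_promoters.tsv"), sep="\t", index=False)
    write_bed(
        [(c.window, c.transcript, c.core_score) for c in cores],
        _out(config, "core_promoters.bed"),
    )
    _log("promoters", n=len(cores), config_hash=config.config_hash())
    return {"cores": cores, "regions": regions, "annotation": annotation, "genome": genome}


def _load_regions(config: PipelineConfig):
    path = _out(config, "core_promoters.tsv")
    if not path.exists():
        raise FileNotFoundError(f"stage 'scan': missing upstream output {path} (run 'promoters')")
    df = pd.read_csv(path, sep="\t")
    regions = {
        r.pri_id: GenomicInterval(r.chrom, r.region_start, r.region_end, r.strand)
        for r in df.itertuples(index=False)
    }
    anchors = {r.pri_id: (r.core_start if r.strand == "+" else r.core_end)
               for r in df.itertuples(index=False)}
    return regions, anchors


def _stage_scan(config: PipelineConfig):
    genome = read_fasta(config.path("genome_path", "scan"))
    annotation = load_annotation(
        config.path("annotation_path", "scan"),
        one_based_inclusive=config.one_based_inclusive,
    )
    records = read_pwm(config.path("pwm_path", "scan"))
    pwms = [pwm_from_counts(r) for r in records]
    regions, anchors = _load_regions(config)
    hits: list[MotifHit] = []
    for pri, region in regions.items():
        for pwm in pwms:
            hits.extend(
                scan_region(pwm, region, genome, threshold=config.scan_threshold,
                            transcript=pri, promoter_start=anchors[pri])
            )
    selected = select_top_k(hits, config.top_k)
    counts = site_counts_per_mirna(selected, annotation)
    hit_rows = pd.DataFrame(
        {
            "pwm_id": [h.pwm_id for h in selected],
            "transcript": [h.transcript for h in selected],
            "chrom": [h.site.chrom for h in selected],
            "start": [h.site.start for h in selected],
            "end": [h.site.end for h in selected],
            "strand": [h.strand for h in selected],
            "score": [h.score for h in selected],
            "relative_position": [h.relative_position for h in selected],
        }
    )
    hit_rows.to_csv(_out(config, "selected_hits.tsv"), sep="\t", index=False)
    write_bed(selected, _out(config, "selected_hits.bed"))
    pd.Series(counts, name="n_sites").rename_axis("mature_id").sort_index().to_csv(
        _out(config, "site_counts.tsv"), sep="\t"
    )
    _log("scan", n_scored=len(hits), n_selected=len(selected), top_k=config.top_k)
    return {"hits": hits, "selected": selected, "site_counts": counts}


def _stage_diffexp(config: PipelineConfig):
    matrix = read_expression_table(config.path("expression_path", "diffexp"))
    results = differential_expression(
        matrix,
        numerator_condition=config.numerator_condition,
        denominator_condition=config.denominator_condition,
        n_perm=config.n_perm,
        seed=config.rng_seed,
    )
    results.table.to_csv(_out(config, "diffexp.tsv"), sep="\t", index_label="probe_id")
    up, down = select_regulated(results, config.fc_threshold, config.p_threshold)
    _log("diffexp", n_probes=len(results), n_up=len(up), n_down=len(down))
    return {"results": results, "up": up, "down": down}


def _read_site_counts(config: PipelineConfig, stage: str) -> dict:
    path = _out(config, "site_counts.tsv")
    if not path.exists():
        raise FileNotFoundError(f"stage {stage!r}: missing upstream output {path} (run 'scan')")
    s = pd.read_csv(path, sep="\t", index_col=0)["n_sites"]
    return s.to_dict()


def _read_diffexp(config: PipelineConfig, stage: str) -> pd.DataFrame:
    path = _out(config, "diffexp.tsv")
    if not path.exists():
        raise FileNotFoundError(f"stage {stage!r}: missing upstream output {path} (run 'diffexp')")
    return pd.read_csv(path, sep="\t", index_col=0)


def _stage_enrich(config: PipelineConfig):
    table = _read_diffexp(config, "enrich")
    counts = _read_site_counts(config, "enrich")
    flags = {probe: counts.get(probe, 0) >= 1 for probe in table.index}
    ranked = rank_order_probes(table, flags, by=config.ordering)
    window = config.enrich_window
    if window > len(table):
        window = max(1, len(table) // 4)
        logger.warning("enrich window %d exceeds %d probes; clamped to %d",
                       config.enrich_window, len(table), window)
    ranked.window, ranked.step = window, config.enrich_step
    curve = enrichment_curve(ranked, n_perm=config.n_perm, seed=config.rng_seed)
    frame = curve.to_frame()
    frame.to_csv(_out(config, "enrichment.tsv"), sep="\t", index=False)
    _log("enrich", n_windows=len(frame), background=f"{curve.background:.4f}")
    return {"ranked": ranked, "curve": curve}


def report_candidates(diffexp_table, site_counts: dict, config: PipelineConfig):
    """Join regulated miRNAs with predicted site counts into candidate reports.

    Returns (up_report, down_report): rows are regulated miRNAs carrying at
    least one selected binding site, columns miRNA / fold_change / p_value /
    n_sites, sorted by (p asc, fold change desc) or fold change desc.
    Probes missing from the site table are reported as a warning, not fatal.
    """
    table = getattr(diffexp_table, "table", diffexp_table)
    up, down = select_regulated(table, config.fc_threshold, config.p_threshold)
    missing = [p for p in up + down if p not in site_counts]
    if missing:
        logger.warning("report: %d regulated probe(s) missing from site table (e.g. %s)",
                       len(missing), missing[:3])
    reports = []
    for probes, pcol, invert in ((up, "p_up", False), (down, "p_down", True)):
        rows = []
        for p in probes:
            n_sites = int(site_counts.get(p, 0))
            if n_sites < 1:
                continue
            fc = table.at[p, "fold_change"]
            rows.append(
                {
                    "miRNA": p,
                    "fold_change": 1.0 / fc if invert else fc,
                    "p_value": table.at[p, pcol],
                    "n_sites": n_sites,
                }
            )
        report = pd.DataFrame(rows, columns=["miRNA", "fold_change", "p_value", "n_sites"])
        if config.sort == "p":
            report = report.sort_values(["p_value", "fold_change"], ascending=[True, False],
                                        ignore_index=True)
        else:
            report = report.sort_values("fold_change", ascending=False, ignore_index=True)
        reports.append(report)
    return reports[0], reports[1]


def _stage_targets(config: PipelineConfig):
    table = _read_diffexp(config, "targets")
    counts = _read_site_counts(config, "targets")
    up_report, down_report = report_candidates(table, counts, config)
    up_report.to_csv(_out(config, "report_up.tsv"), sep="\t", index=False)
    down_report.to_csv(_out(config, "report_down.tsv"), sep="\t", index=False)

    mirna_fa = read_fasta(config.path("mirna_path", "targets"))
    utrs = {g: rec.sequence for g, rec in read_fasta(config.path("utr_path", "targets")).items()}
    sites = []
    for mirna_id in up_report["miRNA"]:
        if mirna_id not in mirna_fa:
            logger.warning("no mature sequence for %s; skipped in seed search", mirna_id)
            continue
        mature = MatureMiRNA(mirna_id, mirna_fa[mirna_id].sequence.replace("T", "U"))
        for gene, utr in utrs.items():
            sites.extend(find_seed_sites(mature, utr, gene))
    site_df = sites_table(sites)
    site_df.to_csv(_out(config, "seed_sites.tsv"), sep="\t", index=False)
    _log("targets", n_candidates=len(up_report), n_seed_sites=len(site_df))
    return {"up_report": up_report, "down_report": down_report, "seed_sites": site_df}


def _stage_network(config: PipelineConfig):
    path = _out(config, "report_up.tsv")
    if not path.exists():
        raise FileNotFoundError(f"stage 'network': missing upstream output {path} (run 'targets')")
    up_report = pd.read_csv(path, sep="\t")
    seed_path = _out(config, "seed_sites.tsv")
    if not seed_path.exists():
        raise FileNotFoundError(
            f"stage 'network': missing upstream output {seed_path} (run 'targets')"
        )
    site_df = pd.read_csv(seed_path, sep="\t")
    repressed = list(up_report["miRNA"])
    targets_map: dict[str, list] = {}
    for row in site_df.itertuples(index=False):
        targets_map.setdefault(row.mirna, [])
        if row.gene not in targets_map[row.mirna]:
            targets_map[row.mirna].append(row.gene)
    net = build_network(config.tf_id, repressed, targets_map)
    export_network(net, _out(config, "network.sif"), "SIF")
    export_network(net, _out(config, "network.graphml"), "GraphML")
    loops = find_feedback_loops(net, config.tf_id)
    _out(config, "feedback_loops.txt").write_text("".join(m + "\n" for m in loops))
    _log("network", n_nodes=len(net), n_edges=len(net.edges), n_loops=len(loops))
    return {"network": net, "feedback_loops": loops}


_STAGE_FUNCS = {
    "promoters": _stage_promoters,
    "scan": _stage_scan,
    "diffexp": _stage_diffexp,
    "enrich": _stage_enrich,
    "targets": _stage_targets,
    "network": _stage_network,
}


def run_stage(name: str, config: PipelineConfig, synthetic: SyntheticStudyConfig | None = None):
    """Run one pipeline stage (or ``all``); outputs land in ``config.out_dir``.

    The ``simulate`` stage also points the config's input paths at the
    generated files, so ``run_stage("all", config)`` is self-contained.
    """
    config.validate()
    if name not in STAGES:
        raise ValueError(f"unknown stage {name!r}; choose from {STAGES}")
    _out(config, "config.json").write_text(config.to_json())
    if name == "simulate":
        return _stage_simulate(config, synthetic)
    if name == "all":
        out = {"simulate": _stage_simulate(config, synthetic)}
        for stage in ("promoters", "scan", "diffexp", "enrich", "targets", "network"):
            out[stage] = _STAGE_FUNCS[stage](config)
        return out
    return _STAGE_FUNCS[name](config)
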