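"""End-to-end orchestration: simulate -> splice -> call -> clip ->
consequence -> integrate, from a single config, with a deterministic run
manifest.

Every stage writes TSV/BED reports into the output directory; the manifest
records the config hash, the seed, package version and per-stage row counts,
so a rerun with the same config and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core_io import (
    ConfigurationError,
    FastaReader,
    SampleSheet,
    read_bedgraph,
    read_crosslinks,
    read_gtf,
    read_junction_counts,
)
from .splicing import (
    build_psi_table,
    diff_splicing,
    event_class_breakdown,
    extract_splice_events,
)
from .calls import call_events, permutation_control
from .clip import (
    annotate_regions,
    binding_overlap_enrichment,
    call_clusters,
    flank_motif_enrichment,
    pentamer_enrichment,
    rna_map,
)
from .consequence import (
    exon_conservation,
    consequence_table,
    splice_consequence,
)
from .expression import (
    diff_expression,
    long_intron_trend,
    se_expression_enrichment,
    stability_vs_downregulation,
)
from .simulate import SimulationConfig, simulate_study, write_outputs

log = logging.getLogger("skiptic")


@dataclass
class PipelineConfig:
    """All pipeline thresholds and input paths.

    Thresholds default to the analysis definitions used throughout:
    differential splicing FDR 0.01, expression FDR 0.05 (differential
    expression report) and 0.1 (coupling analyses), skiptic/cryptic PSI
    bounds 0.95/0.05 with minimum |dPSI| 0.05, 100-nt intron flanks,
    50 label permutations, and 200-gene bins for the long-intron trend.
    """

    out_dir: str = "skiptic_out"
    seed: int = 0
    # inputs (filled automatically when the simulate stage is enabled)
    gtf: str = ""
    genome_fasta: str = ""
    sample_sheet: str = ""
    sj_dir: str = ""
    crosslinks_bed: str = ""
    conservation_bedgraph: str = ""
    gene_counts: str = ""
    intron_body: str = ""
    # stage toggles
    simulate: bool = True
    run_permutations: bool = True
    run_clip: bool = True
    run_consequence: bool = True
    run_integrate: bool = True
    # thresholds
    fdr_cut_splicing: float = 0.01
    fdr_cut_expression: float = 0.05
    fdr_cut_coupling: float = 0.1
    psi_hi: float = 0.95
    psi_lo: float = 0.05
    dpsi_min: float = 0.05
    min_total: int = 10
    flank: int = 100
    cluster_max_gap: int = 15
    cluster_min_total: int = 3
    pentamer_window: int = 20
    pentamer_shuffles: int = 100
    rna_map_exon_pad: int = 100
    rna_map_intron_pad: int = 300
    rna_map_smooth: int = 15
    rna_map_bootstraps: int = 1000
    nmd_rule_nt: int = 50
    bin_size: int = 200
    n_perm: int = 50
    simulate_config: dict = field(default_factory=dict)

    def __post_init__(self):
        bounded = {
            "fdr_cut_splicing": self.fdr_cut_splicing,
            "fdr_cut_expression": self.fdr_cut_expression,
            "fdr_cut_coupling": self.fdr_cut_coupling,
            "psi_hi": self.psi_hi,
            "psi_lo": self.psi_lo,
            "dpsi_min": self.dpsi_min,
        }
        for name, v in bounded.items():
            if not (0 < v < 1):
                raise ConfigurationError(f"{name} must be in (0, 1), got {v}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config fields: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    _PATH_FIELDS = (
        "out_dir",
        "gtf",
        "genome_fasta",
        "sample_sheet",
        "sj_dir",
        "crosslinks_bed",
        "conservation_bedgraph",
        "gene_counts",
        "intron_body",
    )

    def config_hash(self) -> str:
        """Hash of the analysis parameters (thresholds, seed, simulation
        settings); filesystem locations are excluded so identical analyses
        hash identically wherever they run."""
        d = {k: v for k, v in self.to_dict().items() if k not in self._PATH_FIELDS}
        blob = yaml.safe_dump(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write(df: pd.DataFrame, path: str, cfg_hash: str):
    with open(path, "w") as fh:
        fh.write(f"# skiptic config_hash={cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=False)
    return len(df)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in dependency order; returns the run manifest."""
    cfg = config
    os.makedirs(cfg.out_dir, exist_ok=True)
    chash = cfg.config_hash()
    manifest = {
        "config_hash": chash,
        "seed": cfg.seed,
        "version": __version__,
        "stages": {},
    }
    timers = {}

    def _stage(name):
        log.info("stage %s started", name)
        timers[name] = time.time()

    def _done(name, rows):
        log.info("stage %s done in %.1fs", name, time.time() - timers[name])
        manifest["stages"][name] = {"rows": rows}

    # ------------------------------------------------------------------ simulate
    sim = None
    if cfg.simulate:
        _stage("simulate")
        sim_cfg = SimulationConfig(seed=cfg.seed, **cfg.simulate_config)
        data_dir = os.path.join(cfg.out_dir, "data")
        sim = simulate_study(sim_cfg)
        paths = write_outputs(sim, data_dir)
        cfg.gtf = paths["annotation.gtf"]
        cfg.genome_fasta = paths["genome.fa"]
        cfg.sample_sheet = paths["samples.tsv"]
        cfg.sj_dir = os.path.join(data_dir, "sj")
        cfg.crosslinks_bed = paths["crosslinks.bed"]
        cfg.conservation_bedgraph = paths["conservation.bedGraph"]
        cfg.gene_counts = paths["gene_counts.tsv"]
        cfg.intron_body = paths["intron_body.tsv"]
        _done("simulate", len(sim.truth_events))

    for name, path in [("gtf", cfg.gtf), ("sample_sheet", cfg.sample_sheet), ("sj_dir", cfg.sj_dir)]:
        if not path or not os.path.exists(path):
            raise ConfigurationError(f"required input {name!r} missing: {path!r}")

    # ------------------------------------------------------------------ splice
    _stage("splice")
    models = read_gtf(cfg.gtf)
    sheet = SampleSheet.from_tsv(cfg.sample_sheet)
    sj_paths = {
        s: os.path.join(cfg.sj_dir, f"{s}.SJ.out.tab") for s in sheet.sample_ids
    }
    junctions = read_junction_counts(sj_paths, sheet)
    intron_body = (
        pd.read_csv(cfg.intron_body, sep="\t", index_col=0)
        if cfg.intron_body and os.path.exists(cfg.intron_body)
        else None
    )
    events = extract_splice_events(models, junctions)
    psi_table = build_psi_table(events, junctions, sheet, cfg.min_total, intron_body)
    results = diff_splicing(psi_table, sheet)
    breakdown = event_class_breakdown(results, cfg.fdr_cut_splicing)
    _write(
        results.reset_index(drop=True),
        os.path.join(cfg.out_dir, "diff_splicing.tsv"),
        chash,
    )
    psi_df = psi_table.to_frame().reset_index(names="event_id")
    _write(psi_df, os.path.join(cfg.out_dir, "psi.tsv"), chash)
    _done("splice", len(results))

    # ------------------------------------------------------------------ call
    _stage("call")
    calls = call_events(
        results, cfg.fdr_cut_splicing, cfg.psi_hi, cfg.psi_lo, cfg.dpsi_min
    )
    _write(calls.reset_index(drop=True), os.path.join(cfg.out_dir, "calls.tsv"), chash)
    if cfg.run_permutations and cfg.n_perm > 0:
        perm = permutation_control(
            psi_table,
            sheet,
            n_perm=cfg.n_perm,
            seed=cfg.seed,
            fdr_cut=cfg.fdr_cut_splicing,
            psi_hi=cfg.psi_hi,
            psi_lo=cfg.psi_lo,
            dpsi_min=cfg.dpsi_min,
        )
        _write(perm.to_frame(), os.path.join(cfg.out_dir, "permutations.tsv"), chash)
        manifest["permutation_empirical_p_skiptic"] = _none_nan(perm.empirical_p_skiptic)
    _done("call", int((calls["category"] != "none").sum()))

    event_by_id = {e.event_id: e for e in events}

    def _targets(ids):
        return [event_by_id[i].target for i in ids if i in event_by_id]

    skiptic_ids = list(calls.index[calls["category"] == "skiptic"])
    cryptic_ids = list(calls.index[calls["category"] == "cryptic"])
    cassette_mask = calls["event_class"] == "cassette"
    other_diff_ids = list(
        calls.index[cassette_mask & calls["category"].isin(["alt_shift"])]
    )
    nonsig_ids = list(calls.index[cassette_mask & (calls["category"] == "none")])
    event_exon_keys = {
        (e.target.chrom, e.target.start, e.target.end) for e in events
    }
    constitutive = []
    for m in models:
        for e in m.exons[1:-1]:
            if (e.chrom, e.start, e.end) not in event_exon_keys:
                constitutive.append(e)
    constitutive = sorted(set(constitutive), key=lambda e: (e.chrom, e.start))[:500]

    # ------------------------------------------------------------------ clip
    if cfg.run_clip and cfg.crosslinks_bed and os.path.exists(cfg.crosslinks_bed) and cfg.genome_fasta:
        _stage("clip")
        sites = read_crosslinks(cfg.crosslinks_bed)
        genome = FastaReader(cfg.genome_fasta)
        clusters = call_clusters(sites, cfg.cluster_max_gap, cfg.cluster_min_total)
        with open(os.path.join(cfg.out_dir, "clusters.bed"), "w") as fh:
            fh.write(f"# skiptic config_hash={chash}\n")
            for c in clusters:
                iv = c.interval
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\tcluster\t{c.total}\t{iv.strand}\n"
                )
        regions = annotate_regions(clusters, models)
        _write(
            regions.rename_axis("region").rename("fraction").reset_index(),
            os.path.join(cfg.out_dir, "region_distribution.tsv"),
            chash,
        )
        scores = pentamer_enrichment(
            sites, genome, models, cfg.pentamer_window, cfg.pentamer_shuffles, cfg.seed
        )
        pent = pd.DataFrame(
            {
                "pentamer": scores.z.index,
                "z": scores.z.to_numpy(),
                "observed": scores.observed.to_numpy(),
                "null_mean": scores.null_mean.to_numpy(),
                "null_sd": scores.null_sd.to_numpy(),
            }
        ).sort_values("z", ascending=False)
        _write(pent, os.path.join(cfg.out_dir, "pentamers.tsv"), chash)

        regulated_ids = skiptic_ids or cryptic_ids
        if regulated_ids and nonsig_ids:
            motif_sets = {
                "regulated": _targets(regulated_ids),
                "other_diff": _targets(other_diff_ids),
            }
            motif_sets = {k: v for k, v in motif_sets.items() if v}
            enr = flank_motif_enrichment(
                motif_sets, genome, _targets(nonsig_ids), flank=cfg.flank
            )
            _write(
                enr.reset_index(),
                os.path.join(cfg.out_dir, "flank_motif_enrichment.tsv"),
                chash,
            )
            sign = -1 if skiptic_ids else 1
            profile = rna_map(
                clusters,
                _targets(regulated_ids),
                _targets(nonsig_ids),
                cfg.rna_map_exon_pad,
                cfg.rna_map_intron_pad,
                cfg.rna_map_smooth,
                cfg.rna_map_bootstraps,
                cfg.seed,
                dpsi_sign=sign,
            )
            _write(
                profile.to_frame(), os.path.join(cfg.out_dir, "rna_map.tsv"), chash
            )
            overlap_sets = {
                "skiptic" if skiptic_ids else "cryptic": _targets(regulated_ids),
                "other_diff_cassette": _targets(other_diff_ids),
                "nonsig_cassette": _targets(nonsig_ids)[:500],
                "constitutive": constitutive,
            }
            overlap_sets = {k: v for k, v in overlap_sets.items() if v}
            ov = binding_overlap_enrichment(
                overlap_sets, clusters, cfg.flank, reference="constitutive"
            )
            _write(
                ov.reset_index(),
                os.path.join(cfg.out_dir, "binding_overlap.tsv"),
                chash,
            )
        _done("clip", len(clusters))

    # ------------------------------------------------------------------ consequence
    _stage("consequence")
    n_cons = 0
    cons_df = pd.DataFrame(columns=["event_id", "stability_class"]).set_index(
        "event_id", drop=False
    )
    if cfg.run_consequence and cfg.genome_fasta and skiptic_ids:
        genome = FastaReader(cfg.genome_fasta)
        by_gene: dict = {}
        for m in models:
            by_gene.setdefault(m.gene_id, []).append(m)
        cons_calls = []
        for eid in skiptic_ids:
            ev = event_by_id[eid]
            host = next(
                (
                    m
                    for m in by_gene.get(ev.gene_id, [])
                    if any(
                        x.start == ev.target.start and x.end == ev.target.end
                        for x in m.exons
                    )
                ),
                None,
            )
            if host is None:
                continue
            cons_calls.append(
                splice_consequence(host, ev.target, genome, eid, cfg.nmd_rule_nt)
            )
        cons_df = consequence_table(cons_calls)
        n_cons = len(cons_df)
        _write(
            cons_df.reset_index(drop=True),
            os.path.join(cfg.out_dir, "consequences.tsv"),
            chash,
        )
    if cfg.run_consequence and cfg.conservation_bedgraph and os.path.exists(cfg.conservation_bedgraph):
        track = read_bedgraph(cfg.conservation_bedgraph)
        groups = {}
        if skiptic_ids:
            groups["skiptic"] = _targets(skiptic_ids)
        if cryptic_ids:
            groups["cryptic"] = _targets(cryptic_ids)
        groups["all_exons"] = constitutive
        rows = []
        for name, exons in groups.items():
            scored = exon_conservation(exons, track)
            vals = np.array([c.mean_score for c in scored])
            rows.append(
                {
                    "group": name,
                    "n": len(vals),
                    "median": float(np.median(vals)) if len(vals) else np.nan,
                    "q1": float(np.percentile(vals, 25)) if len(vals) else np.nan,
                    "q3": float(np.percentile(vals, 75)) if len(vals) else np.nan,
                }
            )
        _write(
            pd.DataFrame(rows), os.path.join(cfg.out_dir, "conservation.tsv"), chash
        )
    _done("consequence", n_cons)

    # ------------------------------------------------------------------ integrate
    if cfg.run_integrate and cfg.gene_counts and os.path.exists(cfg.gene_counts):
        _stage("integrate")
        counts = pd.read_csv(cfg.gene_counts, sep="\t", index_col=0)
        de = diff_expression(counts, sheet)
        _write(
            de.reset_index(drop=True), os.path.join(cfg.out_dir, "diff_expression.tsv"), chash
        )
        enr = se_expression_enrichment(calls, de, cfg.fdr_cut_coupling)
        _write(
            enr.reset_index(),
            os.path.join(cfg.out_dir, "se_expression_enrichment.tsv"),
            chash,
        )
        if len(cons_df):
            chi = stability_vs_downregulation(calls, cons_df, de, cfg.fdr_cut_coupling)
            with open(os.path.join(cfg.out_dir, "stability_chi2.json"), "w") as fh:
                json.dump(
                    {
                        "table": np.asarray(chi["table"]).tolist(),
                        "chi2": None if np.isnan(chi["chi2"]) else chi["chi2"],
                        "p": None if np.isnan(chi["p"]) else chi["p"],
                        "prop_damaging_downregulated": _none_nan(
                            chi["prop_damaging_downregulated"]
                        ),
                        "prop_damaging_other": _none_nan(chi["prop_damaging_other"]),
                        "config_hash": chash,
                    },
                    fh,
                    indent=1,
                )
        trend = long_intron_trend(de, models, cfg.bin_size)
        _write(
            trend["bins"], os.path.join(cfg.out_dir, "long_intron_bins.tsv"), chash
        )
        manifest["long_intron_spearman_rho"] = _none_nan(trend["spearman_rho"])
        manifest["n_deg"] = int(
            ((de["fdr"] < cfg.fdr_cut_expression) & de["tested"]).sum()
        )
        _done("integrate", len(de))

    manifest["event_class_breakdown"] = breakdown["class_fractions"]
    manifest["cassette_skipping_fraction"] = _none_nan(
        breakdown["cassette_skipping_fraction"]
    )
    manifest["n_skiptic"] = len(skiptic_ids)
    manifest["n_cryptic"] = len(cryptic_ids)
    manifest["manifest_hash"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True).encode()
    ).hexdigest()[:16]
    with open(os.path.join(cfg.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def _none_nan(x):
    if x is None:
        return None
    x = float(x)
    return None if np.isnan(x) else x
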