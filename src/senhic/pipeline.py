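"""Config-driven end-to-end pipeline.

Stages run in dependency order over a working directory of plain-text
artifacts::

    simulate -> normalize -> compartments -> transitions -> sahf -> tads
             -> enrich -> report

Each stage reads its inputs from the output directory of the previous ones,
so stages can be rerun individually; a missing upstream artifact raises a
:class:`PipelineError` naming the stage to run first. ``report`` writes a
JSON summary with a SHA-256 checksum of every artifact, the effective
parameters and derived per-stage seeds, so two runs from the same config can
be compared byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import yaml

from senhic import compartments as comp
from senhic import enrichment as enr
from senhic import io as sio
from senhic import matrix as mat
from senhic import synthetic as syn
from senhic import tads as tadmod

logger = logging.getLogger(__name__)

STAGES = ("simulate", "normalize", "compartments", "transitions",
          "sahf", "tads", "enrich", "report")

CONDITIONS = syn.CONDITIONS

DEFAULTS: dict = {
    "seed": 0,
    "bin_size": 40_000,
    "chromosome_length_bp": 40_000_000,
    "n_chromosomes": 2,
    # generator knobs (study conditions)
    "checkerboard": 1.6,
    "tad_strength": 3.0,
    "sahf_boost": 3.0,
    "depth": 60.0,
    "bias_sd": 0.5,
    "transition_fraction": 0.10,
    # analysis parameters (defaults follow the published conventions)
    "ice_iterations": 30,
    "low_coverage_quantile": 0.02,
    "min_compartment_bins": 5,
    "sahf_threshold": -20.0,
    "sahf_auto_threshold": True,
    "lvs_cutoff_bp": 2_000_000,
    "lvs_flag_threshold": 0.5,
    "tad_window_bins": 13,
    "tad_z_min": 1.0,
    "border_tolerance_bins": 1,
    "gsea_n_perm": 1000,
    "gsea_weight": 1.0,
    "window_size_bp": 200_000,
    "window_max_bp": 1_400_000,
}


class PipelineError(RuntimeError):
    pass


class ConfigError(ValueError):
    pass


def validate_config(path=None, overrides: dict | None = None) -> dict:
    """Load a YAML key-value config, fill defaults, reject unknown keys."""
    cfg = dict(DEFAULTS)
    loaded: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigError("config must be a mapping of key: value")
    if overrides:
        loaded.update(overrides)
    for key, value in loaded.items():
        if key not in DEFAULTS:
            raise ConfigError(f"unknown config key: {key!r}")
        want = type(DEFAULTS[key])
        if want in (float, int) and isinstance(value, (int, float)) \
                and not isinstance(value, bool):
            value = want(value)
        if not isinstance(value, want):
            raise ConfigError(
                f"config key {key!r}: expected {want.__name__}, "
                f"got {type(value).__name__}")
        cfg[key] = value
    logger.info("effective config: %s", cfg)
    return cfg


def _synthetic_config(cfg: dict) -> syn.SyntheticConfig:
    chroms = tuple(
        (f"chr{i + 1}", cfg["chromosome_length_bp"])
        for i in range(cfg["n_chromosomes"])
    )
    return syn.SyntheticConfig(
        chromosomes=chroms,
        bin_size=cfg["bin_size"],
        checkerboard=cfg["checkerboard"],
        tad_strength=cfg["tad_strength"],
        sahf_boost=cfg["sahf_boost"],
        depth=cfg["depth"],
        bias_sd=cfg["bias_sd"],
        transition_fraction=cfg["transition_fraction"],
        seed=cfg["seed"],
    )


class Pipeline:
    """Stateful driver binding a config to an output directory."""

    def __init__(self, cfg: dict, outdir):
        self.cfg = cfg
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.syncfg = _synthetic_config(cfg)
        self.chroms = [name for name, _ in self.syncfg.chromosomes]

    # -- paths --------------------------------------------------------------
    def path(self, name: str) -> Path:
        return self.outdir / name

    def _require(self, name: str, producer: str) -> Path:
        p = self.path(name)
        if not p.exists():
            raise PipelineError(
                f"missing artifact {name!r}: run stage {producer!r} first")
        return p

    def _bins(self, chrom: str):
        return self.syncfg.bins_for(chrom)

    def _truth(self) -> syn.SyntheticTruth:
        return syn.SyntheticTruth.from_json(self._require("truth.json", "simulate"))

    def _load_matrix(self, name: str, chrom: str, producer: str,
                     normalized: bool) -> mat.ContactMatrix:
        p = self._require(name, producer)
        bins = self._bins(chrom)
        m = mat.load_contact_matrix(p, bins)
        mask = set()
        with open(p) as fh:
            for line in fh:
                if line.startswith("# masked="):
                    mask = {int(x) for x in line.split("=", 1)[1].split(",")}
                if not line.startswith("#"):
                    break
        return mat.ContactMatrix(bins, m.counts, frozenset(mask), normalized)

    def _pca_track(self, condition: str, chrom: str) -> comp.PCATrack:
        p = self._require(f"pca_{condition}_{chrom}.bedgraph", "compartments")
        score = sio.read_bedgraph(p, self._bins(chrom))
        return comp.PCATrack(self._bins(chrom), score, 1.0)

    # -- stages -------------------------------------------------------------
    def simulate(self) -> None:
        truth = syn.plant_architecture(self.syncfg)
        truth.to_json(self.path("truth.json"))
        for cond in CONDITIONS:
            for chrom in self.chroms:
                m = syn.simulate_contacts(truth, cond, chrom)
                mat.save_contact_matrix(m, self.path(f"raw_{cond}_{chrom}.txt"))
        genes, tracks = syn.simulate_expression_and_tracks(truth)
        sio.write_tsv(self.path("genes.tsv"), genes)
        for name, per_chrom in tracks.items():
            for chrom, values in per_chrom.items():
                sio.write_bedgraph(self.path(f"track_{name}_{chrom}.bedgraph"),
                                   self._bins(chrom), values)

    def normalize(self) -> None:
        for cond in CONDITIONS:
            for chrom in self.chroms:
                m = self._load_matrix(f"raw_{cond}_{chrom}.txt", chrom,
                                      "simulate", normalized=False)
                iced = mat.ice_normalize(
                    m, self.cfg["ice_iterations"],
                    self.cfg["low_coverage_quantile"])
                mat.save_contact_matrix(
                    iced, self.path(f"iced_{cond}_{chrom}.txt"))

    def compartments(self) -> None:
        for cond in CONDITIONS:
            for chrom in self.chroms:
                m = self._load_matrix(f"iced_{cond}_{chrom}.txt", chrom,
                                      "normalize", normalized=True)
                gd = sio.read_bedgraph(
                    self._require(f"track_gene_density_{chrom}.bedgraph",
                                  "simulate"), self._bins(chrom))
                track = comp.pca_scores(m, gd)
                sio.write_bedgraph(
                    self.path(f"pca_{cond}_{chrom}.bedgraph"),
                    self._bins(chrom), track.score)
                cs = comp.call_compartments(
                    track, self.cfg["min_compartment_bins"])
                sio.write_bed(self.path(f"compartments_{cond}_{chrom}.bed"),
                              self._bins(chrom), cs.intervals)

    def transitions(self) -> None:
        stats = {}
        for chrom in self.chroms:
            t_g = self._pca_track("growing", chrom)
            t_s = self._pca_track("senescent", chrom)
            t_k = self._pca_track("kd", chrom)
            tm_gs = comp.classify_transitions(t_g, t_s)
            tm_sk = comp.classify_transitions(t_s, t_k)
            sio.write_bed(self.path(f"transitions_gs_{chrom}.bed"),
                          self._bins(chrom),
                          tm_gs.runs(("BA", "AB")))
            for tag, tm in (("gs", tm_gs), ("sk", tm_sk)):
                with open(self.path(f"transitions_{tag}_{chrom}.tsv"), "w") as fh:
                    fh.write("# category\n")
                    fh.write("\n".join(tm.category.astype(str)) + "\n")
            bab = comp.classify_bab(tm_gs, tm_sk)
            sio.write_bed(self.path(f"bab_{chrom}.bed"), self._bins(chrom),
                          [(i, i, "BAB") for i in np.flatnonzero(bab)])
            ov = enr.hypergeometric_overlap(
                tm_gs.bins_in("BA").tolist(),
                tm_sk.bins_in("AB").tolist(),
                self._bins(chrom).n_bins)
            stats[chrom] = {
                "n_BA_gs": int(tm_gs.bins_in("BA").size),
                "n_AB_sk": int(tm_sk.bins_in("AB").size),
                "n_BAB": int(bab.sum()),
                "overlap_p_log10": ov.log10_p,
            }
        with open(self.path("transition_stats.json"), "w") as fh:
            json.dump(stats, fh, indent=1, sort_keys=True)

    def sahf(self) -> None:
        summary = {}
        for cond in ("growing", "senescent", "kd"):
            all_scores = []
            tracks = {}
            for chrom in self.chroms:
                tracks[chrom] = self._pca_track(cond, chrom)
                all_scores.append(tracks[chrom].score)
            threshold = self.cfg["sahf_threshold"]
            if self.cfg["sahf_auto_threshold"]:
                threshold = comp.sahf_threshold_from_scores(
                    np.concatenate(all_scores))
            summary[cond] = {"threshold": float(threshold)}
            for chrom in self.chroms:
                regions = comp.detect_sahf(tracks[chrom], threshold)
                sio.write_bed(self.path(f"sahf_{cond}_{chrom}.bed"),
                              self._bins(chrom),
                              [(s, e, "SAHF") for s, e in regions.regions()])
                m = self._load_matrix(f"iced_{cond}_{chrom}.txt", chrom,
                                      "normalize", normalized=True)
                lvs = comp.lvs_scores(m, self.cfg["lvs_cutoff_bp"])
                sio.write_bedgraph(self.path(f"lvs_{cond}_{chrom}.bedgraph"),
                                   self._bins(chrom), lvs.lvs)
                summary[cond][chrom] = {
                    "n_sahf_bins": int(regions.flagged.sum()),
                    "n_high_lvs_bins": int(np.nansum(
                        lvs.lvs > self.cfg["lvs_flag_threshold"])),
                }
        with open(self.path("sahf_summary.json"), "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True)

    def tads(self) -> None:
        for cond in CONDITIONS:
            tracks = []
            for chrom in self.chroms:
                m = self._load_matrix(f"iced_{cond}_{chrom}.txt", chrom,
                                      "normalize", normalized=True)
                R = tadmod.raw_border_strength(
                    m.counts, self.cfg["tad_window_bins"], m.mask_array())
                tracks.append(tadmod.BorderStrengthTrack(
                    self._bins(chrom), R, np.full_like(R, np.nan),
                    self.cfg["tad_window_bins"]))
            tadmod.zscore_tracks(tracks)  # pooled genome-wide
            for chrom, track in zip(self.chroms, tracks):
                sio.write_bedgraph(
                    self.path(f"border_strength_{cond}_{chrom}.bedgraph"),
                    self._bins(chrom), track.z_score)
                borders = tadmod.call_tad_borders(track, self.cfg["tad_z_min"])
                sio.write_bed(self.path(f"tad_borders_{cond}_{chrom}.bed"),
                              self._bins(chrom),
                              [(b, b, "border") for b in borders.border_bins])

    def enrich(self) -> None:
        genes = sio.read_gene_table(self._require("genes.tsv", "simulate"))
        ranked = genes.set_index("gene_id")["fc_senescent_vs_growing"]
        ranked = np.log2(ranked)
        results = {}
        seed = self.cfg["seed"] + 7001
        ba_genes, ab_genes = [], []
        for chrom in self.chroms:
            with open(self._require(f"transitions_gs_{chrom}.tsv",
                                    "transitions")) as fh:
                cat = np.array([ln.strip() for ln in fh
                                if ln.strip() and not ln.startswith("#")],
                               dtype=object)
            sub = genes[genes["chrom"] == chrom]
            gene_cat = cat[sub["bin"].to_numpy()]
            ba_genes += sub.loc[gene_cat == "BA", "gene_id"].tolist()
            ab_genes += sub.loc[gene_cat == "AB", "gene_id"].tolist()
        for name, ids in (("BA", ba_genes), ("AB", ab_genes)):
            if ids:
                r = enr.preranked_gsea(ranked, ids, self.cfg["gsea_n_perm"],
                                       seed, self.cfg["gsea_weight"])
                results[f"gsea_{name}"] = {
                    "es": r.es, "nes": r.nes, "p": r.p_value,
                    "set_size": r.set_size}
        # distance-window analysis around detected (senescent) SAHF
        sahf_bp = {}
        for chrom in self.chroms:
            regions = []
            p = self._require(f"sahf_senescent_{chrom}.bed", "sahf")
            with open(p) as fh:
                for line in fh:
                    if line.startswith("#"):
                        continue
                    _c, s, e = line.split("\t")[:3]
                    regions.append((int(s), int(e)))
            sahf_bp[chrom] = regions
        sweep = enr.window_sweep(genes, sahf_bp, "fc_senescent_vs_growing",
                                 self.cfg["window_size_bp"],
                                 self.cfg["window_max_bp"])
        sio.write_tsv(self.path("window_sweep.tsv"), sweep)
        results["pct_downregulated_genomewide"] = enr.fraction_downregulated(
            genes["gene_id"], genes, "fc_senescent_vs_growing")
        with open(self.path("enrichment.json"), "w") as fh:
            json.dump(results, fh, indent=1, sort_keys=True)

    def report(self) -> dict:
        artifacts = sorted(p.name for p in self.outdir.iterdir()
                           if p.is_file() and p.name != "report.json")
        checksums = {}
        for name in artifacts:
            h = hashlib.sha256()
            h.update(self.path(name).read_bytes())
            checksums[name] = h.hexdigest()
        rep = {
            "parameters": self.cfg,
            "stage_order": list(STAGES),
            "artifacts": checksums,
            "seed": self.cfg["seed"],
        }
        with open(self.path("report.json"), "w") as fh:
            json.dump(rep, fh, indent=1, sort_keys=True)
        return rep


def run_pipeline(cfg: dict, outdir, stages=("all",)) -> dict:
    """Run the requested stages in dependency order; returns the report.

    ``stages`` may contain ``"all"`` or any subset of :data:`STAGES`;
    requested stages always execute in canonical order.
    """
    wanted = set(STAGES) if "all" in stages else set(stages)
    unknown = wanted - set(STAGES)
    if unknown:
        raise ConfigError(f"unknown stages: {sorted(unknown)}")
    pipe = Pipeline(cfg, outdir)
    for stage in STAGES:
        if stage not in wanted:
            continue
        t0 = time.monotonic()
        logger.info("stage %s: start", stage)
        getattr(pipe, stage)()
        logger.info("stage %s: done in %.1fs", stage, time.monotonic() - t0)
    if "report" in wanted:
        with open(pipe.path("report.json")) as fh:
            return json.load(fh)
    return {}
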