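"""End-to-end orchestration: simulate (or ingest) through shift reports.

One config drives a full run: generate synthetic chromatin (or load user
fragments/peaks/annotation), apply the clustering pre-filters, estimate
the footprint, build V-plots and length profiles, classify sites with
K-means, score long-fragment asymmetry, split the long-fragment class by
aborted-transcript score, and quantify nucleosome shifts upon remodeler
depletion.  Every stage logs input/output counts and the run emits a
machine-readable JSON summary plus TSV/BED artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fragio, footprint, netnuc, peaks, simulate, vplot

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Exactly one of ``simulation`` / ``inputs`` drives a run."""

    outdir: Path
    seed: int = 0
    simulation: simulate.SimulationParams | None = None
    inputs: dict | None = None
    analysis: peaks.AnalysisParams = field(default_factory=peaks.AnalysisParams)
    shift_bp: int = 25
    netseq_reads_per_site: int = 500
    nuc_fragments_per_site: int = 1000

    def __post_init__(self):
        self.outdir = Path(self.outdir)
        if (self.simulation is None) == (self.inputs is None):
            raise ValueError("exactly one of simulation/inputs must be configured")

    @classmethod
    def from_yaml(cls, path, seed: int | None = None, outdir=None) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.get("simulation")
        if sim is not None:
            sim = simulate.SimulationParams(**sim)
        ana = peaks.AnalysisParams(**raw.get("analysis", {}))
        return cls(
            outdir=Path(outdir if outdir is not None else raw.get("outdir", "slimfoot_out")),
            seed=int(seed if seed is not None else raw.get("seed", 0)),
            simulation=sim,
            inputs=raw.get("inputs"),
            analysis=ana,
            shift_bp=int(raw.get("shift_bp", 25)),
            netseq_reads_per_site=int(raw.get("netseq_reads_per_site", 500)),
            nuc_fragments_per_site=int(raw.get("nuc_fragments_per_site", 1000)),
        )


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _simulated_inputs(cfg: RunConfig):
    params = dataclasses.replace(cfg.simulation, seed=cfg.seed)
    panel = simulate.build_site_panel(params)
    chip = simulate.simulate_chip_fragments(panel, params, seed=cfg.seed + 1)
    reads = simulate.simulate_netseq_reads(panel, cfg.netseq_reads_per_site, seed=cfg.seed + 2)
    nuc_before = simulate.simulate_nucleosome_fragments(
        panel, depleted=False, shift_bp=cfg.shift_bp, seed=cfg.seed + 3,
        fragments_per_site=cfg.nuc_fragments_per_site)
    nuc_after = simulate.simulate_nucleosome_fragments(
        panel, depleted=True, shift_bp=cfg.shift_bp, seed=cfg.seed + 4,
        fragments_per_site=cfg.nuc_fragments_per_site)
    return panel, chip, reads, nuc_before, nuc_after


def _panel_peakset(panel: simulate.SitePanel, chip: fragio.FragmentSet,
                   halfwidth: int = 100) -> peaks.PeakSet:
    """One peak per simulated site, summit at the motif center."""
    mids = vplot.fragment_midpoints(chip)
    chroms = chip.frags["chrom"].to_numpy()
    out = []
    for s in panel.sites:
        n = int(((chroms == s.chrom) & (np.abs(mids - s.motif_center) <= halfwidth)).sum())
        motif = fragio.MotifOccurrence(s.chrom, s.motif_center - 7,
                                       s.motif_center + 8, s.motif_strand, "consensus")
        out.append(peaks.Peak(s.chrom, s.motif_center - halfwidth,
                              s.motif_center + halfwidth + 1,
                              summit=s.motif_center, read_count=n,
                              motif=motif, name=s.site_id))
    return peaks.PeakSet(out, "simulated")


def run_analysis(cfg: RunConfig) -> dict:
    """Execute the full analysis; returns the summary dict (also on disk).

    On a stage failure a partial-results manifest is written and a
    StageError naming the stage is raised.
    """
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": cfg.seed, "stages": []}
    stage = "configure"
    try:
        if cfg.simulation is not None:
            stage = "simulate"
            panel, chip, reads, nuc_before, nuc_after = _simulated_inputs(cfg)
            panel.to_tsv(cfg.outdir / "panel.tsv")
            fragio.write_bed(chip, cfg.outdir / "chip_fragments.bed")
            fragio.write_stranded_reads(reads, cfg.outdir / "netseq.bed")
            anchors_all = panel.anchors()
            telomeres = panel.telomeres
            peakset = _panel_peakset(panel, chip)
            truth = anchors_all.set_index("name")["class_label"]
            logger.info("simulated %d sites, %d fragments, %d NET-seq reads",
                        len(panel), len(chip), len(reads))
        else:
            stage = "ingest"
            paths = cfg.inputs
            chip = fragio.read_fragments(paths["fragments"], paths.get("fragments_format", "BED"))
            peakset = peaks.read_peaks(paths["peaks"])
            if paths.get("motifs"):
                occs = [fragio.MotifOccurrence(r["chrom"], r["start"], r["end"],
                                               r["strand"], r["name"])
                        for _, r in fragio._read_bed(paths["motifs"]).iterrows()]
                peaks.attach_motifs(peakset, occs)
            ann = fragio.read_annotation(paths["tss"], paths.get("orfs"), paths.get("telomeres"))
            anchors_all, n_far = peaks.assign_nearest_tss(
                peakset, ann, cfg.analysis.tss_max_dist)
            anchors_all["class_label"] = "?"
            telomeres = ann.telomeres
            reads = (fragio.read_stranded_reads(paths["netseq"])
                     if paths.get("netseq") else None)
            nuc_before = (fragio.read_fragments(paths["nuc_before"])
                          if paths.get("nuc_before") else None)
            nuc_after = (fragio.read_fragments(paths["nuc_after"])
                         if paths.get("nuc_after") else None)
            truth = None
            summary["n_tss_discarded"] = n_far
        summary["stages"].append(stage)
        summary["n_fragments"] = len(chip)
        summary["n_peaks"] = len(peakset)

        stage = "filters"
        filtered, report = peaks.apply_clustering_filters(
            peakset, cfg.analysis.bottom_fraction)
        report.to_frame().to_csv(cfg.outdir / "filter_ledger.tsv", sep="\t", index=False)
        summary["filter_ledger"] = dataclasses.asdict(report)
        assert report.n_input == report.n_motifless + report.n_after_motif
        assert report.n_after_motif == report.n_low_count + report.n_retained
        retained = {p.name for p in filtered.peaks}
        anchors = anchors_all[anchors_all["name"].isin(retained)].reset_index(drop=True)
        summary["stages"].append(stage)
        logger.info("filters: %d -> %d peaks", report.n_input, report.n_retained)

        stage = "footprint"
        short = fragio.select_by_length(chip, 1, cfg.analysis.short_max_len)
        ep = footprint.end_profiles(short, anchors, W=40)
        ep.to_frame().to_csv(cfg.outdir / "end_profiles.tsv", sep="\t", index=False)
        width, L, R = footprint.estimate_footprint_width(ep, flank=40)
        summary["footprint"] = {"width": width, "left": L, "right": R}
        summary["stages"].append(stage)

        stage = "vplot"
        vm = vplot.vplot(chip, anchors, W=400, Lmin=1, Lmax=250)
        vm.to_frame().to_csv(cfg.outdir / "vplot.tsv", sep="\t")
        summary["vplot_total"] = int(vm.counts.sum())
        summary["stages"].append(stage)

        stage = "cluster"
        profiles = vplot.profiles_for_sites(chip, anchors)
        keep = [not p.empty for p in profiles]
        profiles = [p for p in profiles if not p.empty]
        anchors = anchors[np.array(keep, dtype=bool)].reset_index(drop=True)
        result = vplot.cluster_profiles(profiles, K=cfg.analysis.k_clusters,
                                        seed=cfg.seed, restarts=25)
        pd.DataFrame({"peak_id": [p.peak_id for p in profiles],
                      "label": result.labels}).to_csv(
            cfg.outdir / "clusters.tsv", sep="\t", index=False)
        summary["cluster_sizes"] = result.sizes()
        summary["n_clustered"] = len(profiles)
        summary["stages"].append(stage)

        stage = "asymmetry"
        asym = vplot.long_fragment_asymmetry(chip, anchors, cfg.analysis.long_range)
        by_cluster = {}
        for k in sorted(result.sizes()):
            ids = [p.peak_id for p, lab in zip(profiles, result.labels) if lab == k]
            vals = asym.loc[ids].dropna()
            by_cluster[str(k)] = round(float(vals.mean()), 4) if len(vals) else None
        summary["asymmetry_by_cluster"] = by_cluster
        summary["stages"].append(stage)

        K = cfg.analysis.k_clusters
        c4_ids = [p.peak_id for p, lab in zip(profiles, result.labels) if lab == K]
        c4_anchors = anchors[anchors["name"].isin(c4_ids)].reset_index(drop=True)
        if reads is not None and len(c4_anchors) >= 2:
            stage = "netseq_split"
            scores = netnuc.aborted_transcript_score(reads, c4_anchors,
                                                     telomeres=telomeres)
            sub, did_split = netnuc.split_cluster4(scores, seed=cfg.seed)
            sub.to_frame().assign(score=scores).to_csv(
                cfg.outdir / "cluster4_split.tsv", sep="\t")
            summary["subcluster_sizes"] = sub.value_counts().to_dict()
            summary["subcluster_split_done"] = bool(did_split)
            summary["stages"].append(stage)
        else:
            sub, did_split = None, False

        if nuc_before is not None and nuc_after is not None:
            stage = "nucleosome_shift"
            shifts = {}
            groups = {"cluster1": anchors[anchors["name"].isin(
                [p.peak_id for p, lab in zip(profiles, result.labels) if lab == 1])]}
            if did_split:
                for lab in ("4a", "4b"):
                    ids = sub[sub == lab].index
                    groups[f"cluster{lab}"] = c4_anchors[
                        c4_anchors["name"].isin(ids)].reset_index(drop=True)
            for gname, ga in groups.items():
                if not len(ga):
                    continue
                before = netnuc.nucleosome_profile(nuc_before, ga, W=500,
                                                   halfwidth=cfg.analysis.nuc_halfwidth,
                                                   telomeres=telomeres)
                after = netnuc.nucleosome_profile(nuc_after, ga, W=500,
                                                  halfwidth=cfg.analysis.nuc_halfwidth,
                                                  telomeres=telomeres)
                rep = netnuc.nucleosome_shift(before, after, W=500)
                shifts[gname] = dataclasses.asdict(rep)
            summary["nucleosome_shifts"] = shifts
            summary["stages"].append(stage)

        if truth is not None:
            summary["ground_truth_classes"] = (
                truth.loc[anchors["name"]].value_counts().to_dict())
    except Exception as exc:  # noqa: BLE001 - abort with stage name + manifest
        manifest = {"failed_stage": stage, "completed": summary.get("stages", []),
                    "error": str(exc)}
        (cfg.outdir / "partial_manifest.json").write_text(json.dumps(manifest, indent=2))
        raise StageError(stage, exc) from exc

    (cfg.outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=str))
    return summary


def make_fixture(outdir, small: bool = True, seed: int = 0,
                 motif: str = "TTACCCK") -> dict:
    """Write a miniature simulated dataset usable by every reader.

    At the ``small`` scale (5 sites/class, 200 fragments/site) this runs in
    seconds and is the worked example used in the docs.  Emits BED/TSV
    files plus a toy FASTA with the IUPAC consensus planted at each motif
    center, for consensus-scan round-trips.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = simulate.SimulationParams(
        n_sites_per_class=5 if small else 50,
        fragments_per_site=200 if small else 500,
        seed=seed,
    )
    panel = simulate.build_site_panel(params)
    chip = simulate.simulate_chip_fragments(panel, params, seed=seed + 1)
    reads = simulate.simulate_netseq_reads(panel, 200 if small else 500, seed=seed + 2)
    nuc_b = simulate.simulate_nucleosome_fragments(panel, False, 25, seed=seed + 3,
                                                   fragments_per_site=200)
    nuc_a = simulate.simulate_nucleosome_fragments(panel, True, 25, seed=seed + 4,
                                                   fragments_per_site=200)
    panel.to_tsv(outdir / "panel.tsv")
    fragio.write_bed(chip, outdir / "chip_fragments.bed")
    fragio.write_stranded_reads(reads, outdir / "netseq.bed")
    fragio.write_bed(nuc_b, outdir / "nuc_before.bed")
    fragio.write_bed(nuc_a, outdir / "nuc_after.bed")
    pd.DataFrame({
        "chrom": [s.chrom for s in panel.sites],
        "pos": [s.tss_pos for s in panel.sites],
        "strand": [s.tss_strand for s in panel.sites],
        "gene_id": [f"gene_{s.site_id}" for s in panel.sites],
    }).to_csv(outdir / "tss.tsv", sep="\t", index=False)
    panel.telomeres.to_csv(outdir / "telomeres.bed", sep="\t", header=False, index=False)
    with open(outdir / "peaks.narrowPeak", "w") as fh, \
            open(outdir / "motifs.bed", "w") as mh:
        from .vplot import fragment_midpoints
        mids = fragment_midpoints(chip)
        for s in panel.sites:
            count = int((np.abs(mids - s.motif_center) <= 100).sum())
            fh.write(f"{s.chrom}\t{s.motif_center - 100}\t{s.motif_center + 101}\t"
                     f"{s.site_id}\t{count}\t.\t0\t-1\t-1\t100\n")
            mh.write(f"{s.chrom}\t{s.motif_center - 7}\t{s.motif_center + 8}\t"
                     f"consensus\t0\t{s.motif_strand}\n")
    _write_toy_genome(outdir / "genome.fa", panel, motif, seed)
    return {"outdir": str(outdir), "n_sites": len(panel), "n_fragments": len(chip),
            "n_reads": len(reads), "params": dataclasses.asdict(params)}


_IUPAC_PICK = {"A": "A", "C": "C", "G": "G", "T": "T", "R": "A", "Y": "C",
               "S": "G", "W": "A", "K": "G", "M": "A", "B": "C", "D": "G",
               "H": "A", "V": "C", "N": "A"}
_COMP = str.maketrans("ACGT", "TGCA")


def _write_toy_genome(path, panel: simulate.SitePanel, motif: str, seed: int) -> None:
    rng = np.random.default_rng(seed + 99)
    concrete = "".join(_IUPAC_PICK[c] for c in motif.upper())
    for chrom, size in panel.chrom_sizes.items():
        seq = rng.choice(list("ACGT"), size=size)
        for s in panel.sites:
            if s.chrom != chrom:
                continue
            planted = concrete if s.motif_strand == "+" else concrete.translate(_COMP)[::-1]
            start = s.motif_center - len(planted) // 2
            seq[start:start + len(planted)] = list(planted)
        with open(path, "w") as fh:
            fh.write(f">{chrom}\n")
            text = "".join(seq)
            for i in range(0, len(text), 80):
                fh.write(text[i:i + 80] + "\n")
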