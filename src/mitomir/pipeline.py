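"""End-to-end pipeline: simulate inputs, run every stage, write results.

``simulate`` writes a complete, self-consistent synthetic input bundle with
planted truth (spot tables for three hybridizations, mature/precursor
FASTA, an annotated circular genome carrying the planted seed sites, a
dual-channel image pair, the conservation table) and ``run_pipeline`` drives
the stages over it: enrichment classification, then — for the
mitochondria-enriched set — genome seed scanning, structure features with a
group comparison against the cytosol-enriched controls, and conservation
scoring; co-localization statistics run whenever an image pair is given.

All randomness flows from the single ``seed`` in the configuration; two
runs with the same configuration produce byte-identical result files.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from mitomir import __version__, io, synthetic
from mitomir.coloc import cross_correlation_function
from mitomir.enrichment import enrich_pipeline, heatmap_table
from mitomir.groupstats import compare_groups, score_conservation_table
from mitomir.structure import feature_table
from mitomir.synthetic import ArrayDesign, PlantedTruth
from mitomir.targeting import (
    AnnotationSet,
    GenomeSequence,
    MatureMiRNA,
    hits_to_frame,
    scan_panel,
)

__all__ = ["PipelineConfig", "PipelineError", "simulate", "run_pipeline"]

_RNA = np.array(list("ACGU"))


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class PipelineConfig:
    """Paths and parameters of one pipeline run; flags mirror the CLI."""

    scans: list[str] = field(default_factory=list)
    mature_fasta: str | None = None
    precursor_fasta: str | None = None
    genome_fasta: str | None = None
    annotation_gff3: str | None = None
    image_green: str | None = None
    image_red: str | None = None
    conservation_tsv: str | None = None
    cutoff: float = 1.5
    min_arrays: int | None = None
    classify_mode: str = "per-array"
    threshold_adjust: str = "none"
    seed_k: int = 7
    seed_start: int = 1
    strands: str = "both"
    composition_mode: str = "genome"
    max_dx: int = 20
    seed: int = 0
    outdir: str = "mitomir_results"

    def __post_init__(self) -> None:
        if not self.cutoff > 1:
            raise ValueError(f"cutoff must be > 1, got {self.cutoff}")
        if self.seed_k < 4:
            raise ValueError("seed length k must be >= 4")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _random_mirna(rng: np.random.Generator, length: int = 22) -> str:
    return "".join(rng.choice(_RNA, size=length))


def simulate(
    outdir,
    seed: int = 0,
    n_mito: int = 13,
    n_cyto: int = 44,
    n_arrays: int = 3,
    noise_cv: float = 0.1,
    genome_length: int = 16569,
    design: ArrayDesign | None = None,
) -> PipelineConfig:
    """Write a synthetic input bundle plus truth tables under ``outdir``.

    The defaults emulate the study conditions: the 6228-spot quadruplicate
    design hybridized three times, 13 probes planted mitochondria-enriched
    at folds drawn log-uniformly over [1.5, 56], 44 planted
    cytosol-enriched, spot noise CV 0.1, and a 16 569-nt circular genome
    carrying one planted seed site per mitochondrial miRNA.  Returns a
    ready-to-run :class:`PipelineConfig`.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    design = design or ArrayDesign.default()

    mirna_probes = [p for p in design.probe_ids if p not in design.calibrator_ids]
    chosen = rng.choice(len(mirna_probes), size=n_mito + n_cyto, replace=False)
    mito_ids = [mirna_probes[i] for i in chosen[:n_mito]]
    cyto_ids = [mirna_probes[i] for i in chosen[n_mito:]]

    folds: dict[str, float] = {}
    mito_folds = synthetic.sample_mito_folds(rng, n=n_mito)
    for pid, f in zip(mito_ids, mito_folds):
        folds[pid] = float(f)
    for pid, f in zip(cyto_ids, np.exp(rng.uniform(np.log(1.5), np.log(20.0), n_cyto))):
        folds[pid] = float(1.0 / f)

    truth = PlantedTruth(folds=folds, noise_cv=noise_cv, seed=int(rng.integers(2**31)))
    scans = synthetic.gen_array_scans(design, truth, n_arrays=n_arrays)
    scan_paths = []
    for i, scan in enumerate(scans, start=1):
        p = out / f"scan_{i}.tsv"
        io.write_spot_table(scan, p)
        scan_paths.append(str(p))
    pd.DataFrame(
        {"probe_id": list(folds), "true_fold": [folds[p] for p in folds]}
    ).to_csv(out / "truth_folds.csv", index=False)

    # sequences: one mature miRNA per planted probe; hairpin precursors.
    # Mature lengths mirror the observed asymmetry: canonical ~22-nt controls,
    # a broader 17-24-nt spread in the mitochondrial set.
    mature = {
        pid: _random_mirna(rng, length=int(rng.integers(17, 25)))
        for pid in mito_ids
    }
    mature.update(
        {pid: _random_mirna(rng, length=int(rng.integers(21, 24))) for pid in cyto_ids}
    )
    precursor = {
        pid: synthetic.gen_hairpin(
            stem_len=int(rng.integers(14, 19)),
            loop_len=int(rng.integers(8, 13)),
            gc_fraction=0.5,
            seed=int(rng.integers(2**31)),
        )
        for pid in mature
    }
    io.write_fasta(mature, out / "mature.fa")
    io.write_fasta(precursor, out / "precursor.fa")

    # genome with one planted seed site per mitochondrial miRNA
    planted = []
    spacing = genome_length // max(n_mito, 1)
    for i, pid in enumerate(mito_ids):
        strand = "+" if i % 2 == 0 else "-"
        planted.append((mature[pid][:7], i * spacing + 1, strand))
    genome, annotation, site_truth = synthetic.gen_genome_with_sites(
        length=genome_length, planted=planted, circular=True, n_genes=15,
        seed=int(rng.integers(2**31)),
    )
    io.write_fasta({genome.name: genome.seq}, out / "genome.fa")
    annotation.to_gff3(out / "genome.gff3", seqid=genome.name)
    site_truth.assign(mirna_id=mito_ids).to_csv(out / "truth_sites.csv", index=False)

    img_a, img_b = synthetic.gen_coloc_images(
        shape=(128, 128), coloc_fraction=1.0, shift=0, noise=0.02,
        seed=int(rng.integers(2**31)),
    )
    io.write_channel_image(img_a, out / "channel_green.png")
    io.write_channel_image(img_b, out / "channel_red.png")

    from mitomir.groupstats import load_bundled_conservation

    load_bundled_conservation().to_csv(out / "conservation.tsv", sep="\t", index=False)

    return PipelineConfig(
        scans=scan_paths,
        mature_fasta=str(out / "mature.fa"),
        precursor_fasta=str(out / "precursor.fa"),
        genome_fasta=str(out / "genome.fa"),
        annotation_gff3=str(out / "genome.gff3"),
        image_green=str(out / "channel_green.png"),
        image_red=str(out / "channel_red.png"),
        conservation_tsv=str(out / "conservation.tsv"),
        seed=seed,
        outdir=str(out / "results"),
    )


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage name
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc

        return wrapped

    return deco


def run_pipeline(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Run every configured stage; write CSVs and a run log to the output
    directory and return the result tables keyed by stage name.

    A stage failure aborts with the stage name and cause; outputs of earlier
    stages are retained on disk.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict[str, pd.DataFrame] = {}

    log = {
        "config": asdict(config),
        "versions": {
            "mitomir": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(out / "run_log.yaml", "w") as fh:
        yaml.safe_dump(log, fh, sort_keys=False)

    @_stage("enrichment")
    def run_enrichment() -> pd.DataFrame:
        scans = [io.read_spot_table(p) for p in config.scans]
        res = enrich_pipeline(
            scans,
            cutoff=config.cutoff,
            min_arrays=config.min_arrays,
            mode=config.classify_mode,
            adjust=config.threshold_adjust,
        )
        res.to_csv(out / "enrichment.csv")
        heat = heatmap_table(res, plot_path=str(out / "heatmap.png"))
        heat.to_csv(out / "log2_matrix.csv")
        return res

    enr = run_enrichment()
    results["enrichment"] = enr
    mito_ids = list(enr.index[enr["enrichment_class"] == "mito"])
    cyto_ids = list(enr.index[enr["enrichment_class"] == "cyto"])

    if config.genome_fasta and config.mature_fasta:

        @_stage("targeting")
        def run_targeting() -> pd.DataFrame:
            genome = GenomeSequence.from_fasta(config.genome_fasta)
            mature = io.read_fasta(config.mature_fasta)
            panel = [
                MatureMiRNA(mid, seq) for mid, seq in mature.items() if mid in mito_ids
            ]
            if not panel:
                warnings.warn("no mitochondria-enriched probe has a mature sequence")
                return pd.DataFrame()
            if config.annotation_gff3 and Path(config.annotation_gff3).exists():
                annotation = AnnotationSet.from_gff3(
                    config.annotation_gff3, genome_length=len(genome)
                )
            else:
                warnings.warn("no annotation file: hits will be labeled 'intergenic'")
                annotation = AnnotationSet([], genome_length=len(genome))
            reports, merged = scan_panel(
                panel, genome, annotation,
                k=config.seed_k, seed_start=config.seed_start,
                strands=config.strands, composition_mode=config.composition_mode,
            )
            merged.to_csv(out / "seed_scan.csv", index=False)
            all_hits = pd.concat(
                [hits_to_frame(r.hits).assign(mirna_id=mid) for mid, r in reports.items()],
                ignore_index=True,
            )
            all_hits.to_csv(out / "seed_hits.csv", index=False)
            return merged

        results["targeting"] = run_targeting()

    if config.mature_fasta and config.precursor_fasta:

        @_stage("features")
        def run_features() -> pd.DataFrame:
            mature = io.read_fasta(config.mature_fasta)
            precursor = io.read_fasta(config.precursor_fasta)
            groups = {mid: "mitomiR" for mid in mito_ids}
            groups.update({mid: "control" for mid in cyto_ids})
            keep = {mid: s for mid, s in precursor.items() if mid in groups}
            feats = feature_table(mature, keep, groups=groups)
            feats.to_csv(out / "features.csv", index=False)
            both = feats[feats["group"].isin(["mitomiR", "control"])]
            if both["group"].nunique() == 2 and both.groupby("group").size().min() >= 2:
                comp = compare_groups(
                    both, ["mature_length", "pre_length", "mfe", "amfe", "mfei"]
                )
                comp.to_csv(out / "group_comparison.csv", index=False)
                results["comparison"] = comp
            return feats

        results["features"] = run_features()

    if config.conservation_tsv:

        @_stage("conservation")
        def run_conservation() -> pd.DataFrame:
            table = pd.read_csv(config.conservation_tsv, sep="\t")
            scored = score_conservation_table(table)
            scored.to_csv(out / "conservation_scores.csv", index=False)
            return scored

        results["conservation"] = run_conservation()

    if config.image_green and config.image_red:

        @_stage("colocalization")
        def run_coloc() -> pd.DataFrame:
            a = io.read_channel_image(config.image_green)
            b = io.read_channel_image(config.image_red)
            res = cross_correlation_function(a, b, max_dx=config.max_dx)
            df = pd.DataFrame(
                [
                    {
                        "rp": res.rp,
                        "dx_peak": res.dx_peak,
                        "max_ccf": res.max_ccf,
                        "shape": res.shape,
                    }
                ]
            )
            df.to_csv(out / "colocalization.csv", index=False)
            pd.DataFrame({"dx": res.shifts, "ccf": res.ccf}).to_csv(
                out / "ccf_curve.csv", index=False
            )
            return df

        results["colocalization"] = run_coloc()

    return results
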