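"""Synthetic inputs with planted ground truth for every pipeline stage.

The generators emulate the statistical structure of the study design the
pipeline was built for: a dual-channel miRNA microarray of 1460 miRNA probes
plus 97 controls spotted in quadruplicate (6228 spots), with 18 spike-in
calibrator oligos; dual-channel fluorescence micrographs of punctate
staining; a circular mitochondrial-genome-sized sequence with planted miRNA
seed sites; and hairpin RNAs of controlled stem/loop geometry.

Spot intensity model
--------------------
Foreground = background + abundance x fold x dye_bias x lognormal(noise_cv),
with the additive background drawn per spot and reported exactly in the
background column.  This reproduces the ratio-scale behavior of two-color
arrays (lognormal multiplicative noise, calibrators at true fold 1 absorbing
the dye bias) without claiming the scanner's physics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ArrayDesign",
    "PlantedTruth",
    "gen_array_scans",
    "gen_coloc_images",
    "gen_genome_with_sites",
    "gen_hairpin",
    "SPOT_COLUMNS",
]

#: canonical column order of a spot-level table
SPOT_COLUMNS = [
    "probe_id",
    "spot_index",
    "hy5_signal",
    "hy5_background",
    "hy3_signal",
    "hy3_background",
    "is_calibrator",
]

_DNA_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp_dna(seq: str) -> str:
    return seq.translate(_DNA_COMPLEMENT)[::-1]


def _rna_to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


@dataclass(frozen=True)
class ArrayDesign:
    """Layout of one hybridization array.

    ``calibrator_ids`` must be a subset of ``probe_ids``; calibrators are
    spike-in oligos present at equal amounts in both channels (true fold 1).
    """

    probe_ids: tuple[str, ...]
    calibrator_ids: frozenset[str]
    n_replicate_spots: int = 4

    def __post_init__(self) -> None:
        if self.n_replicate_spots < 1:
            raise ValueError("n_replicate_spots must be >= 1")
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise ValueError("probe_ids must be unique")
        missing = set(self.calibrator_ids) - set(self.probe_ids)
        if missing:
            raise ValueError(f"calibrator_ids not in probe_ids: {sorted(missing)}")

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_spots(self) -> int:
        return self.n_probes * self.n_replicate_spots

    @classmethod
    def default(cls) -> "ArrayDesign":
        """The 1460 miRNA + 97 control probe design, quadruplicate spots.

        18 of the control probes are the spike-in calibrators, giving
        (1460 + 97) x 4 = 6228 spots per array.
        """
        mirna = tuple(f"miR-{i:04d}" for i in range(1, 1461))
        ctrl = tuple(f"ctrl-{i:02d}" for i in range(1, 98))
        cal = frozenset(f"ctrl-{i:02d}" for i in range(1, 19))
        return cls(probe_ids=mirna + ctrl, calibrator_ids=cal, n_replicate_spots=4)


@dataclass
class PlantedTruth:
    """Ground-truth parameters for :func:`gen_array_scans`.

    ``folds`` maps probe id -> true mitochondrial/cytosolic abundance ratio;
    probes absent from the map have fold 1.  Calibrator probes always have
    fold 1 regardless of the map.  ``dye_bias`` multiplies every Hy5 signal
    (labelling/scanner asymmetry absorbed by calibrator normalization).
    """

    folds: dict[str, float] = field(default_factory=dict)
    dye_bias: float = 1.3
    abundance_median: float = 5000.0
    abundance_log_sd: float = 0.5
    background_mean: float = 200.0
    background_sd: float = 40.0
    noise_cv: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for probe, fold in self.folds.items():
            if not fold > 0:
                raise ValueError(f"true fold for {probe!r} must be > 0, got {fold}")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.dye_bias <= 0:
            raise ValueError("dye_bias must be > 0")


def _lognormal_unit_mean(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with mean 1 and coefficient of variation ``cv``."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def gen_array_scans(
    design: ArrayDesign, truth: PlantedTruth, n_arrays: int = 3
) -> list[pd.DataFrame]:
    """Generate ``n_arrays`` spot-level scans as data frames.

    Each scan has ``design.n_replicate_spots`` rows per probe with the
    columns of :data:`SPOT_COLUMNS`.  Probe abundances are drawn once per
    probe (shared across arrays, as for one biological sample hybridized
    several times); backgrounds and multiplicative noise are per spot and
    per array.  Equal seeds yield byte-identical output.
    """
    if n_arrays < 1:
        raise ValueError("n_arrays must be >= 1")
    rng = np.random.default_rng(truth.seed)

    probes = np.asarray(design.probe_ids, dtype=object)
    is_cal = np.isin(probes, list(design.calibrator_ids))
    folds = np.array([truth.folds.get(p, 1.0) for p in probes])
    folds[is_cal] = 1.0  # calibrators are spiked equally into both channels

    abundance = truth.abundance_median * np.exp(
        rng.normal(0.0, truth.abundance_log_sd, size=len(probes))
    )
    hy3_true = abundance
    hy5_true = abundance * folds * truth.dye_bias

    n_rep = design.n_replicate_spots
    probe_col = np.repeat(probes, n_rep)
    cal_col = np.repeat(is_cal, n_rep)
    spot_idx = np.tile(np.arange(1, n_rep + 1), len(probes))
    hy5_rep = np.repeat(hy5_true, n_rep)
    hy3_rep = np.repeat(hy3_true, n_rep)

    scans: list[pd.DataFrame] = []
    for _ in range(n_arrays):
        n = len(probe_col)
        bg5 = np.clip(rng.normal(truth.background_mean, truth.background_sd, n), 0, None)
        bg3 = np.clip(rng.normal(truth.background_mean, truth.background_sd, n), 0, None)
        noise5 = _lognormal_unit_mean(rng, truth.noise_cv, n)
        noise3 = _lognormal_unit_mean(rng, truth.noise_cv, n)
        scan = pd.DataFrame(
            {
                "probe_id": probe_col,
                "spot_index": spot_idx,
                "hy5_signal": bg5 + hy5_rep * noise5,
                "hy5_background": bg5,
                "hy3_signal": bg3 + hy3_rep * noise3,
                "hy3_background": bg3,
                "is_calibrator": cal_col,
            }
        )
        scans.append(scan)
    return scans


def sample_mito_folds(
    rng: np.random.Generator, n: int = 13, low: float = 1.5, high: float = 56.0
) -> np.ndarray:
    """Draw planted mitochondrial enrichment folds, log-uniform on [low, high].

    The defaults span the observed range of mitochondrial enrichment of the
    13-miRNA signature (1.5- to 56-fold).
    """
    if not (0 < low <= high):
        raise ValueError("need 0 < low <= high")
    return np.exp(rng.uniform(np.log(low), np.log(high), size=n))


def gen_coloc_images(
    shape: tuple[int, int] = (128, 128),
    coloc_fraction: float = 1.0,
    shift: int = 0,
    noise: float = 0.0,
    n_spots: int = 40,
    spot_sigma: float = 2.0,
    exclusive: bool = False,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Generate a dual-channel image pair of Gaussian blobs on a dark background.

    ``coloc_fraction`` of the blobs are placed at identical coordinates in
    both channels; the remainder are placed independently, or — with
    ``exclusive=True`` — the second channel's blobs are kept away from the
    first channel's (mutually exclusive staining, the "hollow"-CCF case).
    The second channel is then translated horizontally by ``shift`` pixels.
    Returns two float arrays scaled to a 16-bit range.
    """
    if not 0.0 <= coloc_fraction <= 1.0:
        raise ValueError("coloc_fraction must be in [0, 1]")
    h, w = shape
    if abs(shift) >= w:
        raise ValueError(f"shift {shift} exceeds image width {w}")
    if noise < 0:
        raise ValueError("noise must be >= 0")
    rng = np.random.default_rng(seed)

    margin = int(3 * spot_sigma) + abs(shift) + 1
    if 2 * margin >= min(h, w):
        raise ValueError("image too small for the requested blobs/shift")

    def draw(centers: np.ndarray) -> np.ndarray:
        yy, xx = np.mgrid[0:h, 0:w]
        img = np.zeros((h, w))
        for cy, cx in centers:
            img += np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * spot_sigma**2))
        return img

    def sample_centers(k: int) -> np.ndarray:
        cy = rng.uniform(margin, h - margin, size=k)
        cx = rng.uniform(margin, w - margin, size=k)
        return np.column_stack([cy, cx])

    n_shared = int(round(coloc_fraction * n_spots))
    shared = sample_centers(n_shared)
    own_a = sample_centers(n_spots - n_shared)
    centers_a = np.vstack([shared, own_a])

    if exclusive:
        own_b = []
        min_d = 4 * spot_sigma  # adjacent but non-overlapping puncta
        while len(own_b) < n_spots - n_shared:
            cand = sample_centers(1)[0]
            if np.all(np.hypot(*(centers_a - cand).T) >= min_d):
                own_b.append(cand)
        own_b = np.asarray(own_b).reshape(-1, 2)
    else:
        own_b = sample_centers(n_spots - n_shared)
    centers_b = np.vstack([shared, own_b]) if n_shared else own_b
    centers_b = centers_b + np.array([0.0, float(shift)])

    img_a = draw(centers_a)
    img_b = draw(centers_b)
    if noise > 0:
        img_a = np.clip(img_a + rng.normal(0, noise, (h, w)), 0, None)
        img_b = np.clip(img_b + rng.normal(0, noise, (h, w)), 0, None)
    scale = 60000.0 / max(img_a.max(), img_b.max(), 1e-12)
    return img_a * scale, img_b * scale


def gen_genome_with_sites(
    length: int = 16569,
    planted: list[tuple[str, int, str]] | None = None,
    circular: bool = True,
    base_probs: tuple[float, float, float, float] | None = None,
    features: list[tuple[str, str, int, int, str]] | None = None,
    n_genes: int = 0,
    seed: int = 0,
) -> tuple["object", "object", pd.DataFrame]:
    """Generate a random genome with planted miRNA seed target sites.

    ``planted`` is a list of ``(seed_rna, position, strand)``; for each entry
    the genome is edited so that the ``strand`` strand carries the reverse
    complement of the seed starting at 1-based forward position ``position``
    (i.e. a genuine target site for that seed).  Returns
    ``(GenomeSequence, AnnotationSet, truth_table)`` where the truth table
    lists all planted coordinates.  Overlapping planted sites trigger a
    warning; the truth table stays exact.
    """
    from mitomir.targeting import AnnotationSet, GenomeSequence

    planted = planted or []
    rng = np.random.default_rng(seed)
    probs = np.asarray(base_probs if base_probs is not None else (0.25,) * 4)
    probs = probs / probs.sum()
    genome = rng.choice(np.array(list("ACGT")), size=length, p=probs)

    occupied: set[int] = set()
    rows = []
    for seed_rna, pos, strand in planted:
        k = len(seed_rna)
        if not 1 <= pos <= length:
            raise ValueError(f"planted position {pos} outside [1, {length}]")
        if strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {strand!r}")
        seed_dna = _rna_to_dna(seed_rna)
        # '+' site: forward k-mer equals revcomp(seed); '-' site: forward
        # k-mer equals the seed itself (so the minus strand reads revcomp).
        insert = _revcomp_dna(seed_dna) if strand == "+" else seed_dna
        idx = [(pos - 1 + off) % length for off in range(k)]
        if not circular and pos + k - 1 > length:
            raise ValueError("planted site runs off the end of a linear genome")
        if occupied.intersection(idx):
            warnings.warn(f"planted sites overlap at position {pos}", stacklevel=2)
        occupied.update(idx)
        for off, base in zip(idx, insert):
            genome[off] = base
        end = (pos + k - 2) % length + 1
        rows.append(
            {"seed": seed_rna, "position": pos, "end": end, "strand": strand, "k": k}
        )

    seq = "".join(genome)
    truth = pd.DataFrame(rows, columns=["seed", "position", "end", "strand", "k"])

    if features is None and n_genes > 0:
        step = length // n_genes
        features = [
            (f"GENE{i + 1:02d}", "gene", i * step + 1, i * step + int(step * 0.8), "+")
            for i in range(n_genes)
        ]
    annotation = AnnotationSet(features or [], genome_length=length)
    gs = GenomeSequence(name="synthetic", seq=seq, circular=circular)
    return gs, annotation, truth


def gen_hairpin(
    stem_len: int,
    loop_len: int = 4,
    gc_fraction: float = 1.0,
    seed: int | None = None,
) -> str:
    """A hairpin RNA of ``2*stem_len + loop_len`` nt whose optimal nested
    structure contains a stem of ``stem_len`` base pairs.

    The loop is all-A (unable to pair with the stem-proximal bases when
    ``gc_fraction`` is high); the left stem arm mixes G (with prob.
    ``gc_fraction``) and U, and the right arm is its reverse complement.
    """
    if stem_len < 0:
        raise ValueError("stem_len must be >= 0")
    if loop_len < 3:
        raise ValueError("loop_len must be >= 3 (minimum hairpin loop)")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError("gc_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    pairs = [("G", "C") if rng.random() < gc_fraction else ("U", "A") for _ in range(stem_len)]
    left = "".join(p[0] for p in pairs)
    right = "".join(p[1] for p in reversed(pairs))
    return left + "A" * loop_len + right
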