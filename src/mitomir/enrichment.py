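"""Two-channel spot normalization and mitochondrial-enrichment classification.

The chain mirrors standard dual-color miRNA array practice: per-spot net
intensities (foreground minus local background), a detection filter at the
50th percentile of the background intensities, per-spot Hy5/Hy3 ratios,
normalization by the median ratio of the spike-in calibrators, the mean of
the replicate spots per probe, and finally a fold-cutoff classification into
mitochondria-enriched (``mito``), cytosol-enriched (``cyto``), ``unchanged``
or ``filtered``.

Hy5 labels the mitochondrial RNA fraction, Hy3 the cytosolic fraction of the
same cells, so the normalized Hy5/Hy3 ratio directly measures mitochondrial
enrichment of each miRNA.

A scan is a :class:`pandas.DataFrame` with the columns of
:data:`mitomir.synthetic.SPOT_COLUMNS` (an optional boolean ``excluded``
column flags irregular spots removed during image QC).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "net_intensity",
    "background_threshold",
    "filter_spots",
    "spot_ratio",
    "calibrator_normalize",
    "probe_mean_ratio",
    "process_scan",
    "classify_enrichment",
    "heatmap_table",
    "enrich_pipeline",
]

CHANNELS = ("hy5", "hy3")


def _check_channel(channel: str) -> str:
    channel = channel.lower()
    if channel not in CHANNELS:
        raise ValueError(f"channel must be one of {CHANNELS}, got {channel!r}")
    return channel


def net_intensity(scan: pd.DataFrame, channel: str) -> pd.Series:
    """Net signal = spot foreground minus local background (may be negative)."""
    channel = _check_channel(channel)
    return scan[f"{channel}_signal"] - scan[f"{channel}_background"]


def background_threshold(
    scan: pd.DataFrame, channel: str, adjust: str = "none"
) -> float:
    """Detection threshold: 50th percentile (median) of the channel's
    background intensities over all spots of the scan.

    The median uses the mean-of-middle-two convention for even counts.
    ``adjust="calibrator"`` scales the threshold by the ratio of the
    channel's median calibrator net intensity to the geometric mean of the
    two channels' median calibrator nets (a channel that detects the equal
    calibrator spikes more brightly gets a proportionally higher threshold).
    """
    channel = _check_channel(channel)
    if len(scan) == 0:
        raise ValueError("cannot compute a background threshold on an empty scan")
    thr = float(np.median(scan[f"{channel}_background"].to_numpy()))
    if adjust == "none":
        return thr
    if adjust != "calibrator":
        raise ValueError(f"adjust must be 'none' or 'calibrator', got {adjust!r}")
    cal = scan[scan["is_calibrator"].astype(bool)]
    if len(cal) == 0:
        raise ValueError("calibrator threshold adjustment needs calibrator spots")
    med = {c: float(np.median(net_intensity(cal, c).to_numpy())) for c in CHANNELS}
    if min(med.values()) <= 0:
        raise ValueError("non-positive median calibrator net intensity")
    geo = float(np.sqrt(med["hy5"] * med["hy3"]))
    return thr * med[channel] / geo


def filter_spots(scan: pd.DataFrame, adjust: str = "none") -> pd.Series:
    """Boolean mask of spots kept for ratio computation.

    A spot is kept iff its net intensity is >= the background threshold in
    BOTH channels (and it is not flagged ``excluded``).  Negative nets always
    fail since the thresholds are nonnegative.
    """
    thr5 = background_threshold(scan, "hy5", adjust=adjust)
    thr3 = background_threshold(scan, "hy3", adjust=adjust)
    kept = (net_intensity(scan, "hy5") >= thr5) & (net_intensity(scan, "hy3") >= thr3)
    if "excluded" in scan.columns:
        kept &= ~scan["excluded"].astype(bool)
    return kept


def spot_ratio(scan: pd.DataFrame) -> pd.Series:
    """Per-spot Hy5/Hy3 ratio of net intensities (NaN where Hy3 net <= 0)."""
    net5 = net_intensity(scan, "hy5")
    net3 = net_intensity(scan, "hy3")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = net5 / net3
    return ratio.where(net3 > 0)


def calibrator_normalize(ratios: pd.Series, is_calibrator: pd.Series) -> pd.Series:
    """Divide every ratio by the median ratio of the calibrator spots.

    Calibrators are spiked equally into both channels, so their median ratio
    estimates the channel dye bias; after normalization the calibrator median
    is 1.  Raises if no calibrator spot survived the filter (use raw ratios
    then, at your own risk).
    """
    cal = ratios[is_calibrator.astype(bool)].dropna()
    if len(cal) == 0:
        raise ValueError(
            "no calibrator spots passed the filter; cannot normalize "
            "(rerun with raw ratios if you must)"
        )
    return ratios / float(np.median(cal.to_numpy()))


def probe_mean_ratio(ratios: pd.Series, probe_ids: pd.Series) -> pd.Series:
    """Arithmetic mean of the kept replicate-spot ratios per probe."""
    return ratios.groupby(probe_ids.to_numpy()).mean()


def process_scan(scan: pd.DataFrame, adjust: str = "none") -> pd.DataFrame:
    """One scan -> per-probe normalized mean ratios.

    Returns a frame indexed by probe id with ``mean_ratio`` (NaN when no
    spot of the probe passed the filter) and ``n_spots_kept``.
    """
    kept = filter_spots(scan, adjust=adjust)
    ratios = spot_ratio(scan).where(kept)
    norm = calibrator_normalize(ratios, scan["is_calibrator"])
    mean = probe_mean_ratio(norm, scan["probe_id"])
    n_kept = norm.notna().groupby(scan["probe_id"].to_numpy()).sum()
    out = pd.DataFrame({"mean_ratio": mean, "n_spots_kept": n_kept})
    out.index.name = "probe_id"
    return out


def per_array_ratios(scans: list[pd.DataFrame], adjust: str = "none") -> pd.DataFrame:
    """Probe x array matrix of normalized mean Hy5/Hy3 ratios."""
    cols = {
        f"array_{i + 1}": process_scan(scan, adjust=adjust)["mean_ratio"]
        for i, scan in enumerate(scans)
    }
    return pd.DataFrame(cols)


@dataclass(frozen=True)
class ClassificationRule:
    """Fold cutoff and reproducibility rule for the enrichment call."""

    cutoff: float = 1.5
    min_arrays: int | None = None  # None -> probe must pass in every array
    mode: str = "per-array"  # or "mean"

    def __post_init__(self) -> None:
        if not self.cutoff > 1:
            raise ValueError(f"cutoff must be > 1, got {self.cutoff}")
        if self.mode not in {"per-array", "mean"}:
            raise ValueError("mode must be 'per-array' or 'mean'")
        if self.min_arrays is not None and self.min_arrays < 1:
            raise ValueError("min_arrays must be >= 1")


def classify_enrichment(
    ratio_matrix: pd.DataFrame,
    cutoff: float = 1.5,
    min_arrays: int | None = None,
    mode: str = "per-array",
) -> pd.DataFrame:
    """Classify each probe from its per-array normalized mean ratios.

    Under the default ``per-array`` rule a probe is ``mito`` iff its ratio is
    >= ``cutoff`` in every array where it passed the filters (reproducible
    enrichment), ``cyto`` iff the reciprocal ratio is >= ``cutoff`` in every
    passing array, otherwise ``unchanged``.  Probes passing in fewer than
    ``min_arrays`` arrays (default: all provided arrays) are ``filtered``.
    ``mode="mean"`` applies the cutoff to the cross-array mean instead.

    Returns a frame indexed by probe with the per-array ratios, the
    cross-array ``mean_ratio``, ``log2_ratio``, ``enrichment_class`` and the
    ``fold`` of enrichment (max(r, 1/r) of the cross-array mean, >= 1).
    """
    rule = ClassificationRule(cutoff=cutoff, min_arrays=min_arrays, mode=mode)
    need = rule.min_arrays if rule.min_arrays is not None else ratio_matrix.shape[1]

    vals = ratio_matrix.to_numpy(dtype=float)
    n_pass = np.sum(~np.isnan(vals), axis=1)
    sums = np.nansum(vals, axis=1)
    mean_ratio = np.divide(
        sums, n_pass, out=np.full(len(sums), np.nan), where=n_pass > 0
    )

    if rule.mode == "per-array":
        all_hi = np.all(np.isnan(vals) | (vals >= rule.cutoff), axis=1)
        all_lo = np.all(np.isnan(vals) | (vals <= 1.0 / rule.cutoff), axis=1)
    else:
        all_hi = mean_ratio >= rule.cutoff
        all_lo = mean_ratio <= 1.0 / rule.cutoff

    cls = np.where(
        n_pass < need,
        "filtered",
        np.where(all_hi & (n_pass > 0), "mito", np.where(all_lo & (n_pass > 0), "cyto", "unchanged")),
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        fold = np.where(mean_ratio >= 1, mean_ratio, 1.0 / mean_ratio)
        log2r = np.log2(mean_ratio)
    out = ratio_matrix.copy()
    out["mean_ratio"] = mean_ratio
    out["log2_ratio"] = log2r
    out["enrichment_class"] = cls
    out["fold"] = fold
    out.index.name = "probe_id"
    return out


def heatmap_table(
    results: pd.DataFrame, plot_path: str | None = None
) -> pd.DataFrame:
    """Log2-ratio matrix of the differentially expressed probes.

    Rows are the probes classified ``mito`` or ``cyto``, ordered by class
    (mito first) then by decreasing fold; columns are the per-array log2
    normalized Hy5/Hy3 ratios.  With ``plot_path`` a green-to-red scaled
    heatmap PNG is written.
    """
    if len(results) == 0:
        raise ValueError("no classified probes")
    diff = results[results["enrichment_class"].isin(["mito", "cyto"])].copy()
    diff = diff.sort_values(
        ["enrichment_class", "fold"], ascending=[True, False], kind="stable",
        key=lambda s: s if s.name == "fold" else s.map({"mito": 0, "cyto": 1}),
    )
    array_cols = [c for c in results.columns if c.startswith("array_")]
    mat = np.log2(diff[array_cols])
    table = mat.copy()
    table["enrichment_class"] = diff["enrichment_class"]
    table["fold"] = diff["fold"]
    if plot_path is not None and len(mat) > 0:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4, max(2, 0.12 * len(mat))))
        lim = np.nanmax(np.abs(mat.to_numpy())) or 1.0
        im = ax.imshow(mat.to_numpy(), aspect="auto", cmap="RdYlGn_r", vmin=-lim, vmax=lim)
        ax.set_xticks(range(len(array_cols)), array_cols)
        ax.set_yticks([])
        ax.set_ylabel(f"{len(mat)} differentially localized probes")
        fig.colorbar(im, ax=ax, label="log2 Hy5/Hy3")
        fig.tight_layout()
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
    return table


def enrich_pipeline(
    scans: list[pd.DataFrame],
    cutoff: float = 1.5,
    min_arrays: int | None = None,
    mode: str = "per-array",
    adjust: str = "none",
) -> pd.DataFrame:
    """Full chain: filter, ratio, normalize, average, classify, for a set of
    replicate scans of the same sample pair."""
    matrix = per_array_ratios(scans, adjust=adjust)
    return classify_enrichment(matrix, cutoff=cutoff, min_arrays=min_arrays, mode=mode)
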