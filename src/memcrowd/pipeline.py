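"""Configuration-driven orchestration of the full analysis.

``run_analysis`` drives the whole measurement chain over a manifest of
two-channel images: maxima detection, linescan sizing, density, ROI
intensity statistics (mean, rSDM), colocalization (PCC plus its flipped
control), and distance statistics with a matched CSR reference.  Outputs are
plain CSV/JSON tables plus a provenance record (config hash, seed, package
version), and identical config + seed produce identical outputs.

``condition_compare`` summarizes one metric across two result bundles the
way condition panels are usually reported: per-condition means, percent of
control (control mean set to 100%), and a two-tailed t-test.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy import stats as sstats

from . import __version__
from .imaging import (
    Image2D,
    RegionOfInterest,
    ZeroVarianceError,
    pcc,
    pcc_flipped_control,
    roi_mean_intensity,
)
from .maxima import find_maxima, maxima_density, maxima_size
from .points import PointPattern
from .spatial import DEFAULT_BIN_WIDTH_NM, csr_reference, nn_distances, nn_histogram, pair_distribution

logger = logging.getLogger("memcrowd")


@dataclass
class ImageEntry:
    """One manifest entry: paths and roles of a two-channel acquisition."""

    image_id: str
    path_a: str
    path_b: str | None = None
    channel_a: str = "a"
    channel_b: str = "b"
    roi_path: str | None = None
    background_a: float = 0.0
    background_b: float = 0.0
    experiment_id: str | None = None


@dataclass
class RunConfig:
    """All analysis parameters with their standard defaults.

    Defaults follow the established recipe: 25 nm pixels, detection
    pre-smoothing sigma 0.5 px on the noisy (crowd) channel only, 31 x 3
    linescans with the R^2 >= 0.8 and middle-third QC rules, 25 nm distance
    bins, minus-sampling margin equal to the largest analyzed distance, and
    a seeded Monte-Carlo CSR reference.
    """

    images: list[ImageEntry] = field(default_factory=list)
    pixel_size_nm: float = 25.0
    presmooth_sigma_a_px: float = 0.0
    presmooth_sigma_b_px: float = 0.5
    prominence: float | None = None
    linescan_length_px: int = 31
    linescan_width_px: int = 3
    bin_width_nm: float = DEFAULT_BIN_WIDTH_NM
    max_distance_nm: float = 500.0
    margin_nm: float | None = None
    csr_replicates: int = 50
    seed: int = 0
    output_dir: str = "results/run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        images = [ImageEntry(**e) for e in raw.pop("images", [])]
        return cls(images=images, **raw)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def load_image(path: str | Path, pixel_size_nm: float, channel: str = "") -> Image2D:
    """Read a single-channel grayscale TIFF as an Image2D."""
    return Image2D(tifffile.imread(str(path)).astype(float), pixel_size_nm, channel)


def save_image(image: Image2D, path: str | Path) -> None:
    tifffile.imwrite(str(path), image.pixels.astype(np.float32))


def load_roi(path: str | Path, pixel_size_nm: float) -> RegionOfInterest:
    """Read an ROI mask from a binary TIFF/PNG image."""
    import imageio.v3 as iio

    mask = np.asarray(iio.imread(str(path))) > 0
    if mask.ndim == 3:
        mask = mask[..., 0]
    return RegionOfInterest(mask, pixel_size_nm)


def _analyze_channel(
    image: Image2D,
    roi: RegionOfInterest,
    cfg: RunConfig,
    presmooth: float,
    background: float,
) -> tuple[PointPattern, dict]:
    pattern = find_maxima(image, roi, prominence=cfg.prominence, presmooth_sigma_px=presmooth)
    mean_size, table = maxima_size(image, pattern, cfg.linescan_length_px, cfg.linescan_width_px)
    stats = roi_mean_intensity(image, roi, background)
    row = {
        "count": len(pattern),
        "density_per_um2": maxima_density(pattern, roi),
        "mean_size_nm": mean_size,
        "n_sized": int(table["qc_pass"].sum()) if len(table) else 0,
        "mean_intensity": stats.mean,
        "rsdm": stats.rsdm,
    }
    return pattern, row | {"_table": table}


def run_analysis(config: RunConfig) -> dict:
    """Run the full pipeline over a manifest; returns the result bundle.

    The bundle maps ``summary`` to a per-image/channel DataFrame, ``maxima``
    to the concatenated per-maximum table, ``histograms`` to the distance
    statistics (with CSR envelopes), and ``provenance`` to the reproducibility
    record.  Results are also written under ``config.output_dir``.  Failures
    of individual images are logged and skipped, not fatal.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    edges = np.arange(0.0, config.max_distance_nm + config.bin_width_nm, config.bin_width_nm)
    margin = config.margin_nm if config.margin_nm is not None else float(edges[-1])

    summary_rows: list[dict] = []
    maxima_tables: list[pd.DataFrame] = []
    hist_rows: list[dict] = []
    n_failed = 0
    for entry in config.images:
        try:
            img_a = load_image(entry.path_a, config.pixel_size_nm, entry.channel_a)
            roi = (
                load_roi(entry.roi_path, config.pixel_size_nm)
                if entry.roi_path
                else RegionOfInterest.full(img_a)
            )
            pat_a, row_a = _analyze_channel(
                img_a, roi, config, config.presmooth_sigma_a_px, entry.background_a
            )
            channels = {entry.channel_a: (img_a, pat_a, row_a)}
            if entry.path_b:
                img_b = load_image(entry.path_b, config.pixel_size_nm, entry.channel_b)
                pat_b, row_b = _analyze_channel(
                    img_b, roi, config, config.presmooth_sigma_b_px, entry.background_b
                )
                channels[entry.channel_b] = (img_b, pat_b, row_b)
                try:
                    cc = pcc(img_a, img_b, roi)
                    cc_flip = pcc_flipped_control(img_a, img_b, roi)
                except ZeroVarianceError:
                    cc = cc_flip = float("nan")
            for name, (img, pat, row) in channels.items():
                table = row.pop("_table")
                table.insert(0, "channel", name)
                table.insert(0, "image_id", entry.image_id)
                maxima_tables.append(table)
                srow = {"image_id": entry.image_id, "channel": name, **row}
                if entry.path_b:
                    srow["pcc"] = cc
                    srow["pcc_flipped"] = cc_flip
                if entry.experiment_id is not None:
                    srow["experiment_id"] = entry.experiment_id
                summary_rows.append(srow)

            # distance statistics per channel (same-type) and cross-type
            todo: list[tuple[str, PointPattern, PointPattern | None]] = [
                (f"{name}_self", pat, None) for name, (_, pat, _) in channels.items()
            ]
            if entry.path_b and len(pat_a) and len(pat_b):
                todo.append((f"{entry.channel_a}_vs_{entry.channel_b}", pat_a, pat_b))
            for label, ref, tgt in todo:
                if len(ref) < 2:
                    continue
                nn = nn_histogram(ref, tgt, edges, margin)
                g = pair_distribution(ref, tgt, edges, margin)
                env = csr_reference(
                    ref, config.csr_replicates, config.seed, edges, margin
                )
                for i in range(len(edges) - 1):
                    hist_rows.append(
                        {
                            "image_id": entry.image_id,
                            "pair": label,
                            "lo_nm": edges[i],
                            "hi_nm": edges[i + 1],
                            "nn_count": nn.counts[i],
                            "nn_density": nn.density[i],
                            "g": g.counts[i],
                            "csr_nn_mean": env.nn_mean[i],
                            "csr_nn_lo": env.nn_lo[i],
                            "csr_nn_hi": env.nn_hi[i],
                            "csr_g_mean": env.g_mean[i],
                            "csr_g_lo": env.g_lo[i],
                            "csr_g_hi": env.g_hi[i],
                        }
                    )
            logger.info("analyzed %s", entry.image_id)
        except FileNotFoundError as err:
            n_failed += 1
            logger.error("skipping %s: %s", entry.image_id, err)

    summary = pd.DataFrame(summary_rows)
    maxima = pd.concat(maxima_tables, ignore_index=True) if maxima_tables else pd.DataFrame()
    hists = pd.DataFrame(hist_rows)
    provenance = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "n_images": len(config.images),
        "n_failed": n_failed,
    }
    summary.to_csv(out / "summary.csv", index=False)
    maxima.to_csv(out / "maxima.csv", index=False)
    hists.to_csv(out / "histograms.csv", index=False)
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    return {"summary": summary, "maxima": maxima, "histograms": hists, "provenance": provenance}


def condition_compare(
    control: dict | pd.DataFrame,
    treated: dict | pd.DataFrame,
    metric: str,
    channel: str | None = None,
) -> dict:
    """Compare one summary metric between two result bundles.

    Returns per-condition means, the treated value as percent of the control
    mean (control = 100%), and a two-tailed t-test.  The test is paired when
    both bundles carry matching ``experiment_id`` columns, unpaired (Welch)
    otherwise.
    """

    def _series(bundle) -> pd.Series:
        df = bundle["summary"] if isinstance(bundle, dict) else bundle
        if metric not in df.columns:
            raise KeyError(f"metric {metric!r} not present in bundle")
        if channel is not None:
            df = df[df["channel"] == channel]
        return df.set_index(
            df["experiment_id"] if "experiment_id" in df.columns else df.index
        )[metric].dropna()

    a, b = _series(control), _series(treated)
    paired = (
        "experiment_id" in (control["summary"] if isinstance(control, dict) else control).columns
        and a.index.equals(b.index)
        and len(a) == len(b)
    )
    if paired:
        t, p = sstats.ttest_rel(a.values, b.values)
    else:
        t, p = sstats.ttest_ind(a.values, b.values, equal_var=False)
    return {
        "metric": metric,
        "control_mean": float(a.mean()),
        "treated_mean": float(b.mean()),
        "control_pct": 100.0,
        "treated_pct": 100.0 * float(b.mean()) / float(a.mean()),
        "t": float(t),
        "p": float(p),
        "paired": bool(paired),
        "n_control": int(len(a)),
        "n_treated": int(len(b)),
    }
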