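"""Image and table I/O plus report assembly.

Slab images travel as 8-bit grayscale TIFF (lossless) or PNG with a YAML
sidecar recording the acquisition setting, so a written image round-trips
to the identical `EnFaceImage`.  All tables are UTF-8 CSV with a header
row and "." decimals.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .optics import AcquisitionSetting
from .render import EnFaceImage, SLABS

__all__ = ["read_image", "write_image", "write_report", "sidecar_path"]


def sidecar_path(path) -> Path:
    return Path(path).with_suffix(".yaml")


def write_image(img: EnFaceImage, path, write_sidecar: bool = True) -> Path:
    """Write an en-face image as 8-bit grayscale TIFF/PNG plus YAML sidecar."""
    path = Path(path)
    data = np.round(np.clip(img.pixels, 0.0, 1.0) * 255.0).astype(np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile
        tifffile.imwrite(path, data)
    elif path.suffix.lower() == ".png":
        import imageio.v3 as iio
        iio.imwrite(path, data)
    else:
        raise ValueError(f"unsupported image format {path.suffix!r}")
    if write_sidecar:
        meta = {
            "slab": img.slab,
            "pixel_pitch_um": float(img.pixel_pitch_um),
            "acquisition": dataclasses.asdict(img.acquisition),
        }
        sidecar_path(path).write_text(yaml.safe_dump(meta, sort_keys=True))
    return path


def read_image(path, pixel_pitch_um: Optional[float] = None,
               slab: Optional[str] = None) -> EnFaceImage:
    """Read an 8/16-bit grayscale TIFF or PNG as an EnFaceImage.

    Intensities are normalised to [0, 1] by the maximum representable
    value of the stored bit depth.  The pixel pitch and slab label come
    from the YAML sidecar when present, else from the arguments.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile
        data = tifffile.imread(path)
    elif path.suffix.lower() == ".png":
        import imageio.v3 as iio
        data = iio.imread(path)
    else:
        raise ValueError(f"unsupported image format {path.suffix!r}")
    if data.ndim != 2:
        raise ValueError(
            f"{path.name} has {data.ndim} dimensions; convert multi-channel "
            "(RGB/RGBA) images to single-channel grayscale first")
    if data.dtype == np.uint8:
        pixels = data.astype(float) / 255.0
    elif data.dtype == np.uint16:
        pixels = data.astype(float) / 65535.0
    else:
        raise ValueError(f"unsupported bit depth {data.dtype}; expected 8- or "
                         "16-bit grayscale")

    meta = {}
    sc = sidecar_path(path)
    if sc.exists():
        meta = yaml.safe_load(sc.read_text()) or {}
    pitch = pixel_pitch_um if pixel_pitch_um is not None else meta.get(
        "pixel_pitch_um")
    if pitch is None:
        raise ValueError(
            f"no pixel pitch for {path.name}: provide pixel_pitch_um or a "
            "YAML sidecar")
    slab = slab or meta.get("slab")
    if slab not in SLABS:
        raise ValueError(f"unknown or missing slab label {slab!r}")
    if "acquisition" in meta:
        acq = AcquisitionSetting(**meta["acquisition"])
    else:
        side = pixels.shape[0]
        acq = AcquisitionSetting(scan_width_um=pitch * side)
    return EnFaceImage(pixels=pixels, pixel_pitch_um=float(pitch), slab=slab,
                       acquisition=acq)


def write_report(cohort, summary, analysis, out_dir, config_echo=None) -> dict:
    """Write the deterministic report file set for one experiment run.

    Produces cohort.csv (condition means), repeats.csv, table1_like.csv
    (mean +/- SD with omnibus/pairwise p-values), table2_like.csv (Pearson
    r per device/slab/metric), a signal-strength-vs-CCFD scatter, a YAML
    echo of the run configuration and a log file.  All inputs are checked
    before the first file is written, so a failed run leaves no partial
    file set.
    """
    from .experiment import CohortResult
    from .stats import CohortAnalysis

    if not isinstance(cohort, CohortResult):
        raise TypeError("cohort must be a CohortResult")
    if summary is None or len(summary) == 0:
        raise ValueError("empty summary; nothing to report")
    if not isinstance(analysis, CohortAnalysis):
        raise TypeError("analysis must be a CohortAnalysis")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not out.is_dir():
        raise NotADirectoryError(out)

    paths = {
        "cohort": out / "cohort.csv",
        "repeats": out / "repeats.csv",
        "table1": out / "table1_like.csv",
        "table2": out / "table2_like.csv",
        "fig4": out / "fig4_like_ss_vs_ccfd.png",
        "config": out / "run_config.yaml",
        "log": out / "report.log",
    }
    cohort.means.to_csv(paths["cohort"], index=False)
    cohort.repeats.to_csv(paths["repeats"], index=False)
    analysis.table1.to_csv(paths["table1"], index=False)
    analysis.table2.to_csv(paths["table2"], index=False)
    _scatter_ss_ccfd(cohort, paths["fig4"])
    echo = config_echo if config_echo is not None else dataclasses.asdict(
        cohort.config)
    echo = dict(echo)
    echo["seed"] = cohort.seed
    paths["config"].write_text(yaml.safe_dump(echo, sort_keys=True))
    lines = [f"octaquant report: {len(cohort.means)} cohort rows",
             f"seed: {cohort.seed}"]
    for _, row in analysis.table2.iterrows():
        lines.append(
            f"r(SS, {row['slab']} {row['metric']}) [{row['device_model']}] "
            f"= {row['r']:+.3f} (p={row['p_value']:.3g})")
    paths["log"].write_text("\n".join(lines) + "\n")
    return {k: str(v) for k, v in paths.items()}


def _scatter_ss_ccfd(cohort, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cc = cohort.means[cohort.means["slab"] == "CC"]
    devices = sorted(cc["device_model"].unique())
    fig, axes = plt.subplots(1, len(devices), figsize=(5 * len(devices), 4),
                             squeeze=False)
    for ax, device in zip(axes[0], devices):
        sub = cc[cc["device_model"] == device]
        ax.scatter(sub["signal_strength"], sub["ccfd_pct"], s=12, alpha=0.7)
        if sub["signal_strength"].nunique() > 1:
            coef = np.polyfit(sub["signal_strength"], sub["ccfd_pct"], 1)
            xs = np.linspace(sub["signal_strength"].min(),
                             sub["signal_strength"].max(), 50)
            ax.plot(xs, np.polyval(coef, xs), "k--", lw=1)
        ax.set_xlabel("signal strength (0-10)")
        ax.set_ylabel("CC flow deficit (%)")
        ax.set_title(device)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
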