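"""Synthetic signal-strength experiment on a cohort of phantoms.

For every subject one phantom is generated; for every device model (SD,
SS) and filter condition (no filter, OD 0.3, OD 0.6) each slab is rendered
three times with independent speckle/noise draws, quantified, and the
three repeat measurements averaged — the repeated-scan averaging used to
damp dynamic flow variation.  The result is a cohort table of condition
means per (subject, device, slab) feeding the statistics stage.

The cohort default raster is 256 px for retinal slabs and 512 px for the
CC (one quarter of the single-image reference geometry), which keeps a
full 20-subject, 2-device, 3-condition, 3-repeat cohort tractable on one
CPU while preserving every qualitative effect the experiment probes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .optics import AcquisitionSetting, DEVICE_N_ASCANS
from .phantom import PhantomParams, generate_phantom
from .pipeline import quantify_slab
from .render import SLABS, render_slab, signal_strength

__all__ = ["ExperimentConfig", "CohortResult", "run_cohort", "summarize",
           "null_paired_cohort"]

_REPEAT_COLS = ["subject", "device_model", "od", "repeat", "slab",
                "vd_pct", "vld_pct", "ccfd_pct", "analyzed_px",
                "signal_strength"]


@dataclass(frozen=True)
class ExperimentConfig:
    """Study design of the synthetic cohort."""

    od_list: Tuple[float, ...] = (0.0, 0.3, 0.6)
    n_repeats: int = 3
    devices: Tuple[str, ...] = ("SD", "SS")
    noise_floor: float = 0.015
    retina_side: int = 256
    phantom: Optional[PhantomParams] = None

    def __post_init__(self) -> None:
        if len(self.od_list) < 2:
            raise ValueError("need at least two filter conditions")
        if any(od < 0 for od in self.od_list):
            raise ValueError("optical densities must be >= 0")
        if len(set(self.od_list)) != len(self.od_list):
            raise ValueError("duplicate optical densities in od_list")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        for d in self.devices:
            if d not in DEVICE_N_ASCANS:
                raise ValueError(f"unknown device model {d!r}")

    def phantom_params(self) -> PhantomParams:
        if self.phantom is not None:
            return self.phantom
        return PhantomParams(side=self.retina_side)


@dataclass
class CohortResult:
    """Per-repeat measurements and their per-condition means."""

    repeats: pd.DataFrame   # one row per (subject, device, od, repeat, slab)
    means: pd.DataFrame     # one row per (subject, device, od, slab)
    config: ExperimentConfig
    seed: int


def _stream_seed(*parts: int) -> int:
    # independent, reproducible sub-streams below 2**31
    seq = np.random.SeedSequence([int(p) for p in parts])
    return int(seq.generate_state(1)[0] % (2 ** 31))


def run_cohort(n_subjects: int, seed: int,
               config: Optional[ExperimentConfig] = None) -> CohortResult:
    """Run the full synthetic experiment; deterministic for a given seed."""
    if n_subjects < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    config = config or ExperimentConfig()
    params = config.phantom_params()
    rows: List[dict] = []
    for subject in range(1, n_subjects + 1):
        phantom = generate_phantom(_stream_seed(seed, subject), params)
        for d_idx, device in enumerate(config.devices):
            for od_idx, od in enumerate(config.od_list):
                acq = AcquisitionSetting.for_device(
                    device, ndf_od=od,
                    seed=_stream_seed(seed, 10_000 + subject, d_idx, od_idx),
                    noise_floor=config.noise_floor)
                for rep in range(config.n_repeats):
                    scp = render_slab(phantom, "SCP", acq, repeat=rep)
                    ss = signal_strength(scp)
                    for slab in SLABS:
                        img = scp if slab == "SCP" else render_slab(
                            phantom, slab, acq, repeat=rep)
                        metrics = quantify_slab(img, scp)
                        rows.append({
                            "subject": subject, "device_model": device,
                            "od": od, "repeat": rep, "slab": slab,
                            "vd_pct": metrics.vd_pct,
                            "vld_pct": metrics.vld_pct,
                            "ccfd_pct": metrics.ccfd_pct,
                            "analyzed_px": metrics.analyzed_px,
                            "signal_strength": ss,
                        })
    repeats = pd.DataFrame(rows, columns=_REPEAT_COLS)
    means = (repeats
             .groupby(["subject", "device_model", "od", "slab"], as_index=False)
             .agg({"vd_pct": "mean", "vld_pct": "mean", "ccfd_pct": "mean",
                   "analyzed_px": "mean", "signal_strength": "mean"}))
    return CohortResult(repeats=repeats, means=means, config=config,
                        seed=int(seed))


def summarize(cohort: CohortResult | pd.DataFrame) -> pd.DataFrame:
    """Per-condition mean +/- SD summary, one row per (device, slab, metric).

    SD is the sample standard deviation (n-1 denominator) of the subject
    condition means.  Raises if any (subject, device, condition, slab) cell
    is missing.
    """
    means = cohort.means if isinstance(cohort, CohortResult) else cohort
    subjects = means["subject"].unique()
    devices = means["device_model"].unique()
    ods = sorted(means["od"].unique())
    missing = []
    for s in subjects:
        for d in devices:
            for od in ods:
                for slab in SLABS:
                    hit = means[(means["subject"] == s)
                                & (means["device_model"] == d)
                                & (means["od"] == od)
                                & (means["slab"] == slab)]
                    if hit.empty:
                        missing.append((s, d, od, slab))
    if missing:
        raise ValueError(f"cohort table is missing cells: {missing[:10]}"
                         + (" ..." if len(missing) > 10 else ""))

    metric_cols = {"SCP": ["vd_pct", "vld_pct"],
                   "DCP": ["vd_pct", "vld_pct"],
                   "CC": ["ccfd_pct"]}
    rows = []
    for d in devices:
        for slab, cols in metric_cols.items():
            for col in cols + (["signal_strength"] if slab == "SCP" else []):
                row = {"device_model": d, "slab": slab, "metric": col}
                for od in ods:
                    vals = means[(means["device_model"] == d)
                                 & (means["od"] == od)
                                 & (means["slab"] == slab)][col].to_numpy()
                    mu = float(np.mean(vals))
                    sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
                    row[f"mean_od{od}"] = mu
                    row[f"sd_od{od}"] = sd
                    row[f"fmt_od{od}"] = f"{mu:.1f} ± {sd:.2f}"
                rows.append(row)
    return pd.DataFrame(rows)


def null_paired_cohort(n_subjects: int, k: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Null-model paired matrix: subject effects plus repeat noise, no
    condition effect.  Used for type-I error calibration of the omnibus
    tests."""
    subject = rng.normal(0.0, 1.0, size=(n_subjects, 1))
    return subject + rng.normal(0.0, 0.5, size=(n_subjects, k))
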