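"""Session reports, manifests and diagnostic plots."""

from __future__ import annotations

import json
import platform
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .metrics import TBE_THRESHOLDS_MM, MetricsReport, compute_report
from .realtime import PredictionRecord


def _pkg_version() -> str:
    try:
        return version("respirc")
    except PackageNotFoundError:
        return "unknown"


def records_to_frame(
    records: Sequence[PredictionRecord], t_s_ms: float = 100.0 / 3.0
) -> pd.DataFrame:
    """Tabulate a session as (index, time_s, y_mm, yhat_mm, ae_mm)."""
    return pd.DataFrame(
        {
            "index": [r.index for r in records],
            "time_s": [(r.index - 1) * t_s_ms / 1000.0 for r in records],
            "y_mm": [r.y for r in records],
            "yhat_mm": [r.yhat for r in records],
            "ae_mm": [r.ae for r in records],
        }
    )


def write_session_report(
    records: Sequence[PredictionRecord],
    out_dir: str | Path,
    t_s_ms: float = 100.0 / 3.0,
    prefix: str = "session",
) -> MetricsReport:
    """Write predictions CSV and metrics JSON; return the metrics report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records_to_frame(records, t_s_ms).to_csv(out / f"{prefix}_predictions.csv", index=False)
    report = compute_report(records)
    (out / f"{prefix}_metrics.json").write_text(report.to_json(indent=2, sort_keys=True))
    return report


def write_manifest(out_dir: str | Path, config_dict: dict, config_hash: str, seed: int) -> None:
    """Reproducibility manifest: config, hash, seed, package version."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": config_dict,
        "config_hash": config_hash,
        "seed": seed,
        "respirc_version": _pkg_version(),
        "python": platform.python_version(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def plot_session(
    records: Sequence[PredictionRecord],
    out_path: str | Path,
    t_s_ms: float = 100.0 / 3.0,
    title: str = "",
) -> None:
    """Position-vs-time with prediction overlay and AE-vs-time with margin lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = records_to_frame(records, t_s_ms)
    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(10, 6), sharex=True)
    ax1.plot(df.time_s, df.y_mm, "k-", lw=1, label="ground truth")
    ax1.plot(df.time_s, df.yhat_mm, "-", color="tab:brown", lw=1, label="prediction")
    ax1.set_ylabel("position (mm)")
    ax1.legend(loc="upper right", fontsize=8)
    if title:
        ax1.set_title(title)
    ax2.plot(df.time_s, df.ae_mm, "b-", lw=0.8)
    for thr, color in zip(TBE_THRESHOLDS_MM, ("red", "brown", "black")):
        ax2.axhline(thr, ls="--", color=color, lw=0.8, label=f"AE = {thr:g} mm")
    ax2.set_xlabel("time (s)")
    ax2.set_ylabel("AE (mm)")
    ax2.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=110)
    plt.close(fig)
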