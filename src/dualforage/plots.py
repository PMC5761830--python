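"""Diagnostic figures: duration histogram with cut-off, null histograms, index-CV scatter."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def plot_duration_histogram(durations_h, cutoff_h: float, path: Path) -> None:
    """Log-duration histogram of all trips with the ST/LT cut-off line."""
    logs = np.log(np.asarray(durations_h, dtype=float))
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(logs, bins=30, color="steelblue", edgecolor="white")
    ax.axvline(np.log(cutoff_h), color="firebrick", lw=2,
               label=f"cut-off = {cutoff_h:.1f} h")
    ax.set_xlabel("log trip duration (log h)")
    ax.set_ylabel("number of trips")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_null_histogram(null_samples, observed: float, path: Path,
                        label: str = "statistic") -> None:
    """Randomization null distribution with the observed value marked."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(np.asarray(null_samples, dtype=float), bins=30,
            color="grey", edgecolor="white")
    ax.axvline(observed, color="firebrick", ls="--", lw=2, label="observed")
    ax.set_xlabel(label)
    ax.set_ylabel("null frequency")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_index_vs_cv(session_results: pd.DataFrame, path: Path) -> None:
    """Coordination level against relative interval CV, one point per session."""
    ov = session_results[session_results["statistic"] == "st_lt_overlap"]
    cv = session_results[session_results["statistic"] == "interfeed_cv"]
    merged = ov.merge(cv, on=["pair_id", "session_id"], suffixes=("_ov", "_cv"))
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(merged["index_ov"], merged["index_cv"], alpha=0.7)
    ax.axhline(0, color="grey", lw=0.5)
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel("coordination level (overlap, rel. to chance)")
    ax.set_ylabel("interval CV rel. to chance")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
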