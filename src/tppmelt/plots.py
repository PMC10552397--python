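"""Headless-safe diagnostic plots for the differential and dose-response
results (volcano-style scatters and the pseudo-R^2 vs pEC50 view)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def _neglog10(p: pd.Series) -> np.ndarray:
    p = p.to_numpy(float)
    with np.errstate(divide="ignore"):
        return -np.log10(np.clip(p, np.finfo(float).tiny, 1.0))


def plot_distance_volcano(results: pd.DataFrame, path) -> None:
    """Distance score vs Fisher-combined significance, hits colored."""
    fig, ax = plt.subplots(figsize=(5, 4))
    sig = results["significant"].astype(bool)
    colors = np.where(
        sig & (results["distance_score"] > 0), "tab:green",
        np.where(sig, "tab:red", "0.7"),
    )
    ax.scatter(results["distance_score"], _neglog10(results["fisher_p"]),
               s=8, c=colors, linewidths=0)
    ax.set_xlabel("distance score")
    ax.set_ylabel("-log10 combined p")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_delta_tm_volcano(results: pd.DataFrame, path) -> None:
    """Mean melting-point shift vs its significance."""
    fig, ax = plt.subplots(figsize=(5, 4))
    sig = results["significant"].astype(bool)
    colors = np.where(
        sig & (results["delta_tm"] > 0), "tab:green",
        np.where(sig, "tab:red", "0.7"),
    )
    ax.scatter(results["delta_tm"], _neglog10(results["stab_p"]),
               s=8, c=colors, linewidths=0)
    ax.axvline(0, color="0.4", lw=0.5)
    ax.set_xlabel("mean ΔT$_m$ (°C)")
    ax.set_ylabel("-log10 p")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_abundance_volcano(results: pd.DataFrame, path) -> None:
    """Lowest-temperature abundance log2 ratio vs its significance."""
    fig, ax = plt.subplots(figsize=(5, 4))
    sig = results["significant"].astype(bool)
    colors = np.where(
        sig & (results["abundance_log2fc"] > 0), "tab:green",
        np.where(sig, "tab:red", "0.7"),
    )
    ax.scatter(results["abundance_log2fc"], _neglog10(results["abund_p"]),
               s=8, c=colors, linewidths=0)
    ax.axvline(0, color="0.4", lw=0.5)
    ax.set_xlabel("abundance log2 ratio (lowest T)")
    ax.set_ylabel("-log10 p")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ccr_scatter(results: pd.DataFrame, path, direction: str = "positive") -> None:
    """Pseudo-R^2 vs pEC50 for one response direction; point size encodes
    the 50 minus 37 deg C pseudo-R^2 difference."""
    sub = results[results["direction"] == direction]
    fig, ax = plt.subplots(figsize=(5, 4))
    size = 4 + 40 * np.clip(sub["r2_difference"].to_numpy(float), 0, 1)
    ax.scatter(sub["pec50"], sub["pseudo_r2_50"], s=size, alpha=0.6,
               c="tab:green" if direction == "positive" else "tab:red",
               linewidths=0)
    ax.set_xlabel("pEC50")
    ax.set_ylabel("pseudo-R² (50 °C)")
    ax.set_ylim(0, 1.02)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
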