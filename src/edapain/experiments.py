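"""Ablations, window-sensitivity sweeps, and SE recalibration visualization.

All configurations inside one comparison share the same folds and the same
per-fold seeds, so differences reflect the architecture, not the split.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .evaluation import RunReport, Scaler, TrainConfig, run_loocv
from .mscn import vary_branch_window
from .model import ModelConfig, PainIntensityClassifier, dry_run
from .seresnet import SEState
from .simulate import Cohort

BRANCH_NAMES = ("short", "medium", "long")

ABLATION_NAMES = (
    "full",
    "mscn_transformer",
    "mscn_seresnet",
    "mscn_only",
)


def ablation_configs(base: ModelConfig) -> dict[str, ModelConfig]:
    """The four ablation variants: full model, drop SE, drop encoder, MSCN only."""
    return {
        "full": dataclasses.replace(base, use_se=True, use_encoder=True),
        "mscn_transformer": dataclasses.replace(base, use_se=False, use_encoder=True),
        "mscn_seresnet": dataclasses.replace(base, use_se=True, use_encoder=False),
        "mscn_only": dataclasses.replace(base, use_se=False, use_encoder=False),
    }


def run_ablation(
    cohort: Cohort,
    tasks: list[str],
    base_cfg: ModelConfig,
    train_cfg: TrainConfig,
    progress: bool = False,
) -> tuple[pd.DataFrame, dict[tuple[str, str], RunReport]]:
    """Accuracy per (configuration, task); identical folds and seeds across rows."""
    configs = ablation_configs(base_cfg)
    reports: dict[tuple[str, str], RunReport] = {}
    table = {}
    for name, cfg in configs.items():
        row = {}
        for task in tasks:
            rep = run_loocv(cohort, task, cfg, train_cfg, progress=progress)
            reports[(name, task)] = rep
            row[task] = rep.accuracy
        table[name] = row
    df = pd.DataFrame(table).T.loc[list(configs)]
    df.index.name = "configuration"
    return df, reports


def window_sensitivity(
    cohort: Cohort,
    grid: dict[str, list[float]],
    base_cfg: ModelConfig,
    train_cfg: TrainConfig,
    tasks: list[str] = ("T0_vs_T4",),
    sampling_rate: float | None = None,
    progress: bool = False,
) -> pd.DataFrame:
    """Vary one branch window at a time around the baseline.

    ``grid`` maps a branch name ('short'/'medium'/'long') to the window
    lengths (seconds) to try for that branch; every variant keeps the other
    two branches at their baseline windows.  Kernel sizes are recomputed as
    ``round(window * sampling_rate)`` for varied branches.  The baseline row
    is always present and flagged.
    """
    fs = sampling_rate or cohort.protocol.sampling_rate
    seg_len = cohort.protocol.samples_per_segment
    variants: list[tuple[str, ModelConfig, bool]] = [("baseline", base_cfg, True)]
    for branch_name, windows in grid.items():
        idx = BRANCH_NAMES.index(branch_name)
        for w in windows:
            if abs(w - base_cfg.branches[idx].window_seconds) < 1e-12:
                continue
            branches = list(base_cfg.branches)
            branches[idx] = vary_branch_window(branches[idx], w, fs)
            cfg = dataclasses.replace(base_cfg, branches=tuple(branches))
            dry_run(cfg, seg_len)  # fail fast on infeasible geometry
            variants.append((f"{branch_name}={w}", cfg, False))
    rows = []
    for name, cfg, is_baseline in variants:
        row: dict[str, object] = {"variant": name, "baseline": is_baseline}
        for b, bc in zip(BRANCH_NAMES, cfg.branches):
            row[f"{b}_window_s"] = bc.window_seconds
            row[f"{b}_kernel"] = bc.kernel_size
        for task in tasks:
            rep = run_loocv(cohort, task, cfg, train_cfg, progress=progress)
            row[f"accuracy_{task}"] = rep.accuracy
        rows.append(row)
    return pd.DataFrame(rows).set_index("variant")


def se_visualization(
    model: PainIntensityClassifier,
    X: np.ndarray,
    scaler: Scaler | None = None,
    batch_size: int = 64,
) -> dict[str, np.ndarray]:
    """Average pre/post SE feature maps and channel gates over ``X``.

    Works on untrained models too (useful as an initialization diagnostic).
    """
    if model.se is None:
        raise ValueError("model has no squeeze-and-excitation block")
    model.eval()
    Xs = scaler(X) if scaler is not None else X
    pre = post = v = None
    gates = []
    total = 0
    for start in range(0, len(Xs), batch_size):
        xb = Xs[start : start + batch_size]
        model(xb)
        state: SEState = model.se_state
        w = len(xb)
        pre = state.pre_mean * w if pre is None else pre + state.pre_mean * w
        post = state.post_mean * w if post is None else post + state.post_mean * w
        v = state.v_mean * w if v is None else v + state.v_mean * w
        gates.append(np.atleast_2d(state.alpha))
        total += w
    alpha = np.concatenate(gates, axis=0)
    return {
        "pre_mean": pre / total,
        "post_mean": post / total,
        "v_mean": v / total,
        "gates_mean": alpha.mean(axis=0),
        "gates": alpha,
    }


# -- plotting ----------------------------------------------------------------

def plot_roc(fpr: np.ndarray, tpr: np.ndarray, auc: float, path: str | Path,
             label: str = "") -> None:
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(fpr, tpr, label=f"{label} (AUC = {auc:.2f})".strip())
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_comparison_bars(df: pd.DataFrame, path: str | Path, ylabel: str = "Accuracy") -> None:
    numeric = df.select_dtypes(include=[np.number])
    ax = numeric.plot.bar(figsize=(7, 4))
    ax.set_ylabel(ylabel)
    ax.figure.tight_layout()
    ax.figure.savefig(path, dpi=120)
    plt.close(ax.figure)


def plot_se_maps(viz: dict[str, np.ndarray], path: str | Path) -> None:
    fig, axes = plt.subplots(2, 2, figsize=(9, 6))
    for ax, key, title in (
        (axes[0, 0], "pre_mean", "Feature map before SE recalibration"),
        (axes[0, 1], "post_mean", "Feature map after SE recalibration"),
    ):
        im = ax.imshow(viz[key].T, aspect="auto", origin="lower")
        ax.set_title(title)
        ax.set_xlabel("time step")
        ax.set_ylabel("channel")
        fig.colorbar(im, ax=ax)
    axes[1, 0].bar(np.arange(len(viz["gates_mean"])), viz["gates_mean"])
    axes[1, 0].set_title("Mean SE channel gates")
    axes[1, 0].set_xlabel("channel")
    axes[1, 0].set_ylim(0, 1)
    axes[1, 1].axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
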