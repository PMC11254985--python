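"""Figure rendering: mean concentration and UPDRS-change panels.

Plots are conveniences for inspection; every quantitative result lives in
the CSV tables.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

_LABELS = {"sc": "Subcutaneous", "sl": "Sublingual"}


def _dose_panels(cells, column: str, ylabel: str, mcic: float | None = None):
    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
    for ax, formulation in zip(axes, ("sc", "sl")):
        for cell in sorted(
            (c for c in cells if c.formulation == formulation), key=lambda c: c.dose_mg
        ):
            ax.plot(
                cell.mean_profiles["time_min"],
                cell.mean_profiles[column],
                label=f"{cell.dose_mg:g} mg",
            )
        if mcic is not None:
            ax.axhline(-mcic, linestyle="--", color="0.4", label="MCIC")
        ax.set_title(_LABELS[formulation])
        ax.set_xlabel("Time (min)")
        ax.legend(fontsize=8)
    axes[0].set_ylabel(ylabel)
    fig.tight_layout()
    return fig


def plot_mean_concentrations(cells, path: Path) -> None:
    """Dose-coloured mean plasma-concentration panels, one per formulation."""
    fig = _dose_panels(cells, "mean_cp", "Apomorphine plasma concentration (ng/mL)")
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_mean_updrs_change(cells, path: Path, mcic: float) -> None:
    """Mean UPDRS change-from-baseline panels with the dashed MCIC line."""
    fig = _dose_panels(
        cells, "mean_updrs_change", "UPDRS motor score change from baseline", mcic=mcic
    )
    fig.savefig(path, dpi=150)
    plt.close(fig)
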