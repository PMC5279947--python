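"""Driver reproducing the redistribution-model summary figure.

Runs the simulation for both conditions, writes the trajectory and
knockout/control ratio tables, and renders (a) the percent-of-pool
trajectories for mature and immature populations and (b) the final-week
ratio of mature synapse shares.  All outputs are deterministic.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .io import write_manifest, write_ratio, write_trajectories
from .model import predicted_mature_ratio, run_simulation
from .params import BAX_KO, CONTROL, ModelParams

__all__ = ["reproduce_figure9"]


def reproduce_figure9(
    params: ModelParams = ModelParams(),
    out_dir: str | Path = ".",
    window: tuple[int, int] = (36, 43),
) -> dict[str, Path]:
    """Run both conditions and write trajectory, ratio and chart files.

    Returns a mapping of artifact names to paths.  The trajectory CSV has
    one row per condition and day; the ratio CSV covers the requested
    final window (one row per day).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ctrl = run_simulation(params, CONTROL)
    ko = run_simulation(params, BAX_KO)
    ratio = predicted_mature_ratio(ko, ctrl, window)

    paths = {
        "trajectories": out / "trajectories.csv",
        "ratio": out / "mature_ratio.csv",
        "trajectory_plot": out / "synapse_shares.png",
        "ratio_plot": out / "mature_ratio.png",
    }
    write_trajectories([ctrl, ko], paths["trajectories"])
    write_ratio(ratio, paths["ratio"])

    fig, ax = plt.subplots(figsize=(6, 4))
    for traj, color in ((ctrl, "tab:blue"), (ko, "tab:red")):
        ax.plot(traj.day, traj.pct_mature, color=color, label=f"{traj.condition} mature")
        ax.plot(traj.day, traj.pct_immature, color=color, linestyle="--",
                label=f"{traj.condition} immature")
    ax.set_xlabel("day")
    ax.set_ylabel("% of synapse pool")
    ax.set_ylim(0, 100)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(paths["trajectory_plot"], dpi=150)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.bar(ratio["day"], ratio["ratio_pct"], color="tab:gray")
    ax.axhline(100, color="k", linewidth=0.8)
    ax.set_xlabel("day")
    ax.set_ylabel("mature share, KO/control (%)")
    fig.tight_layout()
    fig.savefig(paths["ratio_plot"], dpi=150)
    plt.close(fig)

    write_manifest(out, "reproduce-fig9", params.to_dict(),
                   [p for p in paths.values()])
    return paths
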