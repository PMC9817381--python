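"""Figure helpers: per-model activity traces and partial-residual plots."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .association import RegressionReport, partial_residuals
from .selection import GridResult


def plot_model_membership(hourly_list, grid_results: list[GridResult], outdir) -> list[Path]:
    """One figure per selected model: dashed individual traces, solid mean."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    by_id = {h.participant_id: h for h in hourly_list}
    groups: dict[int, list] = {}
    for res in grid_results:
        groups.setdefault(res.best_number, []).append(res)
    paths = []
    for number, members in sorted(groups.items()):
        fig, ax = plt.subplots(figsize=(9, 3.2))
        traces = []
        for res in members:
            y = by_id[res.participant_id].values
            ax.plot(y, ls="--", lw=0.7, alpha=0.6)
            traces.append(y)
        ax.plot(np.mean(traces, axis=0), lw=1.8, color="black")
        spec = members[0].best_spec
        ax.set_title(f"model #{number} {spec.label()} (n = {len(members)})")
        ax.set_xlabel("hour")
        ax.set_ylabel("MET-minutes")
        path = outdir / f"model_{number:02d}.png"
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths.append(path)
    return paths


def plot_partial_residuals(report: RegressionReport, predictors, path) -> Path:
    """Centered partial-residual panels for the given predictors."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    predictors = list(predictors)
    fig, axes = plt.subplots(1, len(predictors), figsize=(3.4 * len(predictors), 3.2))
    if len(predictors) == 1:
        axes = [axes]
    for ax, pred in zip(axes, predictors):
        pairs = partial_residuals(report, pred)
        ax.scatter(pairs[:, 0], pairs[:, 1], s=16)
        xs = np.array([pairs[:, 0].min(), pairs[:, 0].max()])
        j = report.names.index(pred) if isinstance(pred, str) else int(pred)
        ax.plot(xs, report.slopes[j] * xs, color="black", lw=1.2)
        ax.axhline(0, color="grey", lw=0.5)
        ax.set_xlabel(f"{pred} (centered)")
        ax.set_ylabel("partial residual")
    fig.suptitle(report.scale_name)
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
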