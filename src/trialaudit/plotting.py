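"""Two-panel comparison figure: mean +/- SD per condition for each
averaging order, with significant timepoints shaded."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np

_COLORS = {"yes": "tab:blue", "no": "tab:orange"}


def _panel(ax, t, method: dict, title: str) -> None:
    for cond in ("yes", "no"):
        mean = np.asarray(method["grand_mean"][cond])
        sd = np.asarray(method["replicate_sd"][cond])
        ax.plot(t, mean, color=_COLORS[cond], label=cond)
        ax.fill_between(t, mean - sd, mean + sd, color=_COLORS[cond], alpha=0.25, lw=0)
    mask = np.asarray(method["mask"], dtype=bool)
    if mask.any():
        ylim = ax.get_ylim()
        ax.fill_between(t, ylim[0], ylim[1], where=mask, color="0.8", zorder=0)
        ax.set_ylim(ylim)
    ax.axvline(0.0, color="k", lw=0.5)
    ax.set_title(title)
    ax.set_xlabel("time relative to onset (s)")


def render_comparison_figure(report, path: str | Path | None = None):
    """Render the averaging-order comparison as a two-panel figure.

    ``report`` is either a :class:`~trialaudit.averaging.MethodComparisonResults`
    or its ``to_dict()`` form.  Returns the output path if ``path`` is given,
    else the matplotlib figure.
    """
    if hasattr(report, "to_dict"):
        report = report.to_dict()
    for key in ("methods", "time_axis_s"):
        if key not in report:
            raise ValueError(f"report is missing field {key!r}")
    t = np.asarray(report["time_axis_s"])
    methods = report["methods"]
    fig, axes = plt.subplots(1, len(methods), figsize=(6 * len(methods), 4), sharey=True)
    axes = np.atleast_1d(axes)
    for ax, (label, method) in zip(axes, methods.items()):
        _panel(
            ax,
            t,
            method,
            f"{label} (replicates: {method['replicate_unit']}, "
            f"{method['n_significant']}/{method['n_timepoints']} significant)",
        )
    axes[0].set_ylabel("relative HbO change (a.u.)")
    axes[0].legend(loc="upper right")
    fig.tight_layout()
    if path is not None:
        path = Path(path)
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return path
    return fig
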