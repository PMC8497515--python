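"""Plot helpers mirroring the conventional biomarker-screen figures.

Matplotlib is imported lazily and the Agg backend is forced, so these work
headless.  Both functions write a file and return the output path.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

from .differential import DifferentialResult, TwoGroupResult


def _axes(figsize):
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt.subplots(figsize=figsize)


def plot_lda_scores(results: Sequence[DifferentialResult], path) -> Path:
    """Horizontal bar chart of effect scores for significant features,
    colored by assigned class."""
    sig = [r for r in results if r.significant]
    fig, ax = _axes((7, max(2, 0.4 * len(sig) + 1)))
    classes = sorted({r.assigned_class for r in sig})
    cmap = {c: f"C{i}" for i, c in enumerate(classes)}
    ordered = sorted(sig, key=lambda r: (r.assigned_class, r.effect_size))
    ax.barh(
        [r.feature_id for r in ordered],
        [r.effect_size for r in ordered],
        color=[cmap[r.assigned_class] for r in ordered],
    )
    ax.set_xlabel("effect score (log10 per-million difference)")
    ax.set_title("Differentially abundant features")
    from matplotlib.patches import Patch

    handles = [Patch(color=cmap[c], label=c) for c in classes]
    if handles:
        ax.legend(handles=handles, loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    return Path(path)


def plot_extended_error_bars(
    results: Sequence[TwoGroupResult], class_a: str, class_b: str, path,
    significant_only: bool = True,
) -> Path:
    """Extended error-bar plot: mean proportions on the left, difference of
    mean proportions with its 95% CI on the right."""
    shown = [r for r in results if r.significant] if significant_only else list(results)
    shown = sorted(shown, key=lambda r: r.difference)
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, (left, right) = plt.subplots(
        1, 2, figsize=(9, max(2, 0.4 * len(shown) + 1)), sharey=True,
        gridspec_kw={"width_ratios": [2, 3]},
    )
    y = range(len(shown))
    names = [r.feature_id for r in shown]
    left.barh([i + 0.2 for i in y], [r.mean_a for r in shown], height=0.4, label=class_a)
    left.barh([i - 0.2 for i in y], [r.mean_b for r in shown], height=0.4, label=class_b)
    left.set_yticks(list(y), names, fontsize=8)
    left.set_xlabel("mean proportion (%)")
    left.legend(fontsize=8)
    right.errorbar(
        [r.difference for r in shown], list(y),
        xerr=[
            [r.difference - r.ci_low for r in shown],
            [r.ci_high - r.difference for r in shown],
        ],
        fmt="o", capsize=3,
    )
    right.axvline(0.0, color="grey", lw=0.8)
    right.set_xlabel(f"difference in mean proportions (%): {class_a} - {class_b}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    return Path(path)
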