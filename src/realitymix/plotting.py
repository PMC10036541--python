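"""Figure-style summaries of model predictions.

One panel per condition: the predicted percentage of trials judged "real"
and the mean vividness report split by reality judgment, mirroring the way
the competing accounts are usually displayed side by side.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np

from .sdt_models import CONDITIONS, ModelSpec, condition_prediction

__all__ = ["plot_model_predictions"]


def plot_model_predictions(
    models: list[ModelSpec],
    n_sim: int | None = 20_000,
    seed: int = 0,
    conditions: tuple[str, ...] = CONDITIONS,
):
    """Bar panels of p(real) and judgment-conditional vividness per model.

    Returns the matplotlib Figure; does not call show().
    """
    fig, axes = plt.subplots(
        2, len(models), figsize=(3.2 * len(models), 6), squeeze=False
    )
    x = np.arange(len(conditions))
    for j, model in enumerate(models):
        preds = [
            condition_prediction(model, c, n_sim=n_sim, seed=seed + j)
            for c in conditions
        ]
        ax = axes[0, j]
        ax.bar(x, [100 * p.p_real for p in preds], color="0.4")
        ax.set_xticks(x, conditions, rotation=20)
        ax.set_ylim(0, 100)
        ax.set_title(model.model_id)
        if j == 0:
            ax.set_ylabel('% judged "real"')
        ax = axes[1, j]
        w = 0.38
        ax.bar(
            x - w / 2,
            [p.mean_vividness_given_real for p in preds],
            w,
            label="judged real",
            color="tab:orange",
        )
        ax.bar(
            x + w / 2,
            [p.mean_vividness_given_imagined for p in preds],
            w,
            label="judged imagined",
            color="tab:blue",
        )
        ax.set_xticks(x, conditions, rotation=20)
        if j == 0:
            ax.set_ylabel("mean vividness")
            ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    return fig
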