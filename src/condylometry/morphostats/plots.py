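"""Minimal diagnostic plots (Bland–Altman, discriminant scores)."""

from __future__ import annotations

import numpy as np

from .agreement import bland_altman
from .discriminant import DiscriminantModel


def bland_altman_plot(pairs, ax=None, title=None):
    """Scatter of pair means vs differences with the limits of agreement."""
    import matplotlib.pyplot as plt

    arr = np.asarray(list(pairs), dtype=float)
    res = bland_altman(arr)
    if ax is None:
        _, ax = plt.subplots()
    means = arr.mean(axis=1)
    diffs = arr[:, 0] - arr[:, 1]
    ax.scatter(means, diffs, s=18, alpha=0.7)
    for y, style in ((res.mean_diff, "-"), (res.loa_upper, "--"),
                     (res.loa_lower, "--")):
        ax.axhline(y, color="k", linestyle=style, linewidth=1)
    ax.set_xlabel("mean of measurements")
    ax.set_ylabel("difference")
    if title:
        ax.set_title(title)
    return ax


def discriminant_scatter(model: DiscriminantModel, data, groups, ax=None):
    """Scatter of the first two canonical discriminant scores by group
    (first score vs zero when only one function exists)."""
    import matplotlib.pyplot as plt

    scores = model.transform(data)
    if ax is None:
        _, ax = plt.subplots()
    labels = np.asarray(groups)
    for lev in model.groups:
        pts = scores[labels == lev]
        y = pts[:, 1] if pts.shape[1] > 1 else np.zeros(len(pts))
        ax.scatter(pts[:, 0], y, s=18, alpha=0.7, label=str(lev))
    ax.set_xlabel("function 1")
    ax.set_ylabel("function 2" if scores.shape[1] > 1 else "")
    ax.legend()
    return ax
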