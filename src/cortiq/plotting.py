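"""Figure helpers: scatter of qMR parameters vs myelin, per-tissue
histograms, and depth-slice renders. All functions return matplotlib
figures and never call ``show``."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_scatter_vs_myelin", "plot_histograms", "plot_depth_slice"]

_PARAM_LABEL = {
    "t1": "T1 (ms)",
    "t2": "T2 (ms)",
    "m0": "M0 (r.u.)",
    "mtr": "MTR (%)",
    "myelin": "myelin (% area)",
}


def plot_scatter_vs_myelin(results, params=("t1", "t2", "m0", "mtr")):
    """Scatter of fitted qMR values against myelin content on the histology
    plane; cortical-lesion voxels in red, normal-appearing cortex in blue."""
    from .coreg import extract_slab_plane

    ds = results.model.dataset
    plane = results.plane_index
    content = results.content.data
    roi2d = {
        name: m[:, plane, :] for name, m in results.roi_masks.items()
        if name in ("CL", "NAC")
    }
    fig, axes = plt.subplots(2, 2, figsize=(9, 8))
    qdict = {"t1": results.qmaps.t1, "t2": results.qmaps.t2,
             "m0": results.qmaps.m0, "mtr": results.qmaps.mtr}
    for ax, p in zip(axes.ravel(), params):
        qplane, _ = extract_slab_plane(qdict[p], plane, ds.spec.voxel_size)
        for name, color in (("NAC", "tab:blue"), ("CL", "tab:red")):
            sel = roi2d[name] & np.isfinite(qplane)
            ax.plot(content[sel], qplane[sel], ".", ms=2, color=color,
                    alpha=0.4, label=name)
        ax.set_xlabel("myelin (% area)")
        ax.set_ylabel(_PARAM_LABEL[p])
        ax.legend(markerscale=4, fontsize=8)
    fig.tight_layout()
    return fig


def plot_histograms(results, params=("t1", "t2", "m0", "mtr", "myelin")):
    """Normalized per-tissue histograms (NAC blue, CL red, whole cortex
    black outline)."""
    params = [p for p in params if p in results.histograms]
    fig, axes = plt.subplots(1, len(params), figsize=(3.2 * len(params), 3))
    if len(params) == 1:
        axes = [axes]
    for ax, p in zip(np.ravel(axes), params):
        groups = results.histograms[p]
        for name, color, kind in (
            ("NAC", "tab:blue", "fill"),
            ("CL", "tab:red", "fill"),
            ("cortex", "black", "line"),
        ):
            if name not in groups:
                continue
            h = groups[name]
            centers = 0.5 * (h.bin_edges[:-1] + h.bin_edges[1:])
            if kind == "fill":
                ax.fill_between(centers, h.frequencies, step="mid", alpha=0.4,
                                color=color, label=name)
            else:
                ax.step(centers, h.frequencies, where="mid", color=color,
                        lw=1.2, label=name)
        ax.set_xlabel(_PARAM_LABEL[p])
        ax.set_ylabel("frequency")
        ax.legend(fontsize=7)
    fig.tight_layout()
    return fig


def plot_depth_slice(results, param="t1", fraction=0.25, band=0.05):
    """Map of a fitted parameter restricted to one laminar depth band,
    rendered on the coronal histology plane."""
    from .coreg import extract_slab_plane

    ds = results.model.dataset
    plane = results.plane_index
    qdict = {"t1": results.qmaps.t1, "t2": results.qmaps.t2,
             "m0": results.qmaps.m0, "mtr": results.qmaps.mtr}
    qplane, _ = extract_slab_plane(qdict[param], plane, ds.spec.voxel_size)
    dplane, _ = extract_slab_plane(results.depth, plane, ds.spec.voxel_size)
    sel = np.isfinite(dplane) & (np.abs(dplane - fraction) <= band)
    shown = np.full(qplane.shape, np.nan)
    shown[sel] = qplane[sel]
    fig, ax = plt.subplots(figsize=(5, 5))
    im = ax.imshow(shown.T, origin="lower", cmap="inferno")
    fig.colorbar(im, ax=ax, label=_PARAM_LABEL[param])
    ax.set_title(f"{_PARAM_LABEL[param]} at {int(fraction * 100)}% cortical depth")
    fig.tight_layout()
    return fig
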