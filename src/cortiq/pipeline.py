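"""End-to-end analysis: model and results objects.

`CorticalQMRIModel` bundles a dataset (synthetic specimen or equivalent
real inputs) with an analysis configuration; its :meth:`fit` runs the full
chain — B1 mapping, DESPOT1/DESPOT2 relaxometry, MTR, banding exclusion,
cortical mask erosion, laminar depth field, slide segmentation and
down-sampling — and returns a `CorticalQMRIResults` carrying the fitted
maps, the per-tissue summary table, lesion-vs-normal group tests with
Bonferroni correction, qMR-vs-myelin correlations, normalized histograms,
laminar depth profiles and a voxel-count audit. Deterministic given the
dataset seed; ``results.save(outdir)`` writes a byte-reproducible report
bundle.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from . import __version__
from . import io as cio
from .coreg import extract_slab_plane
from .cortex import depth_summary, erode_mask_6conn
from .histology import DEFAULT_TAU, myelin_content_map, segment_myelin
from .phantom import CORTICAL, PhantomDataset, PhantomSpec, Tissue, generate_phantom
from .relaxometry import QMaps, compute_b1, fit_qmaps, upsample_b1
from .stats import (
    correlate,
    default_bin_edges,
    group_compare,
    normalized_histogram,
    roi_summaries,
)

__all__ = ["AnalysisConfig", "CorticalQMRIModel", "CorticalQMRIResults", "run_pipeline"]

#: Report/tissue naming used throughout: NAC (normal-appearing cortex),
#: CL (cortical lesion), NAWM (normal-appearing WM), WM_lesion.
ROI_LABELS = {
    "NAC": Tissue.CORTEX,
    "CL": Tissue.CORTICAL_LESION,
    "NAWM": Tissue.WM,
    "WM_lesion": Tissue.WM_LESION,
}
PARAMS = ("t1", "t2", "m0", "mtr", "myelin")


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable analysis choices (all defaults mirror the emulated study).

    erosion_iterations
        Passes of the 6-connectivity erosion of the cortical mask (one pass
        removes the single partial-volume boundary layer).
    b1_coarse_factor
        1 computes the B1 map on the native signal grid; k > 1 emulates a
        coarse B1 acquisition (k-fold down-sampled) with trilinear upsampling.
    """

    erosion_iterations: int = 1
    depth_fractions: tuple[float, ...] = (0.25, 0.5, 0.75)
    depth_band: float = 0.05
    histology_tau: float = DEFAULT_TAU
    banding_tol: float = 0.2
    n_bins: int = 64
    alpha: float = 0.05
    n_comparisons: int = 5
    equal_var: bool = True
    b1_coarse_factor: int = 1


class CorticalQMRIModel:
    """The analysis model: a dataset plus an analysis configuration.

    Construct from an existing :class:`~cortiq.phantom.PhantomDataset` or
    with :meth:`from_spec`, then call :meth:`fit`.
    """

    def __init__(self, dataset: PhantomDataset, config: Optional[AnalysisConfig] = None):
        self.dataset = dataset
        self.config = config or AnalysisConfig()

    @classmethod
    def from_spec(
        cls, spec: PhantomSpec, config: Optional[AnalysisConfig] = None
    ) -> "CorticalQMRIModel":
        """Generate the synthetic specimen described by ``spec`` and wrap it."""
        return cls(generate_phantom(spec), config)

    # -- fitting ------------------------------------------------------------

    def fit(self) -> "CorticalQMRIResults":
        ds, cfg = self.dataset, self.config
        signals = ds.signals

        # B1 transmit map from the double-angle pair
        if cfg.b1_coarse_factor > 1:
            f = cfg.b1_coarse_factor
            coarse = {}
            for key in ("dam_1", "dam_2"):
                vol = signals[key]
                small = ndimage.zoom(vol.data, 1.0 / f, order=1, mode="nearest",
                                     grid_mode=True)
                coarse[key] = dataclasses.replace(vol, data=small,
                                                  voxel_size=vol.voxel_size * f)
            b1 = compute_b1(coarse["dam_1"], coarse["dam_2"],
                            nominal_deg=signals["dam_1"].acquisition.flip_deg)
            b1 = upsample_b1(b1, signals["spgr_low"].data.shape)
        else:
            b1 = compute_b1(signals["dam_1"], signals["dam_2"],
                            nominal_deg=signals["dam_1"].acquisition.flip_deg)

        qmaps = fit_qmaps(signals, b1, banding_tol=cfg.banding_tol)

        # mask hygiene and depth
        cortical = ds.labels.mask(*CORTICAL)
        eroded = erode_mask_6conn(cortical, cfg.erosion_iterations)
        depth = ds.depth
        excluded = qmaps.excluded if qmaps.excluded is not None else np.zeros(
            cortical.shape, bool)
        all_valid = np.ones(cortical.shape, bool)
        for v in qmaps.valid.values():
            all_valid &= v
        usable = {p: qmaps.valid[p] & ~excluded for p in ("t1", "t2", "m0", "mtr")}

        # histology: slide -> binary fibers -> MR-resolution content map
        fibers = segment_myelin(ds.slide, tau=cfg.histology_tau)
        content = myelin_content_map(fibers, ds.spec.upsample_factor,
                                     pixel_size_mm=ds.spec.voxel_size)
        plane_idx = ds.slide_plane_index

        # ROI masks (3D); cortical ROIs get the eroded-mask hygiene
        roi3d = {}
        for name, tissue in ROI_LABELS.items():
            m = ds.labels.mask(tissue)
            if tissue in CORTICAL:
                m = m & eroded
            roi3d[name] = m

        qdict = {"t1": qmaps.t1, "t2": qmaps.t2, "m0": qmaps.m0, "mtr": qmaps.mtr}
        mr_summary = roi_summaries(qdict, roi3d, valid_masks=usable)

        # myelin summaries live on the histology plane
        content_mask = content.mask if content.mask is not None else np.ones(
            content.data.shape, bool)
        roi2d = {name: m[:, plane_idx, :] & content_mask for name, m in roi3d.items()}
        my_summary = roi_summaries({"myelin": content.data}, roi2d)
        summary = pd.concat([mr_summary, my_summary], ignore_index=True)

        # group comparisons: CL vs NAC and WM lesion vs NAWM, per parameter
        comparisons: dict[str, dict] = {}
        for pair_name, (ga, gb) in {
            "CL_vs_NAC": ("CL", "NAC"),
            "WMlesion_vs_NAWM": ("WM_lesion", "NAWM"),
        }.items():
            comparisons[pair_name] = {}
            for p in PARAMS:
                if p == "myelin":
                    va = content.data[roi2d[ga]]
                    vb = content.data[roi2d[gb]]
                else:
                    va = qdict[p][roi3d[ga] & usable[p]]
                    vb = qdict[p][roi3d[gb] & usable[p]]
                if va.size < 2 or vb.size < 2:
                    continue
                comparisons[pair_name][p] = group_compare(
                    va, vb, alpha=cfg.alpha, n_comparisons=cfg.n_comparisons,
                    equal_var=cfg.equal_var,
                )

        # voxel-wise correlations with myelin content on the eroded cortical
        # ribbon of the histology plane (CL + NAC)
        plane_ribbon = (roi2d["NAC"] | roi2d["CL"])
        correlations: dict[str, object] = {}
        for p in ("t1", "t2", "m0", "mtr"):
            qplane, _ = extract_slab_plane(qdict[p], plane_idx, ds.spec.voxel_size)
            uplane, _ = extract_slab_plane(
                usable[p].astype(np.uint8), plane_idx, ds.spec.voxel_size)
            sel = plane_ribbon & (uplane > 0)
            if int(sel.sum()) >= 3:
                correlations[p] = correlate(qplane[sel], content.data[sel])

        # normalized histograms per tissue and over the whole cortex
        histograms: dict[str, dict] = {}
        for p in PARAMS:
            if p == "myelin":
                groups = {
                    "CL": content.data[roi2d["CL"]],
                    "NAC": content.data[roi2d["NAC"]],
                    "cortex": content.data[plane_ribbon],
                }
            else:
                groups = {
                    "CL": qdict[p][roi3d["CL"] & usable[p]],
                    "NAC": qdict[p][roi3d["NAC"] & usable[p]],
                    "cortex": qdict[p][(roi3d["NAC"] | roi3d["CL"]) & usable[p]],
                }
            pooled = groups["cortex"]
            if pooled.size == 0:
                continue
            edges = default_bin_edges(pooled, cfg.n_bins)
            histograms[p] = {
                name: normalized_histogram(v, edges)
                for name, v in groups.items() if v.size
            }

        # laminar depth profiles of the fitted maps
        depth_profiles = {
            p: depth_summary(qdict[p], depth, cfg.depth_fractions, cfg.depth_band,
                             valid=usable[p])
            for p in ("t1", "t2", "m0", "mtr")
        }

        counts = {
            "cortical_voxels": int(cortical.sum()),
            "eroded_cortical_voxels": int(eroded.sum()),
            "erosion_removed": int(cortical.sum() - eroded.sum()),
            "banding_excluded": int(excluded.sum()),
            "banding_excluded_in_cortex": int((excluded & eroded).sum()),
            "invalid_any_fit": int((~all_valid).sum()),
        }

        return CorticalQMRIResults(
            model=self,
            b1=b1,
            qmaps=qmaps,
            content=content,
            plane_index=plane_idx,
            depth=depth,
            eroded_cortex=eroded,
            roi_masks=roi3d,
            summary_table=summary,
            comparisons=comparisons,
            correlations=correlations,
            histograms=histograms,
            depth_profiles=depth_profiles,
            counts=counts,
        )


@dataclass
class CorticalQMRIResults:
    """Fitted maps, statistics and diagnostics of one analysis run."""

    model: CorticalQMRIModel
    b1: object
    qmaps: QMaps
    content: object
    plane_index: int
    depth: np.ndarray
    eroded_cortex: np.ndarray
    roi_masks: dict
    summary_table: pd.DataFrame
    comparisons: dict
    correlations: dict
    histograms: dict
    depth_profiles: dict
    counts: dict
    extra: dict = field(default_factory=dict)

    # -- presentation --------------------------------------------------------

    def tissue_table(self) -> pd.DataFrame:
        """Wide per-tissue table: mean (SD) per parameter, Table-1 style."""
        tab = self.summary_table.pivot(index="parameter", columns="roi",
                                       values=["mean", "sd", "n"])
        order = [p for p in PARAMS if p in tab.index]
        return tab.loc[order]

    def summary(self) -> str:
        lines = [
            f"cortiq {__version__} — cortical quantitative MRI analysis",
            "",
            "Per-tissue summaries (mean, SD, n):",
        ]
        wide = self.summary_table.pivot(index="parameter", columns="roi", values="mean")
        sds = self.summary_table.pivot(index="parameter", columns="roi", values="sd")
        ns = self.summary_table.pivot(index="parameter", columns="roi", values="n")
        cols = [c for c in ("NAC", "CL", "NAWM", "WM_lesion") if c in wide.columns]
        units = {"t1": "ms", "t2": "ms", "m0": "r.u.", "mtr": "%", "myelin": "% area"}
        header = f"  {'parameter':<14}" + "".join(f"{c:>18}" for c in cols)
        lines.append(header)
        for p in PARAMS:
            if p not in wide.index:
                continue
            cells = []
            for c in cols:
                m, s = wide.loc[p, c], sds.loc[p, c]
                cells.append(f"{m:9.2f} ({s:6.2f})" if np.isfinite(m) else "      —  ")
            lines.append(f"  {p + ' [' + units[p] + ']':<14}" + "".join(
                f"{cell:>18}" for cell in cells))
        lines.append("")
        lines.append("Group comparisons (two-sided t, Bonferroni-corrected):")
        for pair, res in self.comparisons.items():
            for p, r in res.items():
                star = "*" if r.significant else " "
                lines.append(
                    f"  {pair:<18} {p:<7} t = {r.t:9.2f}  p_corr = {r.p_corrected:.3g} {star}"
                )
        lines.append("")
        lines.append("Correlations with myelin content (histology plane):")
        for p, r in self.correlations.items():
            if r.undefined:
                lines.append(f"  {p:<7} undefined (zero variance)")
            else:
                lines.append(
                    f"  {p:<7} r = {r.pearson_r:+.3f}  rho = {r.spearman_rho:+.3f}"
                    f"  (n = {r.n})"
                )
        lines.append("")
        lines.append("Voxel audit: " + ", ".join(
            f"{k} = {v}" for k, v in sorted(self.counts.items())))
        return "\n".join(lines)

    def report_dict(self) -> dict:
        """JSON-serializable report (deterministic given the dataset seed)."""
        hist = {
            p: {
                grp: {
                    "bin_edges": h.bin_edges.tolist(),
                    "frequencies": h.frequencies.tolist(),
                    "underflow": h.underflow,
                    "overflow": h.overflow,
                    "n": h.n,
                }
                for grp, h in groups.items()
            }
            for p, groups in self.histograms.items()
        }
        return {
            "software": {"name": "cortiq", "version": __version__},
            "seed": self.model.dataset.spec.seed,
            "config": dataclasses.asdict(self.model.config),
            "phantom_spec": cio.spec_to_dict(self.model.dataset.spec),
            "summaries": self.summary_table.to_dict(orient="records"),
            "comparisons": {
                pair: {p: r.as_dict() for p, r in res.items()}
                for pair, res in self.comparisons.items()
            },
            "correlations": {p: r.as_dict() for p, r in self.correlations.items()},
            "histograms": hist,
            "depth_profiles": {
                p: tab.to_dict(orient="records") for p, tab in self.depth_profiles.items()
            },
            "counts": self.counts,
        }

    def save(self, outdir) -> dict:
        """Write the full bundle: fitted NIfTI maps, content map, tables,
        JSON report and a provenance manifest. Returns the file map."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        vox = self.model.dataset.spec.voxel_size
        files = {}
        for name, arr in (
            ("t1", self.qmaps.t1),
            ("t2", self.qmaps.t2),
            ("m0", self.qmaps.m0),
            ("mtr", self.qmaps.mtr),
            ("b1", self.b1.data),
            ("depth", self.depth),
            ("excluded", self.qmaps.excluded.astype(np.uint8)),
            ("eroded_cortex", self.eroded_cortex.astype(np.uint8)),
        ):
            files[name] = str(cio.save_nifti(arr, vox, outdir / f"{name}.nii"))
        files["myelin_content"] = str(
            cio.save_content_map(self.content, outdir / "myelin_content.tif"))
        self.summary_table.to_csv(outdir / "summaries.csv", index=False)
        files["summaries"] = str(outdir / "summaries.csv")
        for p, tab in self.depth_profiles.items():
            tab.to_csv(outdir / f"depth_profile_{p}.csv", index=False)
            files[f"depth_profile_{p}"] = str(outdir / f"depth_profile_{p}.csv")
        with open(outdir / "report.json", "w") as fh:
            json.dump(self.report_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        files["report"] = str(outdir / "report.json")
        # manifest records paths relative to the bundle so reruns into any
        # directory produce identical bytes
        cio.write_manifest(
            {
                "software": {"name": "cortiq", "version": __version__},
                "seed": self.model.dataset.spec.seed,
                "files": {k: Path(v).name for k, v in files.items()},
                "acquisitions": {
                    k: dataclasses.asdict(v.acquisition)
                    for k, v in self.model.dataset.signals.items()
                },
            },
            outdir / "manifest.json",
        )
        files["manifest"] = str(outdir / "manifest.json")
        return files


def run_pipeline(
    spec: PhantomSpec,
    config: Optional[AnalysisConfig] = None,
    outdir=None,
) -> CorticalQMRIResults:
    """Generate the specimen, run the full analysis and optionally save.

    Deterministic given ``spec`` (every random stream derives from
    ``spec.seed``); rerunning with the same spec and output directory
    rewrites byte-identical report files.
    """
    results = CorticalQMRIModel.from_spec(spec, config).fit()
    if outdir is not None:
        results.save(outdir)
    return results
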