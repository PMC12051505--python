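"""End-to-end demo pipeline: simulate -> reconstruct -> clean -> score.

The protocol mirrors the simulation study design: a phantom inside a
+-12.8 mm box is imaged by a uniform spherical array; the reconstruction from
the *full* array is the reference, a 4x uniformly down-sampled array gives
the artifact-contaminated input ``recon0``, and two random subsets (~78% of
the sparse detectors) give the training pair.  Cleaning runs slice by slice;
PSNR/SSIM are reported before and after against the reference, per slice and
on the maximum amplitude projection.

One global seed fans out to phantom, subset and training seeds through
``numpy.random.SeedSequence`` spawn keys, so every random draw is traceable
and a rerun is byte-identical.
"""

from __future__ import annotations

import contextlib
import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .forward import (DEFAULT_DT, SPEED_OF_SOUND, restrict_channels,
                      save_channels, simulate_channels)
from .geometry import (ReconGrid, make_simple_phantom, make_spherical_array,
                       make_vessel_phantom, uniform_downsample)
from .metrics import map_projection, psnr, ssim
from .model import TrainConfig, run_zsa2a_slicewise, sample_subset
from .recon import extract_slices, save_nifti, save_tiff, ubp_backproject

__all__ = ["PipelineConfig", "DemoResult", "run_demo", "derive_seeds"]


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to run the demo pipeline, seeded by one integer.

    The default is the desk-scale protocol: a 512-element sphere down-sampled
    4x to 128 elements, two random subsets of 100 (~78%), reconstructed on a
    128x128x16 grid at 0.2 mm covering the central slab of the +-12.8 mm
    field of view.
    """

    n_detectors: int = 512
    radius: float = 60.0
    coverage: str = "full_sphere"
    phantom_kind: str = "vessel"  # "vessel" | "simple"
    n_branches: int = 6
    fov_half: float = 12.8
    # half-extent of the phantom's box per axis; None = the full FOV cube.
    # Scaled configs that reconstruct only a z-slab confine the phantom to
    # that slab so the reconstructed volume contains the imaged structure
    # (as in the full-scale protocol, where the grid covers the whole cube).
    phantom_box_half: tuple | None = None
    # clean and score only this many central slices of the reconstructed
    # slab (None = all); the full-scale study scores one representative
    # slice of the volume, which this emulates at reduced cost
    process_slices: int | None = None
    sparse_m: int = 128
    subset_size: int = 100
    n_subsets: int = 2
    grid_shape: tuple = (128, 128, 16)
    grid_spacing: float = 0.2
    axis: str = "z"
    c: float = SPEED_OF_SOUND
    dt: float = DEFAULT_DT
    noise_std: float = 0.0
    train: TrainConfig = dataclasses.field(default_factory=TrainConfig)
    seed: int = 0

    def replace(self, **kw) -> "PipelineConfig":
        return dataclasses.replace(self, **kw)

    @classmethod
    def full_scale(cls, **kw) -> "PipelineConfig":
        """The full-scale simulation protocol: 2048 -> 512 detectors, subsets
        of 400, 0.1 mm grid over the whole 25.6 mm cube.  Heavy; hours of CPU."""
        base = dict(n_detectors=2048, sparse_m=512, subset_size=400,
                    grid_shape=(256, 256, 256), grid_spacing=0.1)
        base.update(kw)
        return cls(**base)

    @classmethod
    def bench_scale(cls, **kw) -> "PipelineConfig":
        """Reduced protocol sized for a single CPU: same 4x sparsification
        and ~78% subsets, full in-plane field of view at 0.2 mm on a z-slab
        that contains the phantom, 1000 training iterations, and cleaning /
        scoring of the central slice."""
        base = dict(grid_shape=(128, 128, 12), grid_spacing=0.2,
                    phantom_box_half=(12.8, 12.8, 1.2), process_slices=1,
                    train=TrainConfig(iterations=1000))
        base.update(kw)
        return cls(**base)

    @classmethod
    def mini_scale(cls, **kw) -> "PipelineConfig":
        """Tiny smoke-test configuration (seconds)."""
        base = dict(n_detectors=128, sparse_m=32, subset_size=25,
                    grid_shape=(32, 32, 2), grid_spacing=0.8, n_branches=3,
                    phantom_box_half=(12.8, 12.8, 0.8),
                    train=TrainConfig(iterations=60))
        base.update(kw)
        return cls(**base)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        if self.phantom_box_half is not None:
            d["phantom_box_half"] = list(self.phantom_box_half)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "train" in d and isinstance(d["train"], dict):
            d["train"] = TrainConfig(**d["train"])
        if "grid_shape" in d:
            d["grid_shape"] = tuple(d["grid_shape"])
        if d.get("phantom_box_half") is not None:
            d["phantom_box_half"] = tuple(d["phantom_box_half"])
        return cls(**d)


def derive_seeds(seed: int) -> dict:
    """Fan one global seed out into independent 31-bit child seeds."""
    ss = np.random.SeedSequence(seed)
    kids = ss.spawn(3)
    return {name: int(k.generate_state(1)[0] & 0x7FFFFFFF)
            for name, k in zip(("phantom", "subsets", "train"), kids)}


@dataclasses.dataclass
class DemoResult:
    """Outputs of one demo run: the score table, headline numbers and the
    in-memory volumes (reference / recon0 / recon1 / recon2 / clean /
    artifact)."""

    metrics: pd.DataFrame
    psnr_gain_slice: float
    psnr_gain_map: float
    out_dir: Path | None
    volumes: dict = dataclasses.field(default_factory=dict, repr=False)

    def summary(self) -> str:
        m = self.metrics
        mean = m[m.kind == "slice_mean"].iloc[0]
        mp = m[m.kind == "map"].iloc[0]
        lines = [
            "Demo pipeline — artifact removal scores vs dense reference",
            "-" * 58,
            f"mean slice PSNR  before / after : {mean.psnr_before:7.2f} / "
            f"{mean.psnr_after:7.2f} dB   (gain {self.psnr_gain_slice:+.2f} dB)",
            f"mean slice SSIM  before / after : {mean.ssim_before:7.4f} / "
            f"{mean.ssim_after:7.4f}",
            f"MAP PSNR         before / after : {mp.psnr_before:7.2f} / "
            f"{mp.psnr_after:7.2f} dB   (gain {self.psnr_gain_map:+.2f} dB)",
            f"MAP SSIM         before / after : {mp.ssim_before:7.4f} / "
            f"{mp.ssim_after:7.4f}",
        ]
        return "\n".join(lines)


@contextlib.contextmanager
def _stage(name: str):
    try:
        yield
    except Exception as e:
        raise RuntimeError(f"demo stage '{name}' failed: {e}") from e


def _safe_psnr(ref, test):
    r = np.asarray(ref, dtype=float)
    if r.max() <= 0:
        return float("nan")
    return psnr(r, test)


def _safe_ssim(ref, test):
    r = np.asarray(ref, dtype=float)
    if r.max() - r.min() == 0:
        return float("nan")
    return ssim(r, test)


def run_demo(config: PipelineConfig, out_dir: str | Path | None = None,
             write_volumes: bool = True) -> DemoResult:
    """Run the full protocol and (optionally) write all artifacts to disk."""
    seeds = derive_seeds(config.seed)

    with _stage("simulate"):
        array = make_spherical_array(config.n_detectors, config.radius,
                                     config.coverage)
        half = np.asarray(config.phantom_box_half
                          if config.phantom_box_half is not None
                          else (config.fov_half,) * 3, dtype=float)
        box = np.stack([-half, half])
        if config.phantom_kind == "vessel":
            phantom = make_vessel_phantom(seeds["phantom"], config.n_branches, box)
        elif config.phantom_kind == "simple":
            phantom = make_simple_phantom(seeds["phantom"], box=box)
        else:
            raise ValueError(f"unknown phantom kind {config.phantom_kind!r}")
        data = simulate_channels(phantom, array, dt=config.dt, c=config.c,
                                 noise_std=config.noise_std,
                                 noise_seed=seeds["phantom"])

    grid = ReconGrid.centered(config.grid_shape, config.grid_spacing)

    with _stage("reconstruct_reference"):
        ref = ubp_backproject(data, array, grid, config.c, provenance="full")

    with _stage("reconstruct_sparse"):
        stride_idx = (np.arange(config.sparse_m) * config.n_detectors
                      ) // config.sparse_m
        sparse_array = uniform_downsample(array, config.sparse_m)
        sparse_data = restrict_channels(data, stride_idx)
        recon0 = ubp_backproject(sparse_data, sparse_array, grid, config.c)

    with _stage("reconstruct_subsets"):
        subset_recons = []
        subsets = []
        for j in range(1, config.n_subsets + 1):
            sub = sample_subset(config.sparse_m, config.subset_size,
                                seed=seeds["subsets"], label=j)
            subsets.append(sub)
            sub_array = type(array)(sparse_array.positions[sub.indices],
                                    array.radius, array.coverage)
            sub_data = restrict_channels(sparse_data, sub)
            subset_recons.append(
                ubp_backproject(sub_data, sub_array, grid, config.c,
                                provenance=f"subset{min(j, 2)}"))

    ax = {"x": 0, "y": 1, "z": 2}[config.axis]
    if config.process_slices is not None and \
            config.process_slices < grid.shape[ax]:
        with _stage("select_slices"):
            k = config.process_slices
            lo = (grid.shape[ax] - k) // 2
            shape = list(grid.shape)
            shape[ax] = k
            origin = list(grid.origin)
            origin[ax] += lo * grid.spacing
            sub_grid = ReconGrid(tuple(origin), grid.spacing, tuple(shape))
            sel = [slice(None)] * 3
            sel[ax] = slice(lo, lo + k)
            sel = tuple(sel)

            def crop(img):
                from .recon import ReconImage
                return ReconImage(img.values[sel], sub_grid, img.provenance)

            ref = crop(ref)
            recon0 = crop(recon0)
            subset_recons = [crop(r) for r in subset_recons]

    with _stage("zsa2a"):
        train_cfg = config.train.replace(seed=seeds["train"],
                                         n_subsets=config.n_subsets,
                                         subset_size=config.subset_size)
        dec, histories = run_zsa2a_slicewise(
            recon0, subset_recons[0], subset_recons[1], config.axis, train_cfg,
            extra_volumes=subset_recons[2:], return_losses=True)

    with _stage("metrics"):
        rows = []
        ref_slices = extract_slices(ref, config.axis)
        before_slices = extract_slices(recon0, config.axis)
        after_slices = extract_slices(dec.clean, config.axis)
        for k, (r, b, a) in enumerate(zip(ref_slices, before_slices, after_slices)):
            rows.append({"kind": "slice", "index": k,
                         "psnr_before": _safe_psnr(r.values, b.values),
                         "psnr_after": _safe_psnr(r.values, a.values),
                         "ssim_before": _safe_ssim(r.values, b.values),
                         "ssim_after": _safe_ssim(r.values, a.values)})
        frame = pd.DataFrame(rows)
        mean_row = {"kind": "slice_mean", "index": -1}
        for col in ("psnr_before", "psnr_after", "ssim_before", "ssim_after"):
            mean_row[col] = float(np.nanmean(frame[col].to_numpy()))
        ref_map = map_projection(ref.values, config.axis)
        map_row = {"kind": "map", "index": -1,
                   "psnr_before": _safe_psnr(ref_map, map_projection(recon0.values, config.axis)),
                   "psnr_after": _safe_psnr(ref_map, map_projection(dec.clean.values, config.axis)),
                   "ssim_before": _safe_ssim(ref_map, map_projection(recon0.values, config.axis)),
                   "ssim_after": _safe_ssim(ref_map, map_projection(dec.clean.values, config.axis))}
        frame = pd.concat([frame, pd.DataFrame([mean_row, map_row])],
                          ignore_index=True)

    result = DemoResult(
        metrics=frame,
        psnr_gain_slice=float(mean_row["psnr_after"] - mean_row["psnr_before"]),
        psnr_gain_map=float(map_row["psnr_after"] - map_row["psnr_before"]),
        out_dir=Path(out_dir) if out_dir is not None else None,
        volumes={"reference": ref, "recon0": recon0,
                 "recon1": subset_recons[0], "recon2": subset_recons[1],
                 "clean": dec.clean, "artifact": dec.artifact})

    if out_dir is not None:
        with _stage("write_outputs"):
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            frame.to_csv(out / "metrics.csv", index=False)
            loss_frames = []
            for k, h in enumerate(histories):
                f = h.to_frame()
                f.insert(0, "slice", k)
                loss_frames.append(f)
            pd.concat(loss_frames, ignore_index=True).to_csv(
                out / "losses.csv", index=False)
            if write_volumes:
                save_channels(data, out / "channels.h5", array)
                for name, img in (("reference", ref), ("recon0", recon0),
                                  ("recon1", subset_recons[0]),
                                  ("recon2", subset_recons[1]),
                                  ("clean", dec.clean),
                                  ("artifact", dec.artifact)):
                    save_tiff(img, out / f"{name}.tiff")
                    save_nifti(img, out / f"{name}.nii.gz")
            provenance = {
                "config": config.to_dict(),
                "derived_seeds": seeds,
                "subsets": [s.indices.tolist() for s in subsets],
                "versions": {"zsa2a": __version__, "numpy": np.__version__},
            }
            (out / "provenance.json").write_text(json.dumps(provenance, indent=1))

    return result
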