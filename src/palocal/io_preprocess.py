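"""Readers/writers, fixed preprocessing steps, and dataset assembly.

Preprocessing mirrors the acquisition pipelines: volumetric OR-PAM stacks are
downsampled 4x along the acoustic axis with bicubic antialiased resampling
(the axial resolution limit far exceeds the 3 µm sampling, so 12 µm voxels
lose no structure), and planar PACT images are reduced from their native
2000 x 2400 grid to 896 x 1024 before cropping.

Volumes round-trip through NIfTI (voxel sizes in the header, µm) or
multi-page TIFF (bit-exact for 32-bit floats); frame series and paired
training sets round-trip through HDF5 bundles that carry full provenance
(seed + generation parameters), sufficient to regenerate them bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import tifffile
from skimage.transform import resize as _sk_resize

from . import phantom, localization
from .training import PairedSample

__all__ = [
    "FormatError", "DatasetBundle", "downsample_axial", "resize_2d",
    "assemble_splits", "write_volume", "read_volume",
    "write_series_h5", "read_series_h5", "write_pairs_h5", "read_pairs_h5",
    "generate_paired_samples",
]


class FormatError(ValueError):
    """A file could not be parsed; the message names the offending field."""


@dataclass
class DatasetBundle:
    """A named split of paired samples with regeneration provenance."""

    name: str
    samples: list[PairedSample]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.samples)


# ---------------------------------------------------------------------------
# fixed preprocessing
# ---------------------------------------------------------------------------

def downsample_axial(volume: np.ndarray, factor: int = 4) -> np.ndarray:
    """Bicubic antialiased downsampling along the axial (last) axis.

    The lateral axes are untouched. The axial size must be divisible by
    `factor` (256 acoustic samples -> 64 working voxels at the default).
    """
    volume = np.asarray(volume, dtype=np.float64)
    if volume.ndim != 3:
        raise ValueError("downsample_axial expects a 3D volume")
    nz = volume.shape[2]
    if nz % factor:
        raise ValueError(f"axial size {nz} not divisible by factor {factor}")
    out_shape = volume.shape[:2] + (nz // factor,)
    return _sk_resize(volume, out_shape, order=3, anti_aliasing=True,
                      mode="reflect", preserve_range=True)


def resize_2d(image: np.ndarray, target: tuple[int, int] = (896, 1024)) -> np.ndarray:
    """Bicubic antialiased reduction of a 2D image to `target` (no upscaling).

    Axes scale independently (source and target aspect ratios may differ).
    Resizing to the source size returns the image unchanged.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("resize_2d expects a 2D image")
    if tuple(target) == image.shape:
        return image.copy()
    if any(t > s for t, s in zip(target, image.shape)):
        raise ValueError(f"target {tuple(target)} exceeds source {image.shape}; "
                         "only reduction is supported")
    return _sk_resize(image, tuple(target), order=3, anti_aliasing=True,
                      mode="reflect", preserve_range=True)


def assemble_splits(samples: list, fractions: tuple[float, ...], seed: int,
                    names: tuple[str, ...] = ("train", "val", "test"),
                    provenance: dict | None = None) -> dict[str, DatasetBundle]:
    """Seeded, disjoint, size-stable splits of a sample list.

    Sizes are floor(fraction * n) with the remainder assigned by largest
    fractional part (earlier splits win ties), so (0.8, 0.1, 0.1) on 10
    samples gives 8/1/1.
    """
    if not samples:
        raise ValueError("sample list must not be empty")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    if len(fractions) > len(names):
        raise ValueError("more fractions than split names")
    n = len(samples)
    raw = [f * n for f in fractions]
    sizes = [int(np.floor(r)) for r in raw]
    remainder = n - sum(sizes)
    order = sorted(range(len(fractions)),
                   key=lambda i: (-(raw[i] - sizes[i]), i))
    for i in order[:remainder]:
        sizes[i] += 1
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    out: dict[str, DatasetBundle] = {}
    start = 0
    prov = dict(provenance or {})
    prov.update({"split_seed": seed, "fractions": list(fractions)})
    for name, size in zip(names, sizes):
        idx = perm[start:start + size]
        out[name] = DatasetBundle(name, [samples[i] for i in idx], dict(prov))
        start += size
    return out


# ---------------------------------------------------------------------------
# volumes / images on disk
# ---------------------------------------------------------------------------

def write_volume(path, array: np.ndarray, voxel_size: tuple[float, ...] | None = None) -> None:
    """Write an array as NIfTI (.nii/.nii.gz, voxel sizes in µm) or TIFF."""
    path = Path(path)
    data = np.asarray(array, dtype=np.float32)
    if path.suffix == ".gz" or path.suffix == ".nii":
        affine = np.eye(4)
        if voxel_size is not None:
            for i, v in enumerate(voxel_size[:3]):
                affine[i, i] = v
        img = nib.Nifti1Image(data, affine)
        if voxel_size is not None:
            img.header.set_zooms(tuple(voxel_size[: data.ndim]))
        nib.save(img, str(path))
    elif path.suffix in (".tif", ".tiff"):
        tifffile.imwrite(str(path), data)
    else:
        raise ValueError(f"unsupported volume format: {path.suffix}")


def read_volume(path) -> tuple[np.ndarray, tuple[float, ...] | None]:
    """Read a NIfTI or TIFF volume; returns (array, voxel sizes or None)."""
    path = Path(path)
    try:
        if path.suffix == ".gz" or path.suffix == ".nii":
            img = nib.load(str(path))
            return np.asarray(img.dataobj, dtype=np.float32), tuple(
                float(z) for z in img.header.get_zooms())
        if path.suffix in (".tif", ".tiff"):
            return tifffile.imread(str(path)), None
    except Exception as exc:  # noqa: BLE001 - map any parser failure
        raise FormatError(f"cannot read volume file {path}: {exc}") from exc
    raise ValueError(f"unsupported volume format: {path.suffix}")


# ---------------------------------------------------------------------------
# HDF5 bundles
# ---------------------------------------------------------------------------

def write_series_h5(path, series: phantom.FrameSeries,
                    events: list[phantom.AbsorberEvent] | None = None,
                    provenance: dict | None = None) -> None:
    """Bundle a frame series (+ optional ground-truth events) into HDF5.

    Layout: /frames (F, *grid) float32, /events (n, dim+2) float64 rows of
    (position..., amplitude, frame_index), /config attrs.
    """
    with h5py.File(path, "w") as f:
        f.create_dataset("frames", data=np.stack(series.frames).astype(np.float32))
        cfg = f.create_group("config")
        cfg.attrs["shape"] = series.config.shape
        cfg.attrs["pixel_size"] = series.config.pixel_size
        cfg.attrs["psf_fwhm"] = series.config.psf_fwhm
        cfg.attrs["noise_std"] = series.config.noise_std
        cfg.attrs["background"] = series.config.background
        cfg.attrs["per_frame_time"] = series.per_frame_time
        if events is not None:
            rows = np.array([list(e.position) + [e.amplitude, e.frame_index]
                             for e in events], dtype=np.float64)
            f.create_dataset("events", data=rows.reshape(len(events), -1))
        if provenance:
            f.attrs["provenance"] = json.dumps(provenance)


def read_series_h5(path):
    """Read a frame-series bundle; returns (FrameSeries, events, provenance)."""
    try:
        with h5py.File(path, "r") as f:
            if "frames" not in f:
                raise FormatError(f"{path}: missing /frames dataset")
            if "config" not in f:
                raise FormatError(f"{path}: missing /config group")
            cfg = f["config"].attrs
            for key in ("shape", "pixel_size", "psf_fwhm"):
                if key not in cfg:
                    raise FormatError(f"{path}: /config missing attribute '{key}'")
            config = phantom.ImagingConfig(
                tuple(int(n) for n in cfg["shape"]),
                tuple(float(v) for v in cfg["pixel_size"]),
                tuple(float(v) for v in cfg["psf_fwhm"]),
                noise_std=float(cfg.get("noise_std", 0.0)),
                background=float(cfg.get("background", 0.0)),
            )
            frames = [np.asarray(a, dtype=np.float64) for a in f["frames"][...]]
            series = phantom.FrameSeries(frames, config,
                                         float(cfg.get("per_frame_time", 0.5)))
            events = None
            if "events" in f:
                dim = len(config.shape)
                events = [
                    phantom.AbsorberEvent(tuple(row[:dim]), float(row[dim]),
                                          int(row[dim + 1]))
                    for row in f["events"][...]
                ]
            prov = json.loads(f.attrs["provenance"]) if "provenance" in f.attrs else {}
            return series, events, prov
    except FormatError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"cannot read series bundle {path}: {exc}") from exc


def write_pairs_h5(path, bundles: dict[str, DatasetBundle]) -> None:
    """Write paired sparse/dense samples per split: /<split>/x_i, /<split>/y_i."""
    with h5py.File(path, "w") as f:
        for name, bundle in bundles.items():
            grp = f.create_group(name)
            grp.attrs["provenance"] = json.dumps(bundle.provenance)
            for i, s in enumerate(bundle.samples):
                grp.create_dataset(f"x{i}", data=s.x.astype(np.float32))
                grp.create_dataset(f"y{i}", data=s.y.astype(np.float32))


def read_pairs_h5(path) -> dict[str, DatasetBundle]:
    try:
        out: dict[str, DatasetBundle] = {}
        with h5py.File(path, "r") as f:
            for name in f:
                grp = f[name]
                n = sum(1 for k in grp if k.startswith("x"))
                samples = []
                for i in range(n):
                    if f"y{i}" not in grp:
                        raise FormatError(f"{path}: /{name}/y{i} missing")
                    samples.append(PairedSample(
                        np.asarray(grp[f"x{i}"], dtype=np.float64),
                        np.asarray(grp[f"y{i}"], dtype=np.float64)))
                prov = (json.loads(grp.attrs["provenance"])
                        if "provenance" in grp.attrs else {})
                out[name] = DatasetBundle(name, samples, prov)
        return out
    except FormatError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"cannot read pairs bundle {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# synthetic paired-dataset assembly (desk-scale study conditions)
# ---------------------------------------------------------------------------

def generate_paired_samples(
    n_pairs: int,
    seed: int,
    *,
    grid: int = 64,
    n_frames: int = 60,
    absorbers_per_frame: int = 12,
    reduction: float = 12.0,
    unit: str = "events",
    noise_std: float = 0.02,
    depth: int = 3,
) -> list[PairedSample]:
    """Generate 2D sparse/dense localization pairs from random vessel phantoms.

    Runs the full pipeline per pair: grow a vessel tree, simulate a regular
    planar acquisition of `n_frames` frames with flowing absorbers, localize
    every frame, then superimpose all localizations (dense target) and a
    random 1/`reduction` subset (sparse input). Images are `grid` x `grid`
    with 25 µm pixels. Phantoms that yield no localizations are skipped and
    replaced from the same seeded stream, so exactly `n_pairs` samples are
    returned (up to a bounded number of retries).
    """
    rng = np.random.default_rng(seed)
    region = (grid * 25.0, grid * 25.0)
    config = phantom.ImagingConfig((grid, grid), (25.0, 25.0), (125.0, 125.0),
                                   noise_std=noise_std)
    pairs: list[PairedSample] = []
    attempts = 0
    while len(pairs) < n_pairs and attempts < 2 * n_pairs + 10:
        attempts += 1
        sub = int(rng.integers(0, 2**31 - 1))
        tree = phantom.generate_vessel_tree(region, 2, depth, sub,
                                            root_radius=45.0, root_length=900.0)
        series = phantom.render_series(tree, n_frames, absorbers_per_frame,
                                       config, seed=sub, mean_step=60.0)
        event_sets = localization.localize_series(
            series, amplitude_threshold=0.25, min_separation=2.0,
            window=7, dog_sigma=2.0)
        n_events = sum(len(es) for es in event_sets)
        if n_events == 0:
            continue
        dense = localization.make_dense(event_sets, superres_factor=1, mode="sum")
        if unit == "events":
            k = max(1, int(round(n_events / reduction)))
        else:
            k = max(1, int(round(len(event_sets) / reduction)))
        sparse = localization.make_sparse(event_sets, k, sub, superres_factor=1,
                                          mode="sum", unit=unit)
        pairs.append(PairedSample(sparse.data[None], dense.data[None]))
    return pairs
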