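"""Synthetic brain-tumor-like phantoms in a source and a shifted target domain.

The generator produces 2-D multi-channel images with nested multi-class
label maps that mimic the structure of multi-modal brain-tumor MRI slices:
class 0 is background, class 1 a necrotic-core-like region (CoreT), class 2
an enhancing-tumor-like ring (EnhT), and class 3 a peritumoral-edema-like
outer ring (ED); the whole tumor (WholeT) is the union of classes 1-3.

Two domain-shift regimes are modeled after the two standard UDA protocols
for brain tumor segmentation:

* cross-subtype — the target domain draws smaller/differently placed tumor
  regions (``region_scale_factor``) with a mild intensity shift, analogous
  to high-grade vs. low-grade glioma populations;
* cross-modality — single-channel images whose target rendering applies a
  monotone intensity nonlinearity and inverted contrast, analogous to a
  T1-weighted vs. T2-weighted shift.

An optional reader extracts normalized 2-D slices from real NIfTI volumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage


# --------------------------------------------------------------------------
# specs and parameters
# --------------------------------------------------------------------------


@dataclass
class PhantomSpec:
    """Geometry of the phantom images and their nested tumor regions.

    ``region_radius_mean`` gives the mean radius (pixels) of each
    non-background class, innermost first; with nesting on, class ``c`` is
    painted where the (elliptical) distance to the tumor center is at most
    its radius and greater than all smaller radii.
    """

    image_height: int = 64
    image_width: int = 64
    n_channels: int = 4
    n_classes: int = 4
    region_radius_mean: tuple[float, ...] = (7.0, 12.0, 18.0)
    region_radius_sd: float = 2.0
    nesting: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if len(self.region_radius_mean) != self.n_classes - 1:
            raise ValueError(
                "region_radius_mean must have one entry per non-background class"
            )
        if any(r < 0 for r in self.region_radius_mean):
            raise ValueError("radii must be nonnegative")
        if self.region_radius_sd < 0:
            raise ValueError("region_radius_sd must be >= 0")


@dataclass
class DomainParams:
    """Rendering parameters of one domain.

    The rendering pipeline is: per-class base intensities -> gamma
    nonlinearity -> gain/offset -> channel mixing -> Gaussian blur ->
    additive Gaussian noise.  ``region_scale_factor`` multiplies the label
    radii (cross-subtype shift); ``channel_mixer`` linearly recombines
    channels (cross-modality shift).
    """

    offset: float = 0.0
    gain: float = 1.0
    gamma_exponent: float = 1.0
    noise_sd: float = 0.0
    blur_sigma: float = 0.0
    region_scale_factor: float = 1.0
    channel_mixer: np.ndarray | None = None

    def __post_init__(self):
        vals = [self.offset, self.gain, self.gamma_exponent, self.noise_sd,
                self.blur_sigma, self.region_scale_factor]
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("DomainParams values must be finite")
        if self.gain <= 0:
            raise ValueError("gain must be > 0")
        if self.gamma_exponent <= 0:
            raise ValueError("gamma_exponent must be > 0")
        if self.noise_sd < 0 or self.blur_sigma < 0:
            raise ValueError("noise_sd and blur_sigma must be >= 0")
        if self.region_scale_factor <= 0:
            raise ValueError("region_scale_factor must be > 0")
        if self.channel_mixer is not None:
            self.channel_mixer = np.asarray(self.channel_mixer, dtype=float)
            if not np.all(np.isfinite(self.channel_mixer)):
                raise ValueError("channel_mixer must be finite")


def source_domain_default() -> DomainParams:
    """Rendering used for the labeled source domain."""
    return DomainParams(noise_sd=0.04, blur_sigma=0.6)


def cross_subtype_target_default() -> DomainParams:
    """Smaller tumors + moderate intensity shift (HGG->LGG-like).

    Calibrated so that a converged source model stays confident on target
    images but loses a substantial fraction of its overlap score — the
    regime black-box adaptation addresses.
    """
    return DomainParams(
        offset=0.08,
        gain=0.85,
        gamma_exponent=1.5,
        noise_sd=0.07,
        blur_sigma=1.0,
        region_scale_factor=0.6,
    )


def cross_modality_target_default() -> DomainParams:
    """Monotone nonlinearity + inverted contrast (T1<->T2-like).

    With the -1 mixer and -1 offset the rendered intensity is
    ``1 - base**gamma``: bright regions become dark and vice versa.
    """
    return DomainParams(
        offset=-1.0,
        gamma_exponent=1.5,
        noise_sd=0.05,
        blur_sigma=0.6,
        channel_mixer=np.array([[-1.0]]),
    )


# --------------------------------------------------------------------------
# label and image generation
# --------------------------------------------------------------------------


def base_intensity_table(spec: PhantomSpec) -> np.ndarray:
    """Per-(class, channel) base intensities; fixed given the spec shape.

    Channel 0 carries a graded whole-lesion contrast (class intensity
    increases with the class index); each further channel ``k`` highlights
    class ``k`` specifically, the way individual MR modalities highlight
    particular tissues.  A small fixed jitter keeps levels from being exactly
    symmetric.  No single channel separates all classes, so a segmenter must
    combine channel contrasts.
    """
    c, ch = spec.n_classes, spec.n_channels
    rng = np.random.default_rng(987654321)
    table = np.full((c, ch), 0.3)
    table[:, 0] = 0.25 + 0.5 * np.arange(c) / max(c - 1, 1)
    for cls in range(1, c):
        k = cls % ch
        if k != 0:
            table[cls, k] = 0.75
    table += 0.03 * rng.standard_normal((c, ch))
    return np.clip(table, 0.05, 0.95)


def make_phantom_label(
    spec: PhantomSpec, rng: np.random.Generator, region_scale: float = 1.0
) -> np.ndarray:
    """Draw one nested-region label map.

    Radii are sampled per class around ``region_radius_mean * region_scale``;
    the tumor center and per-axis ellipticity are random.  Regeneration is
    attempted up to 10 times if a positive-radius class ends up empty
    (e.g. the region falls outside the image).
    """
    h, w = spec.image_height, spec.image_width
    means = np.asarray(spec.region_radius_mean, dtype=float) * region_scale
    rows, cols = np.mgrid[0:h, 0:w]
    for _ in range(10):
        radii = means + spec.region_radius_sd * region_scale * rng.standard_normal(
            len(means)
        )
        radii = np.maximum(radii, 0.0)
        radii = np.sort(radii) if spec.nesting else radii
        rmax = radii.max() if len(radii) else 0.0
        margin = min(rmax, (min(h, w) - 1) / 2)
        cr = rng.uniform(margin, h - 1 - margin)
        cc = rng.uniform(margin, w - 1 - margin)
        stretch = rng.uniform(0.8, 1.25, size=2)
        d = np.sqrt(((rows - cr) / stretch[0]) ** 2 + ((cols - cc) / stretch[1]) ** 2)
        label = np.zeros((h, w), dtype=np.int64)
        if spec.nesting:
            # paint outermost class first, inner classes overwrite
            for cls in range(spec.n_classes - 1, 0, -1):
                r = radii[cls - 1]
                if r > 0:
                    label[d <= r] = cls
        else:
            for cls in range(1, spec.n_classes):
                r = radii[cls - 1]
                if r > 0:
                    jr = cr + rng.uniform(-h / 4, h / 4)
                    jc = cc + rng.uniform(-w / 4, w / 4)
                    dd = np.sqrt((rows - jr) ** 2 + (cols - jc) ** 2)
                    label[dd <= r] = cls
        ok = all(
            (label == cls).sum() > 0
            for cls in range(1, spec.n_classes)
            if radii[cls - 1] > 0
        )
        if ok:
            return label
    raise RuntimeError(
        "failed to place all tumor classes in 10 attempts; radii too large "
        "for the image size"
    )


def render_image(
    label: np.ndarray,
    domain: DomainParams,
    spec: PhantomSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """Render a (C_ch, H, W) image from a label map under domain params."""
    if label.shape != (spec.image_height, spec.image_width):
        raise ValueError("label shape inconsistent with spec")
    table = base_intensity_table(spec)  # (C, C_ch)
    base = table[label]  # (H, W, C_ch)
    img = base.transpose(2, 0, 1).astype(np.float64)  # (C_ch, H, W)
    img = domain.gain * np.power(img, domain.gamma_exponent) + domain.offset
    if domain.channel_mixer is not None:
        mixer = domain.channel_mixer
        if mixer.shape != (spec.n_channels, spec.n_channels):
            raise ValueError("channel_mixer must be C_ch x C_ch")
        img = np.einsum("dc,chw->dhw", mixer, img)
    if domain.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, sigma=(0, domain.blur_sigma, domain.blur_sigma))
    if domain.noise_sd > 0:
        img = img + domain.noise_sd * rng.standard_normal(img.shape)
    return img.astype(np.float32)


# --------------------------------------------------------------------------
# dataset bundles
# --------------------------------------------------------------------------


@dataclass
class DatasetBundle:
    """Four-split dataset: labeled source train, unlabeled target train,
    labeled target val (model selection only) and target test.

    Target-train labels are retained privately for diagnostics and are never
    consumed by the adaptation loop.
    """

    spec: PhantomSpec
    source_params: DomainParams
    target_params: DomainParams
    seed: int
    source_train_images: np.ndarray
    source_train_labels: np.ndarray
    target_train_images: np.ndarray
    target_val_images: np.ndarray
    target_val_labels: np.ndarray
    target_test_images: np.ndarray
    target_test_labels: np.ndarray
    target_train_labels_private: np.ndarray = field(repr=False, default=None)

    @property
    def split_sizes(self) -> tuple[int, int, int, int]:
        return (
            len(self.source_train_images),
            len(self.target_train_images),
            len(self.target_val_images),
            len(self.target_test_images),
        )

    # -- persistence ------------------------------------------------------

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest = {
            "spec": asdict(self.spec),
            "source_params": _params_to_json(self.source_params),
            "target_params": _params_to_json(self.target_params),
            "seed": self.seed,
            "splits": {
                "source_train": len(self.source_train_images),
                "target_train": len(self.target_train_images),
                "target_val": len(self.target_val_images),
                "target_test": len(self.target_test_images),
            },
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        np.savez_compressed(
            out / "arrays.npz",
            source_train_images=self.source_train_images,
            source_train_labels=self.source_train_labels,
            target_train_images=self.target_train_images,
            target_train_labels_private=self.target_train_labels_private,
            target_val_images=self.target_val_images,
            target_val_labels=self.target_val_labels,
            target_test_images=self.target_test_images,
            target_test_labels=self.target_test_labels,
        )

    @classmethod
    def load(cls, in_dir: str | Path) -> "DatasetBundle":
        p = Path(in_dir)
        manifest = json.loads((p / "manifest.json").read_text())
        arrays = np.load(p / "arrays.npz")
        spec = PhantomSpec(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in manifest["spec"].items()
        })
        return cls(
            spec=spec,
            source_params=_params_from_json(manifest["source_params"]),
            target_params=_params_from_json(manifest["target_params"]),
            seed=manifest["seed"],
            source_train_images=arrays["source_train_images"],
            source_train_labels=arrays["source_train_labels"],
            target_train_images=arrays["target_train_images"],
            target_val_images=arrays["target_val_images"],
            target_val_labels=arrays["target_val_labels"],
            target_test_images=arrays["target_test_images"],
            target_test_labels=arrays["target_test_labels"],
            target_train_labels_private=arrays["target_train_labels_private"],
        )


def _params_to_json(p: DomainParams) -> dict:
    d = asdict(p)
    if d["channel_mixer"] is not None:
        d["channel_mixer"] = np.asarray(d["channel_mixer"]).tolist()
    return d


def _params_from_json(d: dict) -> DomainParams:
    d = dict(d)
    if d.get("channel_mixer") is not None:
        d["channel_mixer"] = np.asarray(d["channel_mixer"])
    return DomainParams(**d)


def _generate_split(spec, params, n, rng):
    labels = np.stack([
        make_phantom_label(spec, rng, region_scale=params.region_scale_factor)
        for _ in range(n)
    ]) if n else np.zeros((0, spec.image_height, spec.image_width), dtype=np.int64)
    images = np.stack([
        render_image(lab, params, spec, rng) for lab in labels
    ]) if n else np.zeros(
        (0, spec.n_channels, spec.image_height, spec.image_width), dtype=np.float32
    )
    return images, labels


def make_dataset(
    spec: PhantomSpec,
    source_params: DomainParams,
    target_params: DomainParams,
    n_train_source: int,
    n_train_target: int,
    n_val: int,
    n_test: int,
    seed: int,
) -> DatasetBundle:
    """Generate the four splits with disjoint per-split random streams."""
    ss = np.random.SeedSequence(seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(4)]
    src_img, src_lab = _generate_split(spec, source_params, n_train_source, rngs[0])
    tgt_img, tgt_lab = _generate_split(spec, target_params, n_train_target, rngs[1])
    val_img, val_lab = _generate_split(spec, target_params, n_val, rngs[2])
    tst_img, tst_lab = _generate_split(spec, target_params, n_test, rngs[3])
    return DatasetBundle(
        spec=spec,
        source_params=source_params,
        target_params=target_params,
        seed=seed,
        source_train_images=src_img,
        source_train_labels=src_lab,
        target_train_images=tgt_img,
        target_val_images=val_img,
        target_val_labels=val_lab,
        target_test_images=tst_img,
        target_test_labels=tst_lab,
        target_train_labels_private=tgt_lab,
    )


def export_png(images: np.ndarray, labels: np.ndarray | None,
               out_dir: str | Path, prefix: str = "case") -> None:
    """Write phantom images (first channel) and label maps as PNGs for
    visual inspection."""
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, img in enumerate(images):
        ch0 = img[0]
        lo, hi = ch0.min(), ch0.max()
        scaled = np.zeros_like(ch0) if hi == lo else (ch0 - lo) / (hi - lo)
        iio.imwrite(out / f"{prefix}_{i:03d}_img.png",
                    (255 * scaled).astype(np.uint8))
        if labels is not None:
            n_cls = max(int(labels[i].max()), 1)
            iio.imwrite(out / f"{prefix}_{i:03d}_label.png",
                        (labels[i] * (255 // n_cls)).astype(np.uint8))


# --------------------------------------------------------------------------
# NIfTI slice reader (optional real-data path)
# --------------------------------------------------------------------------


def read_nifti_slices(
    volume_paths: str | Path | list[str | Path],
    label_path: str | Path | None = None,
    slice_axis: int = 2,
):
    """Extract normalized 2-D slices from NIfTI volume(s).

    ``volume_paths`` may be a single path or a list of co-registered
    modality volumes, which become image channels in the given order.  Each
    volume is z-scored over its nonzero voxels.  Label values are remapped
    to contiguous ``[0, C)`` in sorted order.

    Returns ``(images, labels_or_none, spacing)`` where images has shape
    ``(n_slices, n_channels, H, W)`` and spacing is the in-plane pixel
    spacing in mm.
    """
    import nibabel as nib

    if isinstance(volume_paths, (str, Path)):
        volume_paths = [volume_paths]
    channels = []
    spacing = 1.0
    shape = None
    for vp in volume_paths:
        img = nib.load(str(vp))
        data = np.asanyarray(img.dataobj).astype(np.float64)
        if data.ndim != 3:
            raise ValueError(f"{vp}: expected a 3-D volume, got ndim={data.ndim}")
        if shape is None:
            shape = data.shape
            zooms = img.header.get_zooms()[:3]
            inplane = [z for ax, z in enumerate(zooms) if ax != slice_axis % 3]
            spacing = float(np.mean(inplane))
        elif data.shape != shape:
            raise ValueError("modality volumes have mismatched shapes")
        nz = data != 0
        if nz.any():
            mu, sd = data[nz].mean(), data[nz].std()
            data = (data - mu) / (sd if sd > 0 else 1.0)
        channels.append(np.moveaxis(data, slice_axis % 3, 0))  # (S, H, W)
    images = np.stack(channels, axis=1).astype(np.float32)  # (S, C_ch, H, W)

    labels = None
    if label_path is not None:
        lab_img = nib.load(str(label_path))
        lab = np.asanyarray(lab_img.dataobj)
        if lab.shape != shape:
            raise ValueError("label volume shape mismatches image volumes")
        lab = np.moveaxis(lab, slice_axis % 3, 0).astype(np.int64)
        values = np.unique(lab)
        remap = {int(v): i for i, v in enumerate(values)}
        labels = np.vectorize(remap.get, otypes=[np.int64])(lab)
    return images, labels, spacing
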