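"""Readers, writers, configuration and checkpoints.

Conventions: images are 8-bit grayscale PNG (or a 2-D NIfTI slice); masks are
indexed PNG with the palette 0=black (background), 1=blue (blood pool),
2=green (myocardium), 3=yellow (LGE).  Mask code 4 (microvascular
obstruction) is accepted on input and remapped to 3, since MVO is folded
into the LGE class.  Cohorts are described by a CSV manifest with columns
``path_image, path_mask, patient_id, split``.  Checkpoints are ``.npz``
archives holding the flat parameter/buffer state plus a JSON metadata record
(architecture spec, seed, config hash).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image
from skimage.transform import resize

from .backbones import ModelSpec
from .model import SegmentationModel, build_myinet
from .phantom import Cohort, LabeledImage

__all__ = [
    "PALETTE",
    "read_labeled_image",
    "write_labeled_image",
    "write_cohort",
    "read_manifest_cohort",
    "load_config",
    "save_config",
    "config_hash",
    "save_checkpoint",
    "load_checkpoint",
]

#: Mask palette (class code -> RGB), mirroring the usual display semantics:
#: unmasked background, blue blood pool, green myocardium, yellow LGE.
PALETTE = {0: (0, 0, 0), 1: (0, 0, 255), 2: (0, 200, 0), 3: (255, 255, 0)}

MVO_INPUT_CODE = 4


def _read_image_grid(path: Path) -> np.ndarray:
    path = Path(path)
    if path.suffix in (".nii", ".gz") or path.name.endswith(".nii.gz"):
        import nibabel as nib

        data = np.asarray(nib.load(str(path)).dataobj, dtype=np.float64)
        data = np.squeeze(data)
        if data.ndim != 2:
            raise ValueError(f"{path}: expected a single 2-D slice, got {data.shape}")
        lo, hi = data.min(), data.max()
        return (data - lo) / (hi - lo) if hi > lo else np.zeros_like(data)
    img = Image.open(path).convert("L")
    return np.asarray(img, dtype=np.float64) / 255.0


def read_labeled_image(image_path, mask_path, size: int = 256,
                       patient_id: str = "P000", slice_index: int = 0,
                       ) -> LabeledImage:
    """Read an image/mask pair, resize to ``size`` and normalise.

    Intensities are rescaled to [0, 1] and resized bilinearly; masks are
    resized nearest-neighbour.  MVO (code 4) is remapped to LGE (code 3).
    """
    pixels = _read_image_grid(Path(image_path))
    mask = np.asarray(Image.open(mask_path), dtype=np.int64)
    if mask.ndim == 3:
        raise ValueError(f"{mask_path}: expected an indexed (single-channel) mask")
    bad = set(int(v) for v in np.unique(mask)) - {0, 1, 2, 3, MVO_INPUT_CODE}
    if bad:
        raise ValueError(f"{mask_path}: unknown mask codes {sorted(bad)}")
    mask[mask == MVO_INPUT_CODE] = 3

    if pixels.shape != (size, size):
        pixels = resize(pixels, (size, size), order=1, preserve_range=True,
                        anti_aliasing=True)
    if mask.shape != (size, size):
        mask = resize(mask.astype(float), (size, size), order=0,
                      preserve_range=True).astype(np.int64)
    return LabeledImage(np.clip(pixels, 0.0, 1.0), mask, patient_id, slice_index)


def write_labeled_image(li: LabeledImage, image_path, mask_path) -> None:
    """Write the image as 8-bit grayscale PNG and the mask as indexed PNG."""
    img = Image.fromarray(np.round(li.pixels * 255).astype(np.uint8), mode="L")
    img.save(image_path)
    mask = Image.fromarray(li.labels.astype(np.uint8), mode="P")
    palette = np.zeros(768, dtype=np.uint8)
    for code, rgb in PALETTE.items():
        palette[3 * code: 3 * code + 3] = rgb
    mask.putpalette(palette.tolist())
    mask.save(mask_path)


def write_cohort(cohort: Cohort, out_dir) -> Path:
    """Write a cohort's PNGs plus the CSV manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for im in cohort.images:
        stem = f"{im.patient_id}_s{im.slice_index:02d}"
        image_path = out_dir / "images" / f"{stem}.png"
        mask_path = out_dir / "masks" / f"{stem}.png"
        write_labeled_image(im, image_path, mask_path)
        rows.append({
            "path_image": str(image_path.relative_to(out_dir)),
            "path_mask": str(mask_path.relative_to(out_dir)),
            "patient_id": im.patient_id,
            "split": cohort.split_assignment[im.patient_id],
        })
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_manifest_cohort(manifest_path, size: int | None = None) -> Cohort:
    """Load a cohort from a manifest CSV (paths relative to the manifest)."""
    manifest_path = Path(manifest_path)
    table = pd.read_csv(manifest_path)
    base = manifest_path.parent
    images = []
    assignment = {}
    for i, row in table.iterrows():
        probe = Image.open(base / row.path_image)
        img_size = size if size is not None else probe.size[1]
        im = read_labeled_image(base / row.path_image, base / row.path_mask,
                                size=img_size, patient_id=str(row.patient_id),
                                slice_index=i)
        images.append(im)
        assignment[str(row.patient_id)] = str(row.split)
    return Cohort(images=images, split_assignment=assignment)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def config_hash(cfg: dict) -> str:
    canon = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(model: SegmentationModel, path, *, seed: int = 0,
                    extra_meta: dict | None = None) -> None:
    meta = {
        "spec": vars(model.spec).copy(),
        "seed": seed,
    }
    if extra_meta:
        meta.update(extra_meta)
    state = {f"param/{k}": v for k, v in model.state_dict().items()}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta, default=str).encode(), dtype=np.uint8), **state)


def load_checkpoint(path) -> tuple[SegmentationModel, dict]:
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["__meta__"]).decode())
        state = {k[len("param/"):]: archive[k] for k in archive.files
                 if k.startswith("param/")}
    spec_fields = {k: v for k, v in meta["spec"].items()}
    spec = ModelSpec(**spec_fields)
    model = build_myinet(spec, seed=int(meta.get("seed", 0)))
    model.load_state_dict(state)
    return model, meta
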