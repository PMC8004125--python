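"""Disk layout: PNG frames/patches, VIA JSON, manifests.

Layout written by the CLI stages::

    study/
      frames/frame000_bmode.png   frames/frame000_ceus.png  ...
      annotations.json            # VIA-3 style polygons
    patches/
      HCC_frame000_r017_c068_none_bmode.png (+ _ceus.png) ...
    features.csv                  # per-patch texture table

Every stage also writes ``manifest.json`` recording the configuration
snapshot, seeds, package version and sha256 digests of the files it read
and wrote, so a run can be checked for bit-identical reproduction.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
from PIL import Image

from .annotations import PairedPatch, AnnotatedFramePair


def save_image(array: np.ndarray, path: str | Path) -> None:
    Image.fromarray(np.asarray(array, dtype=np.uint8), mode="L").save(path)


def load_image(path: str | Path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("L"))


def save_study(study, out_dir: str | Path) -> Path:
    """Write frames as PNG pairs plus the VIA polygon file."""
    from .annotations import PolygonAnnotation, write_via_annotations

    out = Path(out_dir)
    (out / "frames").mkdir(parents=True, exist_ok=True)
    annotations = []
    for frame, poly in zip(study.frames, study.polygons):
        save_image(frame.bmode, out / "frames" / f"{frame.frame_id}_bmode.png")
        save_image(frame.ceus, out / "frames" / f"{frame.frame_id}_ceus.png")
        annotations.append(PolygonAnnotation(frame_id=frame.frame_id,
                                             vertices=poly))
    write_via_annotations(annotations, out / "annotations.json",
                          project_name=study.patient_id)
    return out


def load_frames(frames_dir: str | Path) -> list[AnnotatedFramePair]:
    frames_dir = Path(frames_dir)
    pairs = []
    for bpath in sorted(frames_dir.glob("*_bmode.png")):
        fid = bpath.name[:-len("_bmode.png")]
        cpath = frames_dir / f"{fid}_ceus.png"
        if not cpath.exists():
            raise FileNotFoundError(f"missing CEUS frame for {fid}")
        pairs.append(AnnotatedFramePair(frame_id=fid, bmode=load_image(bpath),
                                        ceus=load_image(cpath)))
    return pairs


def save_patches(patches, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, p in enumerate(patches):
        stem = (f"{i:05d}_{p.label}_{p.origin[0]}_r{int(p.origin[1]):03d}"
                f"_c{int(p.origin[2]):03d}_{p.augmentation_tag}")
        save_image(p.bmode, out / f"{stem}_bmode.png")
        save_image(p.ceus, out / f"{stem}_ceus.png")
    return out


def load_patches(patch_dir: str | Path) -> list[PairedPatch]:
    patch_dir = Path(patch_dir)
    patches = []
    for bpath in sorted(patch_dir.glob("*_bmode.png")):
        stem = bpath.name[:-len("_bmode.png")]
        _, label, rest = stem.split("_", 2)
        frame_part, rpart, cpart, tag = rest.rsplit("_", 3)
        patches.append(PairedPatch(
            bmode=load_image(bpath),
            ceus=load_image(patch_dir / f"{stem}_ceus.png"),
            label=label,
            origin=(frame_part, int(rpart[1:]), int(cpart[1:])),
            augmentation_tag=tag))
    return patches


# ---------------------------------------------------------------------------
# Manifests

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(out_dir: str | Path, stage: str, config: dict,
                   seeds: dict, inputs=(), outputs=()) -> Path:
    """Record a stage's configuration and file digests."""
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    doc = {
        "stage": stage,
        "version": __version__,
        "config": config,
        "seeds": seeds,
        "inputs": {str(p): _sha256(Path(p)) for p in inputs},
        "outputs": {str(p): _sha256(Path(p)) for p in outputs},
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(doc, indent=1, sort_keys=True))
    return path


def validate_manifest(manifest_path: str | Path) -> bool:
    """True when every recorded output digest still matches on disk."""
    doc = json.loads(Path(manifest_path).read_text())
    for p, digest in {**doc["inputs"], **doc["outputs"]}.items():
        if not Path(p).exists() or _sha256(Path(p)) != digest:
            return False
    return True
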