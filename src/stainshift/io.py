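"""File interfaces: slides, manifests, stain targets, checkpoints."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from PIL import Image

from . import stains, synthetic
from ._rng import child_seed

MANIFEST_COLUMNS = ["patient_id", "label", "batch", "path", "tissue_seed"]


def read_slide(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path).convert("RGB"))
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    return arr.astype(np.uint8)


def write_slide(path: str | Path, image: np.ndarray) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image)
    else:
        Image.fromarray(image).save(path)


def write_cohort(
    patients: list[synthetic.VirtualPatient],
    profile_A: synthetic.StainProfile,
    profile_B: synthetic.StainProfile,
    out_dir: str | Path,
    height: int = 768,
    width: int = 768,
    seed: int = 0,
    image_format: str = "png",
) -> pd.DataFrame:
    """Render every patient's batch pair to disk with manifest + config."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for patient in patients:
        pair = synthetic.make_batch_pair(
            patient, profile_A, profile_B, height, width, seed
        )
        for batch, image in (("A", pair.slide_A), ("B", pair.slide_B)):
            rel = f"slides/p{patient.patient_id:04d}_{batch}.{image_format}"
            write_slide(out_dir / rel, image)
            rows.append(
                {
                    "patient_id": patient.patient_id,
                    "label": patient.label,
                    "batch": batch,
                    "path": rel,
                    "tissue_seed": patient.tissue_seed,
                }
            )
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    config = {
        "seed": seed,
        "height": height,
        "width": width,
        "n_patients": len(patients),
        "profiles": {
            name: {
                "stain_matrix": p.stain_matrix.tolist(),
                "intensity_scale": p.intensity_scale.tolist(),
                "illumination_I0": p.illumination_I0.tolist(),
                "noise_sd": p.noise_sd,
            }
            for name, p in (("A", profile_A), ("B", profile_B))
        },
    }
    (out_dir / "cohort.yaml").write_text(yaml.safe_dump(config))
    return manifest


def read_manifest(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


class FileSlideStore:
    """Slide access for a manifest of on-disk images."""

    def __init__(self, manifest: pd.DataFrame, root: str | Path = "."):
        self.root = Path(root)
        self._paths = {
            (int(r.patient_id), r.batch): r.path for r in manifest.itertuples()
        }

    def slide(self, patient_id: int, batch: str) -> np.ndarray:
        return read_slide(self.root / self._paths[(int(patient_id), batch)])


def save_target(path: str | Path, target: stains.NormalizationTarget) -> None:
    Path(path).write_text(target.to_json())


def load_target(path: str | Path) -> stains.NormalizationTarget:
    return stains.NormalizationTarget.from_json(Path(path).read_text())


def save_weights(path: str | Path, net, config: dict | None = None) -> None:
    """Checkpoint a Sequential's parameters (npz + JSON-ish sidecar)."""
    arrays = {f"p{i}": p for i, p in enumerate(net.state())}
    np.savez(path, **arrays)
    if config is not None:
        Path(str(path) + ".yaml").write_text(yaml.safe_dump(config))


def load_weights(path: str | Path, net) -> None:
    with np.load(path) as data:
        net.load_state([data[f"p{i}"] for i in range(len(data.files))])
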