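"""Standard-format I/O: NIfTI volumes, FSL bvals/bvecs, TCK streamlines, config.

Volumes are NIfTI-1 with RAS+ mm conventions; the phantom affine is the
identity scaled by the voxel size. Streamlines use the TCK (MRtrix) format in
mm coordinates; a TRK import shim is provided. Provenance labels are
run-length encoded into the TCK header and recovered on read. Only
single-shell diffusion data are accepted.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .core import Connectome, DWIDataset, GradientTable, VoxelGrid

__all__ = [
    "read_dwi",
    "write_dwi",
    "read_mask",
    "write_mask",
    "read_tck",
    "write_tck",
    "read_trk",
    "load_config",
    "stage_seed",
    "write_manifest",
]

_B0_THRESHOLD = 50.0  # s/mm^2


def _load_bvals_bvecs(path_bval, path_bvec) -> tuple[np.ndarray, np.ndarray]:
    bvals = np.loadtxt(path_bval).ravel()
    bvecs = np.loadtxt(path_bvec)
    if bvecs.ndim != 2:
        raise ValueError("bvec file must be a 2-D table")
    # accept both FSL dialects: 3 rows x N columns, or N rows x 3 columns
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape[1] != 3:
        raise ValueError(f"cannot interpret bvec shape {bvecs.shape}")
    if bvecs.shape[0] != bvals.shape[0]:
        raise ValueError("bval and bvec entry counts differ")
    return bvals, bvecs


def read_dwi(path_nifti, path_bval, path_bvec, path_mask=None) -> DWIDataset:
    """Load one acquisition repeat from NIfTI + FSL bvals/bvecs.

    b=0 volumes are averaged into the b0 image and separated from the
    diffusion-weighted volumes; a single-shell check rejects multi-shell
    data; direction vectors are normalized.
    """
    img = nib.load(str(path_nifti))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError("expected a 4-D diffusion volume")
    bvals, bvecs = _load_bvals_bvecs(path_bval, path_bvec)
    if bvals.shape[0] != data.shape[3]:
        raise ValueError("bval count does not match the 4th data dimension")
    is_b0 = bvals < _B0_THRESHOLD
    shells = np.unique(np.round(bvals[~is_b0], -1))
    if shells.size != 1:
        raise ValueError(
            f"only single-shell data are accepted; found b-values {sorted(shells)}"
        )
    dirs = bvecs[~is_b0]
    norms = np.linalg.norm(dirs, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero-norm gradient direction with nonzero b-value")
    dirs = dirs / norms[:, None]
    gradients = GradientTable(dirs, float(shells[0]))
    if not is_b0.any():
        raise ValueError("no b=0 volume found")
    b0 = data[..., is_b0].mean(axis=3)
    signal = data[..., ~is_b0]
    vs = float(np.abs(img.affine[0, 0]))
    grid = VoxelGrid(data.shape[:3], vs)
    if path_mask is not None:
        mask = np.asarray(nib.load(str(path_mask)).dataobj) > 0
    else:
        mask = b0 > 0
    return DWIDataset(signal, b0, mask, gradients, grid)


def write_dwi(dataset: DWIDataset, path_nifti, path_bval, path_bvec) -> None:
    """Write one repeat as NIfTI (b0 first) plus FSL-style bvals/bvecs."""
    data = np.concatenate([dataset.b0[..., None], dataset.signal], axis=3)
    nib.save(nib.Nifti1Image(data.astype(np.float32), dataset.grid.affine()), str(path_nifti))
    n = dataset.gradients.n_directions
    bvals = np.concatenate([[0.0], np.full(n, dataset.gradients.b_value)])
    bvecs = np.vstack([[0.0, 0.0, 0.0], dataset.gradients.directions]).T  # 3 x (N+1)
    np.savetxt(str(path_bval), bvals[None, :], fmt="%g")
    np.savetxt(str(path_bvec), bvecs, fmt="%.8f")


def read_mask(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj) > 0


def write_mask(mask: np.ndarray, grid: VoxelGrid, path) -> None:
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), grid.affine()), str(path))


def _quote(text: str) -> str:
    # TCK header values may not contain ':' or newlines; percent-encode
    from urllib.parse import quote

    return quote(text, safe="")


def _unquote(text: str) -> str:
    from urllib.parse import unquote

    return unquote(text)


def _encode_provenance(labels: list[str]) -> str:
    runs = []
    for lab in labels:
        if runs and runs[-1][0] == lab:
            runs[-1][1] += 1
        else:
            runs.append([lab, 1])
    return ";".join(f"{_quote(lab)}*{n}" for lab, n in runs)


def _decode_provenance(text: str, n: int) -> list[str]:
    labels: list[str] = []
    if text:
        for run in text.split(";"):
            lab, _, count = run.rpartition("*")
            labels.extend([_unquote(lab)] * int(count))
    if len(labels) != n:
        labels = ["unknown"] * n
    return labels


def write_tck(connectome: Connectome, path) -> None:
    """Write streamlines as TCK (mm coordinates, provenance in the header)."""
    tractogram = nib.streamlines.Tractogram(
        [s.astype(np.float32) for s in connectome.streamlines],
        affine_to_rasmm=np.eye(4),
    )
    header = {
        "provenance": _encode_provenance(connectome.provenance),
        "connectome_label": _quote(connectome.label),
    }
    nib.streamlines.save(nib.streamlines.TckFile(tractogram, header=header), str(path))


def read_tck(path) -> Connectome:
    """Read a TCK file, recovering provenance labels from the header."""
    try:
        tck = nib.streamlines.load(str(path))
    except Exception as exc:
        size = Path(path).stat().st_size if Path(path).exists() else 0
        raise ValueError(f"cannot read TCK stream {path!r} (size {size} bytes): {exc}") from exc
    streamlines = [np.asarray(s, dtype=float) for s in tck.streamlines]
    header = dict(tck.header)
    prov = _decode_provenance(str(header.get("provenance", "")), len(streamlines))
    return Connectome(streamlines, prov,
                      label=_unquote(str(header.get("connectome_label", ""))))


def read_trk(path) -> Connectome:
    """Import shim for TRK tractograms (converted to mm RAS coordinates)."""
    trk = nib.streamlines.load(str(path))
    return Connectome([np.asarray(s, dtype=float) for s in trk.streamlines])


def export_weights_tsv(connectome: Connectome, path) -> None:
    import pandas as pd

    if connectome.weights is None:
        raise ValueError("connectome carries no weights")
    pd.DataFrame(
        {
            "streamline": np.arange(len(connectome)),
            "provenance": connectome.provenance,
            "weight": connectome.weights,
        }
    ).to_csv(path, sep="\t", index=False)


def load_config(path) -> dict:
    """Load a YAML run configuration; requires a global integer seed."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if "seed" not in cfg:
        raise ValueError("run configuration must define a global 'seed'")
    return cfg


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed (< 2^31)."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, inputs: dict, seeds: dict, outputs: list) -> Path:
    """Record inputs, seeds, package version and output checksums as JSON."""
    from . import __version__

    out_dir = Path(out_dir)
    manifest = {
        "version": __version__,
        "inputs": inputs,
        "seeds": seeds,
        "outputs": {
            str(Path(p).name): _checksum(Path(p)) for p in outputs if Path(p).exists()
        },
    }
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return path
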