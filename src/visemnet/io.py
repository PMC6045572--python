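"""On-disk formats: array containers with JSON manifests, TSV, NIfTI.

Stage representations and brain patterns are stored as a ``.npz`` array
container next to a JSON manifest carrying the ordering metadata (stage
ids, item order, grid shape, region map).  Norms and RDMs travel as TSV.
Volumetric patterns can be exported to NIfTI (one volume per item per
subject) for inspection in standard neuroimaging viewers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .rsa import RDM
from .syndata import StageRepresentation, SyntheticBrain

__all__ = [
    "save_stages",
    "load_stages",
    "save_brain",
    "load_brain",
    "rdm_to_tsv",
    "rdm_from_tsv",
    "brain_to_nifti",
]


def save_stages(stages: list[StageRepresentation], prefix) -> None:
    prefix = Path(prefix)
    arrays = {f"stage_{i:03d}": s.matrix for i, s in enumerate(stages)}
    np.savez_compressed(prefix.with_suffix(".npz"), **arrays)
    manifest = {
        "stage_ids": [s.stage_id for s in stages],
        "items": stages[0].items if stages else [],
    }
    prefix.with_suffix(".json").write_text(json.dumps(manifest, indent=2))


def load_stages(prefix) -> list[StageRepresentation]:
    prefix = Path(prefix)
    manifest = json.loads(prefix.with_suffix(".json").read_text())
    data = np.load(prefix.with_suffix(".npz"))
    stages = []
    for i, sid in enumerate(manifest["stage_ids"]):
        stages.append(
            StageRepresentation(
                stage_id=sid, items=list(manifest["items"]), matrix=data[f"stage_{i:03d}"]
            )
        )
    return stages


def save_brain(brain: SyntheticBrain, prefix) -> None:
    prefix = Path(prefix)
    arrays = {f"subject_{s:03d}": P for s, P in enumerate(brain.patterns)}
    np.savez_compressed(prefix.with_suffix(".npz"), **arrays)
    manifest = {
        "n_subjects": brain.n_subjects,
        "grid_shape": list(brain.grid_shape),
        "region_map": brain.region_map.tolist(),
        "truth": brain.truth,
        "snr": brain.snr,
        "items": brain.items,
    }
    prefix.with_suffix(".json").write_text(json.dumps(manifest, indent=2))


def load_brain(prefix) -> SyntheticBrain:
    prefix = Path(prefix)
    manifest = json.loads(prefix.with_suffix(".json").read_text())
    data = np.load(prefix.with_suffix(".npz"))
    patterns = [data[f"subject_{s:03d}"] for s in range(manifest["n_subjects"])]
    return SyntheticBrain(
        n_subjects=manifest["n_subjects"],
        grid_shape=tuple(manifest["grid_shape"]),
        region_map=np.array(manifest["region_map"], dtype=object),
        patterns=patterns,
        truth=manifest["truth"],
        snr=manifest["snr"],
        items=manifest["items"],
    )


def rdm_to_tsv(rdm: RDM, path) -> None:
    import pandas as pd

    pd.DataFrame(rdm.matrix, index=rdm.items, columns=rdm.items).to_csv(
        path, sep="\t", index_label="item"
    )


def rdm_from_tsv(path) -> RDM:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col="item")
    rdm = RDM(items=list(df.index), matrix=df.to_numpy(dtype=float))
    rdm.validate()
    return rdm


def brain_to_nifti(brain: SyntheticBrain, subject: int, path) -> None:
    """Export one subject's patterns as a 4-D NIfTI (x, y, z, item)."""
    import nibabel as nib

    vols = brain.patterns[subject].T.reshape(*brain.grid_shape, len(brain.items))
    img = nib.Nifti1Image(vols.astype(np.float32), affine=np.eye(4))
    nib.save(img, str(path))
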