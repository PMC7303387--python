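"""Reading and writing the on-disk forms: NIfTI volumes, BIDS-style event
and motion TSVs, and JSON manifests for synthetic datasets."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import Bold4D
from .paradigm import TaskParadigm, build_paradigm
from .simulate import (
    GroundTruthCluster,
    SessionRun,
    SimulationConfig,
    SyntheticDataset,
    make_region_atlas,
)


def write_bold(bold: Bold4D, path: str | Path) -> None:
    img = nib.Nifti1Image(bold.data.astype(np.float32), bold.affine)
    img.header.set_zooms(tuple(bold.voxel_size_mm) + (bold.tr_seconds,))
    nib.save(img, str(path))


def read_bold(path: str | Path, mask: np.ndarray) -> Bold4D:
    img = nib.load(str(path))
    tr = float(img.header.get_zooms()[3])
    return Bold4D(data=np.asarray(img.dataobj, dtype=float),
                  affine=img.affine, tr_seconds=tr, mask=mask)


def write_mask(mask: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), str(path))


def write_events_tsv(paradigm: TaskParadigm, path: str | Path) -> None:
    rows = paradigm.onsets()
    pd.DataFrame(rows, columns=["onset", "duration", "trial_type"]).to_csv(
        path, sep="\t", index=False
    )


def write_motion_tsv(params: np.ndarray, path: str | Path) -> None:
    cols = ["rot_x_deg", "rot_y_deg", "rot_z_deg",
            "trans_x_mm", "trans_y_mm", "trans_z_mm"]
    pd.DataFrame(np.atleast_2d(params), columns=cols).to_csv(
        path, sep="\t", index=False
    )


def read_motion_tsv(path: str | Path) -> np.ndarray:
    return pd.read_csv(path, sep="\t").to_numpy(dtype=float)


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> None:
    """Write a synthetic cohort: one NIfTI + sidecars per member, one manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_mask(dataset.mask, dataset.affine, out / "brain_mask.nii")
    nib.save(nib.Nifti1Image(dataset.atlas.astype(np.int8), dataset.affine),
             str(out / "region_atlas.nii"))
    manifest = {
        "config": _config_dict(dataset.config),
        "members": [],
    }
    for (subject, session, run_id), member in sorted(dataset.members.items()):
        stem = f"sub-{subject:02d}_ses-{session}_{run_id}"
        write_bold(member.bold, out / f"{stem}_bold.nii")
        write_events_tsv(dataset.paradigms[run_id], out / f"{stem}_events.tsv")
        write_motion_tsv(member.motion_true, out / f"{stem}_motion.tsv")
        manifest["members"].append({
            "subject": subject, "session": session, "run": run_id,
            "bold": f"{stem}_bold.nii",
            "truths": [asdict(t) for t in member.truths],
        })
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))


def _config_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    if isinstance(d["motion_profile"], np.ndarray):
        d["motion_profile"] = d["motion_profile"].tolist()
    d["grid_shape"] = list(d["grid_shape"])
    return d


def load_dataset(in_dir: str | Path) -> SyntheticDataset:
    """Reload a cohort written by :func:`write_dataset`."""
    src = Path(in_dir)
    manifest = json.loads((src / "manifest.json").read_text())
    cfg = manifest["config"]
    if isinstance(cfg["motion_profile"], list):
        cfg["motion_profile"] = np.asarray(cfg["motion_profile"])
    cfg["grid_shape"] = tuple(cfg["grid_shape"])
    config = SimulationConfig(**cfg)
    mask = np.asarray(nib.load(str(src / "brain_mask.nii")).dataobj) > 0
    affine = nib.load(str(src / "brain_mask.nii")).affine
    atlas_p = src / "region_atlas.nii"
    atlas = (np.asarray(nib.load(str(atlas_p)).dataobj).astype(np.int8)
             if atlas_p.exists() else make_region_atlas(mask, affine))
    members = {}
    runs = set()
    for m in manifest["members"]:
        key = (m["subject"], m["session"], m["run"])
        runs.add(m["run"])
        bold = read_bold(src / m["bold"], mask)
        motion = read_motion_tsv(src / f"sub-{m['subject']:02d}_ses-{m['session']}_{m['run']}_motion.tsv")
        truths = tuple(
            GroundTruthCluster(center_mm=tuple(t["center_mm"]),
                               radius_mm=t["radius_mm"],
                               amplitude=t["amplitude"],
                               condition_label=t["condition_label"])
            for t in m["truths"]
        )
        members[key] = SessionRun(bold=bold, motion_true=motion, truths=truths)
    return SyntheticDataset(
        config=config, members=members, mask=mask, affine=affine, atlas=atlas,
        paradigms={r: build_paradigm(r) for r in sorted(runs)},
    )
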