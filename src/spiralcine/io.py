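"""HDF5 / JSON serialization of trajectories, raw data, sessions and reports."""

from __future__ import annotations

import dataclasses
import json

import h5py
import numpy as np

from .encoding import CoilSensitivities, KSpaceBundle
from .gating import CardiacPhaseBins
from .phantom import PhantomConfig, PhantomFrame, Session
from .trajectory import SpiralTrajectory, density_compensation


def save_trajectory(path: str, traj: SpiralTrajectory, with_dcf: bool = True):
    with h5py.File(path, "w") as f:
        _write_traj(f, traj, with_dcf)


def _write_traj(group, traj: SpiralTrajectory, with_dcf: bool = False):
    group.create_dataset("kx", data=traj.arm_coords[..., 0])
    group.create_dataset("ky", data=traj.arm_coords[..., 1])
    if with_dcf:
        group.create_dataset("dcf", data=density_compensation(traj))
    group.attrs["fov_mm"] = traj.fov_mm
    group.attrs["res_mm"] = traj.resolution_mm
    group.attrs["dwell_s"] = traj.dwell_time
    group.attrs["n_arms"] = traj.n_arms
    group.attrs["rotation_offset"] = traj.rotation_offset
    group.attrs["center_undersampling"] = traj.center_undersampling
    group.attrs["edge_undersampling"] = traj.edge_undersampling


def _read_traj(group) -> SpiralTrajectory:
    coords = np.stack([group["kx"][...], group["ky"][...]], axis=-1)
    return SpiralTrajectory(
        arm_coords=coords, n_arms=int(group.attrs["n_arms"]),
        dwell_time=float(group.attrs["dwell_s"]),
        rotation_offset=float(group.attrs["rotation_offset"]),
        fov_mm=float(group.attrs["fov_mm"]),
        resolution_mm=float(group.attrs["res_mm"]),
        center_undersampling=float(group.attrs.get("center_undersampling", 5.0)),
        edge_undersampling=float(group.attrs.get("edge_undersampling", 15.0)))


def load_trajectory(path: str) -> SpiralTrajectory:
    with h5py.File(path, "r") as f:
        return _read_traj(f)


def save_kspace(path: str, bundle: KSpaceBundle):
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=bundle.samples.astype(np.complex64))
        f.create_dataset("arm_times", data=bundle.arm_times)
        _write_traj(f.create_group("trajectory"), bundle.traj)


def load_kspace(path: str) -> KSpaceBundle:
    with h5py.File(path, "r") as f:
        return KSpaceBundle(f["data"][...].astype(np.complex128),
                            f["arm_times"][...], _read_traj(f["trajectory"]))


def save_session(path: str, session: Session):
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=session.kspace.samples.astype(np.complex64))
        f.create_dataset("arm_times", data=session.kspace.arm_times)
        _write_traj(f.create_group("trajectory"), session.kspace.traj)
        _write_traj(f.create_group("base_trajectory"), session.base_traj)
        f.create_dataset("coil_maps", data=session.coils.maps.astype(np.complex64))
        truth = f.create_group("truth")
        truth.create_dataset("images", data=np.stack(
            [fr.image for fr in session.frames]).astype(np.float32))
        truth.create_dataset("masks", data=np.stack(
            [fr.mask for fr in session.frames]))
        truth.create_dataset("frame_times", data=session.frame_times)
        truth.create_dataset("phases", data=[fr.phase_fraction
                                             for fr in session.frames])
        truth.create_dataset("lv_areas_mm2", data=[fr.lv_area_mm2
                                                   for fr in session.frames])
        truth.create_dataset("triggers_s", data=session.triggers_s)
        truth.create_dataset("pattern_index", data=session.pattern_index)
        truth.create_dataset("rotation_offsets", data=session.rotation_offsets)
        truth.attrs["config_json"] = json.dumps(dataclasses.asdict(session.config))
        truth.attrs["mode"] = session.mode


def load_session(path: str) -> Session:
    with h5py.File(path, "r") as f:
        traj = _read_traj(f["trajectory"])
        ks = KSpaceBundle(f["data"][...].astype(np.complex128),
                          f["arm_times"][...], traj, traj_ref="session")
        truth = f["truth"]
        cfg = PhantomConfig(**json.loads(truth.attrs["config_json"]))
        frames = [PhantomFrame(image=img, mask=msk, time_s=float(t),
                               phase_fraction=float(p), lv_area_mm2=float(a))
                  for img, msk, t, p, a in zip(
                      truth["images"][...], truth["masks"][...],
                      truth["frame_times"][...], truth["phases"][...],
                      truth["lv_areas_mm2"][...])]
        return Session(kspace=ks, base_traj=_read_traj(f["base_trajectory"]),
                       coils=CoilSensitivities(f["coil_maps"][...].astype(np.complex128)),
                       frames=frames, frame_times=truth["frame_times"][...],
                       pattern_index=truth["pattern_index"][...],
                       rotation_offsets=truth["rotation_offsets"][...],
                       triggers_s=truth["triggers_s"][...],
                       config=cfg, mode=str(truth.attrs["mode"]))


def save_bins(path: str, bins: CardiacPhaseBins):
    payload = {"triggers_s": bins.trigger_times.tolist(),
               "n_phases": bins.n_phases,
               "assignment": bins.assignment.tolist(),
               "discarded": bins.discarded.astype(int).tolist()}
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_bins(path: str) -> CardiacPhaseBins:
    with open(path) as fh:
        p = json.load(fh)
    return CardiacPhaseBins(np.asarray(p["triggers_s"]), int(p["n_phases"]),
                            np.asarray(p["assignment"], int),
                            np.asarray(p["discarded"], bool))


def save_recon(path: str, images: np.ndarray, masks: np.ndarray,
               frame_times: np.ndarray):
    with h5py.File(path, "w") as f:
        f.create_dataset("images", data=np.asarray(images, np.float32))
        f.create_dataset("masks", data=np.asarray(masks, np.uint8))
        f.create_dataset("frame_times", data=frame_times)


def export_masks_nifti(path: str, masks: np.ndarray, pixel_mm: float,
                       slice_thickness_mm: float = 8.0):
    """Mask series as a NIfTI volume (x, y, t) with pixel geometry."""
    import nibabel as nib
    arr = np.moveaxis(np.asarray(masks, np.uint8), 0, -1)
    affine = np.diag([pixel_mm, pixel_mm, slice_thickness_mm, 1.0])
    nib.save(nib.Nifti1Image(arr, affine), path)
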