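"""File I/O: HDF5 raw data, NIfTI image series, CSV tables, YAML configs."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .acquisition import RawAcquisition
from .encoding import EncodingScheme, FlowEncode, GradientWaveform
from .phantom import FlowMarkers, TriggerStream
from .quantify import FlowWaveform
from .recon import CardiacSeries, VelocityChannel
from .trajectory import SpiralTrajectory

__all__ = [
    "save_raw", "load_raw", "save_series", "load_series",
    "save_waveforms_csv", "save_markers_csv", "waveform_to_csv",
    "save_trajectory", "load_config", "save_config", "export_waveform_csv",
]


def save_raw(path: str | Path, raw: RawAcquisition) -> None:
    """Persist a RawAcquisition to HDF5 (records + trajectory + coil maps)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=raw.data.astype(np.complex64))
        f.create_dataset("times_ms", data=raw.times_ms)
        f.create_dataset("encode_index", data=raw.encode_index)
        f.create_dataset("arm_index", data=raw.arm_index)
        f.create_dataset("trigger_times_ms", data=raw.triggers.trigger_times_ms)
        f.create_dataset("coil_maps", data=raw.coil_maps)
        f.create_dataset("traj/coords", data=raw.trajectory.coords)
        f.create_dataset("traj/dcf", data=raw.trajectory.dcf)
        f.attrs["seed"] = raw.seed
        f.attrs["mean_hr_bpm"] = raw.triggers.mean_hr_bpm
        f.attrs["hr_sd_bpm"] = raw.triggers.hr_sd_bpm
        t = raw.trajectory
        f.attrs["traj_meta"] = json.dumps(
            dict(angle_increment_deg=t.angle_increment_deg, kmax=t.kmax,
                 n_turns=t.n_turns, readout_duration_ms=t.readout_duration_ms)
        )
        s = raw.scheme
        f.attrs["scheme"] = json.dumps(
            dict(
                scheme_type=s.scheme_type, tr_ms=s.tr_ms, te_ms=s.te_ms,
                flip_angle_deg=s.flip_angle_deg,
                channel_map=[list(c) for c in s.channel_map],
                encodes=[
                    dict(role=e.role, venc=e.venc, delta_m1=e.delta_m1,
                         index_in_block=e.index_in_block,
                         raster_us=e.waveform.raster_us,
                         samples=e.waveform.samples.tolist())
                    for e in s.encodes
                ],
            )
        )


def load_raw(path: str | Path) -> RawAcquisition:
    with h5py.File(path, "r") as f:
        sj = json.loads(f.attrs["scheme"])
        encodes = tuple(
            FlowEncode(
                role=e["role"], venc=e["venc"], delta_m1=e["delta_m1"],
                waveform=GradientWaveform(
                    samples=np.asarray(e["samples"]), raster_us=e["raster_us"]
                ),
                index_in_block=e["index_in_block"],
            )
            for e in sj["encodes"]
        )
        scheme = EncodingScheme(
            scheme_type=sj["scheme_type"], encodes=encodes, tr_ms=sj["tr_ms"],
            te_ms=sj["te_ms"], flip_angle_deg=sj["flip_angle_deg"],
            channel_map=tuple((int(a), int(b), float(v))
                              for a, b, v in sj["channel_map"]),
        )
        tj = json.loads(f.attrs["traj_meta"])
        traj = SpiralTrajectory(
            coords=f["traj/coords"][...], dcf=f["traj/dcf"][...],
            angle_increment_deg=tj["angle_increment_deg"], kmax=tj["kmax"],
            n_turns=tj["n_turns"], readout_duration_ms=tj["readout_duration_ms"],
        )
        triggers = TriggerStream(
            trigger_times_ms=f["trigger_times_ms"][...],
            mean_hr_bpm=float(f.attrs["mean_hr_bpm"]),
            hr_sd_bpm=float(f.attrs["hr_sd_bpm"]),
        )
        return RawAcquisition(
            data=f["data"][...].astype(np.complex128),
            times_ms=f["times_ms"][...],
            encode_index=f["encode_index"][...],
            arm_index=f["arm_index"][...],
            scheme=scheme, trajectory=traj, triggers=triggers,
            coil_maps=f["coil_maps"][...], seed=int(f.attrs["seed"]),
        )


def save_series(outdir: str | Path, series: CardiacSeries) -> None:
    """Write a CardiacSeries as NIfTI volumes plus a JSON sidecar.

    One ``velocity_ch<i>.nii.gz`` per channel and one ``magnitude.nii.gz``
    (cardiac phase along the 3rd axis); venc, time offsets, and phase
    duration in ``series.json``.
    """
    import nibabel as nib

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    aff = np.diag([series.pixel_mm, series.pixel_mm, 1.0, 1.0])
    nib.save(
        nib.Nifti1Image(np.moveaxis(series.magnitude, 0, -1).astype(np.float32), aff),
        outdir / "magnitude.nii.gz",
    )
    meta = {
        "n_phases": series.n_phases,
        "phase_duration_ms": series.phase_duration_ms,
        "pixel_mm": series.pixel_mm,
        "channels": [],
    }
    for i, ch in enumerate(series.channels):
        nib.save(
            nib.Nifti1Image(np.moveaxis(ch.velocity, 0, -1).astype(np.float32), aff),
            outdir / f"velocity_ch{i}.nii.gz",
        )
        meta["channels"].append(
            {"effective_venc": ch.effective_venc, "time_offset_ms": ch.time_offset_ms}
        )
    (outdir / "series.json").write_text(json.dumps(meta, indent=2))


def load_series(outdir: str | Path) -> CardiacSeries:
    import nibabel as nib

    outdir = Path(outdir)
    meta = json.loads((outdir / "series.json").read_text())
    mag = np.moveaxis(
        np.asarray(nib.load(outdir / "magnitude.nii.gz").dataobj, dtype=float), -1, 0
    )
    channels = []
    for i, chm in enumerate(meta["channels"]):
        v = np.moveaxis(
            np.asarray(nib.load(outdir / f"velocity_ch{i}.nii.gz").dataobj,
                       dtype=float), -1, 0,
        )
        channels.append(
            VelocityChannel(velocity=v, effective_venc=chm["effective_venc"],
                            time_offset_ms=chm["time_offset_ms"])
        )
    return CardiacSeries(
        magnitude=mag, channels=tuple(channels),
        phase_duration_ms=meta["phase_duration_ms"], pixel_mm=meta["pixel_mm"],
    )


def save_masks(outdir: str | Path, masks: dict[str, np.ndarray],
               pixel_mm: float) -> None:
    import nibabel as nib

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    aff = np.diag([pixel_mm, pixel_mm, 1.0, 1.0])
    for label, m in masks.items():
        nib.save(nib.Nifti1Image(m.astype(np.uint8), aff),
                 outdir / f"mask_{label}.nii.gz")


def save_waveforms_csv(path: str | Path,
                       waveforms: dict[str, FlowWaveform]) -> None:
    """Tidy CSV: one row per ROI x cardiac phase."""
    rows = []
    for label, w in waveforms.items():
        for p, q in enumerate(w.values):
            rows.append(
                dict(roi=label, phase=p, flow_ml_min=float(q),
                     cycle_length_ms=w.cycle_length_ms)
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def save_markers_csv(path: str | Path, marker_map: dict[str, FlowMarkers]) -> None:
    """Tidy CSV: one row per ROI with mean/range/deltaV."""
    rows = [
        dict(roi=label, mean_ml_min=m.mean, range_ml_min=m.range, delta_v_ul=m.delta_v)
        for label, m in marker_map.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def waveform_to_csv(path: str | Path, wf: GradientWaveform) -> None:
    """Export a gradient waveform as CSV (time us, amplitude mT/m)."""
    t = np.arange(len(wf.samples)) * wf.raster_us
    pd.DataFrame({"time_us": t, "amplitude_mT_m": wf.samples}).to_csv(
        path, index=False
    )


export_waveform_csv = waveform_to_csv


def save_trajectory(path: str | Path, traj: SpiralTrajectory) -> None:
    """Export trajectory (coords m^-1, dcf, timing) to HDF5."""
    with h5py.File(path, "w") as f:
        f.create_dataset("coords", data=traj.coords)
        f.create_dataset("dcf", data=traj.dcf)
        f.attrs["angle_increment_deg"] = traj.angle_increment_deg
        f.attrs["kmax"] = traj.kmax
        f.attrs["n_turns"] = traj.n_turns
        f.attrs["readout_duration_ms"] = traj.readout_duration_ms


def load_config(path: str | Path) -> dict:
    with open(path) as f:
        return yaml.safe_load(f)


def save_config(path: str | Path, config: dict) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(config, f, sort_keys=False)
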