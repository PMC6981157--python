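"""Readers/writers for volumes (NIfTI, MetaImage), strain fields and event
logs (HDF5), and VOI label volumes."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .imageproc import DensityImage
from .microfe import StrainField
from .voi import VOI_CODES, VOISet

__all__ = [
    "read_image",
    "write_image",
    "write_strain_field",
    "read_strain_field",
    "write_event_log",
    "read_event_log",
    "write_voi_set",
    "read_voi_set",
]


def write_image(image: DensityImage, path: str | Path) -> Path:
    """Write a density image as NIfTI (.nii/.nii.gz) or MetaImage (.mha)."""
    path = Path(path)
    suffixes = "".join(path.suffixes)
    if suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        affine = np.diag([image.voxel_size_mm] * 3 + [1.0])
        nib.save(nib.Nifti1Image(image.values.astype(np.float32), affine), str(path))
    elif path.suffix == ".mha":
        _write_metaimage(image, path)
    else:
        raise ValueError(f"unsupported image format: {path.name}")
    return path


def read_image(path: str | Path, frame: int = 0) -> DensityImage:
    path = Path(path)
    if "".join(path.suffixes).endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(str(path))
        voxel_mm = float(img.header.get_zooms()[0])
        return DensityImage(
            np.asarray(img.dataobj, dtype=np.float64), voxel_size=voxel_mm * 1000.0, frame=frame
        )
    if path.suffix == ".mha":
        return _read_metaimage(path, frame=frame)
    raise ValueError(f"unsupported image format: {path.name}")


def _write_metaimage(image: DensityImage, path: Path) -> None:
    # Minimal uncompressed MetaImage: ASCII header + little-endian raw data.
    # DimSize is fastest-varying first, so the raw buffer is Fortran-ordered.
    nx, ny, nz = image.shape
    sp = image.voxel_size_mm
    header = (
        "ObjectType = Image\n"
        "NDims = 3\n"
        "BinaryData = True\n"
        "BinaryDataByteOrderMSB = False\n"
        f"DimSize = {nx} {ny} {nz}\n"
        f"ElementSpacing = {sp:.9g} {sp:.9g} {sp:.9g}\n"
        "ElementType = MET_FLOAT\n"
        "ElementDataFile = LOCAL\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(np.asfortranarray(image.values.astype("<f4")).tobytes(order="F"))


def _read_metaimage(path: Path, frame: int = 0) -> DensityImage:
    with open(path, "rb") as fh:
        header: dict[str, str] = {}
        while True:
            line = fh.readline().decode("ascii").strip()
            key, _, val = line.partition("=")
            header[key.strip()] = val.strip()
            if key.strip() == "ElementDataFile":
                break
        if header.get("ElementType") != "MET_FLOAT":
            raise ValueError(f"unsupported ElementType {header.get('ElementType')}")
        dims = tuple(int(d) for d in header["DimSize"].split())
        spacing = float(header["ElementSpacing"].split()[0])
        raw = np.frombuffer(fh.read(), dtype="<f4", count=int(np.prod(dims)))
    values = raw.reshape(dims, order="F").astype(np.float64)
    return DensityImage(values, voxel_size=spacing * 1000.0, frame=frame)


def write_strain_field(field: StrainField, path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("eff_strain", data=field.eff_strain, compression="gzip")
        f.create_dataset("sed", data=field.sed, compression="gzip")
        f.create_dataset("displacement", data=field.displacement, compression="gzip")
        f.attrs["residual"] = field.residual
        f.attrs["n_iter"] = field.n_iter
        if field.strain_voigt is not None:
            f.create_dataset("strain_voigt", data=field.strain_voigt, compression="gzip")
    return path


def read_strain_field(path: str | Path) -> StrainField:
    with h5py.File(path, "r") as f:
        return StrainField(
            eff_strain=f["eff_strain"][()],
            sed=f["sed"][()],
            displacement=f["displacement"][()],
            residual=float(f.attrs["residual"]),
            n_iter=int(f.attrs["n_iter"]),
            strain_voigt=f["strain_voigt"][()] if "strain_voigt" in f else None,
        )


def write_event_log(log, path: str | Path) -> Path:
    """Serialise a phantom EventLog (events + preceding strain) to HDF5."""
    import dataclasses

    path = Path(path)
    with h5py.File(path, "w") as f:
        if log.rule is not None:
            f.attrs["rule"] = json.dumps(dataclasses.asdict(log.rule))
        if log.loading is not None:
            f.attrs["loading"] = json.dumps(dataclasses.asdict(log.loading))
        for i, step in enumerate(log.steps):
            g = f.create_group(f"step_{i:03d}")
            g.create_dataset("formed", data=step.formed)
            g.create_dataset("resorbed", data=step.resorbed)
            g.create_dataset("matured", data=step.matured, compression="gzip")
            g.create_dataset("eff_strain", data=step.eff_strain, compression="gzip")
    return path


def read_event_log(path: str | Path):
    from .phantom import EventLog, HealingLoading, HealingRule, StepEvents

    with h5py.File(path, "r") as f:
        rule = HealingRule(**json.loads(f.attrs["rule"])) if "rule" in f.attrs else None
        loading = (
            HealingLoading(**json.loads(f.attrs["loading"])) if "loading" in f.attrs else None
        )
        steps = []
        for name in sorted(k for k in f.keys() if k.startswith("step_")):
            g = f[name]
            steps.append(
                StepEvents(
                    formed=g["formed"][()],
                    resorbed=g["resorbed"][()],
                    matured=g["matured"][()],
                    eff_strain=g["eff_strain"][()],
                )
            )
    return EventLog(steps=steps, rule=rule, loading=loading)


def write_voi_set(vois: VOISet, path: str | Path) -> Path:
    """Write the VOI partition as one labelled volume plus a JSON sidecar."""
    path = Path(path)
    label_img = DensityImage(vois.labels().astype(float), voxel_size=vois.voxel_size)
    write_image(label_img, path)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "codes": VOI_CODES,
                "tv_defect_mm3": vois.tv_defect,
                "tv_fragment_mm3": vois.tv_fragment,
                "voxel_size_um": vois.voxel_size,
            },
            indent=2,
        )
    )
    return path


def read_voi_set(path: str | Path) -> VOISet:
    path = Path(path)
    img = read_image(path)
    labels = np.rint(img.values).astype(np.uint8)
    masks = {name: labels == code for name, code in VOI_CODES.items()}
    return VOISet(
        dc=masks["DC"], dp=masks["DP"], fc=masks["FC"], fp=masks["FP"], voxel_size=img.voxel_size
    )
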