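"""Volume and geometry file I/O.

NIfTI (via nibabel) is the primary volume format; MetaImage (.mha) is
written/read through SimpleITK, and DICOM series can be read (not
written).  Volumes keep the package's (x, y, z) axis order with voxel
sizes in mm; truth geometry is serialised as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import SimpleITK as sitk

from .phantom import PhantomTruth
from .volume import Grid, VoxelVolume


def write_volume(volume: VoxelVolume, path: str | Path) -> Path:
    """Write a volume as NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd)."""
    path = Path(path)
    suffixes = "".join(path.suffixes)
    if suffixes.endswith((".nii", ".nii.gz")):
        affine = np.diag(list(volume.spacing) + [1.0])
        affine[:3, 3] = volume.origin
        img = nib.Nifti1Image(np.asarray(volume.values, dtype=np.float32), affine)
        nib.save(img, str(path))
    elif suffixes.endswith((".mha", ".mhd")):
        img = sitk.GetImageFromArray(
            np.ascontiguousarray(np.transpose(volume.values, (2, 1, 0)).astype(np.float32))
        )
        img.SetSpacing(tuple(volume.spacing))
        img.SetOrigin(tuple(volume.origin))
        sitk.WriteImage(img, str(path))
    else:
        raise ValueError(f"unsupported volume format: {path.name}")
    return path


def read_volume(path: str | Path) -> VoxelVolume:
    """Read NIfTI / MetaImage files or a DICOM series directory."""
    path = Path(path)
    if path.is_dir():  # DICOM series
        reader = sitk.ImageSeriesReader()
        names = reader.GetGDCMSeriesFileNames(str(path))
        if not names:
            raise ValueError(f"no DICOM series found in {path}")
        reader.SetFileNames(names)
        img = reader.Execute()
        return _from_sitk(img)
    suffixes = "".join(path.suffixes)
    if suffixes.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        affine = img.affine
        spacing = tuple(float(abs(affine[i, i])) for i in range(3))
        origin = tuple(float(affine[i, 3]) for i in range(3))
        values = np.asarray(img.dataobj, dtype=np.float32)
        grid = Grid(values.shape, spacing, origin)
        return VoxelVolume(values, grid)
    if suffixes.endswith((".mha", ".mhd")) or path.suffix == ".dcm":
        return _from_sitk(sitk.ReadImage(str(path)))
    raise ValueError(f"unsupported volume format: {path.name}")


def _from_sitk(img: sitk.Image) -> VoxelVolume:
    values = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0)).astype(np.float32)
    grid = Grid(values.shape, tuple(img.GetSpacing()), tuple(img.GetOrigin()))
    return VoxelVolume(values, grid)


def write_truth_geometry(truth: PhantomTruth, path: str | Path) -> Path:
    """Serialise analytic truth geometry (centerlines, diameters) to JSON."""
    path = Path(path)
    spec = truth.spec
    payload = {
        "materials": {
            "contrast_hu": spec.contrast_hu,
            "soft_tissue_hu": spec.soft_tissue_hu,
            "myocardium_hu": spec.myocardium_hu,
            "bone_hu": spec.bone_hu,
            "air_hu": spec.air_hu,
            "iodine_mg_per_ml": spec.iodine_mg_per_ml,
        },
        "heart": {
            "center": list(spec.heart_center),
            "ventricle_radius": spec.ventricle_radius,
            "myocardium_outer_radius": spec.myocardium_outer_radius,
        },
        "vessels": [
            {
                "label": g.label,
                "centerline": g.points.tolist(),
                "arc_length": g.arc.tolist(),
                "reference_diameter": g.reference_diameter_at(g.arc).tolist(),
                "true_diameter": g.diameter_at(g.arc).tolist(),
                "stenosis": (
                    None
                    if g.spec.stenosis is None
                    else {
                        "s_center": g.spec.stenosis.s_center,
                        "severity": g.spec.stenosis.severity,
                        "length_mm": g.spec.stenosis.length_mm,
                    }
                ),
            }
            for g in truth.vessels.values()
        ],
        "stent": (
            None
            if spec.stent is None
            else {
                "vessel": spec.stent.vessel_label,
                "s_center": spec.stent.s_center,
                "length_mm": spec.stent.length_mm,
                "nominal_diameter_mm": spec.stent.nominal_diameter_mm,
                "strut_hu": spec.stent.strut_hu,
                "strut_thickness_mm": spec.stent.strut_thickness_mm,
            }
        ),
    }
    path.write_text(json.dumps(payload, indent=2))
    return path
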