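"""File I/O: density tables, ligand parameters, calibrations, phantoms.

Exchange formats
----------------
* long density table (CSV): ``area,receptor,stratum,brain,density`` with
  stratum in {sg, g, ig}; the canonical replicate-level format;
* wide strata table (CSV): ``area,receptor,brain,mean_sg,mean_g,mean_ig,
  mean_all,n_profiles``;
* ligand parameters: YAML/JSON keyed by receptor name;
* film calibration: JSON (parameters, residuals, valid gray range);
* phantom: 16-bit TIFF or PNG raster plus a JSON sidecar with contours,
  standards ROIs and the rendered ground truth.

Numeric outputs written by the pipeline carry a provenance comment line
(``# provenance: ...``) which the readers skip.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibration import FilmCalibration, LigandParams
from .profiles import CorticalGeometry
from .synthetic import Phantom

STRATUM_VOCAB = ("sg", "g", "ig")
_STRATUM_SUGGESTIONS = {
    "supragranular": "sg", "granular": "g", "infragranular": "ig",
    "layeriv": "g", "layer4": "g", "iv": "g",
    "i-iii": "sg", "v-vi": "ig", "upper": "sg", "lower": "ig",
}


class TableFormatError(ValueError):
    """Raised for malformed density tables, with offending line numbers."""


def write_density_table(df: pd.DataFrame, path, provenance: str | None = None) -> None:
    """Write a long density table; optional provenance comment line first."""
    path = Path(path)
    with open(path, "w") as fh:
        if provenance:
            fh.write(f"# provenance: {provenance}\n")
        df.to_csv(fh, index=False)


def read_density_table(path, known_areas=None, known_receptors=None) -> pd.DataFrame:
    """Read and validate a long density table (fmol/mg protein).

    Checks header, stratum vocabulary (suggesting sg/g/ig for common
    synonyms), numeric parsability and non-negative densities; errors cite
    1-based file line numbers.  ``known_areas`` / ``known_receptors``
    restrict the accepted name sets.
    """
    path = Path(path)
    with open(path) as fh:
        raw_lines = fh.readlines()
    lines = [(i + 1, line.rstrip("\n")) for i, line in enumerate(raw_lines)
             if line.strip() and not line.lstrip().startswith("#")]
    if not lines:
        raise TableFormatError(f"{path}: empty table")
    header = [c.strip() for c in lines[0][1].split(",")]
    expected = ["area", "receptor", "stratum", "brain", "density"]
    if header != expected:
        raise TableFormatError(
            f"{path}: line {lines[0][0]}: header must be {','.join(expected)}")

    records = []
    for lineno, line in lines[1:]:
        parts = [c.strip() for c in line.split(",")]
        if len(parts) != 5:
            raise TableFormatError(f"{path}: line {lineno}: expected 5 fields, "
                                   f"got {len(parts)}")
        area, receptor, stratum, brain, density = parts
        if stratum not in STRATUM_VOCAB:
            hint = _STRATUM_SUGGESTIONS.get(stratum.lower())
            extra = f" (did you mean {hint!r}?)" if hint else ""
            raise TableFormatError(
                f"{path}: line {lineno}: unknown stratum {stratum!r}{extra}")
        try:
            brain_i = int(brain)
            density_f = float(density)
        except ValueError as exc:
            raise TableFormatError(f"{path}: line {lineno}: {exc}") from exc
        if density_f < 0:
            raise TableFormatError(
                f"{path}: line {lineno}: negative density {density_f}")
        if known_areas is not None and area not in known_areas:
            raise TableFormatError(f"{path}: line {lineno}: unknown area {area!r}")
        if known_receptors is not None and receptor not in known_receptors:
            raise TableFormatError(f"{path}: line {lineno}: unknown receptor {receptor!r}")
        records.append((area, receptor, stratum, brain_i, density_f))
    return pd.DataFrame.from_records(
        records, columns=["area", "receptor", "stratum", "brain", "density"])


def write_strata_table(df: pd.DataFrame, path, provenance: str | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if provenance:
            fh.write(f"# provenance: {provenance}\n")
        df.to_csv(fh, index=False)


def read_strata_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    required = {"area", "receptor", "brain", "mean_sg", "mean_g", "mean_ig", "mean_all"}
    missing = required - set(df.columns)
    if missing:
        raise TableFormatError(f"{path}: missing columns {sorted(missing)}")
    return df


# --------------------------------------------------------------------------
# Ligand parameters and calibration
# --------------------------------------------------------------------------

def write_ligand_params(ligands: dict[str, LigandParams], path) -> None:
    """YAML (or JSON, by suffix) file keyed by receptor name."""
    payload = {name: lig.to_dict() for name, lig in ligands.items()}
    path = Path(path)
    with open(path, "w") as fh:
        if path.suffix == ".json":
            json.dump(payload, fh, indent=2)
        else:
            yaml.safe_dump(payload, fh)


def read_ligand_params(path) -> dict[str, LigandParams]:
    path = Path(path)
    with open(path) as fh:
        payload = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
    return {name: LigandParams.from_dict(d) for name, d in payload.items()}


def write_calibration(cal: FilmCalibration, path) -> None:
    Path(path).write_text(cal.to_json())


def read_calibration(path) -> FilmCalibration:
    return FilmCalibration.from_json(Path(path).read_text())


# --------------------------------------------------------------------------
# Phantom rasters and sidecars
# --------------------------------------------------------------------------

def write_phantom(phantom: Phantom, image_path, sidecar_path=None) -> None:
    """Raster as 16-bit TIFF/PNG plus a JSON sidecar with the annotations."""
    image_path = Path(image_path)
    if image_path.suffix.lower() in (".tif", ".tiff"):
        import tifffile
        tifffile.imwrite(image_path, phantom.image)
    elif image_path.suffix.lower() == ".png":
        from PIL import Image
        Image.fromarray(phantom.image.astype(np.uint16)).save(image_path)
    else:
        raise ValueError(f"unsupported raster format {image_path.suffix!r}")

    if sidecar_path is None:
        sidecar_path = image_path.with_suffix(".json")
    sidecar = {
        "receptor": phantom.receptor,
        "brain": int(phantom.brain),
        "seed": int(phantom.spec.seed),
        "film": phantom.film.params(),
        "ligand": phantom.ligand.to_dict(),
        "standards_rois": [{"roi": list(map(int, roi)), "known_R": level}
                           for roi, level in phantom.standards_rois],
        "pial_contour": phantom.pial_contour.tolist(),
        "wm_contour": phantom.wm_contour.tolist(),
        "areas": {
            name: {
                "pial": g.pial.tolist(), "wm": g.wm.tolist(),
                "border_fractions": list(g.border_fractions),
                "agranular": g.agranular,
                "layer3_lower_fraction": g.layer3_lower_fraction,
            } for name, g in phantom.area_geometries.items()
        },
        "truth": phantom.truth.to_dict(orient="records"),
    }
    Path(sidecar_path).write_text(json.dumps(sidecar, indent=2))


def read_phantom_image(image_path) -> np.ndarray:
    image_path = Path(image_path)
    if image_path.suffix.lower() in (".tif", ".tiff"):
        import tifffile
        return tifffile.imread(image_path)
    from PIL import Image
    return np.asarray(Image.open(image_path), dtype=np.uint16)


def read_geometries(sidecar_path) -> dict[str, CorticalGeometry]:
    sidecar = json.loads(Path(sidecar_path).read_text())
    return {
        name: CorticalGeometry(
            pial=np.asarray(d["pial"], dtype=float),
            wm=np.asarray(d["wm"], dtype=float),
            border_fractions=tuple(d["border_fractions"]),
            agranular=d["agranular"],
            layer3_lower_fraction=d["layer3_lower_fraction"],
            area=name,
        ) for name, d in sidecar["areas"].items()
    }
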