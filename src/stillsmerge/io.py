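"""File formats: per-image reflection text files and merged MTZ/text output.

Per-image format (plain text, one file per still)::

    # stillsmerge image
    image_id 12
    orientation m00 m01 m02 m10 m11 m12 m20 m21 m22
    cell_a 106.1
    wavelength 1.46
    h k l I sigI
    1 2 3 1523.4 41.2
    ...

Header lines are mandatory; malformed body lines are skipped with a warning
carrying the line number.  The format round-trips losslessly (values printed
with repr precision).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import gemmi
import numpy as np

from .geometry import Orientation, UnitCell
from .image import ImageModel
from .scaling import MergedDataset

__all__ = ["read_image_file", "write_image_file", "write_merged", "read_merged_text",
           "write_hand_table"]


def write_image_file(image: ImageModel, path: str | Path) -> None:
    path = Path(path)
    g = lambda v: format(float(v), ".17g")
    lines = ["# stillsmerge image", f"image_id {image.image_id}"]
    lines.append("orientation " + " ".join(g(v) for v in image.orientation.U.ravel()))
    lines.append(f"cell_a {g(image.cell.a)}")
    lines.append(f"wavelength {g(image.mu_estimate)}")
    lines.append("h k l I sigI")
    for (h, k, l), i, s in zip(image.hkl, image.i_raw, image.sigma_raw):
        lines.append(f"{h} {k} {l} {g(i)} {g(s)}")
    path.write_text("\n".join(lines) + "\n")


def read_image_file(path: str | Path) -> ImageModel:
    """Parse a per-image reflection file; hard fail on a bad header,
    skip-with-warning on malformed body rows."""
    path = Path(path)
    lines = path.read_text().splitlines()
    header: dict[str, str] = {}
    body_start = None
    for i, line in enumerate(lines):
        if line.startswith("#"):
            continue
        if line.strip() == "h k l I sigI":
            body_start = i + 1
            break
        parts = line.split(None, 1)
        if len(parts) == 2:
            header[parts[0]] = parts[1]
    for key in ("image_id", "orientation", "cell_a", "wavelength"):
        if key not in header:
            raise ValueError(f"{path}: missing header field {key!r}")
    if body_start is None:
        raise ValueError(f"{path}: missing 'h k l I sigI' body marker")
    U = np.array([float(v) for v in header["orientation"].split()])
    if U.size != 9:
        raise ValueError(f"{path}: orientation must have 9 entries")
    orientation = Orientation(U.reshape(3, 3))  # raises if not orthonormal
    cell = UnitCell(float(header["cell_a"]))
    hkl, ivals, svals = [], [], []
    for ln, line in enumerate(lines[body_start:], start=body_start + 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split()
        try:
            if len(parts) != 5:
                raise ValueError("expected 5 fields")
            h, k, l = int(parts[0]), int(parts[1]), int(parts[2])
            i, s = float(parts[3]), float(parts[4])
            if s <= 0:
                raise ValueError("non-positive sigma")
        except ValueError as exc:
            warnings.warn(f"{path}:{ln}: skipping malformed line ({exc})")
            continue
        hkl.append((h, k, l))
        ivals.append(i)
        svals.append(s)
    return ImageModel(
        image_id=int(header["image_id"]),
        orientation=orientation,
        mu_estimate=float(header["wavelength"]),
        hkl=np.array(hkl, dtype=int).reshape(-1, 3),
        i_raw=np.array(ivals),
        sigma_raw=np.array(svals),
        cell=cell,
    )


def write_merged(
    dataset: MergedDataset, path: str | Path, fmt: str = "text", overwrite: bool = False
) -> None:
    """Write a merged dataset as MTZ (H K L I SIGI MULT) or whitespace text.

    The text table has one reflection per line, columns ``h k l I sigI mult``.
    Refuses to overwrite an existing file unless ``overwrite`` is set.
    """
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace")
    if len(dataset) == 0:
        raise ValueError("refusing to write an empty merged dataset")
    if fmt == "text":
        lines = ["# h k l I sigI mult"]
        for (h, k, l), i, s, m in zip(
            dataset.hkl, dataset.intensity, dataset.sigma, dataset.multiplicity
        ):
            lines.append(f"{h} {k} {l} {i:.6f} {s:.6f} {m}")
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "mtz":
        mtz = gemmi.Mtz(with_base=True)
        mtz.spacegroup = gemmi.SpaceGroup(dataset.cell.space_group)
        mtz.set_cell_for_all(dataset.cell.gemmi_cell)
        mtz.add_dataset("merged")
        mtz.add_column("I", "J")
        mtz.add_column("SIGI", "Q")
        mtz.add_column("MULT", "I")
        data = np.column_stack(
            [
                dataset.hkl.astype(float),
                dataset.intensity,
                dataset.sigma,
                dataset.multiplicity.astype(float),
            ]
        )
        mtz.set_data(data)
        mtz.write_to_file(str(path))
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_merged_text(path: str | Path, cell: UnitCell | None = None) -> MergedDataset:
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        p = line.split()
        rows.append((int(p[0]), int(p[1]), int(p[2]), float(p[3]), float(p[4]), int(p[5])))
    hkl = np.array([[r[0], r[1], r[2]] for r in rows], dtype=int)
    return MergedDataset(
        hkl=hkl,
        intensity=np.array([r[3] for r in rows]),
        sigma=np.array([r[4] for r in rows]),
        multiplicity=np.array([r[5] for r in rows], dtype=int),
        cell=cell or UnitCell(),
    )


def write_hand_table(path: str | Path, image_ids, hands, vectors) -> None:
    """Audit table of the ambiguity resolution: image_id, hand, vector components."""
    lines = ["# image_id hand x1 x2"]
    for iid, h, v in zip(image_ids, hands, vectors):
        lines.append(f"{iid} {h} {v[0]:.6f} {v[1]:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")
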