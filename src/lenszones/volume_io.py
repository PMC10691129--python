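"""Volume serialization: multi-page TIFF + JSON sidecar.

One TIFF page per B-scan; the sidecar carries the scan geometry, coordinate
state, provenance and an array checksum so files are self-describing and
round-trips are verifiably bit-identical.  Intensities are stored at the
in-memory dtype (float32 on the 16-bit a.u. scale) — no silent downcast.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

from .errors import ValidationError
from .render import OctVolume, ScanGeometry

SCHEMA_VERSION = "lenszones.VolumeBundle/1"


@dataclass(frozen=True)
class VolumeBundle:
    """Paths of a written volume (TIFF stack + JSON metadata) and its checksum."""

    tiff_path: Path
    meta_path: Path
    sha256: str


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_volume(volume: OctVolume, path) -> VolumeBundle:
    """Write the volume as a multi-page TIFF plus JSON sidecar."""
    path = Path(path)
    data = np.ascontiguousarray(volume.data)
    tifffile.imwrite(path, data, photometric="minisblack")
    digest = hashlib.sha256(data.tobytes()).hexdigest()
    meta = {
        "schema": SCHEMA_VERSION,
        "shape": list(data.shape),
        "dtype": str(data.dtype),
        "scan": volume.scan.to_dict(),
        "coordinate_state": volume.coordinate_state,
        "axial_pitch_mm": volume.axial_pitch_mm,
        "provenance": volume.provenance,
        "flagged": volume.flagged.tolist() if volume.flagged is not None else None,
        "sha256": digest,
    }
    meta_path = _sidecar_path(path)
    meta_path.write_text(json.dumps(meta, indent=1))
    return VolumeBundle(tiff_path=path, meta_path=meta_path, sha256=digest)


def read_volume(path) -> OctVolume:
    """Read a volume bundle; refuses on any shape/metadata mismatch."""
    path = Path(path)
    meta_path = _sidecar_path(path)
    if not meta_path.exists():
        raise ValidationError(f"missing metadata sidecar {meta_path}")
    meta = json.loads(meta_path.read_text())
    if meta.get("schema") != SCHEMA_VERSION:
        raise ValidationError(f"unsupported metadata schema {meta.get('schema')!r}")
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    expected = tuple(meta["shape"])
    if data.shape != expected:
        raise ValidationError(
            f"TIFF shape {data.shape} does not match metadata shape {expected}"
        )
    if str(data.dtype) != meta["dtype"]:
        raise ValidationError(f"TIFF dtype {data.dtype} != metadata dtype {meta['dtype']}")
    digest = hashlib.sha256(np.ascontiguousarray(data).tobytes()).hexdigest()
    if digest != meta["sha256"]:
        raise ValidationError("volume checksum mismatch: file corrupted or edited")
    flagged = meta.get("flagged")
    return OctVolume(
        data=data,
        scan=ScanGeometry(**meta["scan"]),
        coordinate_state=meta["coordinate_state"],
        axial_pitch_mm=meta["axial_pitch_mm"],
        provenance=list(meta.get("provenance", [])),
        flagged=np.asarray(flagged, dtype=bool) if flagged is not None else None,
    )
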