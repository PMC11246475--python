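"""JSON persistence for calibration artifacts.

One schema (``conformap-calibration-v1``) covers all methods; the
``method`` field dispatches loading.  Artifacts carry everything needed to
apply a calibrated predictor elsewhere — thresholds/margins, alpha, the
class roster (which fixes the bitmask band order for raster products), the
calibration size, and creation metadata.  Writes are atomic (temp file +
rename) so a crashed run never leaves a half-written artifact.
"""

from __future__ import annotations

import json
import os
import tempfile
from datetime import datetime, timezone

from .classification import LacCalibration, MondrianCalibration
from .regression import RegressionCalibration

__all__ = ["save_calibration", "load_calibration", "write_json_atomic"]

_LOADERS = {
    "lac": LacCalibration.from_json,
    "mondrian": MondrianCalibration.from_json,
    "absolute_residual": RegressionCalibration.from_json,
    "cqr": RegressionCalibration.from_json,
}


def write_json_atomic(doc: dict, path) -> None:
    directory = os.path.dirname(os.path.abspath(path)) or "."
    fd, tmp = tempfile.mkstemp(dir=directory, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as handle:
            json.dump(doc, handle, indent=2, sort_keys=True)
            handle.write("\n")
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def save_calibration(calibration, path, *, extra: dict | None = None) -> None:
    """Serialize a calibration object to a JSON artifact file."""
    doc = calibration.to_json()
    doc["created"] = datetime.now(timezone.utc).isoformat(timespec="seconds")
    from . import __version__

    doc["conformap_version"] = __version__
    if extra:
        doc.update(extra)
    write_json_atomic(doc, path)


def load_calibration(path):
    """Load a calibration artifact, dispatching on its ``method`` field."""
    with open(path) as handle:
        doc = json.load(handle)
    if doc.get("schema") != "conformap-calibration-v1":
        raise ValueError(f"{path} is not a conformap calibration artifact")
    method = doc.get("method")
    if method not in _LOADERS:
        raise ValueError(f"unknown calibration method {method!r} in {path}")
    return _LOADERS[method](doc)
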