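"""Study containers and file formats.

The canonical exchange format is one JSON document per study
(schema ``lvmass-contour/1``)::

    {
      "schema": "lvmass-contour/1",
      "study_id": "pig001",
      "phase": "end-diastole",
      "contours": [
        {"view": "AP4CH", "boundary": "endocardium",
         "points": [[x, y], ...],          # cm
         "base_indices": [0, 123]},        # apical views only
        ...
      ],
      "linear": {"ivsd": 0.97, "lvidd": 4.8, "pwtd": 0.97},   # cm, optional
      "metadata": {...}                                        # optional
    }

A flat CSV point list (columns ``view, boundary, x, y``, points in tracing
order) is accepted for interoperability; it carries no base landmarks or
linear measures.  All coordinates are centimetres.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import ContourError, GeometryError, TracingError, ValidationError
from .geometry import (
    BiplaneTracing,
    LinearMeasures,
    PlanarContour,
    PsaxTracing,
)

SCHEMA = "lvmass-contour/1"


@dataclass(frozen=True)
class StudyMeasurements:
    """All tracings and linear measures of one subject at one phase."""

    study_id: str
    biplane: Optional[BiplaneTracing] = None
    psax: Optional[PsaxTracing] = None
    linear: Optional[LinearMeasures] = None
    phase: str = "end-diastole"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.biplane is None and self.psax is None and self.linear is None:
            raise ValidationError(
                f"study {self.study_id!r}: at least one measurement group "
                "(biplane, psax, linear) is required")


@dataclass(frozen=True)
class RunConfig:
    """Pipeline-wide constants."""

    density: float = 1.05
    n_disks: int = 20
    loa_multiplier: float = 1.96
    alpha: float = 0.05
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValidationError("density must be > 0")
        if self.n_disks < 1:
            raise ValidationError("n_disks must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError("alpha must lie in (0, 1)")


# ---------------------------------------------------------------------------
# JSON round trip
# ---------------------------------------------------------------------------

def _contour_to_dict(c: PlanarContour) -> dict:
    d = {"view": c.view, "boundary": c.boundary,
         "points": [[float(x), float(y)] for x, y in c.points]}
    if c.base_indices is not None:
        d["base_indices"] = list(c.base_indices)
    return d


def write_study(study: StudyMeasurements, path) -> None:
    """Serialize a study to the ``lvmass-contour/1`` JSON format."""
    contours = []
    if study.biplane is not None:
        bi = study.biplane
        for c in (bi.ap4ch_endo, bi.ap2ch_endo, bi.ap4ch_epi, bi.ap2ch_epi):
            if c is not None:
                contours.append(_contour_to_dict(c))
    if study.psax is not None:
        contours.append(_contour_to_dict(study.psax.endo))
        contours.append(_contour_to_dict(study.psax.epi))
    doc = {"schema": SCHEMA, "study_id": study.study_id, "phase": study.phase,
           "contours": contours}
    if study.linear is not None:
        lm = study.linear
        doc["linear"] = {k: v for k, v in
                         (("ivsd", lm.ivsd), ("lvidd", lm.lvidd),
                          ("pwtd", lm.pwtd), ("lvids", lm.lvids))
                         if v is not None}
    if study.metadata:
        doc["metadata"] = study.metadata
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def _parse_contour(rec: dict, idx: int, study_id: str, phase: str) -> PlanarContour:
    where = f"study {study_id!r}, contours[{idx}]"
    for key in ("view", "boundary", "points"):
        if key not in rec:
            raise ValidationError(f"{where}: missing field {key!r}")
    base = rec.get("base_indices")
    try:
        return PlanarContour(
            points=np.asarray(rec["points"], dtype=float),
            view=str(rec["view"]), boundary=str(rec["boundary"]), phase=phase,
            base_indices=tuple(base) if base is not None else None)
    except (ContourError, TypeError, ValueError) as err:
        raise ValidationError(f"{where} ({rec.get('view')}/{rec.get('boundary')}): {err}")


def _assemble(study_id: str, phase: str, contours: list[PlanarContour],
              linear: Optional[LinearMeasures], metadata: dict) -> StudyMeasurements:
    by_key = {}
    for c in contours:
        key = (c.view, c.boundary)
        if key in by_key:
            raise ValidationError(f"study {study_id!r}: duplicate contour for {key}")
        by_key[key] = c

    biplane = None
    if ("AP4CH", "endocardium") in by_key and ("AP2CH", "endocardium") in by_key:
        try:
            biplane = BiplaneTracing(
                ap4ch_endo=by_key[("AP4CH", "endocardium")],
                ap2ch_endo=by_key[("AP2CH", "endocardium")],
                ap4ch_epi=by_key.get(("AP4CH", "epicardium")),
                ap2ch_epi=by_key.get(("AP2CH", "epicardium")))
        except (ContourError, TracingError) as err:
            raise ValidationError(f"study {study_id!r}: biplane tracing invalid: {err}")

    psax = None
    if ("PSAX", "endocardium") in by_key and ("PSAX", "epicardium") in by_key:
        try:
            psax = PsaxTracing(endo=by_key[("PSAX", "endocardium")],
                               epi=by_key[("PSAX", "epicardium")])
        except (ContourError, TracingError) as err:
            raise ValidationError(f"study {study_id!r}: PSAX tracing invalid: {err}")

    return StudyMeasurements(study_id=study_id, biplane=biplane, psax=psax,
                             linear=linear, phase=phase, metadata=metadata)


def read_study(path) -> StudyMeasurements:
    """Load and validate a study from JSON (or a CSV point list)."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return read_study_csv(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as err:
        raise ValidationError(f"{path}: not valid JSON: {err}")
    if not isinstance(doc, dict):
        raise ValidationError(f"{path}: expected a JSON object")
    if doc.get("schema") != SCHEMA:
        raise ValidationError(
            f"{path}: schema {doc.get('schema')!r} is not {SCHEMA!r}")
    if "study_id" not in doc:
        raise ValidationError(f"{path}: missing field 'study_id'")
    study_id = str(doc["study_id"])
    phase = str(doc.get("phase", "end-diastole"))

    contours = [_parse_contour(rec, i, study_id, phase)
                for i, rec in enumerate(doc.get("contours", []))]

    linear = None
    if "linear" in doc:
        lin = doc["linear"]
        for key in ("ivsd", "lvidd", "pwtd"):
            if key not in lin:
                raise ValidationError(
                    f"study {study_id!r}: linear measures missing field {key!r}")
        try:
            linear = LinearMeasures(ivsd=float(lin["ivsd"]), lvidd=float(lin["lvidd"]),
                                    pwtd=float(lin["pwtd"]),
                                    lvids=float(lin["lvids"]) if "lvids" in lin else None)
        except (GeometryError, ValueError) as err:
            raise ValidationError(f"study {study_id!r}: linear measures invalid: {err}")

    return _assemble(study_id, phase, contours, linear, dict(doc.get("metadata", {})))


def read_study_csv(path, study_id: Optional[str] = None) -> StudyMeasurements:
    """Import a flat ``view, boundary, x, y`` CSV point list."""
    import pandas as pd

    path = Path(path)
    df = pd.read_csv(path)
    required = {"view", "boundary", "x", "y"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"{path}: CSV must have columns {sorted(required)}, got {list(df.columns)}")
    study_id = study_id or path.stem
    contours = []
    for i, ((view, boundary), grp) in enumerate(df.groupby(["view", "boundary"],
                                                           sort=False)):
        rec = {"view": view, "boundary": boundary,
               "points": grp[["x", "y"]].to_numpy().tolist()}
        if view in ("AP4CH", "AP2CH"):
            # tracing convention: apical borders start and end at the annulus
            rec["base_indices"] = [0, len(rec["points"]) - 1]
        contours.append(_parse_contour(rec, i, study_id, "end-diastole"))
    return _assemble(study_id, "end-diastole", contours, None, {})
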