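"""Data model and I/O for digitized longitudinal tooth-section tracings.

A :class:`ToothSection` bundles everything a histologist traces on a
thin-section micrograph of a (deciduous first molar) mesio-buccal cusp:
the enamel–dentine junction (EDJ) polyline from dentine horn to cervix,
the closed enamel outline, 200-µm prism segment traces, striae of
Retzius / accentuated lines / the neonatal line, and the cross-striation
run measurements used to estimate local daily secretion rates.

Sections are serialized to a package-defined JSON schema (shipped as a
JSON-Schema document in ``odontochron/data/tracing.schema.json``).
Partial inputs are accepted as ImageJ-style two-column XY CSV exports
and tpsDig TPS landmark/curve files.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .geometry import Point2D, Polyline

STRIA_KINDS = ("retzius", "accentuated", "neonatal")
NOMINAL_SEGMENT_UM = 200.0
MIN_RUN_STRIATIONS = 6

__all__ = [
    "CrossStriationRun",
    "StriaTrace",
    "PrismSegmentTrace",
    "ToothSection",
    "ChronologyRecord",
    "TracingError",
    "read_tracing",
    "write_tracing",
    "read_xy_table",
    "read_tps",
    "write_tps",
    "write_chronology_table",
]


class TracingError(ValueError):
    """Raised when a tracing file violates the schema or its invariants."""


@dataclass(frozen=True)
class CrossStriationRun:
    """A run of consecutive daily cross-striations measured on one segment.

    ``run_length / n_striations`` is one local daily-secretion-rate
    (DSR) reading in µm/day. Runs shorter than 6 striations are accepted
    with a warning: they are usable but noisier.
    """

    segment_index: int
    run_length: float  # µm
    n_striations: int

    def __post_init__(self) -> None:
        if self.run_length <= 0:
            raise TracingError(f"run_length must be > 0, got {self.run_length}")
        if self.n_striations < 1:
            raise TracingError("n_striations must be >= 1")
        if self.n_striations < MIN_RUN_STRIATIONS:
            warnings.warn(
                f"cross-striation run on segment {self.segment_index} has only "
                f"{self.n_striations} striations (< {MIN_RUN_STRIATIONS})",
                stacklevel=2,
            )

    @property
    def dsr(self) -> float:
        """Local daily secretion rate of this run, µm/day."""
        return self.run_length / self.n_striations


@dataclass(frozen=True)
class StriaTrace:
    """One traced incremental line, running from the enamel down to the EDJ."""

    id: str
    path: Polyline
    kind: str = "retzius"

    def __post_init__(self) -> None:
        if self.kind not in STRIA_KINDS:
            raise TracingError(f"unknown stria kind {self.kind!r}")


@dataclass(frozen=True)
class PrismSegmentTrace:
    """A ~200 µm prism segment of the chaining procedure.

    ``terminal_stria`` names the stria of Retzius at the segment's outer
    end; the last (cervical) segment may have none and may be shorter
    than the nominal 200 µm.
    """

    index: int
    path: Polyline
    start_on_edj: Point2D
    terminal_stria: Optional[str] = None


@dataclass
class SectionFlags:
    worn_horn: bool = False       # dentine horn worn: CFT/Ci are minimum estimates
    broken_cervix: bool = False   # cervical enamel missing: CFT/Cc unusable
    exclude_cc: bool = False      # editorial exclusion from crown-completion stats


@dataclass
class ToothSection:
    """Full digitized tracing of one longitudinal section plus metadata."""

    id: str
    site: str
    arch: str                      # "upper" | "lower"
    side: str
    sex: str                       # "M" | "F" | "unknown"
    wear_stage: int                # Molnar grade 1..8
    edj: Polyline                  # dentine horn -> cervix
    enamel_outline: Polyline       # closed (first == last vertex implied)
    prisms: list[PrismSegmentTrace] = field(default_factory=list)
    striae: list[StriaTrace] = field(default_factory=list)
    runs: list[CrossStriationRun] = field(default_factory=list)
    flags: SectionFlags = field(default_factory=SectionFlags)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.arch not in ("upper", "lower"):
            raise TracingError(f"arch must be upper/lower, got {self.arch!r}")
        if not 1 <= int(self.wear_stage) <= 8:
            raise TracingError(f"Molnar wear stage out of range: {self.wear_stage}")
        idx = [p.index for p in self.prisms]
        if idx != sorted(idx) or len(set(idx)) != len(idx):
            raise TracingError("prism segments must be ordered by unique index")
        labels = {s.id for s in self.striae}
        if len(labels) != len(self.striae):
            raise TracingError("duplicate stria ids")
        for p in self.prisms:
            if p.terminal_stria is not None and p.terminal_stria not in labels:
                raise TracingError(
                    f"prism {p.index} references missing stria {p.terminal_stria!r}"
                )
        nnl = [s for s in self.striae if s.kind == "neonatal"]
        if len(nnl) > 1:
            raise TracingError("more than one neonatal line in section")
        if not nnl:
            warnings.warn(
                f"section {self.id}: no neonatal line traced; chronology will be "
                "restricted to CFT (no Ci/Cc split)",
                stacklevel=2,
            )

    @property
    def neonatal_line(self) -> Optional[StriaTrace]:
        for s in self.striae:
            if s.kind == "neonatal":
                return s
        return None

    def runs_for_segment(self, index: int) -> list[CrossStriationRun]:
        return [r for r in self.runs if r.segment_index == index]


@dataclass
class ChronologyRecord:
    """One tooth's crown-chronology summary (a Table-1-style row).

    Day values are integer-rounded for reporting; ``None`` marks a value
    that is not available or editorially excluded. ``cft_ci_eligible``
    mirrors the "unworn dentine horn" footnote (tooth counts toward
    CFT/Ci means); ``cc_excluded`` mirrors the "excluded for Cc"
    footnote (broken cervical portion).
    """

    id: str
    arch: str
    sex: str
    wear_stage: int
    cft: Optional[float] = None            # days
    ci: Optional[float] = None             # days before birth
    cc: Optional[float] = None             # days after birth
    inner_dsr_mean: Optional[float] = None  # µm/day
    n_accentuated: int = 0
    site: str = ""
    individual: str = ""
    cft_ci_eligible: bool = True
    cc_excluded: bool = False

    def __post_init__(self) -> None:
        if all(v is not None for v in (self.cft, self.ci, self.cc)):
            if abs(self.cft - (self.ci + self.cc)) > 1.0 + 1e-9:
                raise TracingError(
                    f"{self.id}: CFT={self.cft} != CI+CC={self.ci + self.cc} (±1 d)"
                )


# ---------------------------------------------------------------------------
# tracing JSON
# ---------------------------------------------------------------------------

SCHEMA_TAG = "odontochron-tracing/1"


def _poly_to_list(poly: Polyline) -> list[list[float]]:
    return [[round(float(x), 6), round(float(y), 6)] for x, y in poly.coords]


def section_to_dict(section: ToothSection) -> dict:
    return {
        "schema": SCHEMA_TAG,
        "id": section.id,
        "site": section.site,
        "arch": section.arch,
        "side": section.side,
        "sex": section.sex,
        "wear_stage": int(section.wear_stage),
        "flags": asdict(section.flags),
        "edj": _poly_to_list(section.edj),
        "enamel_outline": _poly_to_list(section.enamel_outline),
        "prisms": [
            {
                "index": p.index,
                "path": _poly_to_list(p.path),
                "start_on_edj": [round(p.start_on_edj.x, 6), round(p.start_on_edj.y, 6)],
                "terminal_stria": p.terminal_stria,
            }
            for p in section.prisms
        ],
        "striae": [
            {"id": s.id, "kind": s.kind, "path": _poly_to_list(s.path)}
            for s in section.striae
        ],
        "runs": [
            {
                "segment_index": r.segment_index,
                "run_length": round(r.run_length, 6),
                "n_striations": r.n_striations,
            }
            for r in section.runs
        ],
    }


def section_from_dict(doc: dict) -> ToothSection:
    if doc.get("schema") != SCHEMA_TAG:
        raise TracingError(f"not an {SCHEMA_TAG} document")
    try:
        return ToothSection(
            id=doc["id"],
            site=doc.get("site", ""),
            arch=doc["arch"],
            side=doc.get("side", ""),
            sex=doc.get("sex", "unknown"),
            wear_stage=doc["wear_stage"],
            edj=Polyline(doc["edj"], dedup=True),
            enamel_outline=Polyline(doc["enamel_outline"], dedup=True),
            prisms=[
                PrismSegmentTrace(
                    index=p["index"],
                    path=Polyline(p["path"], dedup=True),
                    start_on_edj=Point2D(*p["start_on_edj"]),
                    terminal_stria=p.get("terminal_stria"),
                )
                for p in doc.get("prisms", [])
            ],
            striae=[
                StriaTrace(id=s["id"], kind=s.get("kind", "retzius"),
                           path=Polyline(s["path"], dedup=True))
                for s in doc.get("striae", [])
            ],
            runs=[
                CrossStriationRun(
                    segment_index=r["segment_index"],
                    run_length=r["run_length"],
                    n_striations=r["n_striations"],
                )
                for r in doc.get("runs", [])
            ],
            flags=SectionFlags(**doc.get("flags", {})),
        )
    except KeyError as exc:
        raise TracingError(f"tracing document missing field {exc}") from exc


def write_tracing(section: ToothSection, path) -> None:
    Path(path).write_text(
        json.dumps(section_to_dict(section), indent=1, sort_keys=True) + "\n"
    )


def read_tracing(path) -> ToothSection:
    """Load a tracing JSON file, validating all section invariants.

    A missing neonatal line is tolerated (warning; chronology restricted
    to CFT). A terminal stria label that names no traced stria is a hard
    error.
    """
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise TracingError(f"{path}: not valid JSON ({exc})") from exc
    return section_from_dict(doc)


# ---------------------------------------------------------------------------
# ImageJ XY CSV
# ---------------------------------------------------------------------------

def read_xy_table(path, role: str = "edj") -> Polyline:
    """Read a two-column ImageJ XY export (µm) into a polyline.

    A header row is optional; exactly repeated consecutive points are
    collapsed. ``role`` is advisory (edj / prism / stria) and recorded
    nowhere — assembly into a section is the caller's job.
    """
    if role not in ("edj", "prism", "stria"):
        raise TracingError(f"unknown XY role {role!r}")
    rows = []
    with open(path, newline="") as fh:
        for i, row in enumerate(csv.reader(fh)):
            if not row or all(not c.strip() for c in row):
                continue
            cells = [c for c in row if c.strip()][:2]
            try:
                rows.append((float(cells[0]), float(cells[1])))
            except (ValueError, IndexError):
                if i == 0:
                    continue  # header
                raise TracingError(f"{path}: non-numeric XY row {i + 1}: {row}")
    if len(rows) < 2:
        raise TracingError(f"{path}: need at least 2 coordinate rows")
    return Polyline(rows, dedup=True)


# ---------------------------------------------------------------------------
# TPS landmark / curve files (tpsDig dialect)
# ---------------------------------------------------------------------------

def read_tps(path) -> list[tuple[str, Polyline]]:
    """Read a tpsDig TPS file's curves as named polylines.

    Supports LM, CURVES, POINTS, ID and IMAGE records. Landmarks (LM)
    are parsed and skipped — only curves become polylines. Curves are
    named ``<id>:curve<k>`` where ``<id>`` comes from the ID record (or
    the file stem).
    """
    lines = Path(path).read_text().splitlines()
    name = Path(path).stem
    polylines: list[tuple[str, Polyline]] = []
    pending: list[list[tuple[float, float]]] = []
    i = 0

    def take_points(n: int, record: str) -> list[tuple[float, float]]:
        nonlocal i
        pts = []
        for _ in range(n):
            if i >= len(lines):
                raise TracingError(f"{path}: {record} promises {n} points, file ends early")
            parts = lines[i].split()
            if len(parts) < 2:
                raise TracingError(f"{path}: bad coordinate line under {record}: {lines[i]!r}")
            try:
                pts.append((float(parts[0]), float(parts[1])))
            except ValueError:
                raise TracingError(f"{path}: non-numeric coordinates under {record}: {lines[i]!r}")
            i += 1
        return pts

    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line:
            continue
        key, _, val = line.partition("=")
        key = key.strip().upper()
        if key == "LM":
            take_points(int(val), f"LM={val}")
        elif key == "CURVES":
            ncurves = int(val)
            for k in range(ncurves):
                while i < len(lines) and not lines[i].strip():
                    i += 1
                if i >= len(lines) or not lines[i].strip().upper().startswith("POINTS"):
                    raise TracingError(f"{path}: CURVES={ncurves} but curve {k + 1} has no POINTS record")
                npts = int(lines[i].split("=")[1])
                i += 1
                pending.append(take_points(npts, f"POINTS={npts}"))
        elif key == "ID":
            name = val.strip()
        elif key in ("IMAGE", "SCALE", "COMMENT"):
            continue
        else:
            raise TracingError(f"{path}: unrecognized TPS record {line!r}")
    for k, pts in enumerate(pending, start=1):
        polylines.append((f"{name}:curve{k}", Polyline(pts, dedup=True)))
    return polylines


def write_tps(curves: Sequence[tuple[str, Polyline]], path, specimen_id: str = "0") -> None:
    """Write named polylines as one TPS specimen record with curves."""
    out = ["LM=0", f"CURVES={len(curves)}"]
    for _, poly in curves:
        out.append(f"POINTS={len(poly)}")
        out.extend(f"{x:.6f} {y:.6f}" for x, y in poly.coords)
    out.append(f"ID={specimen_id}")
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# chronology table (Table-1-style CSV)
# ---------------------------------------------------------------------------

TABLE_COLUMNS = [
    "id", "site", "individual", "arch", "sex", "wear_stage",
    "cft_days", "ci_days", "cc_days", "inner_dsr_um_day", "n_accentuated",
    "cft_ci_eligible", "cc_excluded",
]

_NA = "n.a."


def write_chronology_table(records: Sequence[ChronologyRecord], path) -> None:
    """Emit chronology records as a deterministic CSV.

    Missing values are written as ``n.a.``; day values are rounded to
    integer days (half away from zero), DSR to 2 decimals.
    """
    def day(v):
        return _NA if v is None else str(int(np.floor(v + 0.5)) if v >= 0 else -int(np.floor(-v + 0.5)))

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(TABLE_COLUMNS)
        for r in records:
            w.writerow([
                r.id, r.site, r.individual, r.arch, r.sex, r.wear_stage,
                day(r.cft), day(r.ci), day(r.cc),
                _NA if r.inner_dsr_mean is None else f"{r.inner_dsr_mean:.2f}",
                r.n_accentuated,
                int(r.cft_ci_eligible), int(r.cc_excluded),
            ])
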