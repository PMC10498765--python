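"""Coronary tree data model and I/O.

A coronary tree is a rooted directed tree of vessel segments. Each segment
carries a length and proximal/distal lumen diameters (optionally a full
diameter profile along its centerline). Stenoses are explicit annotations
that locally override the diameter profile — diameter inside the lesion is
``reference_diameter * (1 - severity)`` — so severity sweeps are scriptable
without editing the geometry.

Two on-disk formats are supported (see ``docs/tree-schema.md``):

* JSON, schema version ``ffru-tree/1``:
  ``{"schema": "ffru-tree/1", "units": {"length": "mm"}, "root": ...,
  "segments": [...], "stenoses": [...]}``
* a two-file CSV dialect: ``segments.csv`` (id, parent, length, d_prox,
  d_dist) and optional ``stenoses.csv`` (segment, start, length, severity,
  ref_diameter).

Files may declare lengths in mm, cm or m; the in-memory tree is always SI.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .errors import DomainError, SchemaError, TreeStructureError
from .units import length_from_si, length_to_si


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Segment:
    """One vessel segment between two branch points (or root/leaf ends).

    Lengths and diameters are metres. ``diameter_profile`` is an optional
    ordered list of (arc position, diameter) pairs spanning [0, L]; when
    absent the lumen tapers linearly from ``d_prox`` to ``d_dist``.
    """

    id: str
    length: float
    d_prox: float
    d_dist: float
    parent: str | None = None
    diameter_profile: tuple[tuple[float, float], ...] | None = None

    def healthy_diameter(self, s: float) -> float:
        """Lumen diameter at arc position ``s`` ignoring stenoses."""
        if not 0.0 <= s <= self.length * (1 + 1e-12):
            raise DomainError(f"arc position {s} outside [0, {self.length}] on {self.id}")
        s = min(s, self.length)
        if self.diameter_profile is None:
            t = s / self.length
            return (1.0 - t) * self.d_prox + t * self.d_dist
        pts = self.diameter_profile
        for (s0, d0), (s1, d1) in zip(pts, pts[1:]):
            if s0 <= s <= s1:
                t = 0.0 if s1 == s0 else (s - s0) / (s1 - s0)
                return (1.0 - t) * d0 + t * d1
        return pts[-1][1]


@dataclass(frozen=True)
class Stenosis:
    """Focal lesion on a segment.

    ``severity`` is the fractional diameter reduction in (0, 1); the lumen
    diameter inside the lesion is ``ref_diameter * (1 - severity)``.
    All positions/lengths are metres along the segment centerline.
    """

    segment: str
    start: float
    length: float
    severity: float
    ref_diameter: float

    @property
    def end(self) -> float:
        return self.start + self.length

    @property
    def lesion_diameter(self) -> float:
        return self.ref_diameter * (1.0 - self.severity)


@dataclass
class CoronaryTree:
    """Rooted directed tree of segments with stenosis annotations."""

    segments: dict[str, Segment]
    stenoses: list[Stenosis] = field(default_factory=list)
    root: str | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.root is None:
            roots = [s.id for s in self.segments.values() if s.parent is None]
            if len(roots) != 1:
                raise TreeStructureError(f"expected exactly one root, found {roots}")
            self.root = roots[0]
        self._children: dict[str, list[str]] = {sid: [] for sid in self.segments}
        for seg in self.segments.values():
            if seg.parent is not None:
                if seg.parent not in self.segments:
                    raise TreeStructureError(
                        f"segment {seg.id!r} references unknown parent {seg.parent!r}")
                self._children[seg.parent].append(seg.id)
        for kids in self._children.values():
            kids.sort()

    def children(self, segment_id: str) -> list[str]:
        return self._children[segment_id]

    @property
    def outlets(self) -> list[str]:
        """Terminal segment ids (leaves), in sorted order."""
        return sorted(sid for sid, kids in self._children.items() if not kids)

    def stenoses_on(self, segment_id: str) -> list[Stenosis]:
        return [s for s in self.stenoses if s.segment == segment_id]

    def descendants_outlets(self, segment_id: str) -> list[str]:
        """Outlet ids whose root path passes through ``segment_id`` (inclusive)."""
        out: list[str] = []
        stack = [segment_id]
        while stack:
            sid = stack.pop()
            kids = self._children[sid]
            if not kids:
                out.append(sid)
            stack.extend(kids)
        return sorted(out)

    def with_stenoses(self, stenoses: Iterable[Stenosis]) -> "CoronaryTree":
        """Copy of the tree with a replaced stenosis list (geometry shared)."""
        return CoronaryTree(segments=dict(self.segments), stenoses=list(stenoses),
                            root=self.root, metadata=dict(self.metadata))


@dataclass(frozen=True)
class PatientPhysiology:
    """Patient-level scalars, in the clinical units they are reported in."""

    p_systolic: float            # mmHg
    p_diastolic: float           # mmHg
    cardiac_output: float        # L/min
    heart_rate: float | None = None       # beats/min (diameter-flow method)
    myocardial_mass: float | None = None  # g (diameter-flow method)

    def __post_init__(self) -> None:
        if not self.p_systolic > self.p_diastolic > 0:
            raise DomainError(
                f"require systolic > diastolic > 0, got "
                f"({self.p_systolic}, {self.p_diastolic}) mmHg")
        if not self.cardiac_output > 0:
            raise DomainError(f"cardiac output must be > 0, got {self.cardiac_output}")


# ---------------------------------------------------------------------------
# geometric primitives
# ---------------------------------------------------------------------------

def area_of_diameter(d: float) -> float:
    return math.pi * d * d / 4.0


def segment_mean_area(segment: Segment) -> float:
    """Mean cross-section area, (A_inlet + A_outlet)/2, from end diameters.

    A full diameter profile, if present, is deliberately ignored here: the
    two-point mean defines the baseline branch resistance; profiles feed the
    piecewise integration in :mod:`ffrnet.resistance`.
    """
    return 0.5 * (area_of_diameter(segment.d_prox) + area_of_diameter(segment.d_dist))


def effective_intervals(
    segment: Segment, stenoses: Sequence[Stenosis] = (),
) -> list[tuple[float, float, float, float]]:
    """Piecewise-linear lumen description with stenosis overrides applied.

    Returns ordered intervals ``(s0, s1, d0, d1)`` covering [0, L]. Inside a
    lesion the diameter is the constant lesion diameter; where lesions
    overlap the narrowest wins.
    """
    breaks = {0.0, segment.length}
    if segment.diameter_profile:
        breaks.update(s for s, _ in segment.diameter_profile)
    for st in stenoses:
        if st.segment != segment.id:
            raise DomainError(f"stenosis on {st.segment!r} applied to segment {segment.id!r}")
        breaks.add(min(max(st.start, 0.0), segment.length))
        breaks.add(min(max(st.end, 0.0), segment.length))
    pts = sorted(breaks)

    def diameter_at(s: float, side: float) -> float:
        # side nudges the sample into the interval so lesion edges are sharp
        probe = s + side
        d = segment.healthy_diameter(min(max(s, 0.0), segment.length))
        for st in stenoses:
            if st.start - 1e-15 <= probe <= st.end + 1e-15:
                d = min(d, st.lesion_diameter)
        return d

    intervals = []
    for s0, s1 in zip(pts, pts[1:]):
        if s1 - s0 <= 0:
            continue
        eps = (s1 - s0) * 1e-9
        intervals.append((s0, s1, diameter_at(s0, +eps), diameter_at(s1, -eps)))
    return intervals


def path_to_root(tree: CoronaryTree, node: str) -> list[str]:
    """Segment ids from the root down to ``node`` inclusive (proximal→distal)."""
    if node not in tree.segments:
        raise KeyError(f"unknown segment id {node!r}")
    path = [node]
    seen = {node}
    while (parent := tree.segments[path[-1]].parent) is not None:
        if parent in seen:
            raise TreeStructureError(f"cycle detected through {parent!r}")
        path.append(parent)
        seen.add(parent)
    return path[::-1]


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Violation:
    segment: str
    rule: str
    message: str

    def __str__(self) -> str:
        return f"[{self.segment}] {self.rule}: {self.message}"


def validate_tree(tree: CoronaryTree) -> list[Violation]:
    """Check every type invariant; returns violations instead of raising."""
    out: list[Violation] = []
    for seg in tree.segments.values():
        if not seg.length > 0:
            out.append(Violation(seg.id, "length_positive", f"L = {seg.length}"))
        for name, d in (("d_prox", seg.d_prox), ("d_dist", seg.d_dist)):
            if not d > 0:
                out.append(Violation(seg.id, "diameter_positive", f"{name} = {d}"))
        if seg.diameter_profile is not None:
            pts = seg.diameter_profile
            ss = [s for s, _ in pts]
            if any(b <= a for a, b in zip(ss, ss[1:])):
                out.append(Violation(seg.id, "profile_monotone",
                                     "arc positions must be strictly increasing"))
            if not pts or not math.isclose(pts[0][0], 0.0, abs_tol=1e-12):
                out.append(Violation(seg.id, "profile_span", "first position must be 0"))
            if not pts or not math.isclose(pts[-1][0], seg.length, rel_tol=1e-9):
                out.append(Violation(seg.id, "profile_span", "last position must be L"))
            if pts and not math.isclose(pts[0][1], seg.d_prox, rel_tol=1e-9):
                out.append(Violation(seg.id, "profile_endpoints",
                                     "profile start diameter != d_prox"))
            if pts and not math.isclose(pts[-1][1], seg.d_dist, rel_tol=1e-9):
                out.append(Violation(seg.id, "profile_endpoints",
                                     "profile end diameter != d_dist"))
            if any(d <= 0 for _, d in pts):
                out.append(Violation(seg.id, "diameter_positive", "profile diameter <= 0"))
    for st in tree.stenoses:
        if st.segment not in tree.segments:
            out.append(Violation(st.segment, "stenosis_segment", "unknown segment"))
            continue
        seg = tree.segments[st.segment]
        if not 0 < st.severity < 1:
            out.append(Violation(st.segment, "severity_bound",
                                 f"severity {st.severity} outside (0, 1)"))
        if st.start < 0 or st.end > seg.length * (1 + 1e-9):
            out.append(Violation(st.segment, "lesion_extent",
                                 f"lesion [{st.start}, {st.end}] outside [0, {seg.length}]"))
        if not st.length > 0:
            out.append(Violation(st.segment, "lesion_length", f"length {st.length}"))
        if not st.ref_diameter > 0:
            out.append(Violation(st.segment, "ref_diameter", f"{st.ref_diameter}"))

    g = nx.DiGraph()
    g.add_nodes_from(tree.segments)
    g.add_edges_from((s.parent, s.id) for s in tree.segments.values() if s.parent)
    if len(tree.segments) and not nx.is_arborescence(g):
        out.append(Violation(tree.root or "?", "tree_structure",
                             "segment graph is not a rooted tree"))
    return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

SCHEMA_VERSION = "ffru-tree/1"


def _segment_from_record(rec: dict, to_si) -> Segment:
    for key in ("id", "length", "d_prox", "d_dist"):
        if key not in rec:
            raise SchemaError(f"segment record missing field {key!r}: {rec}")
    profile = rec.get("diameter_profile")
    if profile is not None:
        profile = tuple((to_si(s), to_si(d)) for s, d in profile)
    parent = rec.get("parent")
    if parent in ("", None) or (isinstance(parent, float) and math.isnan(parent)):
        parent = None
    else:
        parent = str(parent)
    return Segment(
        id=str(rec["id"]), length=to_si(float(rec["length"])),
        d_prox=to_si(float(rec["d_prox"])), d_dist=to_si(float(rec["d_dist"])),
        parent=parent, diameter_profile=profile,
    )


def _stenosis_from_record(rec: dict, to_si) -> Stenosis:
    for key in ("segment", "start", "length", "severity", "ref_diameter"):
        if key not in rec:
            raise SchemaError(f"stenosis record missing field {key!r}: {rec}")
    return Stenosis(
        segment=str(rec["segment"]), start=to_si(float(rec["start"])),
        length=to_si(float(rec["length"])), severity=float(rec["severity"]),
        ref_diameter=to_si(float(rec["ref_diameter"])),
    )


def _build_tree(seg_records, st_records, unit: str, metadata: dict) -> CoronaryTree:
    def to_si(x: float) -> float:
        return length_to_si(x, unit)

    segments: dict[str, Segment] = {}
    for rec in seg_records:
        seg = _segment_from_record(rec, to_si)
        if seg.id in segments:
            raise TreeStructureError(f"duplicate segment id {seg.id!r}")
        segments[seg.id] = seg
    if not segments:
        raise SchemaError("tree has no segments")
    stenoses = [_stenosis_from_record(rec, to_si) for rec in st_records]
    tree = CoronaryTree(segments=segments, stenoses=stenoses, metadata=metadata)
    structural = [v for v in validate_tree(tree) if v.rule == "tree_structure"]
    if structural:
        raise TreeStructureError(str(structural[0]))
    return tree


def load_tree(path: str | Path) -> CoronaryTree:
    """Load a tree from an ``ffru-tree/1`` JSON file; result is in SI metres."""
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(doc, dict):
        raise SchemaError(f"{path}: top level must be an object")
    schema = doc.get("schema", SCHEMA_VERSION)
    if schema != SCHEMA_VERSION:
        raise SchemaError(f"{path}: unsupported schema {schema!r}")
    unit = doc.get("units", {}).get("length", "m")
    metadata = dict(doc.get("metadata", {}))
    metadata.setdefault("name", path.stem)
    return _build_tree(doc.get("segments", []), doc.get("stenoses", []), unit, metadata)


def load_tree_csv(segments_csv: str | Path, stenoses_csv: str | Path | None = None,
                  units: str = "mm") -> CoronaryTree:
    """Load a tree from the two-file CSV dialect (lengths default to mm)."""
    seg_df = pd.read_csv(segments_csv)
    st_records: list[dict] = []
    if stenoses_csv is not None:
        st_records = pd.read_csv(stenoses_csv).to_dict("records")
    return _build_tree(seg_df.to_dict("records"), st_records, units,
                       {"name": Path(segments_csv).stem})


def write_tree(tree: CoronaryTree, path: str | Path, units: str = "m") -> None:
    """Write a tree as ``ffru-tree/1`` JSON in the requested length unit."""
    def conv(x: float) -> float:
        return length_from_si(x, units)

    segments = []
    for seg in tree.segments.values():
        rec: dict = {"id": seg.id, "parent": seg.parent, "length": conv(seg.length),
                     "d_prox": conv(seg.d_prox), "d_dist": conv(seg.d_dist)}
        if seg.diameter_profile is not None:
            rec["diameter_profile"] = [[conv(s), conv(d)] for s, d in seg.diameter_profile]
        segments.append(rec)
    doc = {
        "schema": SCHEMA_VERSION,
        "units": {"length": units},
        "metadata": tree.metadata,
        "root": tree.root,
        "segments": segments,
        "stenoses": [
            {"segment": st.segment, "start": conv(st.start), "length": conv(st.length),
             "severity": st.severity, "ref_diameter": conv(st.ref_diameter)}
            for st in tree.stenoses
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def scale_stenosis(st: Stenosis, severity: float) -> Stenosis:
    """Same lesion at a different severity (for sweeps)."""
    return replace(st, severity=severity)
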