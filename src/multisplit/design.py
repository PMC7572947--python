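"""Chunk-level study design.

A thoracic CT stack is tiled, from the pulmonary apex downward, into
contiguous ~1-cm "chunks" of axial slices, each scored as a single
annotation unit.  Chunks are labelled with the lung zone containing their
center slice (upper: apex to carina; middle: carina to lower pulmonary
vein; lower: vein to lung base), and one chunk per zone — the one closest
to the zone midpoint — is designated a *multi-reader chunk* to be assessed
by several readers.  All slice indices are 0-based.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .errors import DegenerateZoneError, EmptyDesignError, InvalidParameterError

ZONES = ("upper", "middle", "lower")

#: Physical cranio-caudal extent of one chunk, in mm.
CHUNK_EXTENT_MM = 10.0


@dataclass(frozen=True)
class ScanGeometry:
    """Per-subject slice-stack extent and anatomical landmark slice indices.

    Landmarks (apex, carina, lower pulmonary vein, lung base) partition the
    cranio-caudal extent into the three lung zones used for regional
    emphysema scoring.
    """

    subject_id: str
    n_slices: int
    slice_thickness_mm: float
    apex_idx: int
    carina_idx: int
    vein_idx: int
    base_idx: int

    def __post_init__(self):
        if self.slice_thickness_mm <= 0:
            raise InvalidParameterError(
                f"slice_thickness_mm must be > 0, got {self.slice_thickness_mm}"
            )
        if self.n_slices < 1:
            raise InvalidParameterError(f"n_slices must be >= 1, got {self.n_slices}")
        if not (0 <= self.apex_idx < self.carina_idx < self.vein_idx < self.base_idx):
            raise InvalidParameterError(
                "landmarks must satisfy 0 <= apex < carina < vein < base, got "
                f"{self.apex_idx}, {self.carina_idx}, {self.vein_idx}, {self.base_idx}"
            )
        if self.base_idx > self.n_slices - 1:
            raise InvalidParameterError(
                f"base_idx {self.base_idx} beyond last slice {self.n_slices - 1}"
            )


@dataclass
class Chunk:
    """A contiguous block of axial slices scored as one annotation unit."""

    subject_id: str
    chunk_idx: int
    start_slice: int
    end_slice: int
    zone: str | None = None
    is_multi_reader: bool = False

    @property
    def center_slice(self) -> int:
        """Center slice index, rounded down for even-length chunks."""
        return (self.start_slice + self.end_slice) // 2

    @property
    def n_slices(self) -> int:
        return self.end_slice - self.start_slice + 1


def slices_per_chunk(
    slice_thickness_mm: float, chunk_extent_mm: float = CHUNK_EXTENT_MM
) -> int:
    """Smallest slice count whose stacked thickness covers the chunk extent.

    With 0.6-mm slices and a 1-cm chunk this is 17 (17 x 0.6 = 10.2 mm).
    """
    if slice_thickness_mm <= 0 or chunk_extent_mm <= 0:
        raise InvalidParameterError(
            "slice thickness and chunk extent must both be positive, got "
            f"{slice_thickness_mm} and {chunk_extent_mm}"
        )
    # smallest n with n * thickness >= extent; guard float ratios like 10/1.0
    n = math.ceil(chunk_extent_mm / slice_thickness_mm - 1e-9)
    return max(n, 1)


def split_into_chunks(geometry: ScanGeometry) -> list[Chunk]:
    """Tile the apex-to-base extent into equal chunks; drop a trailing partial.

    Chunks are contiguous, non-overlapping, ordered from the apex downward.
    A final block of fewer than ``slices_per_chunk`` slices at the lung base
    is discarded so that every chunk holds the same number of slices.
    """
    spc = slices_per_chunk(geometry.slice_thickness_mm)
    extent = geometry.base_idx - geometry.apex_idx + 1
    n_chunks = extent // spc
    if n_chunks < 1:
        raise EmptyDesignError(
            f"subject {geometry.subject_id}: extent of {extent} slices is "
            f"shorter than one chunk ({spc} slices)"
        )
    return [
        Chunk(
            subject_id=geometry.subject_id,
            chunk_idx=k,
            start_slice=geometry.apex_idx + k * spc,
            end_slice=geometry.apex_idx + (k + 1) * spc - 1,
        )
        for k in range(n_chunks)
    ]


def assign_zones(chunks: list[Chunk], geometry: ScanGeometry) -> list[Chunk]:
    """Label each chunk with the lung zone containing its center slice.

    Zone boundaries are half-open toward the feet: upper = [apex, carina),
    middle = [carina, vein), lower = [vein, base].  A chunk centered exactly
    on a landmark therefore belongs to the zone below it.  Raises if any
    zone ends up empty (the design requires one mid-zone chunk per zone).
    """
    out = []
    for ch in chunks:
        c = ch.center_slice
        if c < geometry.carina_idx:
            zone = "upper"
        elif c < geometry.vein_idx:
            zone = "middle"
        else:
            zone = "lower"
        out.append(replace_zone(ch, zone))
    present = {ch.zone for ch in out}
    for zone in ZONES:
        if zone not in present:
            raise DegenerateZoneError(zone, geometry.subject_id)
    return out


def replace_zone(chunk: Chunk, zone: str) -> Chunk:
    return Chunk(
        subject_id=chunk.subject_id,
        chunk_idx=chunk.chunk_idx,
        start_slice=chunk.start_slice,
        end_slice=chunk.end_slice,
        zone=zone,
        is_multi_reader=chunk.is_multi_reader,
    )


def _zone_bounds(geometry: ScanGeometry) -> dict[str, tuple[int, int]]:
    """Inclusive slice ranges of the three zones."""
    return {
        "upper": (geometry.apex_idx, geometry.carina_idx - 1),
        "middle": (geometry.carina_idx, geometry.vein_idx - 1),
        "lower": (geometry.vein_idx, geometry.base_idx),
    }


def select_multi_reader_chunks(
    chunks: list[Chunk], geometry: ScanGeometry
) -> list[Chunk]:
    """Designate the chunk nearest each zone's midpoint as multi-reader.

    Per zone the chunk whose center slice lies closest to the midpoint of
    the zone's slice range is selected; ties go to the smaller chunk index.
    Returns a new chunk list with exactly three chunks flagged, one per zone.
    """
    bounds = _zone_bounds(geometry)
    out = [replace_zone(ch, ch.zone) for ch in chunks]
    for zone in ZONES:
        members = [ch for ch in out if ch.zone == zone]
        if not members:
            raise DegenerateZoneError(zone, geometry.subject_id)
        lo, hi = bounds[zone]
        midpoint = (lo + hi) / 2.0
        best = min(members, key=lambda ch: (abs(ch.center_slice - midpoint), ch.chunk_idx))
        best.is_multi_reader = True
    return out


def design_subject(geometry: ScanGeometry) -> list[Chunk]:
    """Full per-subject design: split, zone, and multi-reader selection."""
    chunks = split_into_chunks(geometry)
    chunks = assign_zones(chunks, geometry)
    return select_multi_reader_chunks(chunks, geometry)


def design_study(geometries: Iterable[ScanGeometry]) -> pd.DataFrame:
    """Design all subjects and return the long chunk table.

    Columns: subject_id, chunk_idx, start_slice, end_slice, zone,
    is_multi_reader.
    """
    rows = []
    for geom in geometries:
        for ch in design_subject(geom):
            rows.append(
                {
                    "subject_id": ch.subject_id,
                    "chunk_idx": ch.chunk_idx,
                    "start_slice": ch.start_slice,
                    "end_slice": ch.end_slice,
                    "zone": ch.zone,
                    "is_multi_reader": ch.is_multi_reader,
                }
            )
    return pd.DataFrame(rows)
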