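"""Sliding-window DEG-density scan and refractory-region calling.

The scan tiles every chromosome with fixed-size windows at a fixed step,
assigns each gene to every window containing its anchor point (the gene
start; half-open membership), counts directed DEGs per window for each
contrast, flags windows reaching a minimum DEG count, intersects flagged
windows across contrasts, and merges runs of flagged windows into
locus-scale refractory regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .annotation import Annotation


class ScanError(ValueError):
    pass


class GridMismatchError(ScanError):
    """Windows from different grids (size/step) cannot be combined."""


@dataclass
class Window:
    """One genomic window, optionally annotated with DEG content.

    ``coordination`` is the fraction of the window's DEGs sharing the
    majority fold-change direction (0.0 when the window has no DEGs).
    """

    chrom: str
    start: int
    end: int
    member_gene_ids: frozenset[str]
    grid_id: str = ""
    contrast: Optional[str] = None
    deg_ids: frozenset[str] = frozenset()
    deg_directions: dict[str, str] = field(default_factory=dict)

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)

    @property
    def deg_count(self) -> int:
        return len(self.deg_ids)

    @property
    def coordination(self) -> float:
        return _coordination(self.deg_directions)


def _coordination(directions: Mapping[str, str]) -> float:
    if not directions:
        return 0.0
    n_up = sum(1 for d in directions.values() if d == "up")
    n_down = len(directions) - n_up
    return max(n_up, n_down) / len(directions)


@dataclass
class WindowGrid:
    """All windows tiling the genome at one (window_size, step)."""

    windows: list[Window]
    window_size: int
    step: int

    @property
    def grid_id(self) -> str:
        return f"{self.window_size}:{self.step}"


@dataclass
class RefractoryRegion:
    """A merged run of flagged windows: a candidate reprogramming-refractory locus."""

    chrom: str
    start: int
    end: int
    windows: list[Window]
    supporting_contrasts: frozenset[str]
    deg_ids: frozenset[str]
    dominant_direction: str  # "up" | "down" | "mixed"
    coordination: float

    @property
    def total_distinct_degs(self) -> int:
        return len(self.deg_ids)


def enumerate_windows(
    annotation: Annotation, window_size: int = 2_000_000, step: int = 1_000_000
) -> WindowGrid:
    """Tile every chromosome with half-open windows and assign genes.

    Windows start at offsets 0, step, 2*step, ... while the start is inside
    the chromosome; the final window is truncated at the chromosome length.
    A gene belongs to every window satisfying start <= anchor < end, so a
    gene whose anchor sits exactly on a boundary goes to the later window.
    """
    if window_size <= 0:
        raise ScanError("window_size must be positive")
    if not (0 < step <= window_size):
        raise ScanError("need 0 < step <= window_size")
    for g in annotation:
        if g.chrom not in annotation.chrom_lengths:
            raise ScanError(f"chromosome {g.chrom!r} absent from chrom_lengths")
    grid_id = f"{window_size}:{step}"
    windows: list[Window] = []
    for chrom in annotation.chroms():
        length = annotation.chrom_lengths[chrom]
        genes = annotation.genes_on(chrom)
        anchors = [(g.anchor, g.gene_id) for g in genes]
        start = 0
        while start < length:
            end = min(start + window_size, length)
            members = frozenset(gid for a, gid in anchors if start <= a < end)
            windows.append(Window(chrom, start, end, members, grid_id))
            start += step
    return WindowGrid(windows, window_size, step)


def scan(
    grid: WindowGrid,
    deg_sets: Mapping[str, Mapping[str, str]],
    min_degs: int = 6,
) -> dict[str, list[Window]]:
    """Flag DEG-rich windows per contrast.

    ``deg_sets`` maps a contrast label to a directed DEG set
    (gene_id -> "up"/"down").  A window is flagged for a contrast iff it
    contains at least ``min_degs`` DEGs of that contrast, regardless of
    direction; the coordination score is reported, not used as a filter.
    """
    if min_degs < 1:
        raise ScanError("min_degs must be >= 1")
    known = set()
    for w in grid.windows:
        known |= w.member_gene_ids
    flagged: dict[str, list[Window]] = {}
    for contrast, degs in deg_sets.items():
        unknown = set(degs) - known
        if unknown:
            raise ScanError(
                f"contrast {contrast!r}: DEG ids not in the annotation/grid: "
                f"{sorted(unknown)[:5]}..."
            )
        hits: list[Window] = []
        for w in grid.windows:
            inside = w.member_gene_ids & set(degs)
            if len(inside) >= min_degs:
                directions = {g: degs[g] for g in inside}
                hits.append(
                    Window(
                        w.chrom, w.start, w.end, w.member_gene_ids, w.grid_id,
                        contrast=contrast, deg_ids=frozenset(inside),
                        deg_directions=directions,
                    )
                )
        flagged[contrast] = hits
    return flagged


def intersect_contrasts(flagged: Mapping[str, Sequence[Window]]) -> list[Window]:
    """Windows flagged in every supplied contrast.

    Windows must come from identical grids (same window size and step).
    The result carries the union of DEG ids over contrasts and a contrast
    label joining all supplied contrasts; it is commutative in contrast
    order.
    """
    if not flagged:
        return []
    grid_ids = {w.grid_id for ws in flagged.values() for w in ws}
    if len(grid_ids) > 1:
        raise GridMismatchError(f"windows from different grids: {sorted(grid_ids)}")
    contrasts = sorted(flagged)
    key_maps = [{w.key: w for w in flagged[c]} for c in contrasts]
    common_keys = set(key_maps[0])
    for km in key_maps[1:]:
        common_keys &= set(km)
    label = "&".join(contrasts)
    out: list[Window] = []
    for key in sorted(common_keys):
        per = [km[key] for km in key_maps]
        directions: dict[str, str] = {}
        for w in per:
            directions.update(w.deg_directions)
        w0 = per[0]
        out.append(
            Window(
                w0.chrom, w0.start, w0.end, w0.member_gene_ids, w0.grid_id,
                contrast=label, deg_ids=frozenset(directions),
                deg_directions=directions,
            )
        )
    return out


def merge_flagged(
    windows: Sequence[Window],
    max_gap: int = 0,
    direction_threshold: float = 0.75,
) -> list[RefractoryRegion]:
    """Merge flagged windows into refractory regions.

    Windows on one chromosome merge when they overlap or are separated by
    at most ``max_gap`` bp.  The region's dominant direction is "up" or
    "down" when at least ``direction_threshold`` of its distinct DEGs
    share that direction, else "mixed".  Input must be sorted by
    (chrom, start).
    """
    keys = [(w.chrom, w.start) for w in windows]
    if keys != sorted(keys):
        raise ScanError("flagged windows must be sorted by (chrom, start)")
    regions: list[RefractoryRegion] = []
    current: list[Window] = []
    for w in windows:
        if current and w.chrom == current[-1].chrom and w.start <= max(
            c.end for c in current
        ) + max_gap:
            current.append(w)
        else:
            if current:
                regions.append(_build_region(current, direction_threshold))
            current = [w]
    if current:
        regions.append(_build_region(current, direction_threshold))
    return regions


def _build_region(windows: list[Window], direction_threshold: float) -> RefractoryRegion:
    directions: dict[str, str] = {}
    contrasts: set[str] = set()
    for w in windows:
        directions.update(w.deg_directions)
        for c in (w.contrast or "").split("&"):
            if c:
                contrasts.add(c)
    n = len(directions)
    n_down = sum(1 for d in directions.values() if d == "down")
    n_up = n - n_down
    if n > 0 and n_down / n >= direction_threshold:
        dominant = "down"
    elif n > 0 and n_up / n >= direction_threshold:
        dominant = "up"
    else:
        dominant = "mixed"
    return RefractoryRegion(
        chrom=windows[0].chrom,
        start=min(w.start for w in windows),
        end=max(w.end for w in windows),
        windows=list(windows),
        supporting_contrasts=frozenset(contrasts),
        deg_ids=frozenset(directions),
        dominant_direction=dominant,
        coordination=_coordination(directions),
    )


def windows_to_dataframe(windows: Sequence[Window]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [w.chrom for w in windows],
            "start": [w.start for w in windows],
            "end": [w.end for w in windows],
            "contrast": [w.contrast for w in windows],
            "n_genes": [len(w.member_gene_ids) for w in windows],
            "deg_count": [w.deg_count for w in windows],
            "coordination": [round(w.coordination, 6) for w in windows],
            "deg_ids": [",".join(sorted(w.deg_ids)) for w in windows],
        }
    )


def regions_to_dataframe(regions: Sequence[RefractoryRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in regions],
            "start": [r.start for r in regions],
            "end": [r.end for r in regions],
            "n_windows": [len(r.windows) for r in regions],
            "contrasts": [",".join(sorted(r.supporting_contrasts)) for r in regions],
            "total_distinct_degs": [r.total_distinct_degs for r in regions],
            "dominant_direction": [r.dominant_direction for r in regions],
            "coordination": [round(r.coordination, 6) for r in regions],
        }
    )
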