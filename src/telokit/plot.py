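"""Deterministic SVG line plots of windowed telomeric-repeat counts.

One sub-plot (track) per sequence, ordered by descending sequence length,
with a single polyline of the summed forward+reverse count per window — a
telomere may be assembled on either strand, so the strands are not drawn
separately.  A complete chromosome shows a peak at each end of its track.

The output is plain SVG 1.1 with inline styling, no timestamps and no
generated ids: identical input produces byte-identical SVG, which makes the
plots safe to commit and diff.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List

import pandas as pd

from telokit.search import SEARCH_COLUMNS
from telokit.seqio import read_tsv

MARGIN_LEFT = 70.0
MARGIN_RIGHT = 20.0
TRACK_PAD_TOP = 24.0
TRACK_PAD_BOTTOM = 16.0


@dataclass
class PlotSpec:
    """What to draw: a window-count table plus geometry knobs."""

    rows: pd.DataFrame
    width: float = 1000.0
    height_per_track: float = 120.0
    max_tracks: int = 25

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height_per_track <= 0:
            raise ValueError("plot dimensions must be positive")
        if self.max_tracks < 1:
            raise ValueError("max_tracks must be >= 1")


def load_windows_tsv(path: str | Path) -> pd.DataFrame:
    """Read a search/find window-count TSV, validating column names and types."""
    header, rows = read_tsv(path)
    if header != SEARCH_COLUMNS:
        raise ValueError(f"{path}: expected columns {SEARCH_COLUMNS}, found {header}")
    parsed = []
    for i, row in enumerate(rows, start=2):
        try:
            parsed.append((row[0], int(row[1]), int(row[2]), int(row[3]), int(row[4])))
        except ValueError as exc:
            raise ValueError(f"{path}: line {i}: {exc}") from None
    return pd.DataFrame(parsed, columns=SEARCH_COLUMNS)


def _fmt(x: float) -> str:
    """Fixed two-decimal coordinate formatting (byte-deterministic)."""
    return f"{x:.2f}"


def plot_svg(spec: PlotSpec, out: str | Path | None = None) -> str:
    """Render the window-count table as an SVG document.

    One track per sequence (descending length, capped at
    ``spec.max_tracks``); each track holds one polyline with one vertex per
    window.  Returns the SVG text; writes it to ``out`` when given.
    """
    rows = spec.rows
    if rows is None or len(rows) == 0:
        raise ValueError("nothing to plot: the window-count table is empty")

    # sequence length = end of its last window; tracks by descending length
    lengths = rows.groupby("id", sort=False)["window_end"].max()
    order = sorted(lengths.index, key=lambda sid: (-int(lengths[sid]), sid))
    order = order[: spec.max_tracks]

    plot_w = spec.width - MARGIN_LEFT - MARGIN_RIGHT
    track_h = spec.height_per_track - TRACK_PAD_TOP - TRACK_PAD_BOTTOM
    total_h = spec.height_per_track * len(order)

    parts: List[str] = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{_fmt(spec.width)}" height="{_fmt(total_h)}" '
        f'viewBox="0 0 {_fmt(spec.width)} {_fmt(total_h)}">',
        '<rect width="100%" height="100%" fill="white"/>',
    ]

    for t, sid in enumerate(order):
        sub = rows[rows["id"] == sid]
        seq_len = int(lengths[sid])
        y_max = max(int((sub["forward_repeat_number"] + sub["reverse_repeat_number"]).max()), 1)
        top = t * spec.height_per_track + TRACK_PAD_TOP
        base = top + track_h
        x_scale = plot_w / max(seq_len, 1)

        pts = []
        for _, r in sub.iterrows():
            mid = (int(r["window_start"]) + int(r["window_end"])) / 2.0
            total = int(r["forward_repeat_number"]) + int(r["reverse_repeat_number"])
            x = MARGIN_LEFT + mid * x_scale
            y = base - (total / y_max) * track_h
            pts.append(f"{_fmt(x)},{_fmt(y)}")

        parts.append(
            f'<text x="{_fmt(MARGIN_LEFT)}" y="{_fmt(top - 8)}" '
            f'font-family="monospace" font-size="12" fill="black">{sid}</text>'
        )
        # axes: x = position along the sequence, y = repeat count per window
        parts.append(
            f'<line x1="{_fmt(MARGIN_LEFT)}" y1="{_fmt(base)}" '
            f'x2="{_fmt(MARGIN_LEFT + plot_w)}" y2="{_fmt(base)}" '
            f'stroke="black" stroke-width="1"/>'
        )
        parts.append(
            f'<line x1="{_fmt(MARGIN_LEFT)}" y1="{_fmt(top)}" '
            f'x2="{_fmt(MARGIN_LEFT)}" y2="{_fmt(base)}" '
            f'stroke="black" stroke-width="1"/>'
        )
        parts.append(
            f'<text x="{_fmt(MARGIN_LEFT - 6)}" y="{_fmt(top + 4)}" text-anchor="end" '
            f'font-family="monospace" font-size="10" fill="black">{y_max}</text>'
        )
        parts.append(
            f'<text x="{_fmt(MARGIN_LEFT - 6)}" y="{_fmt(base + 4)}" text-anchor="end" '
            f'font-family="monospace" font-size="10" fill="black">0</text>'
        )
        parts.append(
            f'<text x="{_fmt(MARGIN_LEFT + plot_w)}" y="{_fmt(base + 12)}" text-anchor="end" '
            f'font-family="monospace" font-size="10" fill="black">{seq_len} nt</text>'
        )
        parts.append(
            f'<polyline fill="none" stroke="#1f77b4" stroke-width="1.5" '
            f'points="{" ".join(pts)}"/>'
        )

    # global axis labels
    parts.append(
        f'<text x="{_fmt(MARGIN_LEFT + plot_w / 2)}" y="{_fmt(total_h - 2)}" '
        f'text-anchor="middle" font-family="monospace" font-size="11" '
        f'fill="black">Position (nt)</text>'
    )
    parts.append(
        f'<text x="12" y="{_fmt(total_h / 2)}" text-anchor="middle" '
        f'font-family="monospace" font-size="11" fill="black" '
        f'transform="rotate(-90 12 {_fmt(total_h / 2)})">Repeat count per window</text>'
    )
    parts.append("</svg>")
    doc = "\n".join(parts) + "\n"
    if out is not None:
        Path(out).write_text(doc, encoding="utf-8")
    return doc
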