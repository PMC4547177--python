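"""Static glyph-matrix rendering of a pan-genome matrix.

Each present gene is drawn as a strand glyph — an arrow pointing upwards for
a forward-strand gene and downwards for a reverse-strand gene — in the cell
(pan gene row x genome column).  Cell colour encodes presence, strand, or
TIGRFAM family (20 equidistant-hue colours); an optional group-size column
encodes the core/orphan/dispensable classification (blue / red / red-to-blue
gradient).  Rendering builds a resolution-independent display list that is
serialised to SVG 1.1, rasterised through Pillow (PNG/JPEG/TIFF), or written
as a small self-contained vector PDF.

Rendering is pure: identical (matrix, config) input yields byte-identical
SVG output.
"""

from __future__ import annotations

import colorsys
import hashlib
from dataclasses import dataclass, field
from typing import Sequence

from .matrix import CORE, ORPHAN, PanGenomeMatrix, classify

__all__ = [
    "RenderConfig",
    "Document",
    "tigrfam_palette",
    "colour_for",
    "render_matrix",
    "render_overview",
    "export_image",
    "PALETTE_SIZE",
    "DEFAULT_PRESENCE_COLOUR",
]

PALETTE_SIZE = 20
DEFAULT_PRESENCE_COLOUR = "#3c3c3c"
STRAND_COLOURS = {"+": "#1f77b4", "-": "#e6821e"}
CORE_COLOUR = (0, 0, 255)
ORPHAN_COLOUR = (255, 0, 0)
AGN_HIGHLIGHT = "#fff3b0"
RASTER_FORMATS = ("PNG", "JPEG", "TIFF")
VECTOR_FORMATS = ("SVG", "PDF")


def _hex(rgb: tuple[int, int, int]) -> str:
    return "#{:02x}{:02x}{:02x}".format(*rgb)


def tigrfam_palette(saturation: float = 0.65, brightness: float = 0.85) -> list[str]:
    """20 colours with hues i/20, i = 0..19, at fixed saturation/brightness."""
    out = []
    for i in range(PALETTE_SIZE):
        r, g, b = colorsys.hsv_to_rgb(i / PALETTE_SIZE, saturation, brightness)
        out.append(_hex((round(r * 255), round(g * 255), round(b * 255))))
    return out


def colour_for(tigrfam_id: str | None, palette: Sequence[str] | None = None) -> str:
    """Stable colour for a TIGRFAM id; repetition beyond 20 families is
    accepted.  Unassigned genes get the default presence colour."""
    if tigrfam_id is None or tigrfam_id == "":
        return DEFAULT_PRESENCE_COLOUR
    palette = palette if palette is not None else tigrfam_palette()
    digest = hashlib.md5(tigrfam_id.encode("utf-8")).digest()
    return palette[int.from_bytes(digest[:4], "big") % len(palette)]


@dataclass(frozen=True)
class RenderConfig:
    cell_size: int = 12
    colour_scheme: str = "presence"  # presence | strand | tigrfam
    group_size_scheme: str | None = "core_orphan"  # core_orphan | uniform_black | None
    region: tuple[int, int] | None = None  # 1-based inclusive pan gene ranks
    show_headers: bool = True
    saturation: float = 0.65
    brightness: float = 0.85

    def __post_init__(self) -> None:
        if self.cell_size < 4:
            raise ValueError("cell_size must be >= 4 px")
        if self.colour_scheme not in ("presence", "strand", "tigrfam"):
            raise ValueError(f"unknown colour scheme {self.colour_scheme!r}")
        if self.group_size_scheme not in ("core_orphan", "uniform_black", None):
            raise ValueError(f"unknown group size scheme {self.group_size_scheme!r}")


@dataclass
class Document:
    """Resolution-independent drawing: primitives in pixel coordinates."""

    width: float
    height: float
    elements: list[tuple] = field(default_factory=list)

    def rect(self, x, y, w, h, fill, stroke=None) -> None:
        self.elements.append(("rect", x, y, w, h, fill, stroke))

    def polygon(self, points, fill) -> None:
        self.elements.append(("polygon", tuple(points), fill))

    def text(self, x, y, s, size=9, fill="#000000", bold=False) -> None:
        self.elements.append(("text", x, y, s, size, fill, bold))

    @property
    def glyph_count(self) -> int:
        return sum(1 for e in self.elements if e[0] == "polygon")

    # -- serialisation ------------------------------------------------------

    def to_svg(self) -> str:
        def f(v) -> str:
            return f"{v:.2f}".rstrip("0").rstrip(".")

        parts = [
            '<?xml version="1.0" encoding="UTF-8"?>\n'
            f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
            f'width="{f(self.width)}" height="{f(self.height)}" '
            f'viewBox="0 0 {f(self.width)} {f(self.height)}">'
        ]
        for e in self.elements:
            if e[0] == "rect":
                _, x, y, w, h, fill, stroke = e
                s = f'<rect x="{f(x)}" y="{f(y)}" width="{f(w)}" height="{f(h)}"'
                s += f' fill="{fill}"' if fill else ' fill="none"'
                if stroke:
                    s += f' stroke="{stroke}"'
                parts.append(s + "/>")
            elif e[0] == "polygon":
                _, pts, fill = e
                coords = " ".join(f"{f(x)},{f(y)}" for x, y in pts)
                parts.append(f'<polygon points="{coords}" fill="{fill}"/>')
            elif e[0] == "text":
                _, x, y, s, size, fill, bold = e
                esc = s.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")
                weight = ' font-weight="bold"' if bold else ""
                parts.append(
                    f'<text x="{f(x)}" y="{f(y)}" font-family="monospace" '
                    f'font-size="{f(size)}" fill="{fill}"{weight}>{esc}</text>'
                )
        parts.append("</svg>\n")
        return "\n".join(parts)

    def to_image(self, scale: float = 1.0):
        from PIL import Image, ImageDraw

        w, h = max(1, round(self.width * scale)), max(1, round(self.height * scale))
        img = Image.new("RGB", (w, h), "#ffffff")
        draw = ImageDraw.Draw(img)
        for e in self.elements:
            if e[0] == "rect":
                _, x, y, rw, rh, fill, stroke = e
                box = [x * scale, y * scale, (x + rw) * scale, (y + rh) * scale]
                draw.rectangle(box, fill=fill, outline=stroke)
            elif e[0] == "polygon":
                _, pts, fill = e
                draw.polygon([(px * scale, py * scale) for px, py in pts], fill=fill)
            elif e[0] == "text":
                _, x, y, s, size, fill, bold = e
                # y is the text baseline in vector output
                draw.text((x * scale, (y - size) * scale), s, fill=fill)
        return img

    def to_pdf(self) -> bytes:
        return _minimal_pdf(self)


def _classification_colour(pg, n: int, scheme: str) -> str:
    if scheme == "uniform_black":
        return "#000000"
    cat = classify(pg, n)
    if cat == CORE:
        return _hex(CORE_COLOUR)
    if cat == ORPHAN:
        return _hex(ORPHAN_COLOUR)
    # dispensable: linear red (size 2) -> blue (size n-1)
    t = 0.0 if n <= 3 else (pg.size - 2) / (n - 3)
    rgb = tuple(
        round(ORPHAN_COLOUR[i] + t * (CORE_COLOUR[i] - ORPHAN_COLOUR[i]))
        for i in range(3)
    )
    return _hex(rgb)


def render_matrix(matrix: PanGenomeMatrix, config: RenderConfig | None = None) -> Document:
    """Draw the glyph matrix: rows = pan genes (region), columns = genomes."""
    cfg = config or RenderConfig()
    n_rows_total = len(matrix)
    lo, hi = cfg.region if cfg.region is not None else (1, n_rows_total)
    if n_rows_total and not (1 <= lo <= hi <= n_rows_total):
        raise ValueError(f"region {cfg.region} outside matrix bounds [1, {n_rows_total}]")
    rows = list(matrix)[lo - 1 : hi] if n_rows_total else []

    n = len(matrix.genome_roster)
    cs = cfg.cell_size
    label_w = (
        max([60] + [len(pg.display_label) * 7 for pg in rows]) + 8
        if cfg.show_headers
        else 0
    )
    top = cs + 6 if cfg.show_headers else 0
    size_col = cs + 4 if cfg.group_size_scheme else 0
    width = label_w + n * cs + size_col + 2
    height = top + len(rows) * cs + 2

    doc = Document(width, height)
    palette = tigrfam_palette(cfg.saturation, cfg.brightness)

    if cfg.show_headers:
        for j, g in enumerate(matrix.genome_roster):
            doc.text(label_w + j * cs + 1, top - 3, str(g)[: max(1, cs // 6)], size=min(9, cs - 2))

    pad = max(1.0, cs * 0.15)
    for i, pg in enumerate(rows):
        y = top + i * cs
        if cfg.show_headers:
            if pg.is_aggregated:
                doc.rect(0, y, label_w - 2, cs, AGN_HIGHLIGHT)
            doc.text(2, y + cs - pad, pg.display_label, size=min(9, cs - 2), bold=pg.is_aggregated)
        for j, g in enumerate(matrix.genome_roster):
            x = label_w + j * cs
            doc.rect(x, y, cs, cs, None, "#dddddd")
            m = pg.members.get(g)
            if m is None:
                continue
            if cfg.colour_scheme == "presence":
                fill = DEFAULT_PRESENCE_COLOUR
            elif cfg.colour_scheme == "strand":
                fill = STRAND_COLOURS[m.strand]
            else:
                fill = colour_for(pg.tigrfam_id, palette)
            if m.strand == "+":
                pts = [
                    (x + cs / 2, y + pad),
                    (x + cs - pad, y + cs - pad),
                    (x + pad, y + cs - pad),
                ]
            else:
                pts = [
                    (x + pad, y + pad),
                    (x + cs - pad, y + pad),
                    (x + cs / 2, y + cs - pad),
                ]
            doc.polygon(pts, fill)
        if cfg.group_size_scheme:
            doc.rect(
                label_w + n * cs + 4,
                y,
                cs,
                cs,
                _classification_colour(pg, n, cfg.group_size_scheme),
            )
    return doc


def render_overview(
    matrix: PanGenomeMatrix,
    view_region: tuple[int, int] | None = None,
    width: int = 240,
    height: int = 40,
) -> Document:
    """Thumbnail of the whole matrix with a red rectangle marking the
    currently viewed pan gene rank interval."""
    doc = Document(width, height)
    n_rows = len(matrix)
    doc.rect(0, 0, width, height, "#f5f5f5", "#999999")
    if n_rows == 0:
        return doc
    n = len(matrix.genome_roster)
    col_w = width / n_rows
    for i, pg in enumerate(matrix):
        frac = pg.size / n
        shade = round(235 - 180 * frac)
        doc.rect(i * col_w, 0, col_w, height, _hex((shade, shade, shade)))
    lo, hi = view_region if view_region is not None else (1, n_rows)
    if not (1 <= lo <= hi <= n_rows):
        raise ValueError(f"view region {view_region} outside [1, {n_rows}]")
    x0 = (lo - 1) / n_rows * width
    x1 = hi / n_rows * width
    doc.rect(x0, 0.5, x1 - x0, height - 1, None, "#ff0000")
    return doc


def export_image(doc: Document, path, format: str | None = None, dpi: int = 96) -> None:
    """Write the document as SVG, PDF, or a raster (PNG/JPEG/TIFF).

    The format defaults to the file suffix.  SVG output is byte-stable for
    identical input.
    """
    fmt = (format or str(path).rsplit(".", 1)[-1]).upper()
    if fmt == "JPG":
        fmt = "JPEG"
    if fmt == "SVG":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(doc.to_svg())
    elif fmt == "PDF":
        with open(path, "wb") as fh:
            fh.write(doc.to_pdf())
    elif fmt in RASTER_FORMATS:
        doc.to_image(scale=dpi / 96).save(path, format=fmt, dpi=(dpi, dpi))
    else:
        raise ValueError(
            f"unsupported image format {fmt!r}; expected one of "
            f"{VECTOR_FORMATS + RASTER_FORMATS}"
        )


# -- minimal vector PDF ------------------------------------------------------


def _pdf_colour(spec: str) -> str:
    r = int(spec[1:3], 16) / 255
    g = int(spec[3:5], 16) / 255
    b = int(spec[5:7], 16) / 255
    return f"{r:.3f} {g:.3f} {b:.3f}"


def _minimal_pdf(doc: Document) -> bytes:
    """Single-page vector PDF (Helvetica, uncompressed content stream)."""
    H = doc.height
    ops: list[str] = []
    for e in doc.elements:
        if e[0] == "rect":
            _, x, y, w, h, fill, stroke = e
            if fill:
                ops.append(f"{_pdf_colour(fill)} rg {x:.2f} {H - y - h:.2f} {w:.2f} {h:.2f} re f")
            if stroke:
                ops.append(
                    f"{_pdf_colour(stroke)} RG 0.75 w {x:.2f} {H - y - h:.2f} {w:.2f} {h:.2f} re S"
                )
        elif e[0] == "polygon":
            _, pts, fill = e
            path = " ".join(
                f"{px:.2f} {H - py:.2f} {'m' if i == 0 else 'l'}"
                for i, (px, py) in enumerate(pts)
            )
            ops.append(f"{_pdf_colour(fill)} rg {path} h f")
        elif e[0] == "text":
            _, x, y, s, size, fill, bold = e
            esc = s.replace("\\", r"\\").replace("(", r"\(").replace(")", r"\)")
            font = "/F2" if bold else "/F1"
            ops.append(
                f"BT {font} {size:.1f} Tf {_pdf_colour(fill)} rg "
                f"{x:.2f} {H - y:.2f} Td ({esc}) Tj ET"
            )
    stream = ("\n".join(ops)).encode("latin-1", "replace")

    objs: list[bytes] = []
    objs.append(b"<< /Type /Catalog /Pages 2 0 R >>")
    objs.append(b"<< /Type /Pages /Kids [3 0 R] /Count 1 >>")
    objs.append(
        (
            f"<< /Type /Page /Parent 2 0 R /MediaBox [0 0 {doc.width:.2f} {doc.height:.2f}] "
            f"/Contents 4 0 R /Resources << /Font << /F1 5 0 R /F2 6 0 R >> >> >>"
        ).encode()
    )
    objs.append(
        b"<< /Length %d >>\nstream\n" % len(stream) + stream + b"\nendstream"
    )
    objs.append(b"<< /Type /Font /Subtype /Type1 /BaseFont /Helvetica >>")
    objs.append(b"<< /Type /Font /Subtype /Type1 /BaseFont /Helvetica-Bold >>")

    out = bytearray(b"%PDF-1.4\n")
    offsets = [0]
    for i, body in enumerate(objs, start=1):
        offsets.append(len(out))
        out += b"%d 0 obj\n" % i + body + b"\nendobj\n"
    xref = len(out)
    out += b"xref\n0 %d\n" % (len(objs) + 1)
    out += b"0000000000 65535 f \n"
    for off in offsets[1:]:
        out += b"%010d 00000 n \n" % off
    out += (
        b"trailer\n<< /Size %d /Root 1 0 R >>\nstartxref\n%d\n%%%%EOF\n"
        % (len(objs) + 1, xref)
    )
    return bytes(out)
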