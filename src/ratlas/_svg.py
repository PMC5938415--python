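"""Tiny SVG serializer for the dot-plot and vector-field exports."""

from __future__ import annotations

from pathlib import Path
from xml.sax.saxutils import escape


class SvgDocument:
    def __init__(self, width: float, height: float) -> None:
        self.width = width
        self.height = height
        self._elements: list[str] = []

    def line(self, x1: float, y1: float, x2: float, y2: float,
             stroke: str = "black", width: float = 1.0) -> None:
        self._elements.append(
            f'<line x1="{x1:.2f}" y1="{y1:.2f}" x2="{x2:.2f}" y2="{y2:.2f}" '
            f'stroke="{stroke}" stroke-width="{width:g}"/>'
        )

    def circle(self, cx: float, cy: float, r: float,
               fill: str = "black", stroke: str = "none") -> None:
        self._elements.append(
            f'<circle cx="{cx:.2f}" cy="{cy:.2f}" r="{r:g}" fill="{fill}" '
            f'stroke="{stroke}"/>'
        )

    def text(self, x: float, y: float, content: str, size: float = 12.0) -> None:
        self._elements.append(
            f'<text x="{x:.2f}" y="{y:.2f}" font-size="{size:g}" '
            f'font-family="sans-serif">{escape(content)}</text>'
        )

    def tostring(self) -> str:
        body = "\n  ".join(self._elements)
        return (
            '<?xml version="1.0" encoding="UTF-8"?>\n'
            f'<svg xmlns="http://www.w3.org/2000/svg" width="{self.width:g}" '
            f'height="{self.height:g}" viewBox="0 0 {self.width:g} {self.height:g}">\n'
            f"  {body}\n</svg>\n"
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.tostring(), encoding="utf-8")
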