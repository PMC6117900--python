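"""Visual and text outputs: COG scatter, per-barcode score chart, reports.

All graphics are standalone SVG 1.1 documents built with the standard
library's ElementTree; the 3D COG scatter uses a fixed-angle orthographic
projection of the (X, Y, Z) divergence axes, with the COGs selected for
barcoding highlighted in brown.  The barcode chart draws one bar per
barcode with height proportional to BarcodeScore2 (floored at zero),
present calls coloured, and bars optionally ordered by the leaf order of a
user-supplied phylogenetic tree (Newick / PHYLIP-style tree files; branch
lengths are ignored for ordering).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from xml.etree import ElementTree as ET

from .cog_metrics import CogStats
from .read_binning import AlignmentPool, BinningResult

log = logging.getLogger(__name__)

SVG_NS = "http://www.w3.org/2000/svg"


@dataclass
class TreeOrder:
    leaf_order: list[str]
    depths: dict[str, int]


def load_tree_order(path: str | Path) -> TreeOrder:
    """Leaf order of a Newick (or PHYLIP-style newick) tree file."""
    import dendropy

    text = Path(path).read_text()
    tree = dendropy.Tree.get(data=text, schema="newick")
    order = []
    depths = {}
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label if leaf.taxon else str(leaf)
        label = label.replace(" ", "_")
        order.append(label)
        depths[label] = leaf.level()
    return TreeOrder(leaf_order=order, depths=depths)


def _svg_root(width: int, height: int) -> ET.Element:
    return ET.Element(
        "svg",
        {
            "xmlns": SVG_NS,
            "version": "1.1",
            "width": str(width),
            "height": str(height),
            "viewBox": f"0 0 {width} {height}",
        },
    )


def _write_svg(root: ET.Element, out_path: str | Path) -> Path:
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    ET.ElementTree(root).write(out_path, xml_declaration=True, encoding="unicode")
    return out_path


def render_cog_scatter(
    stats: list[CogStats],
    selected_ids: set[str] | list[str],
    out_path: str | Path,
    width: int = 640,
    height: int = 480,
) -> Path:
    """Orthographic 3D scatter of the COG divergence axes.

    X (sense-substitution fraction) runs right, Y (protein divergence)
    into the depth axis, Z ((positives-identities)/identities) up.
    Selected COGs are drawn in brown on top of the grey unselected cloud.
    """
    if not stats:
        raise ValueError("no COG stats to plot")
    selected = set(selected_ids)
    root = _svg_root(width, height)
    margin = 50.0
    z_max = max(1e-9, max(s.Z for s in stats))
    # depth (Y) projected at a 30-degree angle
    dx, dy = math.cos(math.pi / 6), math.sin(math.pi / 6)
    span_x = width - 2 * margin - 120 * dx
    span_z = height - 2 * margin - 120 * dy

    def project(x: float, y: float, z: float) -> tuple[float, float]:
        px = margin + x * span_x + y * 120 * dx
        py = height - margin - (z / z_max) * span_z - y * 120 * dy
        return px, py

    axes = ET.SubElement(root, "g", {"stroke": "black", "stroke-width": "1"})
    for start, end, label in (
        ((0, 0, 0), (1, 0, 0), "X: sense substitution fraction"),
        ((0, 0, 0), (0, 1, 0), "Y: 1 - protein identity"),
        ((0, 0, 0), (0, 0, z_max), "Z: (positives-identities)/identities"),
    ):
        (x1, y1), (x2, y2) = project(*start), project(*end)
        ET.SubElement(
            axes,
            "line",
            {"x1": f"{x1:.1f}", "y1": f"{y1:.1f}", "x2": f"{x2:.1f}", "y2": f"{y2:.1f}"},
        )
        text = ET.SubElement(
            root,
            "text",
            {"x": f"{x2 + 4:.1f}", "y": f"{y2 - 4:.1f}", "font-size": "11"},
        )
        text.text = label
    for stat in sorted(stats, key=lambda s: s.cog_id in selected):
        cx, cy = project(stat.X, stat.Y, stat.Z)
        ET.SubElement(
            root,
            "circle",
            {
                "cx": f"{cx:.2f}",
                "cy": f"{cy:.2f}",
                "r": "3",
                "fill": "#8B4513" if stat.cog_id in selected else "#999999",
                "class": "cog selected" if stat.cog_id in selected else "cog",
            },
        )
    return _write_svg(root, out_path)


def render_barcode_chart(
    result: BinningResult,
    out_path: str | Path,
    tree: TreeOrder | None = None,
    width: int = 640,
    height: int = 360,
) -> Path:
    """Bar chart of BarcodeScore2 per barcode, tree-ordered when possible.

    Barcodes missing from the tree are appended after the tree-ordered
    bars; a tree sharing no leaves with the barcode set falls back to
    score ordering with a warning.
    """
    calls = result.calls
    order: list[str]
    if tree is not None:
        matched = [b for b in tree.leaf_order if b in calls]
        if not matched:
            log.warning("tree shares no leaves with the barcode set; ordering by score")
            order = sorted(calls, key=lambda b: -calls[b].score2)
        else:
            rest = sorted(
                (b for b in calls if b not in set(matched)),
                key=lambda b: -calls[b].score2,
            )
            if rest:
                log.warning("barcodes not in tree appended: %s", ", ".join(rest))
            order = matched + rest
    else:
        order = sorted(calls, key=lambda b: -calls[b].score2)

    root = _svg_root(width, height)
    margin = 45.0
    plot_w = width - 2 * margin
    plot_h = height - 2 * margin
    max_score = max([max(c.score2, 0.0) for c in calls.values()] + [result.cutoff2, 1e-9])
    bar_w = plot_w / max(len(order), 1)

    def y_of(score: float) -> float:
        return height - margin - max(score, 0.0) / max_score * plot_h

    baseline = ET.SubElement(
        root,
        "line",
        {
            "x1": f"{margin:.1f}",
            "y1": f"{height - margin:.1f}",
            "x2": f"{width - margin:.1f}",
            "y2": f"{height - margin:.1f}",
            "stroke": "black",
        },
    )
    cut_y = y_of(result.cutoff2)
    ET.SubElement(
        root,
        "line",
        {
            "x1": f"{margin:.1f}",
            "y1": f"{cut_y:.1f}",
            "x2": f"{width - margin:.1f}",
            "y2": f"{cut_y:.1f}",
            "stroke": "#CC0000",
            "stroke-dasharray": "4 3",
            "class": "cutoff",
        },
    )
    for i, barcode_id in enumerate(order):
        call = calls[barcode_id]
        x = margin + i * bar_w
        top = y_of(call.score2)
        ET.SubElement(
            root,
            "rect",
            {
                "x": f"{x + bar_w * 0.1:.2f}",
                "y": f"{top:.2f}",
                "width": f"{bar_w * 0.8:.2f}",
                "height": f"{height - margin - top:.2f}",
                "fill": "#2E8B57" if call.present else "#AAAAAA",
                "class": "bar present" if call.present else "bar",
            },
        )
        label = ET.SubElement(
            root,
            "text",
            {
                "x": f"{x + bar_w / 2:.1f}",
                "y": f"{height - margin + 12:.1f}",
                "font-size": "9",
                "text-anchor": "middle",
            },
        )
        label.text = barcode_id
    return _write_svg(root, out_path)


def write_text_report(result: BinningResult, out_path: str | Path) -> Path:
    """Tab-separated identification report with pool statistics in the header."""
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    pool = result.pool
    with open(out_path, "w") as handle:
        handle.write(f"# n_reads_total\t{pool.n_reads_total}\n")
        handle.write(f"# n_aligned_reads\t{pool.n_aligned_reads}\n")
        handle.write(f"# n_matches\t{pool.n_matches}\n")
        sprime = "NA" if pool.sprime is None else f"{pool.sprime:.6f}"
        a_spec = "NA" if pool.a_specificity is None else f"{pool.a_specificity:.6f}"
        handle.write(f"# sprime\t{sprime}\n")
        handle.write(f"# a_specificity\t{a_spec}\n")
        handle.write(f"# cutoff1\t{result.cutoff1}\n")
        handle.write(f"# cutoff2\t{result.cutoff2}\n")
        handle.write("barcode_id\tbarcode_length\tn_reads\tscore1\tscore2\tcall\n")
        for barcode_id in sorted(result.calls):
            c = result.calls[barcode_id]
            call = "present" if c.present else "absent"
            handle.write(
                f"{barcode_id}\t{c.barcode_length}\t{c.n_reads}\t{c.score1:.6f}\t{c.score2:.6f}\t{call}\n"
            )
    return out_path


def read_text_report(path: str | Path) -> BinningResult:
    """Parse a report written by :func:`write_text_report` back losslessly
    (to the printed precision)."""
    from .read_binning import BarcodeCall

    header: dict[str, str] = {}
    calls: dict[str, BarcodeCall] = {}
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if line.startswith("# "):
                key, value = line[2:].split("\t", 1)
                header[key] = value
                continue
            if line.startswith("barcode_id\t") or not line:
                continue
            barcode_id, length, n_reads, s1, s2, call = line.split("\t")
            calls[barcode_id] = BarcodeCall(
                barcode_id=barcode_id,
                barcode_length=int(length),
                n_reads=int(n_reads),
                score1=float(s1),
                score2=float(s2),
                present=call == "present",
            )
    pool = AlignmentPool(
        hits=[],
        n_barcodes=len(calls),
        n_reads_total=int(header.get("n_reads_total", 0)),
    )
    if header.get("sprime", "NA") != "NA":
        pool.sprime = float(header["sprime"])
    if header.get("a_specificity", "NA") != "NA":
        pool.a_specificity = float(header["a_specificity"])
    return BinningResult(
        calls=calls,
        cutoff1=float(header.get("cutoff1", 2.3)),
        cutoff2=float(header.get("cutoff2", 0.5)),
        pool=pool,
    )
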