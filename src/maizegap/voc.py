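"""Annotation I/O: Pascal-VOC XML (LabelImg style) and YOLO text boxes."""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np

from .metrics import DetectionBox

__all__ = ["write_voc_xml", "read_voc_xml", "write_yolo_txt", "read_yolo_txt"]


def write_voc_xml(
    path: str | Path,
    image_name: str,
    image_size: tuple[int, int],
    boxes,
    label: str = "maize",
) -> None:
    """Write boxes (x_min, y_min, x_max, y_max) as a Pascal-VOC annotation."""
    w, h = image_size
    root = ET.Element("annotation")
    ET.SubElement(root, "folder").text = "images"
    ET.SubElement(root, "filename").text = image_name
    size = ET.SubElement(root, "size")
    ET.SubElement(size, "width").text = str(int(w))
    ET.SubElement(size, "height").text = str(int(h))
    ET.SubElement(size, "depth").text = "3"
    ET.SubElement(root, "segmented").text = "0"
    for box in boxes:
        x0, y0, x1, y1 = (box.x_min, box.y_min, box.x_max, box.y_max) if isinstance(box, DetectionBox) else box
        obj = ET.SubElement(root, "object")
        ET.SubElement(obj, "name").text = getattr(box, "label", label)
        ET.SubElement(obj, "pose").text = "Unspecified"
        ET.SubElement(obj, "truncated").text = "0"
        ET.SubElement(obj, "difficult").text = "0"
        bnd = ET.SubElement(obj, "bndbox")
        ET.SubElement(bnd, "xmin").text = str(int(round(float(x0))))
        ET.SubElement(bnd, "ymin").text = str(int(round(float(y0))))
        ET.SubElement(bnd, "xmax").text = str(int(round(float(x1))))
        ET.SubElement(bnd, "ymax").text = str(int(round(float(y1))))
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, encoding="unicode")


def read_voc_xml(path: str | Path) -> list[DetectionBox]:
    root = ET.parse(path).getroot()
    boxes = []
    for obj in root.iter("object"):
        bnd = obj.find("bndbox")
        boxes.append(
            DetectionBox(
                x_min=float(bnd.find("xmin").text),
                y_min=float(bnd.find("ymin").text),
                x_max=float(bnd.find("xmax").text),
                y_max=float(bnd.find("ymax").text),
                label=(obj.findtext("name") or "maize"),
            )
        )
    return boxes


def write_yolo_txt(path: str | Path, image_size: tuple[int, int], boxes, with_score: bool = False) -> None:
    """YOLO text format: ``class cx cy w h [score]``, coordinates normalized."""
    w, h = image_size
    lines = []
    for box in boxes:
        cx = (box.x_min + box.x_max) / 2.0 / w
        cy = (box.y_min + box.y_max) / 2.0 / h
        bw = (box.x_max - box.x_min) / w
        bh = (box.y_max - box.y_min) / h
        fields = [0, f"{cx:.6f}", f"{cy:.6f}", f"{bw:.6f}", f"{bh:.6f}"]
        if with_score:
            fields.append(f"{box.score:.6f}")
        lines.append(" ".join(str(f) for f in fields))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_yolo_txt(path: str | Path, image_size: tuple[int, int]) -> list[DetectionBox]:
    w, h = image_size
    boxes = []
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        cx, cy, bw, bh = (float(v) for v in parts[1:5])
        score = float(parts[5]) if len(parts) > 5 else 1.0
        boxes.append(
            DetectionBox(
                x_min=(cx - bw / 2) * w,
                y_min=(cy - bh / 2) * h,
                x_max=(cx + bw / 2) * w,
                y_max=(cy + bh / 2) * h,
                score=score,
            )
        )
    return boxes
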