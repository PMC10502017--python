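"""Readers and writers for the on-disk formats.

YOLO label dialect: one row per box, ``class cx cy w h [conf]``, all box
coordinates normalized to [0, 1] by the image size, 6-decimal fixed
formatting, single class 0, optional confidence as a 6th column.

Keypoint CSV dialect: header comment ``# schema=<name>`` followed by
columns ``image,particle_id,point,x_px,y_px,confidence`` — one row per
present keypoint; a keypoint with no row is missing.  Compatible between
ground truth and predictions.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .geometry import (
    BoundingBox,
    DeviceSchema,
    KeypointPose,
    Micrograph,
    Point2D,
    get_schema,
)

__all__ = [
    "read_yolo_labels",
    "write_yolo_labels",
    "read_keypoint_csv",
    "write_keypoint_csv",
    "read_micrograph",
    "write_micrograph",
]


def _image_wh(image_size) -> tuple[float, float]:
    if np.isscalar(image_size):
        return float(image_size), float(image_size)
    w, h = image_size
    return float(w), float(h)


def read_yolo_labels(path, image_size) -> list[BoundingBox]:
    """Read YOLO-format labels, denormalized to pixels.

    ``image_size`` is a scalar (square image) or (width, height).
    Raises ValueError with the line number on a malformed row.
    """
    w_img, h_img = _image_wh(image_size)
    boxes: list[BoundingBox] = []
    text = Path(path).read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) not in (5, 6):
            raise ValueError(f"{path}:{lineno}: expected 5 or 6 columns, got {len(parts)}")
        try:
            class_id = int(parts[0])
            cx, cy, w, h = (float(v) for v in parts[1:5])
            conf = float(parts[5]) if len(parts) == 6 else 1.0
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from None
        if not all(0.0 <= v <= 1.0 for v in (cx, cy, w, h)):
            raise ValueError(
                f"{path}:{lineno}: normalized coordinates must be in [0, 1]"
            )
        if w <= 0 or h <= 0:
            raise ValueError(f"{path}:{lineno}: box size must be positive")
        boxes.append(BoundingBox(
            cx=cx * w_img, cy=cy * h_img, w=w * w_img, h=h * h_img,
            confidence=conf, class_id=class_id,
        ))
    return boxes


def write_yolo_labels(
    boxes: list[BoundingBox], path, image_size, include_confidence: bool = True
) -> None:
    """Write boxes as normalized YOLO rows at 6-decimal precision."""
    w_img, h_img = _image_wh(image_size)
    lines = []
    for box in boxes:
        row = (f"{box.class_id} {box.cx / w_img:.6f} {box.cy / h_img:.6f} "
               f"{box.w / w_img:.6f} {box.h / h_img:.6f}")
        if include_confidence:
            row += f" {box.confidence:.6f}"
        lines.append(row)
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_keypoint_csv(poses: list[KeypointPose], path) -> None:
    """Write poses in the keypoint CSV dialect (schema noted in a header
    comment).  Missing keypoints are simply omitted."""
    path = Path(path)
    schema_name = poses[0].schema.name if poses else "hinge"
    rows = []
    for pose in poses:
        if pose.schema.name != schema_name:
            raise ValueError("all poses in one file must share a schema")
        for name in pose.schema.keypoint_names:
            entry = pose.points.get(name)
            if entry is None:
                continue
            pt, conf = entry
            rows.append((pose.image, pose.particle_id, name, pt.x, pt.y, conf))
    frame = pd.DataFrame(
        rows, columns=["image", "particle_id", "point", "x_px", "y_px", "confidence"]
    )
    with open(path, "w") as fh:
        fh.write(f"# schema={schema_name}\n")
        frame.to_csv(fh, index=False, float_format="%.6f")


def read_keypoint_csv(path, schema: DeviceSchema | None = None) -> list[KeypointPose]:
    """Read a keypoint CSV back into poses grouped by (image, particle_id).

    The schema defaults to the one named in the file's header comment.
    Raises ValueError for a point name unknown to the schema.
    """
    path = Path(path)
    if schema is None:
        with open(path) as fh:
            first = fh.readline().strip()
        if first.startswith("# schema="):
            schema = get_schema(first.split("=", 1)[1])
        else:
            raise ValueError(f"{path}: no schema header; pass schema explicitly")
    frame = pd.read_csv(path, comment="#", dtype={"image": str, "particle_id": str})
    frame["image"] = frame["image"].fillna("")
    poses: list[KeypointPose] = []
    for (image, pid), group in frame.groupby(["image", "particle_id"], sort=False):
        points = {}
        for row in group.itertuples(index=False):
            if row.point not in schema.keypoint_names:
                raise ValueError(
                    f"{path}: point {row.point!r} unknown to schema {schema.name!r}"
                )
            points[row.point] = (Point2D(row.x_px, row.y_px), float(row.confidence))
        poses.append(KeypointPose(
            particle_id=str(pid), schema=schema, points=points, image=str(image),
        ))
    return poses


def read_micrograph(path, nm_per_px: float = 1.4) -> Micrograph:
    """Load a grayscale PNG/TIFF as a [0, 1] float micrograph."""
    arr = np.asarray(Image.open(path).convert("L"), dtype=float) / 255.0
    return Micrograph(pixels=arr, nm_per_px=nm_per_px)


def write_micrograph(m: Micrograph, path) -> None:
    arr = np.clip(np.rint(m.pixels * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)
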