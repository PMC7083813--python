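"""Minimal plain-SVG geometry reader.

Handles the subset of SVG 1.1 the unfolded-cortex templates use: path data
with M/L/H/V/C/S/Q/T/Z commands (quadratics converted to cubics), and
``transform`` attributes composed of matrix / translate / scale / rotate.
Transforms are applied to control points *before* curves are flattened, so
the flattening tolerance is honoured in user space. Elliptical arcs are not
supported and raise :class:`SvgPathError`.
"""

from __future__ import annotations

import math
import re

import numpy as np

__all__ = [
    "SvgPathError",
    "flatten_cubic_bezier",
    "parse_path",
    "flatten_subpath",
    "parse_transform",
    "identity_transform",
    "compose",
    "apply_transform",
]


class SvgPathError(ValueError):
    """Malformed or unsupported SVG path / transform content."""


_TOKEN_RE = re.compile(
    r"([MmLlHhVvCcSsQqTtZzAa])|([-+]?(?:\d*\.\d+|\d+\.?)(?:[eE][-+]?\d+)?)"
)

_TRANSFORM_RE = re.compile(r"(matrix|translate|scale|rotate|skewX|skewY)\s*\(([^)]*)\)")


# ---------------------------------------------------------------------------
# transforms (3x3 homogeneous matrices)

def identity_transform() -> np.ndarray:
    return np.eye(3)


def parse_transform(text: str | None) -> np.ndarray:
    """Parse an SVG ``transform`` attribute into a 3x3 matrix."""
    m = identity_transform()
    if not text:
        return m
    matched_any = False
    for name, args_text in _TRANSFORM_RE.findall(text):
        matched_any = True
        args = [float(a) for a in re.split(r"[\s,]+", args_text.strip()) if a]
        t = np.eye(3)
        if name == "matrix":
            if len(args) != 6:
                raise SvgPathError(f"matrix() needs 6 numbers, got {len(args)}")
            a, b, c, d, e, f = args
            t = np.array([[a, c, e], [b, d, f], [0, 0, 1.0]])
        elif name == "translate":
            tx = args[0]
            ty = args[1] if len(args) > 1 else 0.0
            t[0, 2], t[1, 2] = tx, ty
        elif name == "scale":
            sx = args[0]
            sy = args[1] if len(args) > 1 else sx
            t[0, 0], t[1, 1] = sx, sy
        elif name == "rotate":
            ang = math.radians(args[0])
            ca, sa = math.cos(ang), math.sin(ang)
            rot = np.array([[ca, -sa, 0], [sa, ca, 0], [0, 0, 1.0]])
            if len(args) == 3:
                cx, cy = args[1], args[2]
                pre = np.eye(3)
                pre[0, 2], pre[1, 2] = cx, cy
                post = np.eye(3)
                post[0, 2], post[1, 2] = -cx, -cy
                rot = pre @ rot @ post
            t = rot
        elif name in ("skewX", "skewY"):
            tn = math.tan(math.radians(args[0]))
            if name == "skewX":
                t[0, 1] = tn
            else:
                t[1, 0] = tn
        m = m @ t
    if not matched_any and text.strip():
        raise SvgPathError(f"unparseable transform: {text!r}")
    return m


def compose(parent: np.ndarray, child: np.ndarray) -> np.ndarray:
    return parent @ child


def apply_transform(m: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Apply a 3x3 transform to an (N, 2) array of points."""
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    out = pts @ m[:2, :2].T + m[:2, 2]
    return out[0] if single else out


# ---------------------------------------------------------------------------
# cubic Bezier flattening (de Casteljau midpoint subdivision)

_MAX_DEPTH = 32


def _line_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    """Distance from p to the chord a-b (to point a if chord is degenerate)."""
    ab = b - a
    n2 = float(ab @ ab)
    if n2 < 1e-30:
        return float(np.hypot(*(p - a)))
    return abs(float(ab[0] * (p[1] - a[1]) - ab[1] * (p[0] - a[0]))) / math.sqrt(n2)


def _subdivide(p0, p1, p2, p3, tol, depth, out):
    flat = max(_line_distance(p1, p0, p3), _line_distance(p2, p0, p3))
    if flat <= tol or depth >= _MAX_DEPTH:
        out.append(p3)
        return
    # de Casteljau split at t = 0.5
    p01 = 0.5 * (p0 + p1)
    p12 = 0.5 * (p1 + p2)
    p23 = 0.5 * (p2 + p3)
    p012 = 0.5 * (p01 + p12)
    p123 = 0.5 * (p12 + p23)
    mid = 0.5 * (p012 + p123)
    _subdivide(p0, p01, p012, mid, tol, depth + 1, out)
    _subdivide(mid, p123, p23, p3, tol, depth + 1, out)


def flatten_cubic_bezier(p0, p1, p2, p3, tolerance: float = 0.01) -> np.ndarray:
    """Flatten one cubic Bezier into a polyline from p0 to p3.

    The curve is recursively split at the midpoint until the inner control
    points lie within ``tolerance`` of the chord, which bounds the deviation
    of the emitted chords from the true curve. Degenerate curves (all control
    points coincident) return the chord.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    out: list[np.ndarray] = [p0]
    _subdivide(p0, p1, p2, p3, float(tolerance), 0, out)
    return np.asarray(out)


# ---------------------------------------------------------------------------
# path data

class Subpath:
    """One subpath: a start point, a list of segments, and a closed flag.

    Segments are tuples ``("L", end)`` or ``("C", c1, c2, end)`` with absolute
    coordinates.
    """

    def __init__(self, start):
        self.start = np.asarray(start, dtype=float)
        self.segments: list[tuple] = []
        self.closed = False


def parse_path(d: str) -> list[Subpath]:
    """Parse SVG path data into subpaths of line and cubic segments."""
    tokens = _TOKEN_RE.findall(d)
    if not tokens and d.strip():
        raise SvgPathError(f"unparseable path data: {d!r}")
    # flat stream of commands / floats
    stream: list[str | float] = []
    for cmd, num in tokens:
        stream.append(cmd if cmd else float(num))

    subpaths: list[Subpath] = []
    cur = np.zeros(2)
    sub: Subpath | None = None
    prev_cubic_ctrl: np.ndarray | None = None
    prev_quad_ctrl: np.ndarray | None = None
    i = 0
    command: str | None = None

    def take(n):
        nonlocal i
        if i + n > len(stream) or any(isinstance(v, str) for v in stream[i : i + n]):
            raise SvgPathError(f"path data ended mid-command near token {i}")
        vals = stream[i : i + n]
        i += n
        return vals

    while i < len(stream):
        tok = stream[i]
        if isinstance(tok, str):
            command = tok
            i += 1
            if command in "Zz":
                if sub is not None:
                    sub.closed = True
                    cur = sub.start.copy()
                prev_cubic_ctrl = prev_quad_ctrl = None
                command = None
                continue
        if command is None:
            raise SvgPathError("path data must start with a moveto")
        rel = command.islower()
        c = command.upper()
        if c == "A":
            raise SvgPathError("elliptical arcs are not supported")
        if c == "M":
            x, y = take(2)
            pt = np.array([x, y]) + (cur if rel else 0.0)
            sub = Subpath(pt)
            subpaths.append(sub)
            cur = pt
            # subsequent coordinate pairs are implicit linetos
            command = "l" if rel else "L"
            prev_cubic_ctrl = prev_quad_ctrl = None
            continue
        if sub is None:
            raise SvgPathError("path data must start with a moveto")
        if c == "L":
            x, y = take(2)
            pt = np.array([x, y]) + (cur if rel else 0.0)
            sub.segments.append(("L", pt))
            cur = pt
            prev_cubic_ctrl = prev_quad_ctrl = None
        elif c == "H":
            (x,) = take(1)
            pt = np.array([cur[0] + x if rel else x, cur[1]])
            sub.segments.append(("L", pt))
            cur = pt
            prev_cubic_ctrl = prev_quad_ctrl = None
        elif c == "V":
            (y,) = take(1)
            pt = np.array([cur[0], cur[1] + y if rel else y])
            sub.segments.append(("L", pt))
            cur = pt
            prev_cubic_ctrl = prev_quad_ctrl = None
        elif c in ("C", "S"):
            if c == "C":
                x1, y1, x2, y2, x, y = take(6)
                c1 = np.array([x1, y1]) + (cur if rel else 0.0)
            else:
                x2, y2, x, y = take(4)
                c1 = 2 * cur - prev_cubic_ctrl if prev_cubic_ctrl is not None else cur
            c2 = np.array([x2, y2]) + (cur if rel else 0.0)
            end = np.array([x, y]) + (cur if rel else 0.0)
            sub.segments.append(("C", c1, c2, end))
            prev_cubic_ctrl = c2
            prev_quad_ctrl = None
            cur = end
        elif c in ("Q", "T"):
            if c == "Q":
                qx, qy, x, y = take(4)
                q = np.array([qx, qy]) + (cur if rel else 0.0)
            else:
                x, y = take(2)
                q = 2 * cur - prev_quad_ctrl if prev_quad_ctrl is not None else cur
            end = np.array([x, y]) + (cur if rel else 0.0)
            # exact quadratic -> cubic degree elevation
            c1 = cur + 2.0 / 3.0 * (q - cur)
            c2 = end + 2.0 / 3.0 * (q - end)
            sub.segments.append(("C", c1, c2, end))
            prev_quad_ctrl = q
            prev_cubic_ctrl = None
            cur = end
        else:  # pragma: no cover - regex admits only known letters
            raise SvgPathError(f"unsupported path command {command!r}")
    return subpaths


def flatten_subpath(
    sub: Subpath, tolerance: float = 0.01, transform: np.ndarray | None = None
) -> np.ndarray:
    """Flatten a subpath to an (N, 2) polyline, transforming control points first."""
    m = identity_transform() if transform is None else transform
    pts = [apply_transform(m, sub.start)]
    cur = pts[0]
    for seg in sub.segments:
        if seg[0] == "L":
            end = apply_transform(m, seg[1])
            pts.append(end)
            cur = end
        else:
            _, c1, c2, end = seg
            c1, c2, end = (apply_transform(m, p) for p in (c1, c2, end))
            flat = flatten_cubic_bezier(cur, c1, c2, end, tolerance)
            pts.extend(flat[1:])
            cur = end
    out = np.asarray(pts)
    # drop consecutive duplicate vertices (e.g. zero-length closing segments)
    if len(out) > 1:
        keep = np.ones(len(out), dtype=bool)
        keep[1:] = np.any(np.abs(np.diff(out, axis=0)) > 1e-12, axis=1)
        out = out[keep]
    return out
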