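"""Numba kernels for the soft silhouette rasterizer (forward + backward).

Per-pixel occupancy aggregates over projected faces:

    occ(p) = 1 - prod_f (1 - w_f * sigmoid(k * d_f(p)))

with ``d_f`` the 2D signed distance of pixel center ``p`` into face ``f``
(positive inside) and ``w_f`` a face weight.  With culling enabled, ``w_f``
ramps smoothly from 0 (back-facing) to 1 over a small projected-orientation
band, so back-facing duplicates of the closed surface drop out without
introducing discontinuities as faces turn edge-on; without culling every
non-degenerate face counts fully.  Only pixels within a padded bounding box
of each face are touched; outside it the sigmoid is below numerical noise
for the pad used by the wrapper.  The backward kernel recomputes ``d_f`` and
pushes the upstream mask gradient onto the three projected vertices, using
the envelope form of the point-to-segment distance derivative plus the
(linear) orientation derivative of the fade weight.
"""

import numpy as np
from numba import njit

_S_CLAMP = 1.0 - 1e-12
_ORIENT_RAMP = 1.0  # px^2: fade band for near-edge-on faces under culling


@njit(cache=True, fastmath=False)
def _edge_dist(px, py, ux, uy, vx, vy):
    """Distance from (px,py) to segment (u,v), plus the clamp parameter t."""
    ex, ey = vx - ux, vy - uy
    wx, wy = px - ux, py - uy
    L2 = ex * ex + ey * ey
    if L2 <= 0.0:
        t = 0.0
    else:
        t = (wx * ex + wy * ey) / L2
        if t < 0.0:
            t = 0.0
        elif t > 1.0:
            t = 1.0
    dx = px - (ux + t * ex)
    dy = py - (uy + t * ey)
    return np.sqrt(dx * dx + dy * dy), t, dx, dy


@njit(cache=True, fastmath=False)
def _signed_dist(px, py, ax, ay, bx, by, cx, cy, orient):
    """Signed distance into the triangle; returns (d, edge, t, dx, dy).

    ``edge`` identifies the nearest boundary segment (0: ab, 1: bc, 2: ca);
    (dx, dy) is the unnormalized offset pixel-minus-closest-point.
    """
    d0, t0, x0, y0 = _edge_dist(px, py, ax, ay, bx, by)
    d1, t1, x1, y1 = _edge_dist(px, py, bx, by, cx, cy)
    d2, t2, x2, y2 = _edge_dist(px, py, cx, cy, ax, ay)
    if d0 <= d1 and d0 <= d2:
        dmin, edge, t, dx, dy = d0, 0, t0, x0, y0
    elif d1 <= d2:
        dmin, edge, t, dx, dy = d1, 1, t1, x1, y1
    else:
        dmin, edge, t, dx, dy = d2, 2, t2, x2, y2
    s0 = (bx - ax) * (py - ay) - (by - ay) * (px - ax)
    s1 = (cx - bx) * (py - by) - (cy - by) * (px - bx)
    s2 = (ax - cx) * (py - cy) - (ay - cy) * (px - cx)
    inside = (s0 * orient >= 0.0) and (s1 * orient >= 0.0) and (s2 * orient >= 0.0)
    if inside:
        return dmin, edge, t, dx, dy
    return -dmin, edge, t, dx, dy


@njit(cache=True, fastmath=False)
def _face_weight(orient, cull):
    """Smooth face fade and its orientation derivative.

    With culling: a smoothstep from 0 (back-facing or degenerate) to 1 over
    _ORIENT_RAMP; C1 at both ends, so exactly-degenerate faces (e.g. end
    caps seen edge-on) introduce no gradient kinks.  Without culling, every
    non-degenerate face counts fully (weight 1, zero derivative).
    """
    if cull:
        if orient <= 0.0:
            return 0.0, 0.0
        if orient >= _ORIENT_RAMP:
            return 1.0, 0.0
        t = orient / _ORIENT_RAMP
        return t * t * (3.0 - 2.0 * t), 6.0 * t * (1.0 - t) / _ORIENT_RAMP
    if np.abs(orient) < 1e-12:
        return 0.0, 0.0  # degenerate projected face
    return 1.0, 0.0


@njit(cache=True, fastmath=False)
def raster_forward(p2, faces, h, w, sharpness, pad, cull):
    """Returns (mask, q) with q = prod(1 - w_f s_f) per pixel."""
    q = np.ones((h, w))
    for f in range(faces.shape[0]):
        i0, i1, i2 = faces[f, 0], faces[f, 1], faces[f, 2]
        ax, ay = p2[i0, 0], p2[i0, 1]
        bx, by = p2[i1, 0], p2[i1, 1]
        cx, cy = p2[i2, 0], p2[i2, 1]
        orient = (bx - ax) * (cy - ay) - (by - ay) * (cx - ax)
        fw, _ = _face_weight(orient, cull)
        if fw == 0.0:
            continue
        xmin = int(np.floor(min(ax, min(bx, cx)) - pad))
        xmax = int(np.ceil(max(ax, max(bx, cx)) + pad))
        ymin = int(np.floor(min(ay, min(by, cy)) - pad))
        ymax = int(np.ceil(max(ay, max(by, cy)) + pad))
        if xmin < 0:
            xmin = 0
        if ymin < 0:
            ymin = 0
        if xmax > w - 1:
            xmax = w - 1
        if ymax > h - 1:
            ymax = h - 1
        for py in range(ymin, ymax + 1):
            for px in range(xmin, xmax + 1):
                if q[py, px] < 1e-10:  # pixel already saturated
                    continue
                d, _, _, _, _ = _signed_dist(
                    float(px), float(py), ax, ay, bx, by, cx, cy, orient
                )
                s = fw / (1.0 + np.exp(-sharpness * d))
                if s > _S_CLAMP:
                    s = _S_CLAMP
                q[py, px] *= 1.0 - s
    return 1.0 - q, q


@njit(cache=True, fastmath=False)
def raster_backward(p2, faces, grad_mask, q, sharpness, pad, cull):
    """Gradient of sum(grad_mask * mask) with respect to the projected points."""
    h, w = q.shape
    gp = np.zeros_like(p2)
    for f in range(faces.shape[0]):
        i0, i1, i2 = faces[f, 0], faces[f, 1], faces[f, 2]
        ax, ay = p2[i0, 0], p2[i0, 1]
        bx, by = p2[i1, 0], p2[i1, 1]
        cx, cy = p2[i2, 0], p2[i2, 1]
        orient = (bx - ax) * (cy - ay) - (by - ay) * (cx - ax)
        fw, dfw = _face_weight(orient, cull)
        if fw == 0.0:
            continue
        xmin = int(np.floor(min(ax, min(bx, cx)) - pad))
        xmax = int(np.ceil(max(ax, max(bx, cx)) + pad))
        ymin = int(np.floor(min(ay, min(by, cy)) - pad))
        ymax = int(np.ceil(max(ay, max(by, cy)) + pad))
        if xmin < 0:
            xmin = 0
        if ymin < 0:
            ymin = 0
        if xmax > w - 1:
            xmax = w - 1
        if ymax > h - 1:
            ymax = h - 1
        for py in range(ymin, ymax + 1):
            for px in range(xmin, xmax + 1):
                go = grad_mask[py, px]
                if go == 0.0 or q[py, px] < 1e-10:
                    continue
                d, edge, t, dx, dy = _signed_dist(
                    float(px), float(py), ax, ay, bx, by, cx, cy, orient
                )
                sig = 1.0 / (1.0 + np.exp(-sharpness * d))
                s = fw * sig
                if s > _S_CLAMP:
                    continue  # clamped region: zero local gradient
                one_minus = 1.0 - s
                # d mask / d s_f = prod_{g != f} (1 - s_g) = q / (1 - s_f)
                gs = go * q[py, px] / one_minus
                # distance pathway: d s / d d = fw * k * sig * (1 - sig)
                gd = gs * fw * sharpness * sig * (1.0 - sig)
                dist = np.abs(d)
                if dist >= 1e-12:
                    sign = 1.0 if d >= 0.0 else -1.0
                    nx, ny = dx / dist, dy / dist
                    # d dist / d u = -(1-t) n ; d dist / d v = -t n  (envelope)
                    gux = -gd * sign * (1.0 - t) * nx
                    guy = -gd * sign * (1.0 - t) * ny
                    gvx = -gd * sign * t * nx
                    gvy = -gd * sign * t * ny
                    if edge == 0:
                        gp[i0, 0] += gux
                        gp[i0, 1] += guy
                        gp[i1, 0] += gvx
                        gp[i1, 1] += gvy
                    elif edge == 1:
                        gp[i1, 0] += gux
                        gp[i1, 1] += guy
                        gp[i2, 0] += gvx
                        gp[i2, 1] += gvy
                    else:
                        gp[i2, 0] += gux
                        gp[i2, 1] += guy
                        gp[i0, 0] += gvx
                        gp[i0, 1] += gvy
                if dfw != 0.0:
                    # fade pathway: d s / d orient = sig * dw/d orient
                    gw = gs * sig * dfw
                    gp[i0, 0] += gw * (by - cy)
                    gp[i0, 1] += gw * (cx - bx)
                    gp[i1, 0] += gw * (cy - ay)
                    gp[i1, 1] += gw * (ax - cx)
                    gp[i2, 0] += gw * (ay - by)
                    gp[i2, 1] += gw * (bx - ax)
    return gp
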