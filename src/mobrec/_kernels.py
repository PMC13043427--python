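"""Numba kernels for trajectory segmentation.

These operate on planar coordinates (meters, equirectangular projection around
the trace's mean latitude); at the city scale relevant to pause/flight
decisions (< a few km) the projection error is negligible relative to GPS
noise.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def pause_runs(t, x, y, radius_m, max_gap_s):  # pragma: no cover - numba
    """Maximal contiguous runs whose points stay within radius_m of the
    run's running centroid.  A time gap > max_gap_s closes the run.

    Returns (starts, ends) index arrays (inclusive) of every run with at
    least one point; duration filtering happens in the caller.
    """
    n = t.shape[0]
    starts = np.empty(n, dtype=np.int64)
    ends = np.empty(n, dtype=np.int64)
    n_runs = 0
    if n == 0:
        return starts[:0], ends[:0]
    s = 0
    sx = x[0]
    sy = y[0]
    cnt = 1
    for i in range(1, n):
        gap = t[i] - t[i - 1]
        cx = sx / cnt
        cy = sy / cnt
        d = np.sqrt((x[i] - cx) ** 2 + (y[i] - cy) ** 2)
        if gap > max_gap_s or d > radius_m:
            starts[n_runs] = s
            ends[n_runs] = i - 1
            n_runs += 1
            s = i
            sx = x[i]
            sy = y[i]
            cnt = 1
        else:
            sx += x[i]
            sy += y[i]
            cnt += 1
    starts[n_runs] = s
    ends[n_runs] = n - 1
    n_runs += 1
    return starts[:n_runs].copy(), ends[:n_runs].copy()


@njit(cache=False)
def flight_splits(t, x, y, seg_start, seg_end, min_vertex_m, heading_change_rad,
                  max_gap_s):  # pragma: no cover - numba
    """Split one inter-pause segment [seg_start, seg_end] (inclusive indices)
    into flights.

    Points are decimated to "vertices" spaced >= min_vertex_m apart so that
    headings are evaluated above the GPS-noise floor; the segment is split
    wherever the vertex-to-vertex heading turns by more than
    heading_change_rad, or at time gaps > max_gap_s.  Each flight is the
    (origin_index, destination_index) pair of its bounding vertices.
    """
    max_fl = seg_end - seg_start + 2
    f0 = np.empty(max_fl, dtype=np.int64)
    f1 = np.empty(max_fl, dtype=np.int64)
    nf = 0
    if seg_end <= seg_start:
        return f0[:0], f1[:0]

    # vertex decimation
    verts = np.empty(seg_end - seg_start + 1, dtype=np.int64)
    nv = 0
    verts[nv] = seg_start
    nv += 1
    last = seg_start
    for i in range(seg_start + 1, seg_end + 1):
        d = np.sqrt((x[i] - x[last]) ** 2 + (y[i] - y[last]) ** 2)
        if d >= min_vertex_m or t[i] - t[i - 1] > max_gap_s or i == seg_end:
            verts[nv] = i
            nv += 1
            last = i
    if nv < 2:
        return f0[:0], f1[:0]

    start_v = 0
    prev_heading = np.arctan2(y[verts[1]] - y[verts[0]],
                              x[verts[1]] - x[verts[0]])
    for k in range(2, nv):
        a = verts[k - 1]
        b = verts[k]
        heading = np.arctan2(y[b] - y[a], x[b] - x[a])
        dh = heading - prev_heading
        while dh > np.pi:
            dh -= 2.0 * np.pi
        while dh < -np.pi:
            dh += 2.0 * np.pi
        gap_break = t[b] - t[a] > max_gap_s
        if gap_break:
            # no flight is asserted across a long observation gap
            if start_v < k - 1:
                f0[nf] = verts[start_v]
                f1[nf] = a
                nf += 1
            start_v = k
        elif abs(dh) > heading_change_rad:
            f0[nf] = verts[start_v]
            f1[nf] = a
            nf += 1
            start_v = k - 1
        prev_heading = heading
    if start_v < nv - 1:
        f0[nf] = verts[start_v]
        f1[nf] = verts[nv - 1]
        nf += 1
    return f0[:nf].copy(), f1[:nf].copy()
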