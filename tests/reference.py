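"""Independent reference implementations used as oracles in tests.

Everything here is deliberately written in plain scalar Python (lists,
loops, no numpy vectorization) so that it shares no code path with the
package implementation it checks.
"""

from __future__ import annotations


def refine_box_reference(pixels, box, step, tau, max_iterations=500):
    """Scalar transcription of the corner-deviation shrink loop.

    ``pixels`` is a list of rows (row-major; pixel (x, y) is
    ``pixels[y][x]``), ``box`` an (x1, y1, x2, y2) tuple with inclusive
    corners.  Returns ((x1, y1, x2, y2), iterations, converged).
    """
    height = len(pixels)
    width = len(pixels[0])
    total = 0.0
    for row in pixels:
        for v in row:
            total += v
    mu = total / (height * width)

    x1, y1, x2, y2 = box
    iterations = 0
    while iterations < max_iterations:
        i_tl = pixels[y1][x1]
        i_tr = pixels[y1][x2]
        i_bl = pixels[y2][x1]
        i_br = pixels[y2][x2]
        d_tl = abs(i_tl - mu)
        d_tr = abs(i_tr - mu)
        d_bl = abs(i_bl - mu)
        d_br = abs(i_br - mu)
        if d_tl <= tau and d_tr <= tau and d_bl <= tau and d_br <= tau:
            return (x1, y1, x2, y2), iterations, True
        nx1, ny1, nx2, ny2 = x1, y1, x2, y2
        if d_tl > tau:
            nx1 += step
            ny1 += step
        if d_tr > tau:
            nx2 -= step
            ny1 += step
        if d_bl > tau:
            nx1 += step
            ny2 -= step
        if d_br > tau:
            nx2 -= step
            ny2 -= step
        if nx1 >= nx2 or ny1 >= ny2:
            return (x1, y1, x2, y2), iterations + 1, False
        x1, y1, x2, y2 = nx1, ny1, nx2, ny2
        iterations += 1
    return (x1, y1, x2, y2), max_iterations, False


def mean_reference(pixels):
    """Double-loop arithmetic mean."""
    total = 0.0
    count = 0
    for row in pixels:
        for v in row:
            total += v
            count += 1
    return total / count


def corner_deviations_reference(pixels, box, mu):
    """Scalar corner lookups; box corners inclusive, (x, y) = column, row."""
    x1, y1, x2, y2 = box
    return (
        abs(pixels[y1][x1] - mu),
        abs(pixels[y1][x2] - mu),
        abs(pixels[y2][x1] - mu),
        abs(pixels[y2][x2] - mu),
    )
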