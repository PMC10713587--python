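"""Independent reference implementations used as test oracles."""

import numpy as np
from scipy import ndimage as ndi

from sparsectp.deconv import FitConfig, _basis_pairs


def brute_force_fit_sse(aif_values, tissue, cfg: FitConfig, dt=1.0,
                        n_amp=40):
    """Minimum SSE over a fully discretized (t0, w, a1, a2) grid.

    Amplitudes are enumerated on a uniform grid between 0 and a generous
    upper bound with the constraint a2 <= a1; this discretized exhaustive
    search can never beat the constrained linear solve, so it bounds the
    solver's SSE from above.
    """
    tissue = np.asarray(tissue, float)
    best = np.inf
    peak = max(tissue.max(), 1e-12)
    yty = float(tissue @ tissue)
    frac = np.linspace(0.0, 1.0, 8)
    for t0, w, b1, b2 in _basis_pairs(np.asarray(aif_values, float), cfg, dt):
        bmax = max(b1.max(), 1e-12)
        a1 = np.linspace(0.0, 3.0 * peak / bmax, n_amp)[:, None]
        a2 = a1 * frac[None, :]  # enumerate a2 in [0, a1]
        g11 = float(b1 @ b1)
        g12 = float(b1 @ b2)
        g22 = float(b2 @ b2)
        c1 = float(b1 @ tissue)
        c2 = float(b2 @ tissue)
        sse = (
            yty
            - 2.0 * (a1 * c1 + a2 * c2)
            + a1 * a1 * g11
            + 2.0 * a1 * a2 * g12
            + a2 * a2 * g22
        )
        best = min(best, float(sse.min()))
    return best


def staged_morphology(mask, spacing, min_component_ml=1.0, radius_mm=2.0):
    """Step-by-step composition of independently implemented morphology.

    Uses explicit dilate/erode primitives for closing and opening, a
    per-slice flood-fill-based hole fill, and a hand-rolled component
    filter.
    """
    half = [max(int(np.floor(radius_mm / s + 1e-9)), 0) for s in spacing]
    grids = np.meshgrid(
        *[np.arange(-h, h + 1) * s for h, s in zip(half, spacing)],
        indexing="ij",
    )
    selem = sum(g * g for g in grids) <= radius_mm**2 + 1e-9

    out = ndi.binary_erosion(ndi.binary_dilation(mask, selem), selem)  # closing
    out = ndi.binary_dilation(ndi.binary_erosion(out, selem), selem)  # opening
    filled = np.zeros_like(out)
    for k in range(out.shape[2]):
        sl = out[:, :, k]
        # hole filling via background flood from the border
        inv = ~sl
        border = np.zeros_like(inv)
        border[0, :] = border[-1, :] = True
        border[:, 0] = border[:, -1] = True
        reach = np.zeros_like(inv)
        frontier = border & inv
        while frontier.any():
            reach |= frontier
            grown = ndi.binary_dilation(frontier, np.ones((3, 3), bool)) & inv
            frontier = grown & ~reach
        filled[:, :, k] = sl | (inv & ~reach)
    labels, n = ndi.label(filled, structure=np.ones((3, 3, 3), int))
    voxel_ml = float(np.prod(spacing)) / 1000.0
    keep = np.zeros_like(filled)
    for lab in range(1, n + 1):
        comp = labels == lab
        if comp.sum() * voxel_ml >= min_component_ml:
            keep |= comp
    return keep
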