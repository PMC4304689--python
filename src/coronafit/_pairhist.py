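"""Species-resolved pair-distance histograms (numba kernels).

The Debye sum over N particles is reduced to a sum over distance bins:
all pairwise distances are snapped to bin centres and accumulated per
(species_i, species_j) so that q-dependent amplitudes factor out of the
O(N^2) work.  Histograms count each unordered pair once (i < j, or one
direction for cross blocks); the diagonal i = j is handled analytically
by the engine.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def pair_hist_self(coords, species, n_species, inv_dr, n_bins):
    H = np.zeros((n_species, n_species, n_bins))
    n = coords.shape[0]
    for i in range(n):
        xi = coords[i, 0]
        yi = coords[i, 1]
        zi = coords[i, 2]
        si = species[i]
        for j in range(i + 1, n):
            dx = coords[j, 0] - xi
            dy = coords[j, 1] - yi
            dz = coords[j, 2] - zi
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            k = int(r * inv_dr)
            if k >= n_bins:
                k = n_bins - 1
            H[si, species[j], k] += 1.0
    return H


@njit(cache=True)
def pair_hist_cross(coords_a, species_a, coords_b, species_b,
                    n_species, inv_dr, n_bins):
    H = np.zeros((n_species, n_species, n_bins))
    na = coords_a.shape[0]
    nb = coords_b.shape[0]
    for i in range(na):
        xi = coords_a[i, 0]
        yi = coords_a[i, 1]
        zi = coords_a[i, 2]
        si = species_a[i]
        for j in range(nb):
            dx = coords_b[j, 0] - xi
            dy = coords_b[j, 1] - yi
            dz = coords_b[j, 2] - zi
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            k = int(r * inv_dr)
            if k >= n_bins:
                k = n_bins - 1
            H[si, species_b[j], k] += 1.0
    return H
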