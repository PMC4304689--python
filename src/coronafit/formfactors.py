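"""X-ray atomic form factors for protein atomic groups.

Four-Gaussian Cromer-Mann parametrisations (International Tables for
Crystallography Vol. C) for the elements that occur in protein heavy-atom
groups.  Implicit hydrogens are folded into the heavy-atom amplitude by
adding ``n_H`` hydrogen form factors, so a CH2 group scatters as
``f_C(q) + 2 f_H(q)`` with ``f(0) = 8``.
"""

from __future__ import annotations

import numpy as np

# element -> (a1..a4, b1..b4, c); f(s) = sum a_i exp(-b_i s^2) + c, s = q/(4 pi)
CROMER_MANN: dict[str, tuple[tuple[float, ...], tuple[float, ...], float]] = {
    "H": ((0.489918, 0.262003, 0.196767, 0.049879),
          (20.6593, 7.74039, 49.5519, 2.20159), 0.001305),
    "C": ((2.31000, 1.02000, 1.58860, 0.865000),
          (20.8439, 10.2075, 0.568700, 51.6512), 0.215600),
    "N": ((12.2126, 3.13220, 2.01250, 1.16630),
          (0.005700, 9.89330, 28.9975, 0.582600), -11.529),
    "O": ((3.04850, 2.28680, 1.54630, 0.867000),
          (13.2771, 5.70110, 0.323900, 32.9089), 0.250800),
    "S": ((6.90530, 5.20340, 1.43790, 1.58630),
          (1.46790, 22.2151, 0.253600, 56.1720), 0.866900),
    "P": ((6.43450, 4.17910, 1.78000, 1.49080),
          (1.90670, 27.1570, 0.526000, 68.1645), 1.11490),
}

ATOMIC_NUMBER = {"H": 1, "C": 6, "N": 7, "O": 8, "P": 15, "S": 16}


def atomic_form_factor(element: str, q: np.ndarray | float) -> np.ndarray:
    """In-vacuum form factor f(q) of a single element, in electrons."""
    try:
        a, b, c = CROMER_MANN[element.upper()]
    except KeyError:
        raise KeyError(f"no Cromer-Mann coefficients for element {element!r}")
    s2 = (np.asarray(q, dtype=float) / (4.0 * np.pi)) ** 2
    f = np.full_like(s2, c, dtype=float)
    for ai, bi in zip(a, b):
        f += ai * np.exp(-bi * s2)
    return f


def group_form_factor(element: str, n_h: int, q: np.ndarray | float) -> np.ndarray:
    """Form factor of a heavy atom with ``n_h`` bonded hydrogens folded in."""
    f = atomic_form_factor(element, q)
    if n_h:
        f = f + n_h * atomic_form_factor("H", q)
    return f
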