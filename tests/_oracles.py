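"""Independent brute-force oracles kept deliberately separate from the
implementation they check."""

import itertools

import numpy as np

from exomet.chem import DEFAULT_ELEMENTS, MolecularFormula


def naive_enumerate(target_mass, cfg):
    """Unpruned scan over all six element ranges.

    Every (C, H, N, O, S, P) combination inside ``cfg.element_ranges``
    is mass-checked and filtered; no analytic bounding of C or H.  The
    C×H grid is evaluated with numpy so the scan stays affordable, but
    the candidate *set* is exactly the naive six-deep nested loop's.
    """
    t = DEFAULT_ELEMENTS.masses
    r = cfg.element_ranges
    cvals = np.arange(r["C"][0], r["C"][1] + 1)
    hvals = np.arange(r["H"][0], r["H"][1] + 1)
    C, H = np.meshgrid(cvals, hvals, indexing="ij")
    mass_ch = C * t["C"] + H * t["H"]
    tol = target_mass * cfg.tolerance_ppm * 1e-6
    hc = H / C
    static_ok = (hc >= cfg.hc_range[0]) & (hc <= cfg.hc_range[1])
    found = set()
    for n, s, p, o in itertools.product(
        range(r["N"][0], r["N"][1] + 1),
        range(r["S"][0], r["S"][1] + 1),
        range(r["P"][0], r["P"][1] + 1),
        range(r["O"][0], r["O"][1] + 1),
    ):
        base = n * t["N"] + s * t["S"] + p * t["P"] + o * t["O"]
        ok = np.abs(base + mass_ch - target_mass) <= tol
        if not ok.any():
            continue
        ok &= static_ok
        ok &= o <= cfg.oc_max * C
        d = 1.0 + C - H / 2.0 + (n + p) / 2.0
        ok &= (d >= cfg.dbe_range[0]) & (d <= cfg.dbe_range[1])
        if cfg.require_integer_dbe:
            ok &= (H + n + p) % 2 == 0
        for ci, hi in zip(*np.nonzero(ok)):
            found.add(
                MolecularFormula(
                    {"C": int(cvals[ci]), "H": int(hvals[hi]), "N": n, "O": o, "S": s, "P": p}
                )
            )
    return found
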