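"""Shared independent oracles for the test suite."""

import numpy as np


def brute_force_tmm_factor(obs, ref, trim_m=0.3, trim_a=0.05):
    """Enumerate the TMM trim set explicitly and take the weighted mean of M."""
    lib_o, lib_r = obs.sum(), ref.sum()
    shared = (obs > 0) & (ref > 0)
    o, r = obs[shared] / lib_o, ref[shared] / lib_r
    m = np.log2(o / r)
    a = 0.5 * np.log2(o * r)
    n = m.size
    keep = set(range(n))
    for vals, trim in ((m, trim_m), (a, trim_a)):
        cut = int(np.floor(n * trim))
        order = np.argsort(vals, kind="mergesort")
        keep -= set(order[:cut]) | set(order[n - cut:])
    idx = sorted(keep)
    w = 1.0 / ((lib_o - obs[shared][idx]) / (lib_o * obs[shared][idx])
               + (lib_r - ref[shared][idx]) / (lib_r * ref[shared][idx]))
    return 2.0 ** (np.sum(w * m[idx]) / np.sum(w))
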