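"""Independent brute-force oracle: exhaustive enumeration of the tree.

Enumerates every Bernoulli outcome combination (score test, each potential
IUI cycle, each potential IVF cycle) with its exact probability weight and
applies the stopping rules trajectory-by-trajectory.  Shares no code with the
closed-form engine; expectations are exact sums, not simulations.
"""

import itertools

from artdecision import AgeBand, Strategy


def enumerate_expectations(strategy, draw, age):
    """Exact expectations by path enumeration.

    Returns a dict with preg, preg_via (iui, tiui, ivf), live_birth,
    e_iui_cycles, e_ivf_cycles, cost_iui, cost_ivf.
    """
    strategy = Strategy.coerce(strategy)
    band = AgeBand.coerce(age)
    n_iui, n_ivf = draw.n_iui, draw.n_ivf

    if strategy is Strategy.SOC:
        branches = [(1.0, True, draw.p_iui[band], "iui")]
    else:
        branches = [
            (draw.p_low_cs, False, 0.0, "tiui"),
            (1.0 - draw.p_low_cs, True, draw.p_tiui, "tiui"),
        ]

    acc = {
        "preg": 0.0, "via_iui": 0.0, "via_tiui": 0.0, "via_ivf": 0.0,
        "live_birth": 0.0, "e_iui_cycles": 0.0, "e_ivf_cycles": 0.0,
        "cost_iui": 0.0, "cost_ivf": 0.0,
    }
    for w_branch, do_iui, p_insem, insem_mod in branches:
        if w_branch == 0.0:
            continue
        for iui_bits in itertools.product((0, 1), repeat=n_iui if do_iui else 0):
            w_iui = 1.0
            for b in iui_bits:
                w_iui *= p_insem if b else (1.0 - p_insem)
            # stopping rule: first success ends the IUI stage
            conceived = False
            iui_used = 0
            for k, b in enumerate(iui_bits):
                if b:
                    conceived, iui_used = True, k + 1
                    break
            else:
                iui_used = len(iui_bits)
            if conceived:
                w = w_branch * w_iui
                _tally(acc, draw, band, w, insem_mod, iui_used, 0)
                continue
            p_ivf = draw.p_ivf[band]
            for ivf_bits in itertools.product((0, 1), repeat=n_ivf):
                w_ivf = 1.0
                for b in ivf_bits:
                    w_ivf *= p_ivf if b else (1.0 - p_ivf)
                conceived_ivf = False
                ivf_used = 0
                for k, b in enumerate(ivf_bits):
                    if b:
                        conceived_ivf, ivf_used = True, k + 1
                        break
                else:
                    ivf_used = len(ivf_bits)
                w = w_branch * w_iui * w_ivf
                _tally(acc, draw, band, w, "ivf" if conceived_ivf else None,
                       iui_used, ivf_used)
    return acc


def _tally(acc, draw, band, w, modality, iui_used, ivf_used):
    acc["e_iui_cycles"] += w * iui_used
    acc["e_ivf_cycles"] += w * ivf_used
    acc["cost_iui"] += w * draw.c_iui * iui_used
    acc["cost_ivf"] += w * draw.c_ivf * ivf_used
    if modality is None:
        return
    acc["preg"] += w
    acc[f"via_{modality}"] += w
    l_cond = draw.l_ivf[band] if modality == "ivf" else draw.l_iui[band]
    acc["live_birth"] += w * l_cond
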