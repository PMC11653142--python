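"""Independent brute-force reference for restraint generation.

Enumerates every residue pair in O(n²) and applies each mode's rule
literally, with no shared code with the implementation under test.
"""

from __future__ import annotations

import math


def brute_force_restraints(structure, config):
    """Return a sorted list of (i, j, d0, weight) under the mode rules."""
    mode = config.mode.value
    out = []
    n = len(structure)
    for i in range(n):
        ri = structure[i]
        if ri.ca is None:
            continue
        for j in range(i + 1, n):
            rj = structure[j]
            if rj.ca is None:
                continue
            if ri.chain_id == rj.chain_id:
                if j - i < config.min_seq_gap:
                    continue
            elif not config.include_interchain:
                continue
            d = math.dist(tuple(ri.ca), tuple(rj.ca))
            if d > config.max_distance:
                continue
            w = _weight(mode, ri, rj, config)
            if w is None:
                continue
            out.append((i, j, d, w))
    return out


def _weight(mode, ri, rj, config):
    regular = ("HELIX", "SHEET")
    if mode == "ALL":
        return 1.0
    if mode == "SS2":
        return 1.0 if (ri.ss.value in regular and rj.ss.value in regular) else None
    if mode == "SS1":
        return 1.0 if (ri.ss.value in regular or rj.ss.value in regular) else None
    if mode == "MIN":
        w = min(ri.plddt, rj.plddt) / 100.0
        return None if w < config.plddt_strength_floor else w
    if mode == "MAX":
        w = max(ri.plddt, rj.plddt) / 100.0
        return None if w < config.plddt_strength_floor else w
    if mode == "MEAN":
        w = (ri.plddt + rj.plddt) / 2.0 / 100.0
        if config.mean_floor and w < config.plddt_strength_floor:
            return None
        return w
    if mode == "PLDDT1":
        hits = (ri.plddt > config.plddt_pair_cutoff) + (rj.plddt > config.plddt_pair_cutoff)
        return 1.0 if hits >= 1 else None
    if mode == "PLDDT2":
        hits = (ri.plddt > config.plddt_pair_cutoff) + (rj.plddt > config.plddt_pair_cutoff)
        return 1.0 if hits == 2 else None
    if mode == "CATEGORY":
        w = config.strength_matrix.table[
            _category(ri, config.category_rules), _category(rj, config.category_rules)
        ]
        return None if w == 0.0 else float(w)
    raise AssertionError(f"oracle does not know mode {mode}")


def _category(res, rules):
    base = {"COIL": 0, "TURN": 1, "HELIX": 2, "SHEET": 2}[res.ss.value]
    if res.plddt >= rules.high_conf_cutoff:
        base += 1
    elif res.plddt < rules.low_conf_cutoff:
        base -= 1
    return max(0, min(3, base))
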