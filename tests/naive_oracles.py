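"""Independent brute-force re-implementations used as test oracles.

Everything here evaluates the defining formulas directly — explicit Python
loops, cofactor-expansion determinants, scipy for superposition — and shares
no scoring code with the package.  Data containers (Fragment, Segment,
FragmentBank) are reused as plain structs.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.spatial.transform import Rotation

DEGENERACY_REL_FLOOR = 1e-6


def det3(m) -> float:
    """3x3 determinant by cofactor expansion along the first row."""
    return (
        m[0][0] * (m[1][1] * m[2][2] - m[1][2] * m[2][1])
        - m[0][1] * (m[1][0] * m[2][2] - m[1][2] * m[2][0])
        + m[0][2] * (m[1][0] * m[2][1] - m[1][1] * m[2][0])
    )


def centered(coords) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    mean = [sum(coords[:, k]) / len(coords) for k in range(3)]
    return coords - np.array(mean)


def gram(a, b):
    """Explicit 3x3 matrix of column dot products."""
    out = [[0.0] * 3 for _ in range(3)]
    for r in range(3):
        for c in range(3):
            out[r][c] = float(sum(a[i][r] * b[i][c] for i in range(len(a))))
    return out


def naive_is_degenerate(coords) -> bool:
    g = gram(centered(coords), centered(coords))
    tr = g[0][0] + g[1][1] + g[2][2]
    return det3(g) < DEGENERACY_REL_FLOOR * (tr / 3.0) ** 3


def naive_bc(x, y) -> float:
    xc, yc = centered(x), centered(y)
    num = det3(gram(xc, yc))
    den = math.sqrt(det3(gram(xc, xc)) * det3(gram(yc, yc)))
    return max(-1.0, min(1.0, num / den))


def naive_rigidity(x, y) -> float:
    xc, yc = centered(x), centered(y)
    worst = 0.0
    for i in range(len(xc)):
        nx = math.sqrt(sum(v * v for v in xc[i]))
        ny = math.sqrt(sum(v * v for v in yc[i]))
        worst = max(worst, abs(nx - ny))
    ex = math.sqrt(sum(v * v for v in (xc[-1] - xc[0])))
    ey = math.sqrt(sum(v * v for v in (yc[-1] - yc[0])))
    return max(worst, abs(ex - ey))


def naive_rmsd(x, y) -> float:
    """Superposition RMSD through scipy's orthogonal-Procrustes route."""
    xc, yc = centered(x), centered(y)
    rot, _ = Rotation.align_vectors(yc, xc)
    diff = rot.apply(xc) - yc
    return float(np.sqrt((diff ** 2).sum() / len(xc)))


def _windows(bank, n):
    for seg in bank.segments:
        for start in range(len(seg) - n + 1):
            yield seg, start


def naive_frag_search(query, bank, params, mirrored=False):
    """Hit list as (hit_id, chain, h_start label, bc, rigidity), ordered."""
    q = query.coords
    rows = []
    for seg, start in _windows(bank, len(q)):
        w = seg.coords[start:start + len(q)]
        if naive_is_degenerate(w):
            continue
        bc = naive_bc(q, w)
        rig = naive_rigidity(q, w)
        if mirrored:
            passing = bc <= -params.bc_cutoff and rig <= params.rigidity_cutoff
        else:
            passing = bc >= params.bc_cutoff and rig <= params.rigidity_cutoff
        if passing:
            rec = seg.residues[start]
            rows.append({
                "hit_id": seg.structure_id,
                "h_start": f"{seg.chain_id}:{rec.label}",
                "bc": bc,
                "rigidity": rig,
                "key": (bc if mirrored else -bc, rig, seg.structure_id,
                        (seg.chain_id, rec.num, rec.icode)),
            })
    rows.sort(key=lambda r: r["key"])
    return rows


def naive_graft(window_coords, flank_len, gap_len, q_flanks):
    w = np.asarray(window_coords)
    w_fl = np.vstack([w[:flank_len], w[flank_len + gap_len:]])
    rot, _ = Rotation.align_vectors(centered(q_flanks), centered(w_fl))
    q_mean = np.asarray(q_flanks).mean(axis=0)
    w_mean = w_fl.mean(axis=0)
    loop = w[flank_len:flank_len + gap_len]
    return rot.apply(loop - w_mean) + q_mean


def naive_clash(loop, loop_idx, template, min_sep, cutoff) -> bool:
    """True = passes. template: (chain, seq index or None, xyz)."""
    for li, lp in zip(loop_idx, loop):
        for _, ti, txyz in template:
            if ti is not None and abs(li - ti) < min_sep:
                continue
            d = math.dist(tuple(lp), tuple(txyz))
            if d < cutoff:
                return False
    return True


def naive_loop_search(lq, bank, params, flank_len=4):
    n = 2 * flank_len + lq.gap_length
    q_flanks = np.vstack([lq.n_flank.coords, lq.c_flank.coords])
    rows = []
    for seg, start in _windows(bank, n):
        w = seg.coords[start:start + n]
        w_fl = np.vstack([w[:flank_len], w[flank_len + lq.gap_length:]])
        if naive_is_degenerate(w_fl):
            continue
        bc = naive_bc(q_flanks, w_fl)
        rig = naive_rigidity(q_flanks, w_fl)
        if not (bc >= params.bc_cutoff and rig <= params.rigidity_cutoff):
            continue
        loop = naive_graft(w, flank_len, lq.gap_length, q_flanks)
        if not naive_clash(loop, lq.loop_seq_indices, lq.template_coords,
                           params.min_seq_sep, params.clash_cutoff):
            continue
        rec = seg.residues[start]
        rows.append({
            "hit_id": seg.structure_id,
            "h_start": f"{seg.chain_id}:{rec.label}",
            "bc": bc,
            "rigidity": rig,
            "key": (-bc, rig, seg.structure_id, (seg.chain_id, rec.num, rec.icode)),
        })
    rows.sort(key=lambda r: r["key"])
    return rows


def naive_specificity(query_segments, bank, params):
    """Per-window (chain, start label, sp) via per-window naive frag search."""
    ids = []
    for seg in bank.segments:
        if seg.structure_id not in ids:
            ids.append(seg.structure_id)
    n_total = len(ids)
    out = []
    w = params.window_size
    for seg in query_segments:
        for start in range(len(seg) - w + 1):
            frag = seg.fragment(start, w)
            if naive_is_degenerate(frag.coords):
                sp = math.nan
            else:
                hits = naive_frag_search(frag, bank, params)
                sp = 1.0 - len({h["hit_id"] for h in hits}) / n_total
            out.append((seg.chain_id, seg.residues[start].label, sp))
    return out
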