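"""The four mining services built on the BC and rigidity scores.

* :func:`frag_search` — exhaustive sliding-window search for fragments
  similar to a query (BC >= cutoff, rigidity <= cutoff).
* :func:`mirror_search` — the same for anti-similar (mirror) conformations
  (BC <= -cutoff).
* :func:`loop_search` — candidate conformations for a missing region,
  matched on two 4-residue flanks and screened for steric clashes after
  grafting into the template frame.
* :func:`specificity_search` — per-window rarity profiling of a whole
  structure against a bank: sp = 1 - N_hits / N_total.

All services enumerate every stride-1 window of every contiguous segment;
degenerate (collinear/coplanar) bank windows are skipped with a logged
count, while a degenerate query is a hard error.  Hit lists follow a total
order (score, then rigidity, then hit id, chain, start residue), so two runs
on the same inputs are byte-identical.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .geometry import (
    CLAMP_WARN,
    DEGENERACY_REL_FLOOR,
    MIN_BC_POINTS,
    DegenerateFragmentError,
    Fragment,
    ShapeMismatchError,
    center,
    is_degenerate,
    mirror,
    superpose_kabsch,
)
from .pdbio import EmptyBankError, FragmentBank, LoopQuery, Segment, Structure, contiguous_segments

log = logging.getLogger("bcmine")

#: number of residues in each loop-search flank
FLANK_LEN = 4


@dataclass(frozen=True)
class SearchParams:
    """Cutoffs and sizes driving all services.

    Defaults: BC cutoff 0.95 and rigidity cutoff 1.0 Å (the standard search
    values), hit tables truncated to the best 1000, loop candidates rejected
    when any loop Cα comes within 3.0 Å of a template Cα at least 3 sequence
    positions away, and a 9-residue window for specificity profiling.
    """

    bc_cutoff: float = 0.95
    rigidity_cutoff: float = 1.0
    max_hits: int = 1000
    clash_cutoff: float = 3.0
    min_seq_sep: int = 3
    window_size: int = 9

    def __post_init__(self):
        if not (0.0 < self.bc_cutoff <= 1.0):
            raise ValueError("bc_cutoff must be in (0, 1]")
        if self.rigidity_cutoff < 0:
            raise ValueError("rigidity_cutoff must be >= 0")


@dataclass
class Hit:
    """One query-window match."""

    query_id: str
    hit_id: str
    q_start: str
    q_end: str
    h_start: str
    h_end: str
    bc: float
    rigidity: float
    p_value: float
    rmsd: float
    hit_sequence: str
    is_self: bool
    #: (chain_id, residue number, insertion code) of the match start — the
    #: tail of the deterministic sort key
    h_key: tuple = field(default=(), compare=False)
    #: grafted loop Cα coordinates in the template frame (loop search only)
    loop_coords: Optional[np.ndarray] = field(default=None, compare=False)


def _frag_sort_key(h: Hit):
    return (-h.bc, h.rigidity, h.hit_id, h.h_key)


def _mirror_sort_key(h: Hit):
    return (h.bc, h.rigidity, h.hit_id, h.h_key)


# ---------------------------------------------------------------------------
# Vectorized window scoring
# ---------------------------------------------------------------------------

def _window_stack(seg_coords: np.ndarray, n: int) -> np.ndarray:
    """(n_windows, n, 3) view of all stride-1 windows of a segment."""
    return sliding_window_view(seg_coords, n, axis=0).transpose(0, 2, 1)


def _score_against(Xc: np.ndarray, det_x: float, W: np.ndarray):
    """BC and rigidity of a centered query against a stack of windows.

    Parameters
    ----------
    Xc : (n, 3) centered query coordinates
    det_x : det(XcᵀXc), precomputed
    W : (w, n, 3) raw window coordinates

    Returns
    -------
    bc : (w,) clamped BC scores (NaN where degenerate)
    rig : (w,) rigidity scores
    degenerate : (w,) bool mask of degenerate windows
    """
    C = W - W.mean(axis=1, keepdims=True)
    G = np.einsum("wni,wnj->wij", C, C)
    det_w = np.linalg.det(G)
    tr = np.trace(G, axis1=1, axis2=2)
    degenerate = det_w < DEGENERACY_REL_FLOOR * (tr / 3.0) ** 3
    cross = np.einsum("ni,wnj->wij", Xc, C)
    with np.errstate(divide="ignore", invalid="ignore"):
        bc = np.linalg.det(cross) / np.sqrt(det_x * det_w)
    bc[degenerate] = np.nan
    excursion = np.nanmax(np.abs(bc), initial=0.0) - 1.0
    if excursion > CLAMP_WARN:
        log.warning("BC scores clamped to [-1, 1]; worst excursion %.3g", excursion)
    bc = np.clip(bc, -1.0, 1.0)

    nx = np.linalg.norm(Xc, axis=1)
    nw = np.linalg.norm(C, axis=2)
    radial = np.max(np.abs(nw - nx), axis=1)
    end_x = np.linalg.norm(Xc[-1] - Xc[0])
    end_w = np.linalg.norm(C[:, -1] - C[:, 0], axis=1)
    rig = np.maximum(radial, np.abs(end_w - end_x))
    return bc, rig, degenerate


def _require_valid_query(frag: Fragment) -> tuple[np.ndarray, float]:
    if len(frag) < MIN_BC_POINTS:
        raise ShapeMismatchError(f"query must have >= {MIN_BC_POINTS} residues")
    Xc = center(frag).coords
    if is_degenerate(Xc):
        raise DegenerateFragmentError("query fragment is degenerate (collinear/coplanar)")
    return Xc, float(np.linalg.det(Xc.T @ Xc))


def _window_is_self(query: Fragment, seg: Segment, start: int) -> bool:
    return (
        query.source_id == seg.structure_id
        and query.chain_id == seg.chain_id
        and query.start_res == seg.residues[start].label
    )


def _label(seg: Segment, i: int) -> str:
    return f"{seg.chain_id}:{seg.residues[i].label}"


# ---------------------------------------------------------------------------
# Fragment and mirror search
# ---------------------------------------------------------------------------

def frag_search(
    query: Fragment,
    bank: FragmentBank,
    params: SearchParams = SearchParams(),
    null_model=None,
) -> list[Hit]:
    """Exhaustive search for bank windows similar to the query.

    A window is a hit iff BC >= ``bc_cutoff`` and rigidity <=
    ``rigidity_cutoff``.  Hits are sorted by BC descending (ties: rigidity
    ascending, then hit id, chain, start residue) and carry the Kabsch RMSD
    to the query and, when a null model is supplied, an empirical upper-tail
    P-value.  Windows from the query's own structure/position are flagged
    ``is_self`` but kept.
    """
    return _directional_search(query, bank, params, null_model, mirrored=False)


def mirror_search(
    query: Fragment,
    bank: FragmentBank,
    params: SearchParams = SearchParams(),
    null_model=None,
) -> list[Hit]:
    """Exhaustive search for windows anti-similar (mirror) to the query.

    A window is a hit iff BC <= ``-bc_cutoff`` and rigidity <=
    ``rigidity_cutoff`` (rigidity is reflection invariant, so it is computed
    directly).  Hits are sorted by BC ascending; the reported RMSD is
    between the window and the *mirrored* query.
    """
    return _directional_search(query, bank, params, null_model, mirrored=True)


def _directional_search(query, bank, params, null_model, mirrored: bool) -> list[Hit]:
    from .stats import p_value as _p_value

    Xc, det_x = _require_valid_query(query)
    n = len(query)
    query_id = query.source_id or "query"
    q_start = f"{query.chain_id}:{query.start_res}" if query.chain_id else query.start_res
    q_end = f"{query.chain_id}:{query.end_res}" if query.chain_id else query.end_res
    ref = mirror(query) if mirrored else query

    hits: list[Hit] = []
    n_degenerate = 0
    n_windows = 0
    for seg in bank.segments:
        if len(seg) < n:
            continue
        W = _window_stack(seg.coords, n)
        n_windows += len(W)
        bc, rig, degen = _score_against(Xc, det_x, W)
        n_degenerate += int(degen.sum())
        if mirrored:
            passing = np.nonzero(~degen & (bc <= -params.bc_cutoff) & (rig <= params.rigidity_cutoff))[0]
        else:
            passing = np.nonzero(~degen & (bc >= params.bc_cutoff) & (rig <= params.rigidity_cutoff))[0]
        for w in passing:
            w = int(w)
            frag = seg.fragment(w, n)
            score = float(bc[w])
            if null_model is not None:
                p = _p_value(score, null_model, tail="lower" if mirrored else "upper")
            else:
                p = math.nan
            hits.append(Hit(
                query_id=query_id,
                hit_id=seg.structure_id,
                q_start=q_start,
                q_end=q_end,
                h_start=_label(seg, w),
                h_end=_label(seg, w + n - 1),
                bc=score,
                rigidity=float(rig[w]),
                p_value=p,
                rmsd=superpose_kabsch(frag, ref).rmsd,
                hit_sequence=frag.sequence,
                is_self=_window_is_self(query, seg, w),
                h_key=(seg.chain_id, seg.residues[w].num, seg.residues[w].icode),
            ))
    if n_windows == 0:
        log.warning("no segment long enough for a %d-residue window; empty result", n)
    if n_degenerate:
        log.info("skipped %d degenerate bank window(s)", n_degenerate)
    hits.sort(key=_mirror_sort_key if mirrored else _frag_sort_key)
    return hits


# ---------------------------------------------------------------------------
# Loop search
# ---------------------------------------------------------------------------

def graft_loop(hit_window: Fragment, loop_query: LoopQuery) -> np.ndarray:
    """Place a hit window's loop residues into the template frame.

    The rigid transform that Kabsch-superposes the window's 8 flank Cα onto
    the query's 8 flank Cα (in the template frame) is applied to the
    window's L loop Cα.
    """
    L = loop_query.gap_length
    if len(hit_window) != 2 * FLANK_LEN + L:
        raise ShapeMismatchError(
            f"window has {len(hit_window)} residues; expected {2 * FLANK_LEN + L}"
        )
    w = hit_window.coords
    w_flanks = np.vstack([w[:FLANK_LEN], w[FLANK_LEN + L:]])
    q_flanks = np.vstack([loop_query.n_flank.coords, loop_query.c_flank.coords])
    sup = superpose_kabsch(w_flanks, q_flanks)
    loop = w[FLANK_LEN:FLANK_LEN + L]
    return loop @ sup.rotation.T + sup.translation


def clash_check(
    candidate_loop_coords: np.ndarray,
    loop_query: LoopQuery,
    params: SearchParams = SearchParams(),
) -> bool:
    """Steric screen of a grafted loop against the template.

    Returns False (fail) iff any loop Cα lies within ``clash_cutoff`` Å of a
    template Cα at least ``min_seq_sep`` positions away along the repaired
    sequence.  Template residues closer in sequence (the flanks and their
    immediate neighbours) are exempt; residues on other chains have no
    sequence relationship and are always checked.
    """
    loop = np.asarray(candidate_loop_coords, dtype=float)
    if len(loop_query.template_coords) == 0:
        return True
    t_coords = np.array([xyz for _, _, xyz in loop_query.template_coords])
    t_idx = np.array(
        [idx if idx is not None else -10**9 for _, idx, _ in loop_query.template_coords]
    )
    t_known = np.array([idx is not None for _, idx, _ in loop_query.template_coords])
    l_idx = np.asarray(loop_query.loop_seq_indices)
    sep = np.abs(l_idx[:, None] - t_idx[None, :])
    checked = ~t_known[None, :] | (sep >= params.min_seq_sep)
    d2 = np.sum((loop[:, None, :] - t_coords[None, :, :]) ** 2, axis=2)
    return not bool(np.any(checked & (d2 < params.clash_cutoff ** 2)))


def loop_search(
    loop_query: LoopQuery,
    bank: FragmentBank,
    params: SearchParams = SearchParams(),
    null_model=None,
) -> list[Hit]:
    """Candidate conformations for a missing region of length L.

    Every bank window of length 4 + L + 4 is matched on its two flanks: the
    8 flank Cα (window positions 1-4 and L+5..L+8, jointly centered) are
    scored by BC and rigidity against the query's jointly centered 8 flank
    Cα.  Windows passing the cutoffs are grafted into the template frame by
    Kabsch superposition of the flanks and discarded if the grafted loop
    clashes with the template.  Reported BC, rigidity, RMSD and P-value are
    all flank-based; the grafted loop coordinates ride on the hit.
    """
    from .stats import p_value as _p_value

    L = loop_query.gap_length
    n = 2 * FLANK_LEN + L
    q8 = np.vstack([loop_query.n_flank.coords, loop_query.c_flank.coords])
    q8c = center(q8).coords
    if is_degenerate(q8c):
        raise DegenerateFragmentError("the 8 flank Cα are near-coplanar; BC is undefined")
    det_q = float(np.linalg.det(q8c.T @ q8c))
    flank_idx = np.r_[0:FLANK_LEN, FLANK_LEN + L:n]
    query_id = loop_query.n_flank.source_id or "query"
    q_start = f"{loop_query.chain_id}:{loop_query.n_flank.start_res}"
    q_end = f"{loop_query.chain_id}:{loop_query.c_flank.end_res}"

    hits: list[Hit] = []
    n_degenerate = 0
    n_clash = 0
    for seg in bank.segments:
        if len(seg) < n:
            continue
        W = _window_stack(seg.coords, n)
        F = W[:, flank_idx, :]
        bc, rig, degen = _score_against(q8c, det_q, F)
        n_degenerate += int(degen.sum())
        passing = np.nonzero(~degen & (bc >= params.bc_cutoff) & (rig <= params.rigidity_cutoff))[0]
        for w in passing:
            w = int(w)
            frag = seg.fragment(w, n)
            loop = graft_loop(frag, loop_query)
            if not clash_check(loop, loop_query, params):
                n_clash += 1
                continue
            w_flanks = np.vstack([frag.coords[:FLANK_LEN], frag.coords[FLANK_LEN + L:]])
            q_flanks = np.vstack([loop_query.n_flank.coords, loop_query.c_flank.coords])
            score = float(bc[w])
            if null_model is not None:
                p = _p_value(score, null_model, tail="upper")
            else:
                p = math.nan
            hits.append(Hit(
                query_id=query_id,
                hit_id=seg.structure_id,
                q_start=q_start,
                q_end=q_end,
                h_start=_label(seg, w),
                h_end=_label(seg, w + n - 1),
                bc=score,
                rigidity=float(rig[w]),
                p_value=p,
                rmsd=superpose_kabsch(w_flanks, q_flanks).rmsd,
                hit_sequence=frag.sequence,
                is_self=False,
                h_key=(seg.chain_id, seg.residues[w].num, seg.residues[w].icode),
                loop_coords=loop,
            ))
    if n_degenerate:
        log.info("skipped %d degenerate flank window(s)", n_degenerate)
    if n_clash:
        log.info("discarded %d candidate(s) clashing with the template", n_clash)
    hits.sort(key=_frag_sort_key)
    return hits


# ---------------------------------------------------------------------------
# Specificity profiling
# ---------------------------------------------------------------------------

@dataclass
class WindowScore:
    chain_id: str
    start: str        # residue label of the first window residue
    end: str
    sp: float         # NaN when the window is degenerate
    n_hits: int


@dataclass
class SpecificityProfile:
    """Per-window and per-residue rarity of a structure's fragments.

    For each window, sp = 1 - N_hits / N_total where N_hits counts the
    *distinct proteins* of the bank containing at least one matching window
    and N_total is the number of proteins in the (filtered) bank.  A
    residue's score is the maximum sp over the windows covering it, so a
    residue is marked specific when it belongs to at least one rare
    fragment.
    """

    windows: list[WindowScore]
    residues: list[tuple[str, str, float]]   # (chain_id, residue label, sp)
    n_total: int
    window_size: int


def specificity_search(
    query: Structure,
    bank: FragmentBank,
    params: SearchParams = SearchParams(),
    include_sccs: Optional[str] = None,
    exclude_sccs: Optional[str] = None,
) -> SpecificityProfile:
    """Profile how rare each window of a whole structure is in a bank.

    The bank may be restricted by classification prefix (e.g. include class
    ``b`` while excluding fold ``b.47``).  One protein counts once no matter
    how many of its windows match.  Degenerate query windows get sp NaN.
    """
    fbank = bank.filtered(include_sccs, exclude_sccs)
    if not fbank.segments:
        raise EmptyBankError("classification filter left the bank empty")
    n_total = fbank.n_structures
    w = params.window_size

    windows: list[WindowScore] = []
    best: dict[tuple[str, str], float] = {}
    for seg in contiguous_segments(query):
        for start in range(len(seg) - w + 1):
            frag = seg.fragment(start, w)
            try:
                found = frag_search(frag, fbank, params)
                n_hits = len({h.hit_id for h in found})
                sp = 1.0 - n_hits / n_total
            except DegenerateFragmentError:
                n_hits, sp = 0, math.nan
            windows.append(WindowScore(
                chain_id=seg.chain_id,
                start=seg.residues[start].label,
                end=seg.residues[start + w - 1].label,
                sp=sp,
                n_hits=n_hits,
            ))
            if not math.isnan(sp):
                for i in range(start, start + w):
                    key = (seg.chain_id, seg.residues[i].label)
                    if key not in best or sp > best[key]:
                        best[key] = sp
    residues = [(c, lbl, best[(c, lbl)])
                for c, recs in query.chains.items() for r in recs
                if (c, lbl := r.label) in best]
    return SpecificityProfile(windows=windows, residues=residues,
                              n_total=n_total, window_size=w)
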