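"""Empirical P-value calibration, hit-table CSV output, sequence-logo matrices.

No closed-form null distribution for the BC score is assumed: significance
is calibrated empirically by scoring random pairs of unrelated bank windows
(windows drawn from distinct structures), and a hit's P-value is the add-one
smoothed upper-tail frequency of its score in that null sample.  The null
bank, fragment length, sample size and seed are recorded as comments in the
CSV header so a table is reproducible from its own metadata.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .geometry import DEGENERACY_REL_FLOOR, ShapeMismatchError
from .pdbio import FragmentBank
from .search import Hit, _window_stack

log = logging.getLogger("bcmine")

DEFAULT_NULL_SAMPLES = 10_000
DEFAULT_NULL_SEED = 1

#: 20 amino acids plus 'X' for nonstandard residues
LOGO_ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"

CSV_COLUMNS = [
    "query", "hit", "q_start", "q_end", "h_start", "h_end",
    "bc_score", "rigidity", "p_value", "rmsd", "sequence", "is_self",
]


class CalibrationError(ValueError):
    """The bank cannot support a null calibration at the requested length."""


# ---------------------------------------------------------------------------
# Null model
# ---------------------------------------------------------------------------

@dataclass
class NullModel:
    """Empirical BC-score distribution of unrelated window pairs."""

    sample_scores: np.ndarray    # sorted ascending, all in [-1, 1]
    n_samples: int
    fragment_length: int
    seed: int


def calibrate_null(
    bank: FragmentBank,
    length: int,
    n_samples: int = DEFAULT_NULL_SAMPLES,
    seed: int = DEFAULT_NULL_SEED,
) -> NullModel:
    """Score ``n_samples`` random pairs of length-``length`` windows drawn
    (with replacement) from distinct structures of the bank.

    Deterministic given ``seed``.  Degenerate windows are excluded from the
    pool.  Raises :class:`CalibrationError` when fewer than 2 structures
    contribute windows of the requested length.
    """
    centered: list[np.ndarray] = []
    dets: list[np.ndarray] = []
    struct_of: list[np.ndarray] = []
    sids = {sid: k for k, sid in enumerate(bank.structure_ids)}
    for seg in bank.segments:
        if len(seg) < length:
            continue
        W = _window_stack(seg.coords, length)
        C = W - W.mean(axis=1, keepdims=True)
        G = np.einsum("wni,wnj->wij", C, C)
        det_w = np.linalg.det(G)
        tr = np.trace(G, axis1=1, axis2=2)
        ok = det_w >= DEGENERACY_REL_FLOOR * (tr / 3.0) ** 3
        centered.append(C[ok])
        dets.append(det_w[ok])
        struct_of.append(np.full(int(ok.sum()), sids[seg.structure_id]))
    if not centered:
        raise CalibrationError(f"bank has no non-degenerate window of length {length}")
    C = np.concatenate(centered)
    D = np.concatenate(dets)
    S = np.concatenate(struct_of)
    if len(C) < 2 or len(np.unique(S)) < 2:
        raise CalibrationError(
            f"null calibration needs windows of length {length} from >= 2 structures"
        )

    rng = np.random.default_rng(seed)
    i = rng.integers(0, len(C), size=n_samples)
    j = rng.integers(0, len(C), size=n_samples)
    # resample pairs that landed in the same structure
    for _ in range(1000):
        same = S[i] == S[j]
        if not same.any():
            break
        j[same] = rng.integers(0, len(C), size=int(same.sum()))
    else:  # pragma: no cover - only reachable with pathological banks
        raise CalibrationError("could not draw cross-structure window pairs")

    cross = np.einsum("sni,snj->sij", C[i], C[j])
    scores = np.linalg.det(cross) / np.sqrt(D[i] * D[j])
    scores = np.clip(scores, -1.0, 1.0)
    scores.sort()
    return NullModel(sample_scores=scores, n_samples=n_samples,
                     fragment_length=length, seed=seed)


def p_value(bc: float, null_model: NullModel, tail: str = "upper") -> float:
    """Empirical P-value with add-one smoothing: (1 + #{null at least as
    extreme}) / (n + 1).

    ``tail="upper"`` for similarity hits (large BC); ``tail="lower"`` for
    mirror hits, where extreme means at least as negative.
    """
    s = null_model.sample_scores
    n = len(s)
    if tail == "upper":
        count = n - int(np.searchsorted(s, bc, side="left"))
    elif tail == "lower":
        count = int(np.searchsorted(s, bc, side="right"))
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return (1 + count) / (n + 1)


# ---------------------------------------------------------------------------
# CSV output
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    return "nan" if math.isnan(x) else f"{x:.4f}"


def hits_to_csv(
    hits: Sequence[Hit],
    path: str | Path,
    max_hits: int = 1000,
    null_model: NullModel | None = None,
) -> None:
    """Write a hit table: one row per hit, truncated to the ``max_hits``
    best (the input order, which search already made total).

    Numeric fields carry 4 decimals; comment lines (``#``) record the null
    calibration when one was used.
    """
    path = Path(path)
    with path.open("w", newline="") as fh:
        if null_model is not None:
            fh.write(f"# null: n_samples={null_model.n_samples} "
                     f"length={null_model.fragment_length} seed={null_model.seed}\n")
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for h in hits[:max_hits]:
            writer.writerow([
                h.query_id, h.hit_id, h.q_start, h.q_end, h.h_start, h.h_end,
                _fmt(h.bc), _fmt(h.rigidity), _fmt(h.p_value), _fmt(h.rmsd),
                h.hit_sequence, int(h.is_self),
            ])


# ---------------------------------------------------------------------------
# Sequence logos
# ---------------------------------------------------------------------------

@dataclass
class LogoMatrix:
    """Per-position residue frequencies over the hit sequences.

    ``frequencies`` is (positions, 21) over :data:`LOGO_ALPHABET`; every
    column (position row) sums to 1, or to 0 when there are no sequences.
    """

    frequencies: np.ndarray
    n_sequences: int

    @property
    def alphabet(self) -> str:
        return LOGO_ALPHABET

    def information_content(self) -> np.ndarray:
        """Per-position information (bits) over the 20 standard residues.

        'X' is excluded from the denominator: frequencies are renormalized
        over the standard alphabet before computing 2 - H.
        """
        std = self.frequencies[:, :20]
        totals = std.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(totals > 0, std / totals, 0.0)
            h = -np.where(p > 0, p * np.log2(p), 0.0).sum(axis=1)
        ic = np.log2(20.0) - h
        ic[totals[:, 0] == 0] = 0.0
        return ic


def sequence_logo_matrix(hits: Sequence[Hit]) -> LogoMatrix:
    """Position frequency matrix of the hit sequences.

    All sequences must share one length; residues outside the standard 20
    count as 'X' and are kept in the frequencies.
    """
    seqs = [h.hit_sequence for h in hits]
    if not seqs:
        return LogoMatrix(frequencies=np.zeros((0, len(LOGO_ALPHABET))), n_sequences=0)
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ShapeMismatchError("hit sequences have mixed lengths")
    idx = {a: k for k, a in enumerate(LOGO_ALPHABET)}
    counts = np.zeros((length, len(LOGO_ALPHABET)))
    for s in seqs:
        for j, a in enumerate(s.upper()):
            counts[j, idx.get(a, idx["X"])] += 1
    return LogoMatrix(frequencies=counts / len(seqs), n_sequences=len(seqs))


def logo_to_tsv(logo: LogoMatrix, path: str | Path) -> None:
    """Write the frequency matrix as positions x residues TSV."""
    with Path(path).open("w") as fh:
        fh.write("position\t" + "\t".join(LOGO_ALPHABET) + "\n")
        for j, row in enumerate(logo.frequencies, start=1):
            fh.write(f"{j}\t" + "\t".join(f"{v:.4f}" for v in row) + "\n")
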