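"""Deterministic synthetic Cα structures for testing and calibration.

Every service in this package can be exercised without downloading real
structures: this module generates ideal secondary-structure geometries
(canonical α-helix, near-straight β-strand), protein-like random walks with
fixed 3.8 Å virtual bonds, noise-perturbed and mirrored copies, writes them
as minimal valid PDB files and assembles them into a FragmentBank through
the real parsing path, optionally planting a known query window whose
location is returned as ground truth.

Generated decoys are geometric stand-ins, not physically realistic
conformations: bond angles are protein-like but there is no excluded volume,
hydrogen bonding or side-chain packing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .geometry import Fragment, mirror
from .pdbio import FragmentBank, build_bank

# canonical α-helix Cα parameters: 1.5 Å rise and 100° turn per residue on a
# 2.3 Å radius — chord length ≈ 3.83 Å
HELIX_RISE = 1.5
HELIX_RADIUS = 2.3
HELIX_TURN_DEG = 100.0

# β-strand modeled as a near-straight zig-zag with 3.3 Å rise and a gentle
# right-handed twist (as in real sheets; a perfectly planar zig-zag has no
# 3D volume and no BC score); the zig amplitude keeps consecutive Cα 3.8 Å
# apart
STRAND_RISE = 3.3
STRAND_TWIST_DEG = 15.0
CA_BOND = 3.8

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
    "X": "UNK",
}


@dataclass(frozen=True)
class GeneratorSpec:
    """Recipe for one synthetic structure.

    kind is one of ``helix``, ``strand``, ``random_walk``,
    ``perturbed_copy`` (base fragment + isotropic noise) or
    ``mirrored_copy`` (reflected base fragment).
    """

    kind: str
    length: int = 20
    noise_sigma: float = 0.0
    seed: int = 0
    planted_sequence: Optional[str] = None

    def __post_init__(self):
        if self.length < 4:
            raise ValueError("length must be >= 4")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.kind not in ("helix", "strand", "random_walk",
                             "perturbed_copy", "mirrored_copy"):
            raise ValueError(f"unknown generator kind {self.kind!r}")


# ---------------------------------------------------------------------------
# Fragment generators
# ---------------------------------------------------------------------------

def ideal_helix(n: int, source_id: str = "helix", sequence: str = "") -> Fragment:
    """Cα trace of a canonical right-handed α-helix."""
    if n < 4:
        raise ValueError("helix needs >= 4 residues")
    t = np.deg2rad(HELIX_TURN_DEG) * np.arange(n)
    coords = np.column_stack([
        HELIX_RADIUS * np.cos(t),
        HELIX_RADIUS * np.sin(t),
        HELIX_RISE * np.arange(n),
    ])
    return Fragment(coords=coords, source_id=source_id, chain_id="A",
                    start_res="1", sequence=sequence or "A" * n, end_res=str(n))


def ideal_strand(n: int, source_id: str = "strand", sequence: str = "") -> Fragment:
    """Cα trace of a near-straight twisted β-strand (zig-zag, 3.3 Å rise)."""
    if n < 4:
        raise ValueError("strand needs >= 4 residues")
    omega = np.deg2rad(STRAND_TWIST_DEG)
    amp = math.sqrt(CA_BOND ** 2 - STRAND_RISE ** 2) / (2.0 * math.cos(omega / 2.0))
    k = np.arange(n)
    sign = np.where(k % 2 == 0, 1.0, -1.0)
    coords = np.column_stack([
        STRAND_RISE * k,
        amp * sign * np.cos(omega * k),
        amp * sign * np.sin(omega * k),
    ])
    return Fragment(coords=coords, source_id=source_id, chain_id="A",
                    start_res="1", sequence=sequence or "A" * n, end_res=str(n))


def random_walk_fragment(n: int, seed: int, source_id: str = "",
                         sequence: str = "") -> Fragment:
    """Protein-like random walk: fixed 3.8 Å steps, bond angles uniform in
    [80°, 150°], uniform dihedrals.  Deterministic per seed."""
    if n < 4:
        raise ValueError("walk needs >= 4 residues")
    rng = np.random.default_rng(seed)
    pts = np.zeros((n, 3))
    pts[1] = (CA_BOND, 0.0, 0.0)
    for i in range(2, n):
        b = pts[i - 1] - pts[i - 2]
        b /= np.linalg.norm(b)
        # orthonormal frame around the previous bond
        ref = np.array([0.0, 0.0, 1.0]) if abs(b[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
        u = np.cross(b, ref)
        u /= np.linalg.norm(u)
        v = np.cross(b, u)
        theta = np.deg2rad(rng.uniform(80.0, 150.0))   # angle at the vertex
        phi = rng.uniform(-math.pi, math.pi)
        d = (math.cos(math.pi - theta) * b
             + math.sin(math.pi - theta) * (math.cos(phi) * u + math.sin(phi) * v))
        pts[i] = pts[i - 1] + CA_BOND * d
    return Fragment(coords=pts, source_id=source_id or f"walk{seed}",
                    chain_id="A", start_res="1", sequence=sequence or "A" * n,
                    end_res=str(n))


def perturb(frag: Fragment, sigma: float, seed: int) -> Fragment:
    """Add isotropic Gaussian coordinate noise; deterministic per seed."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return Fragment(coords=frag.coords.copy(), source_id=frag.source_id,
                        chain_id=frag.chain_id, start_res=frag.start_res,
                        sequence=frag.sequence, end_res=frag.end_res)
    rng = np.random.default_rng(seed)
    return Fragment(coords=frag.coords + rng.normal(0.0, sigma, frag.coords.shape),
                    source_id=frag.source_id, chain_id=frag.chain_id,
                    start_res=frag.start_res, sequence=frag.sequence,
                    end_res=frag.end_res)


# ---------------------------------------------------------------------------
# PDB writing
# ---------------------------------------------------------------------------

def write_pdb(path: str | Path,
              chains: Sequence[tuple[str, int | Sequence[int], str, np.ndarray]]) -> None:
    """Write a minimal single-model PDB file.

    ``chains`` is a sequence of (chain_id, numbering, one-letter sequence,
    (N, 3) Cα coordinates) where numbering is either the first residue
    number or an explicit list of residue numbers (e.g. with deletions).
    One CA atom per residue, occupancy 1.00, no altlocs; ATOM + TER + END
    records only.
    """
    lines = []
    serial = 1
    for chain_id, numbering, sequence, coords in chains:
        coords = np.asarray(coords, dtype=float)
        if isinstance(numbering, int):
            numbers = range(numbering, numbering + len(sequence))
        else:
            numbers = list(numbering)
            if len(numbers) != len(sequence):
                raise ValueError("numbering length != sequence length")
        for aa, num, xyz in zip(sequence, numbers, coords):
            res3 = ONE_TO_THREE.get(aa.upper(), "UNK")
            lines.append(
                f"ATOM  {serial:>5d}  CA  {res3:<3s} {chain_id:1s}{num:>4d} "
                f"   {xyz[0]:>8.3f}{xyz[1]:>8.3f}{xyz[2]:>8.3f}"
                f"{1.0:>6.2f}{0.0:>6.2f}          {'C':>2s}"
            )
            serial += 1
        lines.append(f"TER   {serial:>5d}")
        serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_fragment_pdb(path: str | Path, frag: Fragment,
                       chain_id: str = "A", start_num: int = 1) -> None:
    """Convenience: one fragment as a single-chain PDB file."""
    write_pdb(path, [(chain_id, start_num, frag.sequence, frag.coords)])


# ---------------------------------------------------------------------------
# Bank assembly
# ---------------------------------------------------------------------------

def _generate(spec: GeneratorSpec, base: Optional[Fragment]) -> Fragment:
    seq = spec.planted_sequence or ""
    if spec.kind == "helix":
        frag = ideal_helix(spec.length, sequence=seq)
    elif spec.kind == "strand":
        frag = ideal_strand(spec.length, sequence=seq)
    elif spec.kind == "random_walk":
        frag = random_walk_fragment(spec.length, spec.seed, sequence=seq)
    else:
        if base is None:
            raise ValueError(f"kind {spec.kind!r} needs a base fragment")
        frag = mirror(base) if spec.kind == "mirrored_copy" else \
            perturb(base, spec.noise_sigma, spec.seed)
        if seq:
            frag = Fragment(coords=frag.coords, source_id=frag.source_id,
                            chain_id=frag.chain_id, start_res=frag.start_res,
                            sequence=seq, end_res=frag.end_res)
    return frag


def synthetic_bank(
    specs: Sequence[GeneratorSpec],
    out_dir: str | Path,
    planted: Optional[tuple[Fragment, int, int]] = None,
    base: Optional[Fragment] = None,
    manifest: Optional[dict[int, str]] = None,
) -> tuple[FragmentBank, dict]:
    """Write one PDB fixture per spec and build a bank through the real
    parsing path.

    ``planted`` = (fragment, structure index, offset) splices the given
    fragment's coordinates (displaced far from the host so the junctions
    register as chain breaks and the planted window stays intact inside its
    own segment) and sequence into that structure at the 0-based offset.
    ``manifest`` maps a structure index to a classification code.  Returns
    the bank and a ground-truth dict with the planted window's provenance.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth: dict = {"files": [], "structure_ids": []}
    paths = []
    mani: dict[str, tuple[str, str]] = {}
    for k, spec in enumerate(specs):
        frag = _generate(spec, base)
        coords = frag.coords.copy()
        sequence = frag.sequence
        sid = f"synth_{k:03d}"
        if planted is not None and planted[1] == k:
            pfrag, _, offset = planted
            m = len(pfrag)
            if offset < 0 or offset + m > len(coords):
                raise ValueError("planted window does not fit in the host structure")
            block = pfrag.coords - pfrag.coords.mean(axis=0)
            shift = coords[:, 0].max() - coords[:, 0].min() + 500.0
            coords[offset:offset + m] = block + np.array([shift, 0.0, 0.0])
            sequence = sequence[:offset] + pfrag.sequence + sequence[offset + m:]
            truth["planted"] = {
                "structure_id": sid,
                "chain_id": "A",
                "start_num": offset + 1,
                "start_label": str(offset + 1),
                # coordinates as they will read back from the PDB file
                # (3-decimal precision), so identity recovery is exact
                "fragment": Fragment(
                    coords=np.round(coords[offset:offset + m], 3),
                    source_id=sid, chain_id="A",
                    start_res=str(offset + 1), sequence=pfrag.sequence,
                    end_res=str(offset + m),
                ),
            }
        path = out_dir / f"{sid}.pdb"
        write_pdb(path, [("A", 1, sequence, coords)])
        paths.append(path)
        truth["files"].append(str(path))
        truth["structure_ids"].append(sid)
        if manifest and k in manifest:
            mani[path.name] = (sid, manifest[k])
    bank = build_bank(paths, manifest=mani or None)
    return bank, truth
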