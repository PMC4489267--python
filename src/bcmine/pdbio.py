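"""Reading protein structures into Cα chains and building fragment banks.

A structure here is nothing more than its Cα trace: per chain, an ordered
list of (residue label, one-letter code, Cα coordinate) records.  Chains are
split into *segments* — maximal contiguous runs over which sliding windows
may be enumerated — wherever the residue numbering jumps or a consecutive
Cα-Cα distance falls outside the chain-bond gate.  A FragmentBank is the set
of all such segments over a collection of structures, optionally annotated
with SCOP-style classification codes (class.fold.superfamily.family) from a
manifest, so searches can be restricted to e.g. one superfamily.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, NamedTuple, Optional, Sequence

import gemmi
import numpy as np

from .geometry import Fragment

log = logging.getLogger("bcmine")

#: consecutive Cα-Cα distances outside this gate (Å) split a chain.  Centered
#: on the ~3.8 Å virtual bond, wide enough for cis-prolines and distortion,
#: narrow enough to catch unlabeled breaks.
CHAIN_BOND_GATE = (2.5, 4.5)

#: segments shorter than this carry no scorable window and are dropped
MIN_SEGMENT_LEN = 4

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # selenomethionine appears as HETATM but is a standard residue here
    "MSE": "M",
}


class StructureIOError(ValueError):
    """Base class for structure reading / bank errors."""


class ParseError(StructureIOError):
    pass


class EmptyStructureError(StructureIOError):
    pass


class EmptyBankError(StructureIOError):
    pass


class SelectionError(StructureIOError):
    """Query selection did not resolve to a usable fragment."""


class AmbiguousSelectionError(SelectionError):
    pass


class SequenceMismatchError(StructureIOError):
    """Observed residues are not a subsequence of the full sequence."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

class CaRecord(NamedTuple):
    """One residue reduced to its Cα."""

    num: int
    icode: str
    aa: str
    xyz: tuple[float, float, float]

    @property
    def label(self) -> str:
        return f"{self.num}{self.icode}".strip()


@dataclass
class Structure:
    """A structure reduced to per-chain Cα traces, in file order."""

    structure_id: str
    chains: dict[str, list[CaRecord]]

    def chain_sequence(self, chain_id: str) -> str:
        return "".join(r.aa for r in self.chains[chain_id])

    def n_residues(self) -> int:
        return sum(len(v) for v in self.chains.values())


@dataclass
class Segment:
    """A maximal contiguous Cα run; the unit over which windows slide."""

    structure_id: str
    chain_id: str
    residues: list[CaRecord]
    coords: np.ndarray = field(init=False)
    sequence: str = field(init=False)

    def __post_init__(self):
        self.coords = np.array([r.xyz for r in self.residues], dtype=float)
        self.sequence = "".join(r.aa for r in self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def fragment(self, start: int, n: int) -> Fragment:
        """Length-n window beginning at in-segment offset ``start``."""
        if start < 0 or start + n > len(self.residues):
            raise IndexError(f"window [{start}, {start + n}) outside segment of {len(self)}")
        return Fragment(
            coords=self.coords[start:start + n],
            source_id=self.structure_id,
            chain_id=self.chain_id,
            start_res=self.residues[start].label,
            sequence=self.sequence[start:start + n],
            end_res=self.residues[start + n - 1].label,
        )


@dataclass
class FragmentBank:
    """All segments of a structure collection, with optional classification.

    ``manifest`` maps structure_id to its dotted classification code; ids
    absent from the manifest have no code and survive any include filter
    only when no include prefix is given.
    """

    segments: list[Segment]
    manifest: dict[str, str] = field(default_factory=dict)

    @property
    def structure_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for seg in self.segments:
            seen.setdefault(seg.structure_id, None)
        return list(seen)

    @property
    def n_structures(self) -> int:
        return len(self.structure_ids)

    def window_count(self, n: int) -> int:
        return sum(max(0, len(seg) - n + 1) for seg in self.segments)

    def iter_windows(self, n: int) -> Iterator[tuple[Segment, int]]:
        """Yield (segment, start offset) for every length-n window, stride 1."""
        for seg in self.segments:
            for start in range(len(seg) - n + 1):
                yield seg, start

    def filtered(
        self,
        include_sccs: Optional[str] = None,
        exclude_sccs: Optional[str] = None,
    ) -> "FragmentBank":
        """Restrict to structures whose code matches/avoids a dotted prefix."""
        segs = []
        for seg in self.segments:
            code = self.manifest.get(seg.structure_id)
            if include_sccs is not None:
                if code is None or not sccs_matches(code, include_sccs):
                    continue
            if exclude_sccs is not None and code is not None and sccs_matches(code, exclude_sccs):
                continue
            segs.append(seg)
        return FragmentBank(segments=segs, manifest=self.manifest)


def sccs_matches(code: str, prefix: str) -> bool:
    """Dotted-prefix match on component boundaries: g.37 matches g.37.1,
    not g.370."""
    c = code.split(".")
    p = prefix.split(".")
    return len(p) <= len(c) and c[: len(p)] == p


@dataclass
class LoopQuery:
    """Boundary conditions for a gaped-region search.

    Two 4-residue flanks in the template's coordinate frame, the number of
    missing residues between them, and the template's Cα records (with their
    positions along the repaired sequence) for steric-clash screening.
    """

    n_flank: Fragment
    c_flank: Fragment
    gap_length: int
    #: (chain_id, index along the repaired full sequence or None, xyz)
    template_coords: list[tuple[str, Optional[int], tuple[float, float, float]]]
    #: full-sequence indices the missing residues will occupy
    loop_seq_indices: list[int]
    full_sequence: str = ""
    chain_id: str = ""

    def __post_init__(self):
        if len(self.n_flank) != 4 or len(self.c_flank) != 4:
            raise SelectionError("loop flanks must be exactly 4 residues each")
        if self.gap_length < 1:
            raise SelectionError("gap length must be >= 1")


# ---------------------------------------------------------------------------
# Reading PDB files
# ---------------------------------------------------------------------------

def _pick_ca(res: gemmi.Residue) -> Optional[gemmi.Atom]:
    """The single Cα of a residue after altloc resolution.

    Highest occupancy wins; ties break toward altloc 'A'.  Atoms named CA
    that are not carbon (calcium ions) are ignored.
    """
    cands = [a for a in res if a.name == "CA" and a.element.name == "C"]
    if not cands:
        return None
    def key(a: gemmi.Atom):
        alt = a.altloc if a.altloc not in ("\x00", " ") else ""
        return (-a.occ, alt)
    return sorted(cands, key=key)[0]


def read_structure(path: str | Path, structure_id: Optional[str] = None) -> Structure:
    """Read a PDB file into a Cα-trace Structure.

    First MODEL only; one Cα per residue after altloc resolution (highest
    occupancy, ties toward 'A'); residues without a Cα are skipped; HETATM
    residues are kept only when they are standard amino acids (MSE -> M);
    nonstandard ATOM residues get code 'X'.
    """
    path = Path(path)
    sid = structure_id or path.stem
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no model")
    model = st[0]
    chains: dict[str, list[CaRecord]] = {}
    for chain in model:
        records: list[CaRecord] = []
        seen: set[tuple[int, str]] = set()
        for res in chain:
            aa = THREE_TO_ONE.get(res.name)
            if aa is None:
                if res.het_flag == "H":
                    continue  # ligand / water
                aa = "X"
            atom = _pick_ca(res)
            if atom is None:
                continue
            icode = res.seqid.icode.strip()
            if (res.seqid.num, icode) in seen:
                log.warning("%s %s: duplicate residue %s%s, keeping first",
                            sid, chain.name, res.seqid.num, icode)
                continue
            seen.add((res.seqid.num, icode))
            records.append(CaRecord(res.seqid.num, icode, aa,
                                    (atom.pos.x, atom.pos.y, atom.pos.z)))
        if records:
            chains[chain.name] = records
    if not chains:
        raise EmptyStructureError(f"{path}: no Cα atoms")
    return Structure(structure_id=sid, chains=chains)


def read_fasta_sequence(path: str | Path) -> str:
    """First sequence of a FASTA file (or a bare-sequence text file)."""
    from Bio import SeqIO

    path = Path(path)
    try:
        rec = next(SeqIO.parse(str(path), "fasta"), None)
    except (ValueError, OSError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if rec is not None:
        return str(rec.seq).upper()
    text = path.read_text().strip()
    if not text or not re.fullmatch(r"[A-Za-z]+", text.replace("\n", "")):
        raise ParseError(f"{path}: no FASTA record or plain sequence found")
    return text.replace("\n", "").upper()


# ---------------------------------------------------------------------------
# Segments
# ---------------------------------------------------------------------------

def _numbering_consecutive(prev: CaRecord, cur: CaRecord) -> bool:
    # insertion-code runs (15, 15A, 15B, 16) count as consecutive
    if cur.num == prev.num + 1:
        return True
    return cur.num == prev.num and cur.icode != prev.icode


def contiguous_segments(structure: Structure, min_len: int = MIN_SEGMENT_LEN) -> list[Segment]:
    """Split chains into maximal contiguous runs.

    A break is declared wherever the numbering jumps or a consecutive Cα-Cα
    distance falls outside the chain-bond gate.  Runs shorter than
    ``min_len`` are dropped.
    """
    lo, hi = CHAIN_BOND_GATE
    segments: list[Segment] = []
    for chain_id, records in structure.chains.items():
        run: list[CaRecord] = []
        for rec in records:
            if run:
                prev = run[-1]
                d = float(np.linalg.norm(np.subtract(rec.xyz, prev.xyz)))
                if not _numbering_consecutive(prev, rec) or not (lo <= d <= hi):
                    if len(run) >= min_len:
                        segments.append(Segment(structure.structure_id, chain_id, run))
                    run = []
            run.append(rec)
        if len(run) >= min_len:
            segments.append(Segment(structure.structure_id, chain_id, run))
    return segments


# ---------------------------------------------------------------------------
# Bank building
# ---------------------------------------------------------------------------

def read_manifest(path: str | Path) -> dict[str, tuple[str, str]]:
    """TSV with columns file_path, domain_id, sccs_code.

    Returns a map from file basename (and full path) to (domain_id, code).
    A header row is recognized and skipped.
    """
    out: dict[str, tuple[str, str]] = {}
    for i, line in enumerate(Path(path).read_text().splitlines()):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ParseError(f"{path}:{i + 1}: expected 3 tab-separated columns")
        fp, domain_id, code = parts[0], parts[1], parts[2]
        if i == 0 and fp.lower() == "file_path":
            continue
        out[fp] = (domain_id, code)
        out[Path(fp).name] = (domain_id, code)
    return out


def build_bank(
    paths: Sequence[str | Path],
    manifest: Optional[str | Path | dict] = None,
) -> FragmentBank:
    """Read a collection of PDB files into a FragmentBank.

    Unreadable files are logged and skipped, never fatal; zero readable
    structures is an error.  When a manifest maps a file to a domain id, the
    domain id becomes the structure_id and the classification code is
    attached.
    """
    mani: dict[str, tuple[str, str]] = {}
    if manifest is not None:
        mani = manifest if isinstance(manifest, dict) else read_manifest(manifest)
    segments: list[Segment] = []
    codes: dict[str, str] = {}
    n_read = 0
    for p in paths:
        p = Path(p)
        entry = mani.get(str(p)) or mani.get(p.name)
        sid = entry[0] if entry else p.stem
        try:
            st = read_structure(p, structure_id=sid)
        except StructureIOError as exc:
            log.warning("skipping unreadable structure %s: %s", p, exc)
            continue
        n_read += 1
        if entry:
            codes[sid] = entry[1]
        segments.extend(contiguous_segments(st))
    if n_read == 0:
        raise EmptyBankError("no readable structure in the collection")
    return FragmentBank(segments=segments, manifest=codes)


# ---------------------------------------------------------------------------
# Query selection
# ---------------------------------------------------------------------------

_RANGE_RE = re.compile(r"^([^:]+):(-?\d+)([A-Za-z]?)\s*[-–]\s*(-?\d+)([A-Za-z]?)$")


def extract_query_fragment(structure: Structure, selection: str) -> Fragment:
    """Resolve a selection to one contiguous fragment of >= 4 residues.

    Two selection syntaxes:

    * a residue range ``CHAIN:START-END`` (labels as printed in the file,
      insertion codes allowed), e.g. ``A:15-37``;
    * a sequence substring, matched against every contiguous segment; the
      match must be unique across the structure.
    """
    m = _RANGE_RE.match(selection.strip())
    if m:
        return _extract_range(structure, m.group(1), (int(m.group(2)), m.group(3)),
                              (int(m.group(4)), m.group(5)))
    return _extract_substring(structure, selection.strip().upper())


def _extract_range(structure, chain_id, start_key, end_key) -> Fragment:
    segments = [s for s in contiguous_segments(structure, min_len=1)
                if s.chain_id == chain_id]
    if not segments:
        raise SelectionError(f"no chain {chain_id!r} in {structure.structure_id}")
    for seg in segments:
        keys = [(r.num, r.icode) for r in seg.residues]
        if start_key in keys and end_key in keys:
            i, j = keys.index(start_key), keys.index(end_key)
            if j < i:
                raise SelectionError("range end precedes range start")
            n = j - i + 1
            if n < 4:
                raise SelectionError(f"selection spans {n} residues; need >= 4")
            return seg.fragment(i, n)
    raise SelectionError(
        f"range {chain_id}:{start_key[0]}{start_key[1]}-{end_key[0]}{end_key[1]} "
        f"does not resolve to one contiguous run in {structure.structure_id}"
    )


def _extract_substring(structure, sub: str) -> Fragment:
    if len(sub) < 4 or not sub.isalpha():
        raise SelectionError("sequence selection must be >= 4 residue letters")
    matches: list[tuple[Segment, int]] = []
    for seg in contiguous_segments(structure, min_len=1):
        start = 0
        while True:
            i = seg.sequence.find(sub, start)
            if i < 0:
                break
            matches.append((seg, i))
            start = i + 1
    if not matches:
        raise SelectionError(f"sequence {sub!r} not found in any contiguous segment")
    if len(matches) > 1:
        where = ", ".join(f"{s.chain_id}:{s.residues[i].label}" for s, i in matches)
        raise AmbiguousSelectionError(f"sequence {sub!r} matches at {where}")
    seg, i = matches[0]
    return seg.fragment(i, len(sub))


# ---------------------------------------------------------------------------
# Gap detection
# ---------------------------------------------------------------------------

@dataclass
class GapRecord:
    """One maximal run of residues present in the full sequence but missing
    from the structure."""

    chain_id: str
    seq_start: int      # 0-based index in the full sequence of the first missing residue
    length: int
    n_flank: list[CaRecord]   # up to 4 observed residues before the gap
    c_flank: list[CaRecord]   # up to 4 observed residues after the gap
    searchable: bool          # both flanks have 4 observed residues


def _observed_runs(records: list[CaRecord]) -> list[list[CaRecord]]:
    runs: list[list[CaRecord]] = []
    cur: list[CaRecord] = []
    for rec in records:
        if cur and not _numbering_consecutive(cur[-1], rec):
            runs.append(cur)
            cur = []
        cur.append(rec)
    if cur:
        runs.append(cur)
    return runs


def _align_runs(full_sequence: str, runs: list[list[CaRecord]], chain_id: str) -> list[int]:
    """Greedy left-to-right exact placement of observed runs in the full
    sequence; returns the start index of each run."""
    placements: list[int] = []
    pos = 0
    for run in runs:
        seq = "".join(r.aa for r in run)
        idx = full_sequence.find(seq, pos)
        if idx < 0:
            raise SequenceMismatchError(
                f"chain {chain_id}: observed residues starting at {run[0].label} "
                f"({seq[:10]}...) are not a subsequence of the full sequence "
                f"after position {pos}"
            )
        placements.append(idx)
        pos = idx + len(run)
    return placements


def detect_gaps(full_sequence: str, structure: Structure) -> list[GapRecord]:
    """Find missing regions by comparing the full sequence to the structure.

    Each maximal run of residues present in ``full_sequence`` but absent
    from the structure yields one record with the gap length and the 4
    observed residues on each side.  Gaps with fewer than 4 observed
    residues on either side (including chain termini) are reported but
    flagged un-searchable.
    """
    full_sequence = full_sequence.upper()
    gaps: list[GapRecord] = []
    for chain_id, records in structure.chains.items():
        if len(records) > len(full_sequence):
            raise SequenceMismatchError(
                f"chain {chain_id}: structure has more residues than the full sequence"
            )
        runs = _observed_runs(records)
        placements = _align_runs(full_sequence, runs, chain_id)
        # leading gap
        if placements and placements[0] > 0:
            gaps.append(GapRecord(chain_id, 0, placements[0], [], runs[0][:4], False))
        for k in range(len(runs) - 1):
            end_k = placements[k] + len(runs[k])
            L = placements[k + 1] - end_k
            if L <= 0:
                continue
            n_fl = runs[k][-4:]
            c_fl = runs[k + 1][:4]
            gaps.append(GapRecord(chain_id, end_k, L, n_fl, c_fl,
                                  len(n_fl) == 4 and len(c_fl) == 4))
        # trailing gap
        if runs:
            end_last = placements[-1] + len(runs[-1])
            if end_last < len(full_sequence):
                gaps.append(GapRecord(chain_id, end_last,
                                      len(full_sequence) - end_last,
                                      runs[-1][-4:], [], False))
    return gaps


def make_loop_query(structure: Structure, full_sequence: str, gap: GapRecord) -> LoopQuery:
    """Assemble the boundary conditions for searching one detected gap."""
    if not gap.searchable:
        raise SelectionError(
            f"gap at sequence position {gap.seq_start} in chain {gap.chain_id} "
            "lacks 4 observed residues on one side and cannot be searched"
        )
    full_sequence = full_sequence.upper()
    template: list[tuple[str, Optional[int], tuple[float, float, float]]] = []
    for chain_id, records in structure.chains.items():
        if chain_id == gap.chain_id:
            runs = _observed_runs(records)
            placements = _align_runs(full_sequence, runs, chain_id)
            for run, start in zip(runs, placements):
                for off, rec in enumerate(run):
                    template.append((chain_id, start + off, rec.xyz))
        else:
            # other chains carry no sequence relationship to the repaired chain
            for rec in records:
                template.append((chain_id, None, rec.xyz))

    def _flank_fragment(records: list[CaRecord]) -> Fragment:
        return Fragment(
            coords=np.array([r.xyz for r in records], dtype=float),
            source_id=structure.structure_id,
            chain_id=gap.chain_id,
            start_res=records[0].label,
            sequence="".join(r.aa for r in records),
            end_res=records[-1].label,
        )

    return LoopQuery(
        n_flank=_flank_fragment(gap.n_flank),
        c_flank=_flank_fragment(gap.c_flank),
        gap_length=gap.length,
        template_coords=template,
        loop_seq_indices=list(range(gap.seq_start, gap.seq_start + gap.length)),
        full_sequence=full_sequence,
        chain_id=gap.chain_id,
    )
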