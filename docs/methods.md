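# Methods

## The scores

All comparisons operate on Cα traces only. Two fragments of equal length N
are stored as N × 3 coordinate matrices X and Y, each translated so its
centroid is at the origin. The similarity score is the Binet–Cauchy (BC)
kernel correlation

    BC(X, Y) = det(XᵀY) / √(det(XᵀX) · det(YᵀY)),

the cosine between the Grassmann vectors of the two point sets. It is
invariant to rotation (but not reflection) of either argument, equals 1 for
identical shapes, is close to 0 for unrelated conformations and equals −1
for mirror images: reflecting one argument flips the sign of det(XᵀY) and
nothing else. Because the score compares 3 × 3 determinants regardless of N,
one comparison costs O(N) and a bank scan vectorizes into batched 3 × 3
determinants.

BC is deliberately flexible — it is blind to uniform scaling and tolerates
some shape-preserving distortion. The companion rigidity score bounds that
flexibility:

    R'(X, Y) = max_i | ‖X_i‖ − ‖Y_i‖ |
    R(X, Y)  = max( R'(X, Y), | ‖X_N − X_1‖ − ‖Y_N − Y_1‖ | ),

the maximum variation (Å) of residue-to-centroid distances plus the
terminal-to-terminal distance. It is zero for rigidly superposable
fragments, invariant to rotation *and* reflection, and positive for scaled
copies, which is exactly the failure mode of BC it exists to catch.

### Degeneracy

BC divides by det(XᵀX); a collinear or coplanar point set makes it
undefined. A fragment is declared degenerate when
det(XᵀX) < 1e-6 · (tr(XᵀX)/3)³. The criterion is relative, hence unit-safe.
Degenerate bank windows are skipped with a logged count; a degenerate query
is a hard error. Fewer than 4 points are always rejected (3 centered points
span at most a plane). Scores are clamped to [−1, 1]; an excursion beyond
1e-6 triggers a warning, as it would indicate more than rounding noise.

### Superposition

Reported RMSDs come from Kabsch superposition (SVD of XcᵀYc, with the
smallest singular direction flipped when the unconstrained optimum is a
reflection, so the rotation is always proper). Scoring itself never uses
superposition — that is the point of the method — but each reported hit
carries the RMSD to the query (to the *mirrored* query for mirror hits).

## The services

All four services enumerate every stride-1 window of every contiguous
segment of the bank; overlapping hits are all reported and self-windows are
flagged, not removed.

* **Fragment search** — hit iff BC ≥ bc_cutoff and rigidity ≤
  rigidity_cutoff; sorted by BC descending.
* **Mirror search** — hit iff BC ≤ −bc_cutoff and rigidity ≤
  rigidity_cutoff (rigidity is reflection-invariant and computed directly);
  sorted by BC ascending.
* **Loop search** — for a gap of L missing residues, every bank window of
  length 4 + L + 4 is matched on its two 4-residue flanks. The 8 flank Cα
  are centered *jointly* (one centroid for the 8-point set), which is what
  makes the score constrain the relative placement of the two flanks and
  hence the span of the gap. Passing windows are grafted into the template
  frame by Kabsch superposition of the 8 flank atoms, then screened for
  clashes: a candidate is discarded if any loop Cα lies within 3.0 Å of a
  template Cα at least 3 positions away along the repaired sequence
  (residues on other chains carry no sequence relationship and are always
  checked; intra-loop clashes are not checked). Reported BC/rigidity/RMSD
  are flank-based.
* **Specificity profiling** — for each window of size w (default 9) of a
  whole query structure, a fragment search against the bank is summarized
  as sp = 1 − N_hits/N_total, where N_hits counts *distinct bank proteins*
  with ≥ 1 matching window (one protein, one count) and N_total is the
  number of proteins in the (classification-filtered) bank. A residue's
  score is the maximum sp over windows covering it: a residue is specific
  if it belongs to at least one rare fragment. Degenerate query windows get
  sp = NaN rather than a fabricated value.

Hit ordering is a total order — score, then rigidity ascending, then hit
id, chain and start residue — so repeated runs are byte-identical.

## Parameters

| parameter | default | meaning |
|---|---|---|
| bc_cutoff | 0.95 | minimum BC (maximum −BC for mirror search) |
| rigidity_cutoff | 1.0 Å | maximum rigidity score |
| max_hits | 1000 | hit-table truncation (best of the total order) |
| clash_cutoff | 3.0 Å | loop-candidate Cα–Cα rejection distance |
| min_seq_sep | 3 | sequence separation below which clashes are exempt |
| window_size | 9 | fragment size for specificity profiling |

The 0.95/1.0 pair is the standard operating point of the method; 3.0 Å /
3 positions is the published clash rule; 9 residues is the standard
profiling window. The chain-break gate [2.5, 4.5] Å around the 3.8 Å
virtual Cα–Cα bond tolerates cis-prolines and distortion while catching
unlabeled breaks.

## P-values

No closed-form null is assumed. For a given fragment length, the null is
calibrated empirically: n_samples (default 10000) window pairs drawn
uniformly with replacement from *distinct* structures of the bank, scored
by BC. A hit's P-value is the add-one smoothed upper tail,
(1 + #{null ≥ bc}) / (n + 1); mirror hits use the symmetric lower tail. The
calibration seed, length and sample count are recorded as comments in the
CSV header. P-values of null-drawn scores are uniform by construction
(checked by a Kolmogorov–Smirnov test in the suite).

One consequence worth stating plainly: the *raw* BC null distribution
concentrates as N grows (a Grassmann-cosine concentration effect), so raw
null quantiles at different lengths do not coincide. Size-independence of
significance holds here only through the per-length calibration — each
length gets its own null, and the P-value scale is comparable across
lengths even though the score scale is not. A closed-form, size-normalized
significance law could be swapped in behind the same `NullModel` interface.

## Structure input conventions

PDB files are parsed with gemmi, first MODEL only, one Cα per residue.
Altloc resolution keeps the highest occupancy, ties broken toward label
'A'. Residues without a Cα are skipped; HETATM residues are kept only when
they are standard amino acids (MSE → M); nonstandard ATOM residues are kept
with code 'X'. Atoms named CA that are not carbon (calcium ions) are
ignored. Residue identity is (chain, number, insertion code) exactly as
printed — no renumbering — and hit tables report the file's labels. Chains
are split into segments at numbering jumps and at bond-gate violations;
windows never span a segment boundary. Classification filtering uses a TSV
manifest (file_path, domain_id, sccs_code) with dotted-prefix matching on
component boundaries (g.37 matches g.37.1, not g.370).

Gap detection compares the chain's observed residues with the supplied full
sequence by greedy exact placement of each numbering-contiguous run, left to
right. This presumes the deposited sequence is identical to the full
sequence (no scoring-matrix alignment); a run that cannot be placed is a
hard mismatch error. Gaps with fewer than 4 observed residues on either
side — including chain termini — are reported but flagged un-searchable.

## Synthetic data

The fixture generator emulates the geometry the services care about and
nothing more: canonical α-helices (rise 1.5 Å, radius 2.3 Å, 100°/residue),
β-strands as near-straight zig-zags (3.3 Å rise) with a gentle 15°/residue
twist — a perfectly planar zig-zag has no 3D volume and no BC score, and
real sheets are twisted anyway — and random walks with exact 3.8 Å virtual
bonds and vertex angles uniform in [80°, 150°]. Decoy banks of 5–10
structures of 25–44 residues keep every bank below a few hundred windows,
which is what lets the exhaustive naive oracles verify the vectorized
services window-by-window while the whole suite runs in seconds.

Planting splices a query window into a host structure displaced so the
junctions register as chain breaks, leaving the planted window intact in
its own segment; the ground truth records the window's provenance and its
coordinates exactly as they round-trip through the 3-decimal PDB format, so
identity recovery is exact (BC = 1, rigidity = 0, RMSD = 0), not
approximate.

What passing these tests does *not* show: the decoys have no excluded
volume, hydrogen bonding, side chains or realistic Ramachandran statistics,
so null distributions calibrated on them need not match those of real
protein banks, and clash-screen behavior on real packed cores is only
exercised by the engineered obstacle fixtures. The published worked
examples (zinc-finger mining, the von Willebrand loop, trypsin specificity)
require SCOPe/PDB data and are scripted separately
(`scripts/reproduce_applications.py`).

## Known limitations

* Ungapped matching only; no indel tolerance in any service.
* Loop candidates are pruned geometrically, not scored energetically;
  ranking among surviving candidates is by flank BC only.
* mmCIF, assemblies and symmetry are out of scope; PDB format only.
* Specificity profiling re-searches the bank per window; cost grows with
  query length × bank size (fine for domain-scale queries and desk-scale
  banks; the per-window searches are embarrassingly parallel if it ever
  matters).
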